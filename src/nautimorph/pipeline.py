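"""End-to-end pipeline: simulate -> landmark -> slide -> align -> ordinate ->
trees -> stats, from a single configuration.

Every intermediate is an open text format (TPS landmarks, CSV tables, Newick
trees), so digitized landmark data from real specimens can replace the
simulator without code changes.  The run manifest records the configuration
hash, seed, and a checksum per produced file: identical configuration and
seed yield identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bending import bending_energy_matrix, slide_semilandmarks
from .generate import generate_dataset, SyntheticDataset
from .geometry import resample_equidistant
from .njtree import PhenogramTree, neighbor_joining
from .ordination import DistanceMatrix, PCAResult, pc_distance_matrix, pca
from .params import ConfigurationError, ShellParams, SpeciesSpec, default_species_specs
from .procrustes import ProcrustesResult, gpa
from .septal import (
    anova_oneway,
    assign_stage,
    pairwise_comparisons,
    select_stage_points,
)
from .tpsio import write_tps

__all__ = ["PipelineConfig", "PipelineRun", "RunManifest", "run_pipeline"]

log = logging.getLogger(__name__)

CHARACTERS = ("suture", "conch_geometry", "septal_spacing")
STAGES = ("pre_hatching", "middle", "maturity")


@dataclass
class PipelineConfig:
    """Pipeline configuration; the defaults reproduce the study design
    constants (20 suture landmarks, 40 outline landmarks, sections every 45
    degrees, stage proxies at 20 mm / 50 mm / maximum diameter, pre-hatching
    below 30 mm, maturity = last two chambers)."""

    species: list = field(default_factory=default_species_specs)
    n_per_species: int = 2
    seed: int = 0
    k_suture: int = 20
    k_section: int = 40
    section_step_deg: float = 45.0
    start_rule: str = "ventral"
    slide_max_iter: int = 10
    slide_tol: float = 1e-8
    stage_targets: dict = field(
        default_factory=lambda: {"pre_hatching": 20.0, "middle": 50.0, "maturity": "max"}
    )
    pre_hatching_max_diameter: float = 30.0
    alpha: float = 0.05
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.n_per_species < 1:
            raise ConfigurationError("n_per_species must be at least 1")
        if self.k_suture < 3 or self.k_section < 3:
            raise ConfigurationError("landmark counts must be at least 3")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if set(self.stage_targets) != set(STAGES):
            raise ConfigurationError(f"stage_targets must define exactly {STAGES}")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["species"] = [
            {
                "name": s.name,
                "region": s.region,
                "code": s.code,
                "params": asdict(s.mean_params),
                "intraspecific_cv": s.intraspecific_cv,
                "landmark_noise_sd": s.landmark_noise_sd,
            }
            for s in self.species
        ]
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        gen = raw.pop("generator", {})
        lm = raw.pop("landmarks", {})
        sl = raw.pop("sliding", {})
        st = raw.pop("stages", {})
        stats = raw.pop("stats", {})
        kw: dict = {}
        species = gen.get("species", raw.pop("species", "default"))
        if species == "default" or species is None:
            kw["species"] = default_species_specs()
        else:
            kw["species"] = [
                s
                if isinstance(s, SpeciesSpec)
                else SpeciesSpec(
                    name=s["name"],
                    region=s.get("region", ""),
                    code=s.get("code", s["name"]),
                    mean_params=ShellParams(**{
                        k: tuple(v) if k == "section_shape_coeffs" else v
                        for k, v in s.get("params", {}).items()
                    }),
                    intraspecific_cv=s.get("intraspecific_cv", 0.0),
                    landmark_noise_sd=s.get("landmark_noise_sd", 0.0),
                )
                for s in species
            ]
        for key, target in (
            ("n_per_species", gen), ("seed", gen),
            ("k_suture", lm), ("k_section", lm),
            ("section_step_deg", lm), ("start_rule", lm),
        ):
            if key in target:
                kw[key] = target[key]
        if "max_iter" in sl:
            kw["slide_max_iter"] = sl["max_iter"]
        if "tol" in sl:
            kw["slide_tol"] = sl["tol"]
        targets = {k: st[k] for k in STAGES if k in st}
        if targets:
            base = {"pre_hatching": 20.0, "middle": 50.0, "maturity": "max"}
            base.update(targets)
            kw["stage_targets"] = base
        if "pre_hatching_max_diameter" in st:
            kw["pre_hatching_max_diameter"] = st["pre_hatching_max_diameter"]
        if "alpha" in stats:
            kw["alpha"] = stats["alpha"]
        for key in ("seed", "outdir", "n_per_species"):
            if key in raw:
                kw[key] = raw[key]
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # where results land is not part of the analysis
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    files: dict  # relative path -> sha256
    timing_s: dict


@dataclass
class CharacterResult:
    """Morphometric results of one character (suture or conch geometry)."""

    name: str
    meta: pd.DataFrame          # label, specimen_id, group, index, diameter_mm
    reference_label: str
    gpa_result: ProcrustesResult
    pca_result: PCAResult
    trees: dict                  # stage name (or "pooled") -> PhenogramTree


@dataclass
class SeptalResult:
    table: pd.DataFrame          # specimen, group, chamber, angle, diameter, stage
    trees: dict
    anova: dict                  # stage -> AnovaResult
    pairwise: dict               # stage -> list[PairwiseComparison]


@dataclass
class PipelineRun:
    config: PipelineConfig
    dataset: SyntheticDataset
    characters: dict             # name -> CharacterResult
    septal: SeptalResult
    manifest: RunManifest | None = None


# ---------------------------------------------------------------------------
# landmarking and sliding


def landmark_dataset(dataset: SyntheticDataset, config: PipelineConfig):
    """Resample every suture and cross-section into landmark configurations.

    Returns {character: (configs, curves, meta DataFrame)}.
    """
    out = {}
    for char, k in (("suture", config.k_suture), ("conch_geometry", config.k_section)):
        configs, curves, rows = [], [], []
        for rec in dataset.specimens:
            if char == "suture":
                pairs = zip(rec.suture_curves, rec.chamber_numbers)
                diams = rec.diameters_at_chamber
            else:
                pairs = zip(rec.section_outlines, range(len(rec.section_outlines)))
                diams = rec.diameters_at_section
            for (curve, idx), d in zip(pairs, diams):
                cfg = resample_equidistant(curve, k, start_rule=config.start_rule)
                configs.append(cfg)
                curves.append(curve)
                rows.append(
                    {
                        "label": cfg.label,
                        "specimen_id": rec.specimen_id,
                        "group": rec.group,
                        "index": int(idx),
                        "diameter_mm": float(d),
                    }
                )
        out[char] = (configs, curves, pd.DataFrame(rows))
    return out


def choose_reference(configs) -> int:
    """Index of the reference configuration for sliding: median centroid
    size, ties broken by label (deterministic)."""
    order = sorted(range(len(configs)), key=lambda i: (configs[i].centroid_size, configs[i].label))
    return order[(len(order) - 1) // 2]


def slide_character(configs, curves, config: PipelineConfig):
    ref_idx = choose_reference(configs)
    model = bending_energy_matrix(configs[ref_idx])
    slid = slide_semilandmarks(
        configs,
        curves,
        model,
        max_iter=config.slide_max_iter,
        tol=config.slide_tol,
    )
    return slid, configs[ref_idx].label


# ---------------------------------------------------------------------------
# stage selection and trees


def stage_labels(meta: pd.DataFrame, target) -> list[str]:
    """Two configuration labels per specimen, closest to the target diameter
    (or the last two for maturity)."""
    labels = []
    for _, grp in meta.groupby("specimen_id", sort=True):
        grp = grp.sort_values("index")
        i, j = select_stage_points(grp["diameter_mm"].to_numpy(), target)
        labels.extend([grp["label"].iloc[i], grp["label"].iloc[j]])
    return labels


def character_trees(pca_result: PCAResult, meta: pd.DataFrame, stage_targets: dict) -> dict:
    trees = {"pooled": neighbor_joining(pc_distance_matrix(pca_result))}
    for stage, target in stage_targets.items():
        labels = stage_labels(meta, target)
        trees[stage] = neighbor_joining(pc_distance_matrix(pca_result, labels))
    return trees


def septal_frame(dataset: SyntheticDataset, pre_hatching_max_diameter: float = 30.0) -> pd.DataFrame:
    """Long table of septal angles: one row per chamber per specimen."""
    rows = []
    for rec in dataset.specimens:
        stages = assign_stage(rec, pre_hatching_max_diameter).stages
        for c, angle, d, stage in zip(
            rec.chamber_numbers, rec.septal_angles, rec.diameters_at_chamber, stages
        ):
            rows.append(
                {
                    "specimen_id": rec.specimen_id,
                    "species": rec.species,
                    "region": rec.region,
                    "group": rec.group,
                    "chamber": int(c),
                    "angle_deg": float(angle),
                    "diameter_mm": float(d),
                    "stage": stage,
                    "label": f"{rec.specimen_id}|ch{int(c):02d}",
                }
            )
    return pd.DataFrame(rows)


def _septal_distance_matrix(frame: pd.DataFrame) -> DistanceMatrix:
    """Septal spacing is scalar, so tip distance is the absolute difference
    of angles between configuration tips."""
    vals = frame["angle_deg"].to_numpy()
    D = np.abs(vals[:, None] - vals[None, :])
    return DistanceMatrix(labels=frame["label"].tolist(), values=D)


def septal_trees(frame: pd.DataFrame, stage_targets: dict) -> dict:
    trees = {"pooled": neighbor_joining(_septal_distance_matrix(frame))}
    for stage, target in stage_targets.items():
        rows = []
        for _, grp in frame.groupby("specimen_id", sort=True):
            grp = grp.sort_values("chamber")
            i, j = select_stage_points(grp["diameter_mm"].to_numpy(), target)
            rows.append(grp.iloc[[i, j]])
        sub = pd.concat(rows, ignore_index=True)
        trees[stage] = neighbor_joining(_septal_distance_matrix(sub))
    return trees


def septal_stage_stats(frame: pd.DataFrame, alpha: float):
    """Per-stage one-way ANOVA across groups plus Tukey-Kramer pairs."""
    anova, pairwise = {}, {}
    for stage in (
        "pre_hatching",
        "juvenile_submature",
        "mature",
    ):
        sub = frame[frame["stage"] == stage]
        groups = {g: grp["angle_deg"].to_numpy() for g, grp in sub.groupby("group", sort=True)}
        anova[stage] = anova_oneway(groups)
        pairwise[stage] = pairwise_comparisons(groups, alpha=alpha)
    return anova, pairwise


# ---------------------------------------------------------------------------
# outputs


def _write_outputs(outdir: Path, run: PipelineRun) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def register(path: Path):
        files[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    for char, res in run.characters.items():
        tps = outdir / f"landmarks_{char}.tps"
        write_tps(res.gpa_result.aligned, tps, fmt="%.17g")
        register(tps)

        scores = pd.DataFrame(
            res.pca_result.scores,
            columns=[f"PC{i + 1}" for i in range(res.pca_result.scores.shape[1])],
        )
        scores.insert(0, "label", res.pca_result.labels)
        merged = res.meta.merge(scores, on="label")
        csv = outdir / f"pc_scores_{char}.csv"
        merged.to_csv(csv, index=False, float_format="%.17g")
        register(csv)

        resid = pd.DataFrame(
            res.gpa_result.residuals,
            columns=[f"r{i}" for i in range(res.gpa_result.residuals.shape[1])],
        )
        resid.insert(0, "label", res.gpa_result.labels)
        rcsv = outdir / f"procrustes_residuals_{char}.csv"
        resid.to_csv(rcsv, index=False, float_format="%.17g")
        register(rcsv)

        for stage, tree in res.trees.items():
            nwk = outdir / f"tree_{char}_{stage}.nwk"
            nwk.write_text(tree.newick())
            register(nwk)

    septal_csv = outdir / "septal_angles.csv"
    run.septal.table.to_csv(septal_csv, index=False, float_format="%.17g")
    register(septal_csv)
    for stage, tree in run.septal.trees.items():
        nwk = outdir / f"tree_septal_spacing_{stage}.nwk"
        nwk.write_text(tree.newick())
        register(nwk)

    anova_rows = [
        {
            "stage": stage,
            "F": a.F,
            "df_between": a.df_between,
            "df_within": a.df_within,
            "p_value": a.p_value,
        }
        for stage, a in run.septal.anova.items()
    ]
    anova_csv = outdir / "anova_septal_spacing.csv"
    pd.DataFrame(anova_rows).to_csv(anova_csv, index=False, float_format="%.17g")
    register(anova_csv)

    pair_rows = [
        {
            "stage": stage,
            "group_a": c.group_a,
            "group_b": c.group_b,
            "mean_difference_deg": c.mean_difference,
            "interval_low_deg": c.adjusted_interval[0],
            "interval_high_deg": c.adjusted_interval[1],
            "adjusted_p": c.adjusted_p,
            "significant": c.significant,
        }
        for stage, comps in run.septal.pairwise.items()
        for c in comps
    ]
    pair_csv = outdir / "pairwise_septal_spacing.csv"
    pd.DataFrame(pair_rows).to_csv(pair_csv, index=False, float_format="%.17g")
    register(pair_csv)
    return files


# ---------------------------------------------------------------------------
# driver


def run_pipeline(config: PipelineConfig) -> PipelineRun:
    """Run the full analysis and (if config.outdir is set) write all outputs.

    Emits, per character (suture, conch geometry, septal spacing) and per
    stage (pooled, pre-hatching, middle, maturity): PC score CSVs, Newick
    trees, and ANOVA/pairwise tables, plus a manifest with checksums.
    """
    timing: dict[str, float] = {}
    t0 = time.perf_counter()
    dataset = generate_dataset(
        config.species,
        n_per_species=config.n_per_species,
        seed=config.seed,
        section_step_deg=config.section_step_deg,
    )
    timing["simulate"] = time.perf_counter() - t0
    log.info("simulate: %d specimens from %d species specs", len(dataset.specimens), len(config.species))

    characters: dict[str, CharacterResult] = {}
    landmarked = landmark_dataset(dataset, config)
    for char, (configs, curves, meta) in landmarked.items():
        t1 = time.perf_counter()
        slid, ref_label = slide_character(configs, curves, config)
        gpa_result = gpa(slid)
        pca_result = pca(gpa_result.residuals, gpa_result.labels)
        trees = character_trees(pca_result, meta, config.stage_targets)
        timing[char] = time.perf_counter() - t1
        log.info(
            "%s: %d configurations, reference %s, %d PCs",
            char, len(configs), ref_label, pca_result.scores.shape[1],
        )
        characters[char] = CharacterResult(
            name=char,
            meta=meta,
            reference_label=ref_label,
            gpa_result=gpa_result,
            pca_result=pca_result,
            trees=trees,
        )

    t2 = time.perf_counter()
    frame = septal_frame(dataset, config.pre_hatching_max_diameter)
    trees = septal_trees(frame, config.stage_targets)
    anova, pairwise = septal_stage_stats(frame, config.alpha)
    septal = SeptalResult(table=frame, trees=trees, anova=anova, pairwise=pairwise)
    timing["septal_spacing"] = time.perf_counter() - t2

    run = PipelineRun(config=config, dataset=dataset, characters=characters, septal=septal)

    files: dict[str, str] = {}
    if config.outdir is not None:
        outdir = Path(config.outdir)
        files = _write_outputs(outdir, run)
    run.manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        version=__version__,
        files=files,
        timing_s={k: round(v, 3) for k, v in timing.items()},
    )
    if config.outdir is not None:
        manifest_path = Path(config.outdir) / "manifest.json"
        manifest_path.write_text(json.dumps(asdict(run.manifest), indent=2, sort_keys=True) + "\n")
    return run
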