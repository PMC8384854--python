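"""Synthetic nautilid conch generator.

Produces per-specimen ontogenetic series of closed 3D suture curves and
closed 2D whorl cross-section outlines indexed by conch diameter, together
with a septal-spacing schedule showing the three features seen in nautilid
ontogeny: a steep pre-hatching rise in septal angle followed by a steep drop
(>= 20%) at the hatching chamber, a stable mid-ontogeny band at 20-30
degrees, and terminal crowding of the last few septa.

Geometry: conch diameter grows as d(theta) = d0 * W^(theta/360) along a
logarithmic spiral about the z axis; the whorl cross-section is a
harmonically deformed ellipse between the venter (outermost point) and the
umbilical seam; the suture follows the outline, displaced adapically by one
shallow lateral lobe per flank.  Embryonic (pre-hatching) cross-sections
carry a distinct drop-like shape component that is shed at hatching, and
species-specific shape differences unfold gradually through ontogeny — so
juveniles of different species are nearly indistinguishable while adults
separate, as in real nautilids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import __version__
from .geometry import Curve
from .params import GenerationError, ConfigurationError, ShellParams, SpeciesSpec, ANGLE_MID_BAND

__all__ = [
    "SpecimenRecord",
    "SyntheticDataset",
    "septal_schedule",
    "generate_shell",
    "generate_dataset",
    "conch_diameter",
]

#: dense sampling of generated curves (>= 500 so polyline arc length is
#: accurate to ~1e-5 relative)
CURVE_POINTS = 512

#: rotational step between successive whorl cross-sections (degrees)
SECTION_STEP_DEG = 45.0

#: sections are produced back from the aperture down to this rotational angle
SECTION_MIN_ANGLE_DEG = 30.0

#: conch-diameter window (mm) over which species-specific shape unfolds
SHAPE_RAMP_MM = (5.0, 150.0)

#: embryonic (pre-hatching) whorl-section components, shed at hatching: a
#: drop-like cos(t) term and a strong depressed-oval cos(2t) term.  Hatching
#: is an abrupt ecological transition in nautilids and leaves the largest
#: single shape discontinuity of the ontogeny.
EMBRYONIC_C1 = 0.25
EMBRYONIC_C2 = 0.35

#: number of Fourier harmonics carrying the measurement noise along a curve
NOISE_HARMONICS = 6


# ---------------------------------------------------------------------------
# coiling geometry


def conch_diameter(params: ShellParams, theta_deg) -> np.ndarray | float:
    """Conch diameter (mm) at rotational position theta (degrees).

    Diameter is the maximum distance across the spiral in the median plane:
    the venter at theta plus the venter half a revolution back, which grows
    as d0 * W^(theta/360).
    """
    return params.initial_diameter * params.whorl_expansion_rate ** (
        np.asarray(theta_deg, dtype=float) / 360.0
    )


def _venter_radius(params: ShellParams, theta_deg):
    """Radius of the ventral (outermost) point of the whorl at theta."""
    w = params.whorl_expansion_rate
    return conch_diameter(params, theta_deg) / (1.0 + w ** -0.5)


def _shape_ramp(diameter) -> np.ndarray | float:
    """Ontogenetic unfolding of species-specific shape, 0 (juvenile) -> 1."""
    lo, hi = SHAPE_RAMP_MM
    return np.clip((np.asarray(diameter, dtype=float) - lo) / (hi - lo), 0.0, 1.0)


def _effective_shape(params: ShellParams, diameter: float):
    """(aspect, c1, harmonic coeffs, lobe) at a given conch diameter.

    The embryonic components are present below hatching_diameter and shed
    abruptly at hatching; the species-specific aspect and harmonic
    coefficients unfold with the ontogenetic ramp, so juveniles converge on
    a shared shape and adults diverge.
    """
    s = float(_shape_ramp(diameter))
    aspect = 1.0 + (params.section_aspect - 1.0) * s
    coeffs = np.asarray(params.section_shape_coeffs, float) * s
    if diameter < params.hatching_diameter:
        c1 = EMBRYONIC_C1
        coeffs = coeffs.copy()
        coeffs[0] += EMBRYONIC_C2
    else:
        c1 = 0.0
    lobe = params.suture_lobe_amplitude * (0.15 + 0.85 * s)
    return aspect, c1, coeffs, lobe


def _section_points(params: ShellParams, theta_deg, t, shape_at: float | None = None):
    """Cross-section outline points (radial, axial) in mm.

    `theta_deg` may be a scalar or per-point array (used by the suture, whose
    points trail the septal position by the lobe displacement).  `shape_at`
    optionally freezes the shape coefficients at one diameter so a single
    suture does not straddle the hatching transition.
    """
    theta = np.asarray(theta_deg, dtype=float)
    d_here = conch_diameter(params, theta)
    d_shape = float(shape_at) if shape_at is not None else float(np.max(d_here))
    aspect, c1, coeffs, _ = _effective_shape(params, d_shape)

    rv = _venter_radius(params, theta)
    ri = params.umbilical_ratio * rv
    center = 0.5 * (rv + ri)
    a = 0.5 * (rv - ri)
    b = a / aspect

    radial_mod = 1.0 + c1 * np.cos(t)
    for j, c in enumerate(coeffs):
        radial_mod = radial_mod + c * np.cos((j + 2) * t)
    if np.min(radial_mod) <= 0.05:
        raise GenerationError(
            "section_shape_coeffs produce a self-intersecting whorl outline "
            f"(min radial modulation {np.min(radial_mod):.3f})"
        )
    rho = center + radial_mod * a * np.cos(t)
    z = radial_mod * b * np.sin(t)
    if np.min(rho) <= 0.0:
        raise GenerationError("umbilical_ratio places the whorl outline across the coiling axis")
    return rho, z, center, a


def _smooth_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Band-limited periodic noise along a closed curve, total variance sd^2.

    White noise at the dense sampling would corrupt the polyline arc length;
    a low-order Fourier series emulates smooth digitization/biological
    irregularity while keeping curves rectifiable.
    """
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    out = np.zeros(n)
    if sd == 0.0:
        # keep the RNG stream advancing identically for the zero-noise case
        rng.normal(size=2 * NOISE_HARMONICS)
        return out
    amp = sd / np.sqrt(NOISE_HARMONICS)
    coeffs = rng.normal(scale=amp, size=(NOISE_HARMONICS, 2))
    for j in range(NOISE_HARMONICS):
        out += coeffs[j, 0] * np.cos((j + 1) * t) + coeffs[j, 1] * np.sin((j + 1) * t)
    return out


def _section_curve(params, theta_deg, label, noise_sd, rng) -> Curve:
    t = np.linspace(0.0, 2.0 * np.pi, CURVE_POINTS, endpoint=False)
    rho, z, _, _ = _section_points(params, theta_deg, t)
    pts = np.column_stack([rho, z])
    for c in range(2):
        pts[:, c] += _smooth_noise(rng, CURVE_POINTS, noise_sd)
    return Curve(points=pts, closed=True, label=label)


def _suture_curve(params, theta_deg, label, noise_sd, rng) -> Curve:
    """Closed 3D suture curve on the whorl surface at septal position theta.

    Each point trails the septal position azimuthally by the lobe
    displacement lobe * H * sin^2(t) (one shallow lateral lobe per flank,
    none at venter and dorsum), expressed in degrees at the whorl center
    radius.  The outline shape is frozen at the chamber's diameter.
    """
    t = np.linspace(0.0, 2.0 * np.pi, CURVE_POINTS, endpoint=False)
    d_chamber = float(conch_diameter(params, theta_deg))
    lobe = _effective_shape(params, d_chamber)[-1]
    rv = float(_venter_radius(params, theta_deg))
    ri = params.umbilical_ratio * rv
    center = 0.5 * (rv + ri)
    height = rv - ri
    delta_deg = np.degrees(lobe * height * np.sin(t) ** 2 / center)
    theta_pts = theta_deg - delta_deg
    rho, z, _, _ = _section_points(params, theta_pts, t, shape_at=d_chamber)
    ang = np.radians(theta_pts)
    pts = np.column_stack([rho * np.cos(ang), rho * np.sin(ang), z])
    for c in range(3):
        pts[:, c] += _smooth_noise(rng, CURVE_POINTS, noise_sd)
    return Curve(points=pts, closed=True, label=label)


# ---------------------------------------------------------------------------
# septal schedule


def _septal_schedule(params: ShellParams, rng: np.random.Generator) -> np.ndarray:
    """Septal angles (degrees) per chamber; element j belongs to chamber j+2."""
    n, h, cr = params.n_chambers, params.hatching_chamber, params.crowding_chambers
    m = n - 1
    sd = params.angle_noise_sd
    n_ramp = h - 2                      # chambers 2 .. h-1, peak at chamber h-1
    n_plateau = m - n_ramp - cr         # chambers h .. n-cr
    if n_plateau < 1:
        raise ValueError("no room for a mid-ontogeny plateau: reduce hatching/crowding chambers")

    ramp = np.linspace(0.35 * params.angle_pre, params.angle_pre, n_ramp)
    ramp = np.sort(ramp + rng.normal(scale=sd, size=n_ramp))
    ramp = np.maximum(ramp, 1e-3)
    peak = ramp[-1]

    plateau = rng.normal(loc=params.angle_mid, scale=sd, size=n_plateau)
    # the hatching drop contract: the first post-peak angle sits >= 20% below
    # the pre-hatching maximum, and the band stays below that ceiling
    ceiling = 0.8 * peak * (1.0 - 1e-9)
    plateau = np.clip(plateau, 1e-3, ceiling)

    # terminal crowding converges toward a shared crowded spacing (maturity
    # is a common developmental signal, not a species character)
    crowd_base = 0.5 * (ANGLE_MID_BAND[0] + ANGLE_MID_BAND[1])
    # fractions anchored to position from the end (last septum most crowded)
    frac = 0.38 + 0.22 * np.arange(cr)[::-1]
    crowd = crowd_base * frac + rng.normal(scale=0.5 * sd, size=cr)
    crowd[0] = float(np.clip(crowd[0], 0.3 * crowd_base, 0.95 * crowd_base))
    for i in range(1, cr):
        crowd[i] = min(crowd[i], crowd[i - 1] * 0.95)
        crowd[i] = max(crowd[i], crowd[i - 1] * 0.30)

    return np.concatenate([ramp, plateau, crowd])


def septal_schedule(params: ShellParams, seed: int) -> np.ndarray:
    """Public septal-angle schedule: deterministic given (params, seed).

    Length n_chambers - 1 (angles between successive septa; the earliest
    chamber is excluded).  Rises monotonically to a maximum at chamber
    hatching_chamber - 1, drops >= 20% at the hatching chamber, holds a noisy
    stationary band centered on angle_mid, and decreases strictly over the
    last crowding_chambers angles.
    """
    return _septal_schedule(params, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# specimens and datasets


@dataclass
class SpecimenRecord:
    """One individual's ontogenetic series.

    Chambers are numbered from 2 (chamber 1 excluded); suture_curves,
    septal positions/angles and diameters_at_chamber align with
    chamber_numbers.  Cross-sections are stored adapical -> aperture, so
    diameters increase with index and max_diameter equals the last section
    diameter.
    """

    specimen_id: str
    species: str
    region: str
    group: str
    suture_curves: list
    section_outlines: list
    chamber_numbers: np.ndarray
    septal_positions: np.ndarray       # cumulative degrees, starts at 0
    septal_angles: np.ndarray          # degrees per chamber (length n-1)
    diameters_at_chamber: np.ndarray   # mm per chamber
    diameters_at_section: np.ndarray   # mm per section
    max_diameter: float
    shell_params: ShellParams = None   # realized per-specimen parameters

    def __post_init__(self) -> None:
        for name in ("diameters_at_chamber", "diameters_at_section"):
            d = np.asarray(getattr(self, name), float)
            if np.any(np.diff(d) <= 0.0):
                raise ValueError(f"{self.specimen_id}: {name} must increase strictly")
            setattr(self, name, d)
        if np.any(np.asarray(self.septal_angles) <= 0.0):
            raise ValueError(f"{self.specimen_id}: septal angles must all be positive")
        if int(self.chamber_numbers[0]) != 2:
            raise ValueError(f"{self.specimen_id}: chamber numbering must start at 2")
        if len(self.suture_curves) != len(self.chamber_numbers):
            raise ValueError(f"{self.specimen_id}: one suture curve per chamber required")


@dataclass
class SyntheticDataset:
    specimens: list
    species_specs: list
    seed: int
    generator_version: str = __version__

    def by_group(self) -> dict[str, list[SpecimenRecord]]:
        out: dict[str, list[SpecimenRecord]] = {}
        for rec in self.specimens:
            out.setdefault(rec.group, []).append(rec)
        return out


def dataset_to_json(dataset: SyntheticDataset) -> dict:
    """JSON-serializable form of a dataset (full float precision)."""
    return {
        "seed": dataset.seed,
        "generator_version": dataset.generator_version,
        "specimens": [
            {
                "specimen_id": r.specimen_id,
                "species": r.species,
                "region": r.region,
                "group": r.group,
                "chamber_numbers": r.chamber_numbers.tolist(),
                "septal_positions": r.septal_positions.tolist(),
                "septal_angles": r.septal_angles.tolist(),
                "diameters_at_chamber": r.diameters_at_chamber.tolist(),
                "diameters_at_section": r.diameters_at_section.tolist(),
                "max_diameter": r.max_diameter,
                "sutures": [c.points.tolist() for c in r.suture_curves],
                "suture_labels": [c.label for c in r.suture_curves],
                "sections": [c.points.tolist() for c in r.section_outlines],
                "section_labels": [c.label for c in r.section_outlines],
            }
            for r in dataset.specimens
        ],
    }


def dataset_from_json(raw: dict) -> SyntheticDataset:
    """Rebuild a dataset from its JSON form (species specs are not stored)."""
    specimens = []
    for r in raw["specimens"]:
        specimens.append(
            SpecimenRecord(
                specimen_id=r["specimen_id"],
                species=r["species"],
                region=r["region"],
                group=r["group"],
                suture_curves=[
                    Curve(points=np.asarray(p), closed=True, label=lab)
                    for p, lab in zip(r["sutures"], r["suture_labels"])
                ],
                section_outlines=[
                    Curve(points=np.asarray(p), closed=True, label=lab)
                    for p, lab in zip(r["sections"], r["section_labels"])
                ],
                chamber_numbers=np.asarray(r["chamber_numbers"], int),
                septal_positions=np.asarray(r["septal_positions"], float),
                septal_angles=np.asarray(r["septal_angles"], float),
                diameters_at_chamber=np.asarray(r["diameters_at_chamber"], float),
                diameters_at_section=np.asarray(r["diameters_at_section"], float),
                max_diameter=float(r["max_diameter"]),
            )
        )
    return SyntheticDataset(
        specimens=specimens,
        species_specs=[],
        seed=int(raw.get("seed", 0)),
        generator_version=raw.get("generator_version", __version__),
    )


_PERTURBED_FIELDS = (
    "whorl_expansion_rate",
    "umbilical_ratio",
    "section_aspect",
    "suture_lobe_amplitude",
    "angle_pre",
    "angle_mid",
    "initial_diameter",
)


def _draw_params(spec: SpeciesSpec, rng: np.random.Generator) -> ShellParams:
    """Perturb the species mean parameters by the per-parameter CVs."""
    mean = spec.mean_params
    kw = {}
    for name in _PERTURBED_FIELDS:
        cv = spec.cv_for(name)
        z = float(np.clip(rng.normal(), -3.0, 3.0))
        kw[name] = getattr(mean, name) * (1.0 + cv * z)
    cv_c = spec.cv_for("section_shape_coeffs")
    zs = np.clip(rng.normal(size=len(mean.section_shape_coeffs)), -3.0, 3.0)
    kw["section_shape_coeffs"] = tuple(
        c * (1.0 + cv_c * z) for c, z in zip(mean.section_shape_coeffs, zs)
    )
    # keep hard invariants under perturbation
    kw["umbilical_ratio"] = float(np.clip(kw["umbilical_ratio"], 0.0, 0.9))
    kw["angle_mid"] = float(np.clip(kw["angle_mid"], *ANGLE_MID_BAND))
    kw["whorl_expansion_rate"] = max(kw["whorl_expansion_rate"], 1.01)
    try:
        return mean.with_(**kw)
    except ValueError as exc:
        raise GenerationError(f"perturbed parameters invalid for {spec.code}: {exc}") from exc


def generate_shell(
    spec: SpeciesSpec,
    specimen_id: str,
    seed: int,
    section_step_deg: float = SECTION_STEP_DEG,
    section_min_angle_deg: float = SECTION_MIN_ANGLE_DEG,
) -> SpecimenRecord:
    """Generate one synthetic specimen of a species."""
    rng = np.random.default_rng(seed)
    params = _draw_params(spec, rng)
    angles = _septal_schedule(params, rng)
    positions = np.concatenate([[0.0], np.cumsum(angles)])
    total = positions[-1]
    chambers = np.arange(2, params.n_chambers + 1)
    d_chamber = conch_diameter(params, positions[1:])

    noise = spec.landmark_noise_sd
    sutures = [
        _suture_curve(params, positions[i + 1], f"{specimen_id}|ch{c:02d}", noise, rng)
        for i, c in enumerate(chambers)
    ]

    n_sections = int(np.floor((total - section_min_angle_deg) / section_step_deg)) + 1
    if n_sections < 2:
        raise GenerationError("n_chambers too small for two cross-sections")
    thetas = total - section_step_deg * np.arange(n_sections)[::-1]
    sections = [
        _section_curve(params, th, f"{specimen_id}|s{k:02d}", noise, rng)
        for k, th in enumerate(thetas)
    ]
    d_section = np.asarray(conch_diameter(params, thetas), float)

    return SpecimenRecord(
        specimen_id=specimen_id,
        species=spec.name,
        region=spec.region,
        group=spec.label,
        suture_curves=sutures,
        section_outlines=sections,
        chamber_numbers=chambers,
        septal_positions=positions,
        septal_angles=angles,
        diameters_at_chamber=d_chamber,
        diameters_at_section=d_section,
        max_diameter=float(d_section[-1]),
        shell_params=params,
    )


def generate_dataset(
    specs,
    n_per_species: int = 2,
    seed: int = 0,
    section_step_deg: float = SECTION_STEP_DEG,
    section_min_angle_deg: float = SECTION_MIN_ANGLE_DEG,
) -> SyntheticDataset:
    """Generate n_per_species specimens per species spec, deterministically."""
    specs = list(specs)
    if n_per_species < 1:
        raise ConfigurationError("n_per_species must be at least 1")
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ConfigurationError("duplicate species labels in the generator configuration")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(specs) * n_per_species)
    specimens = []
    i = 0
    for spec in specs:
        for j in range(n_per_species):
            sid = f"{spec.code}-{j + 1:02d}"
            specimens.append(
                generate_shell(
                    spec,
                    sid,
                    int(child_seeds[i]) & 0x7FFFFFFF,
                    section_step_deg=section_step_deg,
                    section_min_angle_deg=section_min_angle_deg,
                )
            )
            i += 1
    return SyntheticDataset(specimens=specimens, species_specs=specs, seed=seed)


# ---------------------------------------------------------------------------
# optional surface export for visual inspection


def shell_surface(params: ShellParams, n_theta: int = 200, n_t: int = 60):
    """Swept whorl surface of the conch as a vertex grid and quad faces.

    Returns (vertices, faces): vertices is an (n_theta*n_t, 3) array (mm),
    faces an (m, 4) integer array of quads, suitable for PLY export.
    """
    total = 360.0 * np.log(10.0) / np.log(params.whorl_expansion_rate)  # ~10x growth
    thetas = np.linspace(SECTION_MIN_ANGLE_DEG, total, n_theta)
    t = np.linspace(0.0, 2.0 * np.pi, n_t, endpoint=False)
    verts = np.empty((n_theta, n_t, 3))
    for i, th in enumerate(thetas):
        rho, z, _, _ = _section_points(params, th, t)
        ang = np.radians(th)
        verts[i, :, 0] = rho * np.cos(ang)
        verts[i, :, 1] = rho * np.sin(ang)
        verts[i, :, 2] = z
    faces = []
    for i in range(n_theta - 1):
        for j in range(n_t):
            jn = (j + 1) % n_t
            faces.append([i * n_t + j, i * n_t + jn, (i + 1) * n_t + jn, (i + 1) * n_t + j])
    return verts.reshape(-1, 3), np.asarray(faces, dtype=int)


def write_ply(path, vertices: np.ndarray, faces: np.ndarray) -> None:
    """Write an ASCII PLY mesh (for quick-look rendering of the shell)."""
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(vertices)}",
        "property float x",
        "property float y",
        "property float z",
        f"element face {len(faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    lines += [" ".join("%.6f" % v for v in row) for row in vertices]
    lines += [f"{len(f)} " + " ".join(str(i) for i in f) for f in faces]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
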