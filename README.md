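# nautimorph

3D geometric morphometrics of nautilid conchs: quantify the suture line, the
whorl cross-section ("conch geometry"), and septal spacing through ontogeny,
and ask which of these characters distinguishes species.

Chambered cephalopod shells record their whole growth history: every septum
leaves a suture line where it meets the outer shell wall, and every chamber
marks an increment of rotation around the coiling axis.  Taxonomists have
leaned on suture shape for two centuries, but testing how diagnostic it
really is requires comparing many specimens at *matched* growth stages —
conch shape changes so fast through ontogeny that a small difference in
diameter swamps the difference between species.  `nautimorph` implements the
full comparative workflow on curve data (digitized from CT reconstructions
or produced by its built-in parametric shell simulator):

1. **Equidistant landmarking** — each closed suture curve gets k = 20
   semi-landmarks, each whorl cross-section (taken every 45° of rotation back
   from the aperture) gets k = 40, placed at equal arc-length intervals from
   a deterministic ventral starting point.
2. **Sliding semi-landmarks** — landmarks slide along their own curve to
   minimize the thin-plate-spline bending energy relative to a reference
   individual.  The bending-energy matrix is
   `B = Q₂ (Q₂ᵀ K Q₂)⁻¹ Q₂ᵀ` with kernel `U(r) = r² log r` (2D) or
   `U(r) = −r` (3D); `B` annihilates affine terms, so the energy measures
   only non-affine deformation.
3. **Generalized Procrustes analysis** — configurations are centered, scaled
   to unit centroid size, and iteratively rotated (proper rotations only)
   onto the consensus; the Procrustes residuals go into a **PCA** (covariance
   eigendecomposition, all PCs retained).
4. **Neighbor-joining phenograms** — Euclidean distances over *all* PC
   scores, per ontogenetic stage (conch diameter ≈ 20 mm = pre-hatching,
   ≈ 50 mm = middle ontogeny, maximum diameter = maturity; two chambers and
   two cross-sections per specimen per stage), written as Newick.
5. **Septal-spacing statistics** — spacing is the rotational angle between
   successive septa; stages are pre-hatching (diameter < 30 mm),
   juvenile–submature, and mature (last two chambers); one-way ANOVA across
   species/populations with Tukey–Kramer pairwise comparisons.

The synthetic generator builds Raup-style logarithmic-spiral shells
(diameter `d(θ) = d₀ · W^(θ/360°)`) for nine nautilid species/populations
(two specimens each, mirroring a museum study design), with an embryonic
cross-section shape that is shed abruptly at hatching, species-specific
shape that unfolds through ontogeny, and a septal-spacing schedule with the
diagnostic rise–drop at chamber 7–8, a stable 20–30° band, and terminal
crowding.

## Worked example

```python
from nautimorph.pipeline import PipelineConfig, run_pipeline
from nautimorph.septal import hatching_chamber

run = run_pipeline(PipelineConfig(seed=1, outdir="results_demo"))

for char in ("suture", "conch_geometry"):
    vf = run.characters[char].pca_result.variance_fraction
    print(f"{char}: PC1 {100*vf[0]:.1f}%  PC2 {100*vf[1]:.1f}%  PC3 {100*vf[2]:.1f}%")

rec = run.dataset.specimens[0]
print(f"{rec.specimen_id}: hatching detected at chamber",
      hatching_chamber(rec.septal_angles),
      f"(configured {rec.shell_params.hatching_chamber})")

for stage, a in run.septal.anova.items():
    print(f"septal spacing ANOVA, {stage}: F = {a.F:.2f}, p = {a.p_value:.3g}")
```

prints

```
suture: PC1 54.1%  PC2 28.0%  PC3 5.7%
conch_geometry: PC1 64.0%  PC2 15.5%  PC3 7.0%
Aper-01: hatching detected at chamber 7 (configured 7)
septal spacing ANOVA, pre_hatching: F = 0.38, p = 0.929
septal spacing ANOVA, juvenile_submature: F = 141.65, p = 8.64e-116
septal spacing ANOVA, mature: F = 0.05, p = 1
```

Most shape variance loads on the first two PCs, which carry the ontogenetic
trajectory shared by all species; the septal-spacing drop marks hatching at
the configured chamber; and spacing separates species only in middle
ontogeny — before hatching all species are embryonic look-alikes, and at
maturity septal crowding is a shared developmental signal.  `results_demo/`
receives the slid landmarks (TPS), PC scores and Procrustes residuals (CSV),
twelve Newick trees (3 characters × pooled + 3 stages), the ANOVA/pairwise
tables, and a manifest with per-file checksums.

The same pipeline runs from the shell, stage by stage if desired:

```bash
nautimorph all --seed 42 --outdir out            # everything
nautimorph simulate --seed 42 --outdir out       # curves.json + septal CSV
nautimorph landmark --outdir out                 # slid TPS landmarks
nautimorph analyze  --outdir out                 # GPA + PCA score tables
nautimorph trees --stage middle --character conch_geometry --outdir out
nautimorph stats --outdir out                    # ANOVA + Tukey-Kramer CSVs
```

Real landmark data can enter at any stage: the `analyze`/`trees`/`stats`
subcommands only read the documented TPS/CSV formats.

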