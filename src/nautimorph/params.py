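"""Shell parameters and species specifications for the synthetic generator.

The coiling model is a minimal Raup-style logarithmic spiral: the conch
diameter grows by `whorl_expansion_rate` per full revolution, the whorl
cross-section is a harmonically deformed ellipse swept along the spiral, and
the suture line is the outline-following closed curve displaced adapically by
one shallow lateral lobe per flank, as in nautilids.  Species differ in their
mean parameters; individuals within a species perturb those means by a
per-parameter coefficient of variation, and curves additionally carry
isotropic measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["ShellParams", "SpeciesSpec", "default_species_specs", "ANGLE_MID_BAND"]

#: the admissible band for the stable mid-ontogeny septal angle (degrees)
ANGLE_MID_BAND = (20.0, 30.0)


class GenerationError(ValueError):
    """A parameter draw produced a degenerate (e.g. self-intersecting) shell."""


class ConfigurationError(ValueError):
    """An invalid generator or pipeline configuration."""


@dataclass(frozen=True)
class ShellParams:
    """Parameters of one conch.

    Lengths in mm, angles in degrees.  `section_shape_coeffs` are the
    low-order harmonic coefficients (cos 2t, cos 3t, ...) deforming the
    elliptical whorl outline; `suture_lobe_amplitude` is the lobe depth of
    the suture relative to whorl height; `angle_pre` is the peak septal angle
    of the pre-hatching ramp and `angle_mid` the stable mid-ontogeny spacing;
    `hatching_diameter` is the conch diameter at which the embryonic
    cross-section shape is shed (and which separates the pre-hatching stage).
    """

    whorl_expansion_rate: float = 3.0
    umbilical_ratio: float = 0.12
    section_aspect: float = 1.35
    section_shape_coeffs: tuple = (0.05, 0.01, 0.02)
    suture_lobe_amplitude: float = 0.24
    n_chambers: int = 34
    hatching_chamber: int = 7
    angle_pre: float = 36.0
    angle_mid: float = 25.0
    angle_noise_sd: float = 1.2
    crowding_chambers: int = 2
    initial_diameter: float = 18.0
    hatching_diameter: float = 30.0

    def __post_init__(self) -> None:
        if not self.whorl_expansion_rate > 1.0:
            raise ValueError("whorl_expansion_rate must exceed 1")
        if not 0.0 <= self.umbilical_ratio < 1.0:
            raise ValueError("umbilical_ratio must lie in [0, 1)")
        if not self.section_aspect > 0.0:
            raise ValueError("section_aspect must be positive")
        if not 1 <= len(self.section_shape_coeffs) <= 5:
            raise ValueError("section_shape_coeffs must hold 1-5 harmonics (c2, c3, ...)")
        if sum(abs(c) for c in self.section_shape_coeffs) > 0.6:
            raise ValueError("section_shape_coeffs too large: outline would self-intersect")
        if self.suture_lobe_amplitude < 0.0:
            raise ValueError("suture_lobe_amplitude must be nonnegative")
        if self.hatching_chamber < 4:
            raise ValueError("hatching_chamber must be at least 4")
        if self.crowding_chambers < 1:
            raise ValueError("crowding_chambers must be at least 1")
        if not self.n_chambers > self.hatching_chamber + self.crowding_chambers:
            raise ValueError(
                "n_chambers must exceed hatching_chamber + crowding_chambers"
            )
        lo, hi = ANGLE_MID_BAND
        if not lo <= self.angle_mid <= hi:
            raise ValueError(f"angle_mid must lie in [{lo}, {hi}] degrees")
        if self.angle_pre <= 0.0 or self.angle_noise_sd < 0.0:
            raise ValueError("angle_pre must be positive and angle_noise_sd nonnegative")
        if self.initial_diameter <= 0.0 or self.hatching_diameter <= 0.0:
            raise ValueError("diameters must be positive")

    def with_(self, **kw) -> "ShellParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class SpeciesSpec:
    """A species (or geographic population): mean shell plus variability.

    `intraspecific_cv` is a per-parameter coefficient of variation — either a
    single float for all perturbable parameters or a dict keyed by ShellParams
    field name.  `landmark_noise_sd` (mm) is the isotropic measurement noise
    added to curve points.
    """

    name: str
    region: str
    code: str
    mean_params: ShellParams
    intraspecific_cv: object = field(default=0.0)
    landmark_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        cvs = (
            self.intraspecific_cv.values()
            if isinstance(self.intraspecific_cv, dict)
            else [self.intraspecific_cv]
        )
        if any(c < 0 for c in cvs):
            raise ValueError(f"species {self.code!r}: all CVs must be nonnegative")
        if self.landmark_noise_sd < 0:
            raise ValueError(f"species {self.code!r}: landmark_noise_sd must be nonnegative")

    @property
    def label(self) -> str:
        return self.code

    def cv_for(self, field_name: str) -> float:
        if isinstance(self.intraspecific_cv, dict):
            return float(self.intraspecific_cv.get(field_name, 0.0))
        return float(self.intraspecific_cv)


# Default intraspecific variability: shape parameters vary a few percent
# between individuals, coiling parameters less.  Together with the default
# measurement noise this puts between-species mean shape distance near 3x the
# within-species standard deviation in middle ontogeny and near 1x before
# hatching, where shells of all species are close to the shared embryonic
# shape and the (absolute, mm) measurement noise is relatively larger.
_DEFAULT_CV = {
    "whorl_expansion_rate": 0.008,
    "umbilical_ratio": 0.04,
    "section_aspect": 0.006,
    "section_shape_coeffs": 0.05,
    "suture_lobe_amplitude": 0.06,
    "angle_pre": 0.04,
    "angle_mid": 0.025,
    "initial_diameter": 0.03,
}

_DEFAULT_NOISE_SD = 0.05  # mm

# (name, region, code, aspect, (c2, c3, c4, c5), lobe, umbilicus, W,
#  angle_mid, hatching_chamber, n_chambers, crowding, initial_diameter)
# Shape parameters sit on a near-uniform 9-point configuration in the
# effectively orthogonal shape dimensions (section ellipticity and the
# cos3t/cos4t/cos5t harmonics; pairwise shape distances within ~12% of
# each other), scaled so the between-species mean shape distance is about
# three within-species standard deviations in middle ontogeny.
_SPECIES_TABLE = [
    ("Allonautilus perforatus", "Indonesia", "Aper",
     1.4802, (0.0200, -0.0193, 0.0945, -0.0636), 0.30, 0.10, 2.95, 21.0, 7, 33, 2, 17.5),
    ("Allonautilus scrobiculatus", "Papua New Guinea", "Ascr",
     1.1732, (0.0200, 0.0205, 0.0382, -0.0819), 0.28, 0.14, 3.00, 22.0, 7, 34, 3, 18.0),
    ("Nautilus belauensis", "Palau", "Nbel",
     1.3338, (0.0200, -0.0838, -0.0194, -0.0218), 0.20, 0.11, 3.05, 23.0, 7, 35, 2, 19.0),
    ("Nautilus macromphalus", "New Caledonia", "Nmac",
     1.2053, (0.0200, 0.0382, -0.0806, 0.0127), 0.24, 0.20, 2.90, 24.0, 8, 33, 2, 17.0),
    ("Nautilus pompilius", "Papua New Guinea", "NpomPNG",
     1.3758, (0.0200, 0.0789, 0.0453, 0.0287), 0.22, 0.12, 3.00, 25.0, 7, 34, 3, 18.0),
    ("Nautilus pompilius", "Philippines", "NpomPHL",
     1.4632, (0.0200, 0.0394, -0.0433, -0.0832), 0.26, 0.12, 3.05, 26.0, 7, 35, 2, 18.5),
    ("Nautilus pompilius suluensis", "Philippines", "Nsul",
     1.4697, (0.0200, -0.0533, 0.0728, 0.0831), 0.18, 0.11, 2.95, 27.0, 7, 32, 2, 17.0),
    ("Nautilus repertus", "Western Australia", "Nrep",
     1.5215, (0.0200, 0.0033, -0.0636, 0.0621), 0.24, 0.13, 3.05, 28.0, 8, 36, 3, 19.0),
    ("Nautilus stenomphalus", "Lizard Island, Australia", "Nste",
     1.1271, (0.0200, -0.0239, 0.0463, 0.0638), 0.27, 0.16, 3.00, 29.0, 7, 33, 2, 18.0),
]


def default_species_specs() -> list[SpeciesSpec]:
    """The default study design: 9 species/populations (8 species, with the
    Papua New Guinea and Philippine populations of N. pompilius separate),
    two specimens each giving the 18-specimen default dataset."""
    specs = []
    for (name, region, code, aspect, coeffs, lobe, umb, w, mid,
         hatch, n_ch, crowd, d0) in _SPECIES_TABLE:
        params = ShellParams(
            whorl_expansion_rate=w,
            umbilical_ratio=umb,
            section_aspect=aspect,
            section_shape_coeffs=coeffs,
            suture_lobe_amplitude=lobe,
            n_chambers=n_ch,
            hatching_chamber=hatch,
            angle_mid=mid,
            crowding_chambers=crowd,
            initial_diameter=d0,
        )
        specs.append(
            SpeciesSpec(
                name=name,
                region=region,
                code=code,
                mean_params=params,
                intraspecific_cv=dict(_DEFAULT_CV),
                landmark_noise_sd=_DEFAULT_NOISE_SD,
            )
        )
    return specs
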