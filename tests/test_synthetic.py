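"""Synthetic conch generator: schedule contract, shells, datasets."""

import numpy as np
import pytest

from nautimorph import (
    ShellParams,
    SpeciesSpec,
    conch_diameter,
    default_species_specs,
    generate_dataset,
    generate_shell,
    septal_schedule,
)
from nautimorph.params import ConfigurationError
from conftest import small_species_specs


def noiseless_params(**kw):
    base = dict(angle_noise_sd=0.0, angle_mid=25.0, crowding_chambers=2)
    base.update(kw)
    return ShellParams(**base)


class TestSeptalSchedule:
    def test_zero_noise_plateau_exactly_at_angle_mid(self):
        p = noiseless_params()
        s = septal_schedule(p, seed=0)
        assert s.size == p.n_chambers - 1
        plateau = s[p.hatching_chamber - 2 : -p.crowding_chambers]
        assert np.all(plateau == 25.0)
        tail = s[-2:]
        assert tail[1] < tail[0]

    def test_same_seed_identical_series(self):
        p = ShellParams()
        assert np.array_equal(septal_schedule(p, seed=7), septal_schedule(p, seed=7))

    def test_different_seeds_differ(self):
        p = ShellParams()
        assert not np.array_equal(septal_schedule(p, seed=7), septal_schedule(p, seed=8))

    def test_peak_at_chamber_before_hatching_and_steep_drop(self):
        p = ShellParams()
        for seed in range(50):
            s = septal_schedule(p, seed)
            h = p.hatching_chamber
            peak_idx = int(np.argmax(s[:10]))
            assert peak_idx == h - 3  # chamber h-1
            assert s[h - 2] <= 0.8 * s[h - 3]  # >= 20% drop at the hatching chamber

    @pytest.mark.parametrize("seed", range(0, 200, 7))
    def test_rise_drop_plateau_crowding_contract(self, seed):
        p = ShellParams()
        s = septal_schedule(p, seed)
        h, cr = p.hatching_chamber, p.crowding_chambers
        assert np.all(s > 0.0)
        ramp = s[: h - 2]
        assert np.all(np.diff(ramp) >= 0.0)                      # monotone rise
        assert s[h - 2] <= 0.8 * ramp[-1]                        # steep drop
        plateau = s[h - 2 : -cr]
        assert abs(plateau.mean() - p.angle_mid) < 3.0           # stationary band
        assert plateau.std() < 4 * p.angle_noise_sd + 1e-9
        tail = s[-cr:]
        assert np.all(np.diff(tail) < 0.0)                       # strict crowding

    def test_invalid_hatching_vs_chambers(self):
        with pytest.raises(ValueError, match="n_chambers"):
            ShellParams(n_chambers=9, hatching_chamber=8, crowding_chambers=2)


class TestGenerateShell:
    def spec(self, cv=0.0, noise=0.0, angle_noise=1.2):
        return SpeciesSpec(name="X", region="lab", code="X",
                           mean_params=ShellParams(angle_noise_sd=angle_noise),
                           intraspecific_cv=cv, landmark_noise_sd=noise)

    def test_zero_variance_specimens_identical_up_to_id(self):
        # all variances zero, including the septal-schedule noise
        a = generate_shell(self.spec(angle_noise=0.0), "a", seed=1)
        b = generate_shell(self.spec(angle_noise=0.0), "b", seed=2)
        assert np.array_equal(a.septal_angles, b.septal_angles)
        for ca, cb in zip(a.suture_curves, b.suture_curves):
            assert np.array_equal(ca.points, cb.points)
        for ca, cb in zip(a.section_outlines, b.section_outlines):
            assert np.array_equal(ca.points, cb.points)

    def test_diameters_strictly_increasing_and_max_is_last_section(self):
        rec = generate_shell(self.spec(cv=0.02, noise=0.05), "x", seed=3)
        assert np.all(np.diff(rec.diameters_at_chamber) > 0)
        assert np.all(np.diff(rec.diameters_at_section) > 0)
        assert rec.max_diameter == rec.diameters_at_section[-1]

    def test_chambers_numbered_from_two(self):
        rec = generate_shell(self.spec(), "x", seed=0)
        assert rec.chamber_numbers[0] == 2
        assert len(rec.suture_curves) == rec.shell_params.n_chambers - 1
        assert rec.septal_angles.size == rec.shell_params.n_chambers - 1

    def test_expansion_rate_definition(self):
        p = ShellParams(whorl_expansion_rate=2.0)
        assert conch_diameter(p, 360.0) / conch_diameter(p, 0.0) == pytest.approx(2.0, rel=1e-12)

    def test_degenerate_coeffs_raise_naming_parameter(self):
        with pytest.raises(ValueError, match="section_shape_coeffs"):
            ShellParams(section_shape_coeffs=(0.5, 0.2, 0.1))

    def test_curves_are_closed_and_dense(self):
        rec = generate_shell(self.spec(noise=0.05), "x", seed=4)
        for c in rec.suture_curves[:3] + rec.section_outlines[:3]:
            assert c.closed
            assert c.n_points >= 500


class TestGenerateDataset:
    def test_default_design_yields_18_specimens(self):
        ds = generate_dataset(default_species_specs(), n_per_species=2, seed=0)
        assert len(ds.specimens) == 18
        assert len({r.group for r in ds.specimens}) == 9

    def test_n_per_species_zero_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_dataset(default_species_specs(), n_per_species=0, seed=0)

    def test_duplicate_species_labels_rejected(self):
        specs = small_species_specs()
        with pytest.raises(ConfigurationError, match="duplicate"):
            generate_dataset(specs + [specs[0]], n_per_species=1, seed=0)

    def test_same_seed_bitwise_identical(self):
        specs = small_species_specs(cv=0.02, noise_sd=0.05)
        d1 = generate_dataset(specs, 2, seed=9)
        d2 = generate_dataset(specs, 2, seed=9)
        for a, b in zip(d1.specimens, d2.specimens):
            assert a.specimen_id == b.specimen_id
            assert np.array_equal(a.septal_angles, b.septal_angles)
            assert np.array_equal(a.suture_curves[0].points, b.suture_curves[0].points)
            assert np.array_equal(a.section_outlines[-1].points, b.section_outlines[-1].points)

    def test_different_seeds_differ(self):
        specs = small_species_specs(cv=0.02, noise_sd=0.05)
        d1 = generate_dataset(specs, 1, seed=9)
        d2 = generate_dataset(specs, 1, seed=10)
        assert not np.array_equal(d1.specimens[0].septal_angles, d2.specimens[0].septal_angles)


def test_zero_variance_conspecifics_collapse_downstream():
    """With all variances zero, conspecific specimens coincide at equal index."""
    from nautimorph import procrustes_distance, resample_equidistant

    specs = small_species_specs(cv=0.0, noise_sd=0.0, angle_noise_sd=0.0)
    ds = generate_dataset(specs, 2, seed=3)
    a, b = ds.specimens[0], ds.specimens[1]
    assert a.group == b.group
    for ca, cb in zip(a.section_outlines[:4], b.section_outlines[:4]):
        pa = resample_equidistant(ca, 40)
        pb = resample_equidistant(cb, 40)
        assert procrustes_distance(pa, pb) < 1e-10


def test_ply_surface_export(tmp_path):
    from nautimorph.generate import shell_surface, write_ply

    v, f = shell_surface(ShellParams(), n_theta=30, n_t=16)
    assert v.shape == (30 * 16, 3)
    assert f.max() == len(v) - 1
    path = tmp_path / "shell.ply"
    write_ply(path, v, f)
    head = path.read_text().splitlines()[:2]
    assert head == ["ply", "format ascii 1.0"]
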