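import numpy as np
import pytest

from conftest import make_plate_set
from msbmap.io import InputError, load_fixture_tables
from msbmap.mapping import GridMap, stt_map, thickness_map
from msbmap.morphometry import (MorphometryRecord, bone_height, bootstrap_ci,
                                classify_shape, extreme_levels, level_profile,
                                mean_stt, measure_subject, ols, summarize)
from msbmap.transforms import RigidTransform


def taper_map(width_fn, nz=45, t=10.0):
    """Thickness map whose present width per row follows width_fn(z idx)."""
    nx = 60
    values = np.zeros((nx, nz))
    present = np.zeros((nx, nz), dtype=bool)
    for j in range(nz):
        w = int(width_fn(j))
        lo = (nx - w) // 2
        present[lo:lo + w, j] = True
        values[lo:lo + w, j] = t
    return GridMap(values=values, present=present, origin_xz=(-30.0, -float(nz)),
                   kind="thickness")


class TestScalars:
    def test_slab_height(self):
        s = make_plate_set(thickness=10.0, z_range=(0.0, 50.0))
        assert bone_height(s) == pytest.approx(50.0)

    def test_height_is_translation_invariant(self, default_phantom_nv):
        s = default_phantom_nv.surfaces
        moved = s.transformed(RigidTransform.translation_of((5, 6, -7)))
        assert bone_height(moved) == pytest.approx(bone_height(s))

    def test_phantom_height_matches_spec(self, default_phantom_nv):
        h = bone_height(default_phantom_nv.surfaces)
        assert abs(h - 52.0) <= 2 * default_phantom_nv.spec.voxel_mm

    def test_uniform_slab_profile(self):
        s = make_plate_set(thickness=10.0, x_range=(-25.0, 25.0))
        prof = level_profile(thickness_map(s))
        assert np.allclose(prof.thickness_mm, 10.0, atol=1e-9)
        assert np.all(np.abs(prof.width_mm - 50.0) <= 2.0)

    def test_wedge_profile_monotone_in_z(self):
        s = make_plate_set(anterior_fn=lambda x, z: 20.0 + 0.2 * np.asarray(z),
                           z_range=(-50.0, 0.0))
        prof = level_profile(thickness_map(s))
        assert np.all(np.diff(prof.thickness_mm) > 0)

    def test_extremes_of_wedge_at_the_ends(self):
        s = make_plate_set(anterior_fn=lambda x, z: 20.0 + 0.2 * np.asarray(z))
        ext = extreme_levels(level_profile(thickness_map(s)))
        assert ext["z_sl"] > ext["z_il"]
        assert ext["t_sl"] > ext["t_il"]

    def test_uniform_tie_resolves_superior(self):
        s = make_plate_set(thickness=10.0)
        prof = level_profile(thickness_map(s))
        ext = extreme_levels(prof)
        assert ext["z_sl"] == prof.z_mm.max()
        assert ext["z_il"] == prof.z_mm.max()

    def test_phantom_protuberance_level_is_thickest(self, default_phantom_nv):
        """The analytic field peaks near the protuberances: the thickest row
        exceeds the base thickness and sits superiorly."""
        tf = default_phantom_nv.truth.thickness_field
        ext = extreme_levels(level_profile(tf))
        assert ext["t_sl"] - ext["t_il"] > 2.0
        assert ext["z_sl"] > ext["z_il"]
        peak = tf.values[tf.present].max()
        spec = default_phantom_nv.spec
        assert peak >= spec.base_thickness_mm + 0.8 * spec.protuberance_amp_mm

    def test_mean_stt_constant_map(self):
        s = make_plate_set(thickness=9.0, stt=12.5)
        assert mean_stt(stt_map(s)) == pytest.approx(12.5, abs=1e-9)

    def test_mean_stt_empty_rejected(self):
        empty = GridMap(values=np.zeros((3, 3)),
                        present=np.zeros((3, 3), bool),
                        origin_xz=(0.0, 0.0), kind="stt")
        with pytest.raises(InputError):
            mean_stt(empty)

    def test_measure_subject_invariant(self, default_phantom_nv):
        s = default_phantom_nv.surfaces
        rec = measure_subject(default_phantom_nv, thickness_map(s), stt_map(s))
        assert rec.t_sl_mm >= rec.t_il_mm > 0
        assert rec.height_mm > 0 and rec.w_sl_mm > 0

    def test_record_invariant_enforced(self):
        with pytest.raises(InputError):
            MorphometryRecord("s", 50.0, t_sl_mm=5.0, t_il_mm=8.0,
                              w_sl_mm=50.0, w_il_mm=50.0, shape="trapezoid",
                              mean_stt_mm=10.0)


class TestShape:
    def test_rectangle_is_quadrangular(self):
        assert classify_shape(level_profile(taper_map(lambda j: 40))) \
            == "quadrangular"

    def test_mild_taper_is_trapezoid(self):
        # width 32 inferior -> 40 superior: r = 0.8
        prof = level_profile(taper_map(lambda j: 32 + 8 * j // 45))
        assert classify_shape(prof) == "trapezoid"

    def test_strong_taper_to_inferior_point_is_triangular(self):
        # narrows to ~20% of the superior width at the inferior end
        prof = level_profile(taper_map(lambda j: min(50, 10 + j)))
        assert classify_shape(prof) == "triangular"

    def test_inverse_taper_is_trapezoid(self):
        prof = level_profile(taper_map(lambda j: 48 - 24 * j // 45))
        assert classify_shape(prof) == "trapezoid"


class TestStats:
    def test_constant_vector(self):
        s = summarize([4.2] * 9)
        assert s.mean == s.median == 4.2 and s.sd == 0.0
        assert s.min == s.max == 4.2 and s.n == 9

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=31)
        a, b = summarize(v), summarize(rng.permutation(v))
        assert a.mean == pytest.approx(b.mean) and a.median == b.median

    def test_fixture_medians(self):
        t3 = load_fixture_tables().table3
        assert summarize(t3["height_mm"]).median == pytest.approx(50.7)
        assert round(summarize(t3["thickness_sl_mm"]).mean, 1) == 13.1

    def test_bootstrap_constant_vector_is_degenerate(self):
        lo, hi = bootstrap_ci([3.0] * 12, "median", seed=1)
        assert lo == hi == 3.0

    def test_bootstrap_deterministic_under_seed(self):
        v = np.random.default_rng(5).normal(size=40)
        assert bootstrap_ci(v, "mean", seed=9) == bootstrap_ci(v, "mean", seed=9)

    def test_bootstrap_mean_interval_covers_truth(self):
        """Percentile bootstrap of the mean covers the true mean (0) in at
        least 90 of 100 seeded repetitions at n = 200."""
        rng = np.random.default_rng(0)
        covered = 0
        for rep in range(100):
            v = rng.standard_normal(200)
            lo, hi = bootstrap_ci(v, "mean", seed=rep)
            covered += lo <= 0.0 <= hi
        assert covered >= 90

    def test_bootstrap_needs_two_values(self):
        with pytest.raises(InputError):
            bootstrap_ci([1.0], "mean")


class TestOLS:
    def test_noiseless_fit_is_exact(self):
        x = np.linspace(0, 10, 30)
        fit = ols(2 + 3 * x, x, ["x"])
        assert fit.params["x"] == pytest.approx(3.0, abs=1e-9)
        assert fit.params["const"] == pytest.approx(2.0, abs=1e-9)

    def test_row_permutation_leaves_coefficients(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 2))
        y = 1 + X @ [1.5, -0.5] + rng.normal(0, 0.3, 60)
        perm = rng.permutation(60)
        a = ols(y, X, ["a", "b"]).params
        b = ols(y[perm], X[perm], ["a", "b"]).params
        assert a["a"] == pytest.approx(b["a"]) and a["b"] == pytest.approx(b["b"])

    def test_interval_contains_its_coefficient(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 1))
        y = X[:, 0] + rng.normal(0, 1, 50)
        fit = ols(y, X, ["x"])
        lo, hi = fit.conf_int["x"]
        assert lo <= fit.params["x"] <= hi

    def test_rank_deficient_design_rejected(self):
        X = np.ones((20, 2))  # duplicated constant columns
        with pytest.raises(InputError, match="rank"):
            ols(np.arange(20.0), X, ["a", "b"])
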