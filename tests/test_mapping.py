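import numpy as np
import pytest

from conftest import make_plate_set
from msbmap.io import InputError
from msbmap.mapping import (GridMap, aggregate_mean, aggregate_presence,
                            fraction_ge, fraction_slope_le, map_agreement,
                            roi_map, slope_map, stt_map, thickness_map)


def constant_map(value, shape=(5, 5), origin=(0.0, 0.0), kind="thickness",
                 present=None):
    pres = np.ones(shape, dtype=bool) if present is None else present
    return GridMap(values=np.where(pres, float(value), 0.0), present=pres,
                   origin_xz=origin, kind=kind)


class TestPerSubjectMaps:
    def test_parallel_plates_give_constant_thickness(self):
        s = make_plate_set(thickness=10.0)
        tm = thickness_map(s)
        assert tm.present.any()
        assert np.allclose(tm.values[tm.present], 10.0, atol=1e-9)

    def test_wedge_thickness_matches_linear_form(self):
        s = make_plate_set(anterior_fn=lambda x, z: 6.0 + 0.2 * np.asarray(x),
                           x_range=(-20.0, 20.0))
        tm = thickness_map(s)
        xs, _ = tm.cell_centers()
        for i in range(tm.shape[0]):
            vals = tm.values[i, tm.present[i]]
            if vals.size:
                assert np.abs(vals - (6.0 + 0.2 * xs[i])).max() <= 0.1

    def test_constant_skin_offset_gives_constant_stt(self):
        s = make_plate_set(thickness=8.0, stt=14.4)
        sm = stt_map(s)
        assert np.allclose(sm.values[sm.present], 14.4, atol=1e-9)

    def test_zero_offset_gives_zero_stt(self):
        s = make_plate_set(thickness=8.0, stt=0.0)
        sm = stt_map(s)
        assert np.allclose(sm.values[sm.present], 0.0, atol=1e-12)

    def test_flat_plate_has_zero_slope(self):
        s = make_plate_set(thickness=10.0)
        sl = slope_map(s)
        assert np.allclose(sl.values[sl.present], 0.0, atol=1e-6)

    def test_tilted_plate_slope_is_the_tilt_angle(self):
        t = np.tan(np.radians(20.0))
        s = make_plate_set(anterior_fn=lambda x, z: 30.0 + t * np.asarray(z))
        sl = slope_map(s)
        assert np.abs(sl.values[sl.present] - 20.0).max() <= 0.5

    def test_phantom_maps_match_analytic_truth(self, default_phantom_nv):
        ph = default_phantom_nv
        tol = 2 * ph.spec.voxel_mm
        frac_t, n = map_agreement(thickness_map(ph.surfaces),
                                  ph.truth.thickness_field, tol)
        frac_s, _ = map_agreement(stt_map(ph.surfaces), ph.truth.stt_field, tol)
        frac_a, _ = map_agreement(slope_map(ph.surfaces),
                                  ph.truth.slope_field, 3.0)
        assert n > 1000
        assert frac_t >= 0.95 and frac_s >= 0.95 and frac_a >= 0.90

    def test_non_intersecting_pair_warns_and_returns_empty(self):
        near = make_plate_set(thickness=5.0, x_range=(-10, 0), z_range=(-10, 0))
        far = make_plate_set(thickness=5.0, x_range=(40, 50), z_range=(40, 50))
        mixed = make_plate_set(thickness=5.0)
        mixed.posterior_cortex_front = far.posterior_cortex_front
        mixed.anterior_cortex_front = near.anterior_cortex_front
        with pytest.warns(UserWarning, match="empty map"):
            tm = thickness_map(mixed)
        assert not tm.present.any()

    def test_mesh_refinement_changes_little(self):
        """Halving the surface sampling step changes the thickness map by
        less than one voxel spacing in the median."""
        from msbmap.phantom import PhantomSpec, generate_phantom
        from dataclasses import replace

        coarse = generate_phantom(PhantomSpec(), 2, with_volume=False)
        fine = generate_phantom(replace(PhantomSpec(), mesh_mm=0.625), 2,
                                with_volume=False)
        a = thickness_map(coarse.surfaces)
        b = thickness_map(fine.surfaces)
        frac, n = map_agreement(a, b, coarse.spec.voxel_mm)
        assert n > 1000 and frac >= 0.99


class TestAggregation:
    def test_single_subject_presence_is_binary(self, default_phantom_nv):
        tm = thickness_map(default_phantom_nv.surfaces)
        pres = aggregate_presence([tm])
        assert set(np.unique(pres.values)) <= {0.0, 100.0}

    def test_two_identical_subjects_equal_one(self):
        m = constant_map(9.0)
        one = aggregate_presence([m])
        two = aggregate_presence([m, m])
        assert np.array_equal(one.values, two.values)

    def test_staggered_footprints_have_hand_counted_coverage(self):
        # 10 subjects; all cover cell (5,5); exactly 4 cover cell (0,0)
        maps = []
        for k in range(10):
            origin = (0.0, 0.0) if k < 4 else (3.0, 3.0)
            maps.append(constant_map(8.0, shape=(6, 6), origin=origin))
        pres = aggregate_presence(maps)
        assert pres.value_at(5.5, 5.5) == 100.0
        assert pres.value_at(0.5, 0.5) == 40.0

    def test_mean_of_constants(self):
        out = aggregate_mean([constant_map(10.0), constant_map(20.0)])
        assert np.allclose(out.values[out.present], 15.0)

    def test_mean_of_single_map_is_itself(self):
        m = constant_map(13.0)
        out = aggregate_mean([m])
        assert np.array_equal(out.values, m.values)
        assert np.array_equal(out.present, m.present)

    def test_disjoint_masks_union_without_mixing(self):
        pa = np.zeros((4, 4), dtype=bool)
        pa[:2] = True
        pb = ~pa
        a = constant_map(10.0, shape=(4, 4), present=pa)
        b = constant_map(20.0, shape=(4, 4), present=pb)
        out = aggregate_mean([a, b])
        assert out.present.all()
        assert np.allclose(out.values[:2], 10.0)
        assert np.allclose(out.values[2:], 20.0)

    def test_empty_list_rejected(self):
        with pytest.raises(InputError):
            aggregate_presence([])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        maps = [constant_map(v, origin=(float(rng.integers(0, 3)), 0.0))
                for v in rng.uniform(5, 15, 7)]
        fwd = fraction_ge(maps, 10.0)
        rev = fraction_ge(maps[::-1], 10.0)
        assert np.array_equal(fwd.values, rev.values)


class TestPredicateMaps:
    def test_fraction_ge_all_or_none(self):
        cohort = [constant_map(10.0) for _ in range(5)]
        assert np.allclose(fraction_ge(cohort, 8.0).values, 100.0)
        assert np.allclose(fraction_ge(cohort, 12.0).values, 0.0)

    def test_wedge_cohort_crossing_boundary(self):
        s = make_plate_set(anterior_fn=lambda x, z: 6.0 + 0.2 * np.asarray(x),
                           x_range=(-20.0, 20.0))
        tm = thickness_map(s)
        fr = fraction_ge([tm, tm, tm], 8.0)   # t = 8 at x = 10
        xs, _ = fr.cell_centers()
        for i, x in enumerate(xs):
            present = tm.present[i] if i < tm.shape[0] else np.array([])
            if not present.any():
                continue
            vals = fr.values[i][present]
            if x < 9.0:
                assert np.allclose(vals, 0.0)
            elif x > 11.0:
                assert np.allclose(vals, 100.0)

    def test_fraction_slope_le_threshold_modes(self):
        flat = constant_map(10.0, kind="slope")
        steep = constant_map(15.0, kind="slope")
        strict = fraction_slope_le([flat, steep], 15.0, strict=True)
        loose = fraction_slope_le([flat, steep], 15.0, strict=False)
        assert np.allclose(strict.values[strict.present], 50.0)
        assert np.allclose(loose.values[loose.present], 100.0)

    def test_roi_bounded_by_conjunct_fractions(self):
        rng = np.random.default_rng(1)
        tmaps = [constant_map(0, present=rng.random((6, 6)) < 0.8)
                 for _ in range(6)]
        for m in tmaps:
            m.values[m.present] = rng.uniform(4, 14, m.present.sum())
        smaps = [constant_map(0, kind="slope", present=rng.random((6, 6)) < 0.8)
                 for _ in range(6)]
        for m in smaps:
            m.values[m.present] = rng.uniform(0, 40, m.present.sum())
        roi = roi_map(tmaps, smaps, 8.0, 15.0)
        f_t = fraction_ge(tmaps, 8.0)
        f_s = fraction_slope_le(smaps, 15.0)
        assert (roi.values <= np.minimum(f_t.values, f_s.values) + 1e-9).all()

    def test_roi_zero_when_predicates_hold_on_disjoint_subjects(self):
        thick_ok = constant_map(12.0)
        thick_bad = constant_map(4.0)
        slope_ok = constant_map(5.0, kind="slope")
        slope_bad = constant_map(40.0, kind="slope")
        roi = roi_map([thick_ok, thick_bad], [slope_bad, slope_ok], 10.0, 15.0)
        assert np.allclose(roi.values, 0.0)
        assert np.allclose(fraction_ge([thick_ok, thick_bad], 10.0).values, 50.0)
        assert np.allclose(
            fraction_slope_le([slope_bad, slope_ok], 15.0).values, 50.0)

    def test_roi_monotone_in_length_and_threshold(self):
        rng = np.random.default_rng(2)
        tmaps = [constant_map(v) for v in rng.uniform(5, 13, 8)]
        smaps = [constant_map(v, kind="slope") for v in rng.uniform(5, 25, 8)]
        prev = None
        for L in (6.0, 8.0, 10.0, 12.0):
            cur = roi_map(tmaps, smaps, L, 15.0)
            if prev is not None:
                assert (cur.values <= prev.values + 1e-9).all()
            prev = cur
        lo = roi_map(tmaps, smaps, 8.0, 10.0)
        hi = roi_map(tmaps, smaps, 8.0, 20.0)
        assert (lo.values <= hi.values + 1e-9).all()

    def test_unpaired_roi_lists_rejected(self):
        with pytest.raises(InputError, match="paired"):
            roi_map([constant_map(10.0)], [], 6.0)
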