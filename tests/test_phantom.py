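import numpy as np
import pytest
from dataclasses import replace

from msbmap.morphometry import ols
from msbmap.phantom import (ParameterError, PhantomSpec, PopulationParams,
                            apply_rigid, generate_phantom, sample_cohort,
                            sample_cohort_table)
from msbmap.probe import probe_thickness_map


def test_invalid_specs_name_the_violated_invariant():
    with pytest.raises(ParameterError, match="cortex_mm"):
        generate_phantom(replace(PhantomSpec(), cortex_mm=6.0,
                                 base_thickness_mm=11.0))
    with pytest.raises(ParameterError, match="voxel_mm"):
        generate_phantom(replace(PhantomSpec(), voxel_mm=1.5))
    with pytest.raises(ParameterError, match="height_mm"):
        generate_phantom(replace(PhantomSpec(), height_mm=-1.0))
    with pytest.raises(ParameterError, match="footprint"):
        generate_phantom(replace(PhantomSpec(), protuberance_offset_x_mm=80.0))


def test_flat_spec_gives_zero_slope_everywhere():
    spec = replace(PhantomSpec(), protuberance_amp_mm=0.0,
                   face_curvature_deg=0.0)
    ph = generate_phantom(spec, seed=0, with_volume=False)
    s = ph.truth.slope_field
    assert np.allclose(s.values[s.present], 0.0, atol=1e-12)


def test_uniform_slab_thickness_field():
    spec = replace(PhantomSpec(), base_thickness_mm=10.0,
                   protuberance_amp_mm=0.0, face_curvature_deg=0.0)
    ph = generate_phantom(spec, seed=0, with_volume=False)
    t = ph.truth.thickness_field
    assert np.allclose(t.values[t.present], 10.0, atol=1e-12)


def test_base_thickness_shift_is_exact_when_no_protuberances():
    spec = replace(PhantomSpec(), protuberance_amp_mm=0.0)
    a = generate_phantom(spec, seed=0, with_volume=False)
    b = generate_phantom(replace(spec, base_thickness_mm=spec.base_thickness_mm + 2.5),
                         seed=0, with_volume=False)
    ta, tb = a.truth.thickness_field, b.truth.thickness_field
    assert np.array_equal(ta.present, tb.present)
    assert np.allclose(tb.values[tb.present] - ta.values[ta.present], 2.5,
                       atol=1e-12)


def test_cortical_median_hu_near_configured_mean(default_phantom):
    vol = default_phantom.volume
    med = np.median(vol.hu[vol.labels == 2])
    assert abs(med - 325.0) <= 10.0


def test_every_voxel_has_exactly_one_label(default_phantom):
    labels = default_phantom.volume.labels
    assert set(np.unique(labels)) <= {0, 1, 2, 3}


def test_cortical_shell_encloses_cancellous(default_phantom):
    """No cancellous voxel sits on the outer surface of the bone."""
    from scipy import ndimage

    labels = default_phantom.volume.labels
    bone = (labels == 2) | (labels == 3)
    interior = ndimage.binary_erosion(
        bone, structure=ndimage.generate_binary_structure(3, 1))
    surface = bone & ~interior
    assert not (labels[surface] == 3).any()


def test_volume_probe_reproduces_truth_thickness(default_phantom):
    """Brute-force line probe through the labels matches the analytic field
    within two voxel spacings at random interior cells."""
    ph = default_phantom
    probe = probe_thickness_map(ph.volume)
    truth = ph.truth.thickness_field
    rng = np.random.default_rng(0)
    xs, zs = truth.cell_centers()
    # interior cells: away from the lateral cortical shell
    cand = [(x, z) for i, x in enumerate(xs) for j, z in enumerate(zs)
            if truth.present[i, j]
            and truth.present[max(i - 4, 0), j] and truth.present[
                min(i + 4, truth.shape[0] - 1), j]
            and truth.present[i, max(j - 4, 0)] and truth.present[
                i, min(j + 4, truth.shape[1] - 1)]]
    pick = rng.choice(len(cand), size=50, replace=False)
    tol = 2 * ph.spec.voxel_mm
    bad = 0
    for k in pick:
        x, z = cand[k]
        pv = probe.value_at(x, z)
        tv = truth.value_at(x, z)
        if np.isnan(pv) or abs(pv - tv) > tol:
            bad += 1
    assert bad == 0


def test_generation_is_deterministic():
    a = generate_phantom(PhantomSpec(), seed=5)
    b = generate_phantom(PhantomSpec(), seed=5)
    assert np.array_equal(a.surfaces.skin.vertices, b.surfaces.skin.vertices)
    assert np.array_equal(a.volume.hu, b.volume.hu)
    assert np.array_equal(a.volume.labels, b.volume.labels)


class TestApplyRigid:
    def test_identity_leaves_surfaces_unchanged(self, default_phantom_nv):
        moved = apply_rigid(default_phantom_nv, (0, 0, 0), (0, 0, 0))
        d = np.abs(moved.surfaces.skin.vertices
                   - default_phantom_nv.surfaces.skin.vertices)
        assert d.max() <= 1e-9

    def test_rotation_then_inverse_restores_vertices(self, default_phantom_nv):
        ph = apply_rigid(default_phantom_nv, (10, 0, 0), (0, 0, 0))
        ph = apply_rigid(ph, (-10, 0, 0), (0, 0, 0))
        d = np.abs(ph.surfaces.anterior_cortex_front.vertices
                   - default_phantom_nv.surfaces.anterior_cortex_front.vertices)
        assert d.max() <= 1e-6

    def test_rigidity_of_intervertex_distances(self, default_phantom_nv):
        moved = apply_rigid(default_phantom_nv, (10, 5, 7), (4, -1, 2))
        v0 = default_phantom_nv.surfaces.bone_vertices()[::37]
        v1 = moved.surfaces.bone_vertices()[::37]
        d0 = np.linalg.norm(v0[:, None] - v0[None, :], axis=-1)
        d1 = np.linalg.norm(v1[:, None] - v1[None, :], axis=-1)
        assert np.abs(d0 - d1).max() <= 1e-6

    def test_nonfinite_rotation_rejected(self, default_phantom_nv):
        with pytest.raises(ParameterError):
            apply_rigid(default_phantom_nv, (np.nan, 0, 0), (0, 0, 0))


class TestCohort:
    def test_empty_cohort(self):
        phantoms, table = sample_cohort(0)
        assert phantoms == [] and len(table) == 0

    def test_negative_n_rejected(self):
        with pytest.raises(ParameterError):
            sample_cohort_table(-1)

    def test_determinism(self):
        a = sample_cohort_table(30, seed=9)
        b = sample_cohort_table(30, seed=9)
        assert a.equals(b)

    def test_sex_balanced_and_bmi_positive(self):
        t = sample_cohort_table(49, seed=3)
        assert set(t["male"]) == {0, 1}
        assert abs(t["male"].sum() - 24.5) <= 0.5
        assert (t["bmi"] > 0).all()

    def test_ols_recovers_generating_sex_coefficient(self):
        """OLS on the cohort's true scalars recovers the generating effect
        of sex on superior-level thickness within its 95% interval."""
        t = sample_cohort_table(200, seed=7)
        fit = ols(t["t_sl"], np.column_stack([t["male"], t["body_height_cm"]]),
                  ["male", "height"])
        assert fit.contains("male", PopulationParams().beta_sex_thickness_sl)
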