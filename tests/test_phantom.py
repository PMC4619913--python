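"""Synthetic phantom construction, signal simulation, cohort generation."""

import numpy as np
import pytest

from dtinet.gradients import default_gradient_table
from dtinet.grids import world_to_voxel
from dtinet.phantom import (BundleAsymmetry, BundleSpec, CohortSpec, PhantomSpec,
                            build_phantom, default_cohort_spec,
                            default_phantom_template, generate_cohort,
                            ground_truth_of, simulate_dwi)
from dtinet.tensor import compute_fa, fit_tensor

from .conftest import straight_bundle_spec

FA_ROD = 0.7990222  # FA of diag(1.7, 0.3, 0.3)e-3, from the formula oracle


class TestBuildPhantom:
    def test_straight_bundle_orientation_and_fa(self, straight_phantom):
        spec, labels, tensors = straight_phantom
        fa = compute_fa(tensors).fa
        in_tube = fa > 0.5
        assert in_tube.sum() > 10
        # principal axis of every in-tube voxel is the tube axis (+-x)
        e1 = tensors.principal_direction[in_tube]
        np.testing.assert_allclose(np.abs(e1[:, 0]), 1.0, atol=1e-12)
        np.testing.assert_allclose(fa[in_tube], FA_ROD, atol=1e-6)

    def test_zero_bundles_all_isotropic(self):
        spec = straight_bundle_spec()
        labels, tensors = build_phantom(spec, bundles=())
        assert np.all(compute_fa(tensors).fa == 0.0)

    def test_deterministic(self):
        spec = straight_bundle_spec()
        l1, t1 = build_phantom(spec)
        l2, t2 = build_phantom(spec)
        np.testing.assert_array_equal(l1.labels, l2.labels)
        np.testing.assert_array_equal(t1.tensors, t2.tensors)

    def test_bundle_endpoints_carry_their_labels(self):
        spec = default_phantom_template()
        labels, _ = build_phantom(spec)
        for bundle in spec.bundles:
            for point, region in zip(
                (bundle.centerline[0], bundle.centerline[-1]), bundle.endpoint_regions
            ):
                vox = world_to_voxel(labels.affine, point[None, :])[0]
                assert labels.labels[tuple(vox)] == region

    def test_endpoint_outside_region_raises(self):
        spec = straight_bundle_spec()
        bad = BundleSpec(
            name="stray", centerline=np.array([[4.0, 8.0, 8.0], [36.0, 2.0, 8.0]]),
            radius_mm=1.0, endpoint_regions=(1, 2), hemisphere="left",
        )
        with pytest.raises(ValueError, match="endpoint"):
            build_phantom(spec, bundles=(bad,))

    def test_overlapping_region_masks_rejected(self):
        spec = straight_bundle_spec()
        regions = dict(spec.regions)
        regions[2] = regions[1].copy()
        with pytest.raises(ValueError, match="overlap"):
            PhantomSpec(spec.grid_shape, spec.voxel_size, regions, ())

    def test_unpaired_labels_rejected(self):
        spec = straight_bundle_spec()
        with pytest.raises(ValueError, match="pairs"):
            PhantomSpec(spec.grid_shape, spec.voxel_size, {1: spec.regions[1]}, ())

    def test_bad_diffusivities_rejected(self):
        with pytest.raises(ValueError, match="axial > radial"):
            BundleSpec("x", np.zeros((2, 3)) + [[0, 0, 0], [1, 0, 0]], 1.0, (1, 2),
                       "left", axial_diffusivity=0.3e-3, radial_diffusivity=0.5e-3)


class TestSimulateDWI:
    def test_isotropic_closed_form(self, gtab):
        d = 0.7e-3
        spec = straight_bundle_spec()
        _, tensors = build_phantom(spec, bundles=())
        dwi = simulate_dwi(tensors, gtab, s0=1000.0, noise_sigma=0.0)
        expected = 1000.0 * np.exp(-gtab.bvals * d)
        np.testing.assert_allclose(dwi.data[5, 5, 5], expected, rtol=1e-12)

    def test_b0_equals_s0_exactly(self, gtab, straight_phantom):
        _, _, tensors = straight_phantom
        dwi = simulate_dwi(tensors, gtab, s0=777.0, noise_sigma=0.0)
        assert np.all(dwi.data[..., 0] == 777.0)

    def test_noiseless_forward_fit_roundtrip(self, gtab, straight_phantom):
        _, _, tensors = straight_phantom
        dwi = simulate_dwi(tensors, gtab, noise_sigma=0.0)
        fitted = fit_tensor(dwi)
        rel = np.linalg.norm(fitted.tensors - tensors.tensors, axis=(-2, -1)) \
            / np.linalg.norm(tensors.tensors, axis=(-2, -1))
        assert rel.max() < 1e-9

    def test_rician_noise_keeps_signals_positive_and_is_seeded(self, gtab, straight_phantom):
        _, _, tensors = straight_phantom
        a = simulate_dwi(tensors, gtab, noise_sigma=0.1, seed=5)
        b = simulate_dwi(tensors, gtab, noise_sigma=0.1, seed=5)
        c = simulate_dwi(tensors, gtab, noise_sigma=0.1, seed=6)
        assert np.all(a.data > 0)
        np.testing.assert_array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_non_psd_tensor_names_voxel(self, gtab, straight_phantom):
        _, _, tensors = straight_phantom
        broken = tensors.tensors.copy()
        broken[2, 3, 4] = -1e-3 * np.eye(3)
        from dtinet.tensor import TensorField

        field = TensorField.from_tensors(broken, tensors.affine)
        with pytest.raises(ValueError, match=r"\(2, 3, 4\)"):
            simulate_dwi(field, gtab)


class TestCohort:
    def test_null_effects_mark_no_asymmetry(self):
        spec = default_cohort_spec(n_subjects=4, seed=1)
        truth = ground_truth_of(spec)
        assert truth.region_pairs == {}
        assert truth.bundle_pairs == {}

    def test_radius_effect_marks_both_endpoint_pairs_leftward(self):
        spec = default_cohort_spec(n_subjects=4, seed=1, arcuate_radius_effect=2.0)
        truth = ground_truth_of(spec)
        assert truth.bundle_pairs == {"arcuate": "leftward"}
        assert truth.region_pairs == {(1, 2): "leftward", (3, 4): "leftward"}

    def test_cohort_reproducible_and_subject_stable(self):
        spec = default_cohort_spec(n_subjects=3, seed=42)
        a = [s.dwi.data for s in generate_cohort(spec)]
        b = [s.dwi.data for s in generate_cohort(spec)]
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)
        # subject k does not depend on how many subjects follow it
        spec2 = default_cohort_spec(n_subjects=2, seed=42)
        c = [s.dwi.data for s in generate_cohort(spec2)]
        np.testing.assert_array_equal(a[0], c[0])

    def test_effect_below_tracking_threshold_warns(self):
        spec = default_cohort_spec(n_subjects=1, seed=0)
        spec = CohortSpec(
            n_subjects=1,
            phantom_template=spec.phantom_template,
            asymmetry_effects={"arcuate": BundleAsymmetry(axial_diffusivity=0.2)},
            seed=0,
        )
        with pytest.warns(UserWarning, match="tracking threshold"):
            next(generate_cohort(spec))

    def test_unknown_effect_pair_rejected(self):
        tpl = default_phantom_template()
        with pytest.raises(ValueError, match="unknown bundle pairs"):
            CohortSpec(n_subjects=2, phantom_template=tpl,
                       asymmetry_effects={"nonesuch": BundleAsymmetry(radius=2.0)})

    def test_presence_effect_direction(self):
        assert BundleAsymmetry(presence_right=0.2).direction == "leftward"
        assert BundleAsymmetry(radius=0.5).direction == "rightward"
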