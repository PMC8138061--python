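import numpy as np
import pytest

from msdiffusion import (
    CohortSpec,
    DWIVolume,
    label_components,
    make_gradient_table,
    simulate_cohort,
    simulate_dwi,
)
from msdiffusion.phantom import Bundle, Lesion, PhantomSpec, default_phantom


class TestSignalModel:
    def test_single_tensor_closed_form(self):
        """S/S0 = exp(-b g^T D g): x-gradient on diag(1.7,.3,.3)e-3 at b=1000."""
        bvals = np.array([0.0, 1000.0, 1000.0, 1000.0, 1000.0, 1000.0, 1000.0])
        dirs = np.array(
            [
                [0, 0, 0],
                [1, 0, 0],
                [0, 1, 0],
                [0, 0, 1],
                [np.sqrt(0.5), np.sqrt(0.5), 0],
                [np.sqrt(0.5), 0, np.sqrt(0.5)],
                [0, np.sqrt(0.5), np.sqrt(0.5)],
            ]
        )
        from msdiffusion.gradients import GradientTable

        gt = GradientTable(bvals=bvals, bvecs=dirs)
        spec = PhantomSpec(
            grid_shape=(4, 4, 4),
            bundles=(Bundle(lo=(0, 0, 0), hi=(4, 4, 4)),),
            snr=np.inf,
            mirror_symmetric=False,
        )
        dwi, _ = simulate_dwi(spec, gt, seed=0)
        s = dwi.signal[1, 1, 1]
        assert s[0] == pytest.approx(spec.s0)
        assert s[1] / spec.s0 == pytest.approx(np.exp(-1.7), rel=1e-12)
        assert s[1] / spec.s0 == pytest.approx(0.18268, abs=1e-5)
        assert s[2] / spec.s0 == pytest.approx(np.exp(-0.3), rel=1e-12)

    def test_b0_volumes_equal_s0_everywhere(self, gtab, noiseless_phantom):
        spec, dwi, _ = noiseless_phantom
        b0 = dwi.signal[..., gtab.b0_mask]
        assert np.allclose(b0, spec.s0)

    def test_infinite_snr_is_exactly_noiseless(self, gtab):
        spec = default_phantom(grid_shape=(12, 12, 8))
        a, _ = simulate_dwi(spec, gtab, seed=1)
        b, _ = simulate_dwi(spec, gtab, seed=2)
        np.testing.assert_array_equal(a.signal, b.signal)

    def test_rician_mean_converges_at_high_snr(self, gtab):
        """Signal conservation: mean of many draws ~ noiseless magnitude."""
        spec = default_phantom(grid_shape=(10, 10, 6), snr=50)
        clean, _ = simulate_dwi(
            default_phantom(grid_shape=(10, 10, 6)), gtab, seed=0
        )
        acc = np.zeros_like(clean.signal[..., 0])
        n_draws = 1000
        for k in range(n_draws):
            noisy, _ = simulate_dwi(spec, gtab, seed=k)
            acc += noisy.signal[..., 3]  # a diffusion-weighted volume
        rel = np.abs(acc / n_draws - clean.signal[..., 3]) / clean.signal[..., 3]
        assert rel.mean() < 0.01

    def test_mirror_symmetry_of_noiseless_volume(self, gtab):
        """Left-right flip invariance of the lesion-free mirrored phantom.

        Flipping the grid x axis maps the signal onto itself once gradient
        x components are sign-corrected, which for x-aligned bundles and
        isotropic background leaves every per-volume image unchanged.
        """
        spec = default_phantom(grid_shape=(20, 16, 10))
        dwi, _ = simulate_dwi(spec, gtab, seed=0)
        np.testing.assert_allclose(dwi.signal, dwi.signal[::-1], rtol=1e-12)

    def test_lesion_outside_bundle_rejected(self, gtab):
        spec = default_phantom(
            lesions=(Lesion(center=(2, 2, 2), radius=3.0),), grid_shape=(40, 40, 16)
        )
        with pytest.raises(ValueError, match="grid|inside"):
            simulate_dwi(spec, gtab, seed=0)

    def test_dispersion_reads_as_anisotropy_not_diffusivity(self, gtab):
        """Cone dispersion redistributes orientations, not total diffusivity:
        the fitted MD shifts far less than the fitted AD."""
        from msdiffusion.dti import fit_tensor

        coh = default_phantom(grid_shape=(16, 16, 10))
        disp_spec = PhantomSpec(
            grid_shape=(16, 16, 10),
            bundles=coh.bundles,
            lesions=(
                Lesion(
                    center=(4, 8, 5),
                    radius=2.0,
                    eigvals=(1.7e-3, 0.3e-3, 0.3e-3),
                    dispersion_deg=35.0,
                ),
            ),
        )
        dwi, truth = simulate_dwi(disp_spec, gtab, seed=0)
        tf = fit_tensor(dwi, truth["wm_mask"])
        md = tf.eigvals.mean(axis=-1)
        ad = tf.eigvals[..., 0]
        lesion = truth["lesion_label_volume"] == 1
        nawm = truth["wm_mask"] & ~lesion
        rel_md = abs(md[lesion].mean() - md[nawm].mean()) / md[nawm].mean()
        rel_ad = abs(ad[lesion].mean() - ad[nawm].mean()) / ad[nawm].mean()
        assert rel_md < 0.10
        assert rel_md < rel_ad / 2


class TestNiftiRoundTrip:
    def test_bit_for_bit(self, noiseless_phantom, tmp_path):
        _, dwi, _ = noiseless_phantom
        dwi.save(tmp_path / "dwi.nii.gz")
        back = DWIVolume.load(tmp_path / "dwi.nii.gz")
        np.testing.assert_array_equal(back.signal, dwi.signal)
        np.testing.assert_array_equal(
            back.gradient_table.bvals, dwi.gradient_table.bvals
        )
        np.testing.assert_array_equal(
            back.gradient_table.bvecs, dwi.gradient_table.bvecs
        )
        np.testing.assert_allclose(back.voxel_size, dwi.voxel_size)


class TestCohort:
    def test_group_count_supports(self):
        cohort = CohortSpec(seed=5)
        subjects = simulate_cohort(cohort)
        for s in subjects:
            lo, hi = cohort.count_range[s.group]
            assert lo <= s.lesion_count <= hi

    def test_deterministic_for_fixed_seed(self):
        a = simulate_cohort(CohortSpec(seed=9, n_per_group={"high": 1, "low": 1}))
        b = simulate_cohort(CohortSpec(seed=9, n_per_group={"high": 1, "low": 1}))
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.dwi.signal, sb.dwi.signal)
            assert sa.lesion_count == sb.lesion_count

    def test_total_rois_equal_sum_of_draws(self):
        """Oracle: labeled 26-connected components per subject."""
        subjects = simulate_cohort(CohortSpec(seed=3))
        total = 0
        for s in subjects:
            labeled = label_components(
                s.truth["lesion_label_volume"] > 0, connectivity=26
            )
            assert labeled.n_rois == s.lesion_count
            total += labeled.n_rois
        assert total == sum(s.lesion_count for s in subjects)

    def test_overlapping_group_supports_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            CohortSpec(count_range={"high": (3, 6), "low": (2, 4)}).validate()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            CohortSpec(n_per_group={"high": 0, "low": 2}).validate()
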