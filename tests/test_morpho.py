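"""Nuclear FWHM metrics, group statistics, organelle counts and volumes."""

import numpy as np
import pytest
from scipy import stats

from aggrescope import morpho, syndata
from aggrescope.io_core import ImageStack, Roi, RoiSet
from aggrescope.morpho import FWHM_PER_SIGMA


class TestFwhmProfile:
    def test_gaussian_profile_matches_closed_form(self):
        x = np.arange(101.0)
        y = 100 * np.exp(-((x - 50) ** 2) / (2 * 10.0**2)) + 5
        fwhm = morpho.fwhm_profile(y)
        assert fwhm == pytest.approx(FWHM_PER_SIGMA * 10.0, abs=0.1)

    def test_rectangular_pulse_width_is_pulse_length(self):
        y = np.zeros(40)
        y[10:18] = 1.0  # 8 samples wide
        assert morpho.fwhm_profile(y) == pytest.approx(8.0, abs=0.5)

    def test_monotone_ramp_has_no_crossing(self):
        with pytest.raises(morpho.BoundaryError):
            morpho.fwhm_profile(np.arange(30.0))

    @pytest.mark.parametrize("sigma", [4.0, 8.0, 16.0])
    def test_closed_form_within_half_percent(self, sigma):
        x = np.arange(201.0)
        y = 50 * np.exp(-((x - 100) ** 2) / (2 * sigma**2))
        assert morpho.fwhm_profile(y) == pytest.approx(
            FWHM_PER_SIGMA * sigma, rel=0.005
        )


class TestFitNucleus2D:
    def test_noiseless_sigma_recovered(self):
        imgs, gt = syndata.simulate_nuclei(
            1, sigmas=[8.0], seed=0, noise=syndata.NO_NOISE
        )
        fit = morpho.fit_nucleus_2d(imgs[0], "rfp")
        assert fit.sigma == pytest.approx(8.0, abs=1e-3)
        assert fit.fwhm / fit.sigma == pytest.approx(FWHM_PER_SIGMA, abs=1e-5)

    def test_flat_image_flagged(self):
        with pytest.raises(morpho.FitError):
            morpho.fit_nucleus_2d(np.full((32, 32), 5.0))

    def test_recovery_unbiased_at_moderate_noise(self):
        imgs, gt = syndata.simulate_nuclei(
            50, sigmas=[8.0], seed=3,
            noise=syndata.NoiseModel(gain=1.0, read_noise_sd=30.0),  # SNR ~ 10
        )
        sigmas = [morpho.fit_nucleus_2d(im, "rfp").sigma for im in imgs]
        assert np.mean(sigmas) == pytest.approx(8.0, abs=0.1)

    def test_agrees_with_1d_profile_on_noiseless_gaussians(self):
        for sigma in (4.0, 10.0, 20.0):
            imgs, _ = syndata.simulate_nuclei(
                1, sigmas=[sigma], seed=1, window=160, noise=syndata.NO_NOISE
            )
            frame = imgs[0].channel("rfp")
            fit = morpho.fit_nucleus_2d(frame)
            row = frame[int(round(fit.center[1]))]
            fwhm_1d = morpho.fwhm_profile(row)
            assert fwhm_1d == pytest.approx(fit.fwhm, rel=0.05)


class TestCompareGroups:
    def test_identical_groups_give_p_one(self):
        out = morpho.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_hand_computed_welch_example(self):
        out = morpho.compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert out["t"] == pytest.approx(-3.674, abs=0.001)
        assert out["p"] == pytest.approx(0.021, abs=0.002)

    def test_condensed_nuclei_detected_as_group_difference(self):
        """Planted sigma 10 vs 6 groups separate at p < 0.01 with n = 60."""
        imgs, gt = syndata.simulate_nuclei(60, sigmas=[10.0, 6.0], seed=2)
        fwhms = {0: [], 1: []}
        for im, rec in zip(imgs, gt.records):
            fwhms[rec["group"]].append(morpho.fit_nucleus_2d(im, "rfp").fwhm)
        out = morpho.compare_groups(fwhms[0], fwhms[1])
        assert out["p"] < 0.01
        assert out["mean_a"] > out["mean_b"]

    def test_matches_permutation_test_within_mc_error(self, rng):
        """Welch p agrees with a permutation oracle on random small inputs."""

        def welch_t(a_mat, b_mat):
            va = a_mat.var(axis=-1, ddof=1) / a_mat.shape[-1]
            vb = b_mat.var(axis=-1, ddof=1) / b_mat.shape[-1]
            return (a_mat.mean(axis=-1) - b_mat.mean(axis=-1)) / np.sqrt(va + vb)

        n_perm = 10_000
        for _ in range(20):
            na, nb = int(rng.integers(8, 16)), int(rng.integers(8, 16))
            a = rng.normal(0, 1, na)
            b = rng.normal(rng.uniform(-1, 1), 1, nb)
            out = morpho.compare_groups(a, b)
            pooled = np.concatenate([a, b])
            perms = rng.permuted(
                np.broadcast_to(pooled, (n_perm, na + nb)).copy(), axis=1
            )
            t_perm = welch_t(perms[:, :na], perms[:, na:])
            p_perm = np.mean(np.abs(t_perm) >= abs(out["t"]))
            mc_err = 4 * np.sqrt(max(p_perm * (1 - p_perm), 1e-4) / n_perm)
            # Welch's t-reference and the exact permutation null agree up to
            # the small-sample approximation error of the t distribution
            assert abs(out["p"] - p_perm) < mc_err + 0.02


class TestObjectCounting:
    def _labels(self, frame):
        return ImageStack(frame[None, None].astype(float), ["labels"])

    def _cell(self, x0, y0, size, label):
        pts = np.array(
            [[x0, y0], [x0 + size, y0], [x0 + size, y0 + size], [x0, y0 + size]],
            dtype=float,
        )
        return Roi("polygon", pts, label=label)

    def test_empty_labels_give_zero_counts(self):
        cells = RoiSet("em", [self._cell(0, 0, 30, "c0")])
        objects, counts = morpho.count_objects_per_cell(
            self._labels(np.zeros((32, 32))), cells, {1: "vesicle"}
        )
        assert len(objects) == 0
        assert counts.loc["c0", "vesicle"] == 0

    def test_touching_same_class_squares_are_one_object(self):
        frame = np.zeros((32, 32))
        frame[5:10, 5:10] = 1
        frame[10:15, 10:15] = 1  # corner contact: 8-connectivity joins them
        cells = RoiSet("em", [self._cell(0, 0, 31, "c0")])
        _, counts = morpho.count_objects_per_cell(
            self._labels(frame), cells, {1: "vesicle"}
        )
        assert counts.loc["c0", "vesicle"] == 1

    def test_planted_counts_recovered_exactly(self):
        stack, cells, gt = syndata.simulate_em_sections(
            4, {"vesicle": 3.0, "lipid_droplet": 2.0}, seed=8
        )
        # count on the central section only, restricted to objects crossing it
        mid = stack.pixels.shape[0] // 2
        frame = ImageStack(stack.pixels[mid][None], ["labels"])
        class_map = {v: k for k, v in syndata.EM_CLASS_CODES.items()}
        objects, counts = morpho.count_objects_per_cell(frame, cells, class_map)
        planted_mid = [
            r for r in gt.records
            if abs(r["center_zyx"][0] - mid) <= r["radius_px"] / (0.06 / 0.01)
        ]
        assert len(objects) == len(planted_mid)

    def test_em_group_difference_detected(self):
        """Two conditions with planted class means (2, 6) separate by t-test."""
        rng = np.random.default_rng(0)
        a = rng.poisson(2.0, 203)  # control-like group
        b = rng.poisson(6.0, 133)  # expression-like group
        out = morpho.compare_groups(a, b)
        assert out["p"] < 0.01


class TestVolumes3D:
    def _stack(self, vol):
        return ImageStack(vol[:, None].astype(float), ["labels"])

    def test_single_section_area_to_volume_arithmetic(self):
        vol = np.zeros((1, 20, 20))
        vol[0, 5:15, 5:15] = 3  # 100 px^2
        out = morpho.volumes_3d(self._stack(vol), voxel_um=(0.01, 0.01, 0.06),
                                class_map={3: "mitochondrion"})
        assert len(out) == 1
        assert out.volume_um3.iloc[0] == pytest.approx(6.0e-4)

    def test_object_spanning_sections_is_one_component(self):
        vol = np.zeros((3, 10, 10))
        vol[:, 4:6, 4:6] = 3
        out = morpho.volumes_3d(self._stack(vol), class_map={3: "m"})
        assert len(out) == 1
        assert out.voxels.iloc[0] == 12

    def test_empty_section_separates_components(self):
        vol = np.zeros((5, 10, 10))
        vol[0:2, 4:6, 4:6] = 3
        vol[3:5, 4:6, 4:6] = 3
        out = morpho.volumes_3d(self._stack(vol), class_map={3: "m"})
        assert len(out) == 2

    def test_total_voxel_count_is_conserved(self):
        stack, _, gt = syndata.simulate_em_sections(
            4, {"mitochondrion": 2.0}, seed=5
        )
        out = morpho.volumes_3d(stack, class_map={3: "mitochondrion"})
        labeled = int((stack.pixels[:, 0] == 3).sum())
        assert out.voxels.sum() == labeled
        dx, dy, dz = 0.01, 0.01, 0.06
        assert out.volume_um3.sum() == pytest.approx(labeled * dx * dy * dz)

    def test_sphere_rasterization_oracle(self):
        """A planted ball's voxel count matches direct rasterization."""
        ball = syndata.rasterize_ball((3, 20, 20), (1.0, 10.0, 10.0), 4.0, 6.0)
        zz, yy, xx = np.mgrid[0:3, 0:20, 0:20]
        expected = (((zz - 1) * 6.0) ** 2 + (yy - 10) ** 2 + (xx - 10) ** 2) <= 16.0
        np.testing.assert_array_equal(ball, expected)
        assert ball[1].sum() == 49  # disc of radius 4 on the central section


class TestNuclearPhenotype:
    def test_fragmented_called_on_two_components(self):
        frame = np.zeros((40, 40))
        yy, xx = np.mgrid[0:40, 0:40]
        frame += 100 * np.exp(-((xx - 12) ** 2 + (yy - 20) ** 2) / 18)
        frame += 100 * np.exp(-((xx - 28) ** 2 + (yy - 20) ** 2) / 18)
        assert morpho.call_nuclear_phenotype(frame, [10.0]) == "fragmented"

    def test_condensed_called_below_control_quantile(self):
        imgs, _ = syndata.simulate_nuclei(
            1, sigmas=[4.0], seed=1, noise=syndata.NO_NOISE
        )
        control = [morpho.FWHM_PER_SIGMA * 10.0] * 20
        call = morpho.call_nuclear_phenotype(imgs[0].channel("rfp"), control)
        assert call == "condensed"
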