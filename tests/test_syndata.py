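"""Generator determinism, planted-parameter bookkeeping, and noise model."""

import numpy as np
import pytest

from aggrescope import syndata
from aggrescope.syndata import CellSpec, GenerationError, NoiseModel


class TestDeterminism:
    def test_coloc_cells_reproducible_from_seed(self):
        spec = CellSpec(coloc_fraction=0.5)
        a_imgs, a_rois, _ = syndata.simulate_coloc_cells(3, spec, seed=42)
        b_imgs, b_rois, _ = syndata.simulate_coloc_cells(3, spec, seed=42)
        for a, b in zip(a_imgs, b_imgs):
            np.testing.assert_array_equal(a.pixels, b.pixels)
        for a, b in zip(a_rois, b_rois):
            np.testing.assert_array_equal(a.rois[0].points, b.rois[0].points)

    def test_different_seeds_differ(self):
        spec = CellSpec()
        a, _, _ = syndata.simulate_coloc_cells(1, spec, seed=1)
        b, _, _ = syndata.simulate_coloc_cells(1, spec, seed=2)
        assert not np.array_equal(a[0].pixels, b[0].pixels)

    @pytest.mark.parametrize(
        "gen",
        [
            lambda s: syndata.simulate_bleach_pairs(2, 0.3, seed=s)[0][0][0].pixels,
            lambda s: syndata.simulate_frap_series(2, 0.5, seed=s)[0][0].bleached,
            lambda s: syndata.simulate_nuclei(2, [8.0], seed=s)[0][0].pixels,
            lambda s: syndata.simulate_damfret_events(100, seed=s)[0].to_numpy(),
            lambda s: syndata.simulate_screen_table(50, n_hits=5, seed=s)[0]
            .select_dtypes("number").to_numpy(),
            lambda s: syndata.simulate_blob_fields(2, seed=s)[0][0],
        ],
        ids=["bleach", "frap", "nuclei", "damfret", "screen", "blobs"],
    )
    def test_every_generator_is_seed_deterministic(self, gen):
        np.testing.assert_array_equal(gen(9), gen(9))


class TestNoiseModel:
    def test_no_noise_is_identity(self, rng):
        sig = rng.uniform(0, 100, (16, 16))
        np.testing.assert_array_equal(syndata.NO_NOISE.apply(sig, rng), sig)

    def test_poisson_variance_scales_with_gain(self):
        rng = np.random.default_rng(0)
        sig = np.full(200_000, 100.0)
        for gain in (1.0, 4.0):
            noisy = NoiseModel(gain=gain, read_noise_sd=0.0).apply(sig, rng)
            assert noisy.var() == pytest.approx(gain * 100.0, rel=0.05)


class TestColocCells:
    def test_perfect_colocalization_has_proportional_channels(self):
        spec = CellSpec(coloc_fraction=1.0, noise=None)
        imgs, _, _ = syndata.simulate_coloc_cells(1, spec, seed=3)
        ch1, ch2 = imgs[0].channel("ch1"), imgs[0].channel("ch2")
        inside = ch1 > 0
        np.testing.assert_allclose(ch1[inside], ch2[inside], rtol=1e-9)

    def test_zero_colocalization_puncta_disjoint(self):
        spec = CellSpec(coloc_fraction=0.0, noise=None, background=0.0)
        imgs, _, _ = syndata.simulate_coloc_cells(1, spec, seed=3)
        ch1, ch2 = imgs[0].channel("ch1"), imgs[0].channel("ch2")
        bright1 = ch1 > 0.5 * ch1.max()
        bright2 = ch2 > 0.5 * ch2.max()
        assert not (bright1 & bright2).any()

    def test_roi_is_polyline_inside_image(self):
        imgs, rois, _ = syndata.simulate_coloc_cells(4, CellSpec(), seed=5)
        for img, rs in zip(imgs, rois):
            roi = rs.rois[0]
            assert roi.kind == "polyline"
            assert roi.width_px == 2
            assert 5 <= len(roi.points) <= 11
            h, w = img.pixels.shape[-2:]
            assert roi.points[:, 0].min() >= 0 and roi.points[:, 0].max() < w
            assert roi.points[:, 1].min() >= 0 and roi.points[:, 1].max() < h

    def test_impossible_geometry_raises(self):
        spec = CellSpec(axes_px=(2.0, 2.0), n_puncta=50, coloc_fraction=0.0,
                        punctum_sigma_px=3.0)
        with pytest.raises(GenerationError):
            syndata.simulate_coloc_cells(1, spec, seed=0)


class TestBleachPairs:
    def test_closed_form_quenching_relations(self):
        pairs, _, gt = syndata.simulate_bleach_pairs(
            1, e_true=0.4, bleach_efficiency=1.0, noise=syndata.NO_NOISE, seed=0
        )
        pre, post = pairs[0]
        in_cell = pre.channel("acceptor") > pre.channel("acceptor").min()
        d_pre = pre.channel("donor")[in_cell].max() - 20.0
        d_post = post.channel("donor")[in_cell].max() - 20.0
        assert d_post / d_pre == pytest.approx(1 / 0.6, rel=1e-9)
        assert gt.records[0]["expected_apparent_e"] == pytest.approx(0.4)

    def test_zero_bleach_rejected_but_tiny_bleach_ok(self):
        with pytest.raises(ValueError):
            syndata.simulate_bleach_pairs(1, 0.4, bleach_efficiency=0.0)

    def test_parameter_bounds(self):
        with pytest.raises(ValueError):
            syndata.simulate_bleach_pairs(1, 1.0)


class TestFrapSeries:
    def test_immobile_trace_is_flat(self):
        traces, _ = syndata.simulate_frap_series(1, 0.0, seed=0, noise_sd=0.0)
        tr = traces[0]
        assert np.ptp(tr.bleached) == pytest.approx(0.0, abs=1e-12)

    def test_fully_mobile_fast_trace_returns_to_pre(self):
        traces, _ = syndata.simulate_frap_series(
            1, 1.0, k=5.0, seed=0, noise_sd=0.0
        )
        assert traces[0].bleached[-1] == pytest.approx(traces[0].pre, rel=1e-6)

    def test_half_mobile_plateau_is_midway(self):
        traces, _ = syndata.simulate_frap_series(
            1, 0.5, k=1.0, seed=0, noise_sd=0.0, bleach_floor=0.3
        )
        # plateau = 0.3 + 0.5*(1 - 0.3) = 0.65 of the pre level
        assert traces[0].bleached[-1] == pytest.approx(0.65, rel=1e-4)


class TestDamfretEvents:
    def test_control_always_generated_monomeric(self):
        sample, control, _ = syndata.simulate_damfret_events(
            500, model="always_assembled", seed=1
        )
        assert (control["fret"] / control["acceptor"]).abs().mean() < 0.05
        assert (sample["fret"] / sample["acceptor"]).mean() > 0.2

    def test_threshold_model_splits_at_cutpoint(self):
        cut = 10**3.5
        sample, _, gt = syndata.simulate_damfret_events(
            2000, model="assembly_above_threshold", seed=2, cutpoint=cut
        )
        expr = sample["donor"] + sample["acceptor"]
        amfret = sample["fret"] / sample["acceptor"]
        assert amfret[expr > cut].mean() > 0.2
        assert abs(amfret[expr <= cut].mean()) < 0.05
        planted = np.array([r["assembled"] for r in gt.records])
        np.testing.assert_array_equal(planted, (expr > cut).to_numpy())

    def test_expression_spans_the_range_log_uniformly(self):
        sample, _, _ = syndata.simulate_damfret_events(5000, seed=3)
        expr = np.log10(sample["donor"] + sample["acceptor"])
        assert expr.min() < 2.3 and expr.max() > 4.7


class TestScreenTable:
    def test_planted_roles_have_expected_growth_patterns(self):
        table, gt = syndata.simulate_screen_table(300, n_hits=30, seed=4)
        roles = {r["strain"]: r["role"] for r in gt.records}
        for _, row in table.iterrows():
            role = roles[row["strain"]]
            if role == "hit":
                assert row["growth_wtf4_inducing"] <= 1
                assert row["growth_ev_inducing"] >= 3
            elif role == "galactose_sick":
                assert row["growth_wtf4_inducing"] <= 1
                assert row["growth_ev_inducing"] <= 1
            else:
                assert row["growth_wtf4_inducing"] >= 3

    def test_phenotypes_partition_planted_hits(self):
        _, gt = syndata.simulate_screen_table(1000, n_hits=106, seed=6)
        phen = [r["phenotype"] for r in gt.records if r["role"] == "hit"]
        assert len(phen) == 106
        assert all(p is not None for p in phen)
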