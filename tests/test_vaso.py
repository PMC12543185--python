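"""BOLD correction, percent-signal-change scaling, block GLM, SNR metrics."""

import numpy as np
import pytest

from lamsal import synthetic as syn
from lamsal import vaso
from lamsal.exceptions import (InvalidArgumentError, InvalidDesignError,
                               NumericDomainError)
from lamsal.hrf import block_regressors


class TestBocoCorrect:
    def test_identical_constants_give_zero(self):
        run = syn.PairedVasoRun(np.full((3, 10), 500.0), np.full((3, 10), 500.0))
        out = vaso.boco_correct(run)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)
        assert out.tr == pytest.approx(run.paired_tr / 2)

    def test_single_pair_rejected(self):
        run = syn.PairedVasoRun(np.ones((2, 1)), np.ones((2, 1)))
        with pytest.raises(InvalidArgumentError):
            vaso.boco_correct(run)

    def test_nonpositive_not_nulled_rejected(self):
        run = syn.PairedVasoRun(np.ones((1, 5)),
                                np.array([[1.0, 1.0, 0.0, 1.0, 1.0]]))
        with pytest.raises(NumericDomainError):
            vaso.boco_correct(run)

    def test_common_rescaling_invariance(self, default_timeline, quiet_phantom):
        run = syn.simulate_paired_vaso_run(quiet_phantom, default_timeline,
                                           seed=5)
        scaled = syn.PairedVasoRun(run.nulled * 7.3, run.not_nulled * 7.3,
                                   run.paired_tr, run.baseline)
        np.testing.assert_allclose(vaso.boco_correct(run).data,
                                   vaso.boco_correct(scaled).data, atol=1e-9)

    def test_bold_component_removed(self, default_timeline, quiet_phantom):
        # BOLD leakage = difference between BOCO outputs with and without the
        # BOLD component; its fitted response must stay below 5% of the BOLD
        # amplitude.
        tl = default_timeline
        with_bold = syn.simulate_paired_vaso_run(quiet_phantom, tl,
                                                 cbv_gain=1.0, bold_gain=2.0,
                                                 seed=5)
        without = syn.simulate_paired_vaso_run(quiet_phantom, tl,
                                               cbv_gain=1.0, bold_gain=0.0,
                                               seed=5)
        leak = vaso.boco_correct(with_bold).data - vaso.boco_correct(without).data
        res = vaso.fit_block_glm(vaso.CbvTimeseries(leak, tl.paired_tr / 2),
                                 tl, resample_tr=tl.paired_tr)
        bold_amp = 2.0 * (quiet_phantom.weights @ quiet_phantom.b_true).max()
        assert np.abs(res.condition_betas(quiet_phantom.conditions)).max() \
            < 0.05 * bold_amp

    def test_matches_inverted_nulled_psc_without_bold(self, default_timeline,
                                                      quiet_phantom):
        run = syn.simulate_paired_vaso_run(quiet_phantom, default_timeline,
                                           cbv_gain=1.0, bold_gain=0.0, seed=5)
        out = vaso.boco_correct(run)
        # nulled-only percent signal change, upsampled onto the same grid
        n = run.nulled.shape[1]
        t_up = np.arange(2 * n) * run.paired_tr / 2
        t_null = np.arange(n) * run.paired_tr
        psc = vaso.percent_signal_change(run.nulled)
        up = np.vstack([np.interp(t_up, t_null, psc[v]) for v in range(psc.shape[0])])
        amp = (quiet_phantom.weights @ quiet_phantom.b_true).max()  # psc units
        diff = out.data - (-up)
        diff -= diff.mean(axis=1, keepdims=True)   # centring conventions differ
        assert np.abs(diff).max() < 0.02 * amp


class TestPercentSignalChange:
    def test_constant_series(self):
        np.testing.assert_array_equal(
            vaso.percent_signal_change(np.full((2, 5), 7.0)), 0.0)

    def test_simple_arithmetic(self):
        out = vaso.percent_signal_change(np.array([[99.0, 101.0]]))
        np.testing.assert_allclose(out, [[-1.0, 1.0]])

    def test_per_run_scaling(self):
        ts = np.array([[1.0, 3.0, 10.0, 30.0]])
        out = vaso.percent_signal_change(ts, run_lengths=[2, 2])
        np.testing.assert_allclose(out.reshape(2, 2).mean(axis=1), 0.0,
                                   atol=1e-12)

    def test_zero_mean_voxel_flagged(self, caplog):
        out = vaso.percent_signal_change(np.array([[1.0, -1.0], [1.0, 3.0]]))
        assert np.isnan(out[0]).all()
        assert np.isfinite(out[1]).all()


class TestBlockGlm:
    def test_noiseless_identity(self, default_timeline):
        tr = default_timeline.paired_tr / 2
        n_t = int(default_timeline.run_duration // tr)
        reg = block_regressors(default_timeline, np.arange(n_t) * tr)
        ts = vaso.CbvTimeseries(1.5 * reg[:, 0][None, :], tr)
        res = vaso.fit_block_glm(ts, default_timeline)
        assert res.betas[0, 0] == pytest.approx(1.5, abs=1e-9)
        assert abs(res.betas[0, 1]) < 1e-9

    def test_betas_linear_in_data(self, default_timeline, v1_phantom):
        run = syn.simulate_paired_vaso_run(v1_phantom, default_timeline, seed=8)
        ts = vaso.boco_correct(run)
        res1 = vaso.fit_block_glm(ts, default_timeline)
        res3 = vaso.fit_block_glm(vaso.CbvTimeseries(3.0 * ts.data, ts.tr),
                                  default_timeline)
        np.testing.assert_allclose(res3.betas, 3.0 * res1.betas, atol=1e-9)

    def test_duplicated_condition_column_rejected(self, default_timeline):
        tr = default_timeline.paired_tr / 2
        n_t = int(default_timeline.run_duration // tr)
        reg = block_regressors(default_timeline, np.arange(n_t) * tr)
        ts = vaso.CbvTimeseries(np.random.default_rng(0).normal(size=(2, n_t)),
                                tr)
        with pytest.raises(InvalidDesignError, match="collinear"):
            vaso.fit_block_glm(ts, default_timeline, nuisance=reg[:, [0]])

    def test_end_to_end_recovery_within_2se(self, default_timeline):
        phantom = syn.generate_laminar_phantom(200, "v1_like", 1.0, 50.0,
                                               seed=5, noise_sd=0.5)
        from lamsal import laminar
        run = syn.simulate_paired_vaso_run(phantom, default_timeline, seed=5)
        ts = vaso.boco_correct(run)
        res = vaso.fit_block_glm(ts, default_timeline,
                                 resample_tr=default_timeline.paired_tr)
        B, se = laminar.unmix_layers(
            res.condition_betas(phantom.conditions), phantom.weights)
        z = np.abs(B - phantom.b_true) / se
        assert z.max() <= 3.0
        assert (z <= 2.0).mean() >= 0.8


class TestSnrMetrics:
    def test_constant_series_flagged(self, default_timeline):
        tsnr, cnr, valid = vaso.snr_metrics(np.full((1, 54), 5.0),
                                            default_timeline, 5.02)
        assert np.isinf(tsnr[0]) and not valid[0]

    def test_cnr_arithmetic(self, default_timeline):
        tr = 5.02
        n_t = 54
        times = np.arange(n_t) * tr
        stim = ~np.isnan(default_timeline.block_labels(times))
        rng = np.random.default_rng(0)
        x = np.where(stim, 102.0, 100.0) + rng.normal(0, 1e-9, n_t)
        base = x + np.tile([0.5, -0.5], n_t // 2 + 1)[:n_t]  # residual sd known
        tsnr, cnr, valid = vaso.snr_metrics(base[None, :], default_timeline, tr)
        resid_sd = np.tile([0.5, -0.5], n_t // 2 + 1)[:n_t].std(ddof=1)
        assert cnr[0] == pytest.approx(2.0 / resid_sd, rel=0.05)

    def test_pure_noise_cnr_near_zero(self, default_timeline):
        rng = np.random.default_rng(1)
        data = 100.0 + rng.normal(0, 1.0, size=(1000, 54))
        tsnr, cnr, valid = vaso.snr_metrics(data, default_timeline, 5.02)
        assert abs(cnr[valid].mean()) < 3.0 / np.sqrt(1000) * cnr[valid].std()

    def test_needs_both_states(self):
        tl = syn.StimulusTimeline((), (syn.Block(0.0, 270.0, 90.0),), 270.0)
        with pytest.raises(InvalidArgumentError):
            vaso.snr_metrics(np.ones((1, 54)), tl, 5.02)
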