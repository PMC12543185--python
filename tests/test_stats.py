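"""Group statistics: rm-ANOVA, t tests, permutation FWE, Holm, BCEA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as scst

from lamsal import stats as st
from lamsal import synthetic as syn
from lamsal.exceptions import InvalidArgumentError


def _long_table(values):
    """subjects x levels array -> tidy frame."""
    n_s, n_l = values.shape
    return pd.DataFrame({
        "subject": np.repeat(np.arange(n_s), n_l),
        "level": np.tile(np.arange(n_l), n_s),
        "y": values.ravel(),
    })


class TestRmAnova:
    def test_no_effect_gives_zero_f(self):
        vals = np.tile(np.array([1.0, 2.0, 3.0, 4.0])[:, None], (1, 3))
        out = st.rm_anova(_long_table(vals), "y", "level", "subject")
        assert out.loc[0, "F"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_sums_of_squares(self):
        vals = np.array([[1.0, 2.0, 4.0],
                         [2.0, 4.0, 5.0],
                         [3.0, 3.0, 6.0],
                         [4.0, 5.0, 9.0]])
        n_s, n_l = vals.shape
        grand = vals.mean()
        ss_level = n_s * ((vals.mean(axis=0) - grand) ** 2).sum()
        ss_subj = n_l * ((vals.mean(axis=1) - grand) ** 2).sum()
        ss_tot = ((vals - grand) ** 2).sum()
        ss_err = ss_tot - ss_level - ss_subj
        f_oracle = (ss_level / (n_l - 1)) / (ss_err / ((n_s - 1) * (n_l - 1)))
        out = st.rm_anova(_long_table(vals), "y", "level", "subject")
        assert out.loc[0, "F"] == pytest.approx(f_oracle, rel=1e-9)
        assert (out.loc[0, "df1"], out.loc[0, "df2"]) == (2, 6)

    def test_two_level_f_equals_squared_paired_t(self, rng):
        vals = rng.normal(size=(8, 2))
        out = st.rm_anova(_long_table(vals), "y", "level", "subject")
        t = st.paired_t(vals[:, 0], vals[:, 1])
        assert out.loc[0, "F"] == pytest.approx(t.t**2, abs=1e-9)

    def test_two_way_design(self, rng):
        rows = []
        for s in range(6):
            for depth in ("deep", "middle", "superficial"):
                for theta in (90, 15, 0):
                    rows.append({"subject": s, "depth": depth, "theta": theta,
                                 "y": rng.normal()})
        out = st.rm_anova(pd.DataFrame(rows), "y", ["depth", "theta"],
                          "subject")
        assert set(out["effect"]) == {"depth", "theta", "depth * theta"}
        assert out["p"].between(0, 1).all()

    def test_missing_cells_rejected(self):
        df = _long_table(np.ones((4, 3))).iloc[:-1]
        with pytest.raises(InvalidArgumentError):
            st.rm_anova(df, "y", "level", "subject")


class TestPairedT:
    def test_equal_vectors(self):
        res = st.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.degenerate

    def test_hand_arithmetic(self):
        res = st.paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2.0 * math.sqrt(3.0), rel=1e-12)
        assert res.df == 2

    def test_matches_scipy(self, rng):
        a, b = rng.normal(size=(2, 15))
        res = st.paired_t(a, b)
        t, p = scst.ttest_rel(a, b)
        assert res.t == pytest.approx(t) and res.p == pytest.approx(p)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(5.0)
        assert st.pearson_r(x, 2 * x + 1).r == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        assert st.pearson_r([1.0, 2.0, 3.0], [1.0, 3.0, 2.0]).r == \
            pytest.approx(0.5)

    def test_degenerate(self):
        assert st.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]).degenerate


class TestPermutationFwe:
    def test_exhaustive_matches_enumeration_oracle(self, rng):
        n = 5
        behav = rng.normal(size=n)
        fmri = rng.normal(size=(n, 1))
        res = st.permutation_fwe(behav, fmri, exhaustive=True)
        # independent oracle: enumerate all 120 permutations with corrcoef
        obs = np.corrcoef(behav, fmri[:, 0])[0, 1]
        null = [np.corrcoef(behav[list(p)], fmri[:, 0])[0, 1]
                for p in itertools.permutations(range(n))]
        p_oracle = np.mean(np.asarray(null) >= obs)
        assert res.p_fwe[0] == pytest.approx(p_oracle, abs=1e-12)
        assert res.n_perm == 120

    def test_sampled_p_in_valid_range(self, rng):
        behav = rng.normal(size=10)
        fmri = rng.normal(size=(10, 3))
        res = st.permutation_fwe(behav, fmri, n_perm=500, seed=1)
        assert res.p_fwe.min() >= 1.0 / 501.0
        assert res.p_fwe.max() <= 1.0
        assert res.null_max_r.shape == (500,)

    def test_strong_signal_detected(self, rng):
        behav = np.linspace(0, 1, 20) + rng.normal(0, 0.05, 20)
        fmri = np.column_stack([behav + rng.normal(0, 0.05, 20),
                                rng.normal(size=20)])
        res = st.permutation_fwe(behav, fmri, n_perm=1000, seed=2)
        assert res.p_fwe[0] < 0.01
        assert res.observed_r[0] > res.fwe_threshold

    def test_constant_behavior_rejected(self):
        with pytest.raises(InvalidArgumentError):
            st.permutation_fwe(np.ones(6), np.random.default_rng(0)
                               .normal(size=(6, 2)), n_perm=100)


class TestHolm:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(st.holm_correct([0.03]), [0.03])

    def test_step_down_arithmetic(self):
        np.testing.assert_allclose(st.holm_correct([0.01, 0.04]), [0.02, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(st.holm_correct([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            st.holm_correct([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hst.lists(hst.floats(0.0, 1.0), min_size=1, max_size=8))
    def test_between_unadjusted_and_bonferroni(self, pvals):
        p = np.asarray(pvals)
        adj = st.holm_correct(p)
        bonf = np.minimum(p * p.size, 1.0)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= bonf + 1e-12)


class TestGazePreprocessing:
    def test_blink_padding_and_interpolation(self):
        tr = syn.simulate_gaze(5, 0.2, 0.2, 0.0, 0.0, seed=1)
        tr.valid[2000:2100] = False
        tr = syn.GazeTrace(tr.t, tr.x, tr.y, tr.valid, ((2000, 2100),), None)
        out = st.preprocess_gaze(tr, blink_pad_ms=200)
        assert not out.valid[1800:2300].any()
        assert np.isfinite(out.x).all()

    def test_detrend_removes_linear_drift(self):
        tr = syn.simulate_gaze(10, 0.2, 0.2, 0.0, 0.0, seed=1)
        drifted = syn.GazeTrace(tr.t, tr.x + np.linspace(0, 5, tr.t.size),
                                tr.y, tr.valid, (), None)
        out = st.preprocess_gaze(drifted)
        slope = np.polyfit(out.t, out.x, 1)[0]
        assert abs(slope) < 1e-6


class TestBcea:
    def test_closed_form_isotropic(self):
        n = 1000
        rng = np.random.default_rng(0)
        # exact unit-variance, uncorrelated samples by construction
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        y -= np.polyfit(x, y, 1)[0] * x
        x = (x - x.mean()) / x.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)
        tr = syn.GazeTrace(np.arange(n), x, y, np.ones(n, bool), (), None)
        res = st.bcea(tr, preprocess=False)
        assert res.area == pytest.approx(math.pi * scst.chi2.ppf(0.95, 2),
                                         rel=1e-6)
        assert res.area == pytest.approx(18.82, abs=0.01)

    def test_identical_samples_degenerate(self):
        n = 200
        tr = syn.GazeTrace(np.arange(n), np.zeros(n), np.zeros(n),
                           np.ones(n, bool), (), None)
        res = st.bcea(tr, preprocess=False)
        assert res.area == 0.0 and res.degenerate

    def test_simulated_trace_matches_generating_parameters(self):
        tr = syn.simulate_gaze(60, 0.3, 0.2, 0.1, 0.2, seed=2)
        res = st.bcea(tr)
        truth = math.pi * scst.chi2.ppf(0.95, 2) * 0.3 * 0.2 \
            * math.sqrt(1 - 0.1**2)
        assert res.area == pytest.approx(truth, rel=0.10)

    def test_rotation_invariance(self, rng):
        n = 2000
        x = rng.normal(0, 0.3, n)
        y = rng.normal(0, 0.2, n)
        theta = 0.7
        xr = math.cos(theta) * x - math.sin(theta) * y
        yr = math.sin(theta) * x + math.cos(theta) * y
        a = st.bcea(syn.GazeTrace(np.arange(n), x, y, np.ones(n, bool), (),
                                  None), preprocess=False)
        b = st.bcea(syn.GazeTrace(np.arange(n), xr, yr, np.ones(n, bool), (),
                                  None), preprocess=False)
        assert b.area == pytest.approx(a.area, rel=1e-9)

    def test_too_few_valid_samples_rejected(self):
        tr = syn.GazeTrace(np.arange(50), np.zeros(50), np.zeros(50),
                           np.ones(50, bool), (), None)
        with pytest.raises(InvalidArgumentError):
            st.bcea(tr, preprocess=False)


class TestGazeBelowFixation:
    def _trace(self, y, labels):
        n = y.size
        return syn.GazeTrace(np.arange(n), np.zeros(n), y, np.ones(n, bool),
                             (), labels)

    def test_symmetric_trace_near_half(self, rng):
        y = rng.normal(0, 1.0, 20_000)
        frac = st.gaze_below_fixation_fraction(
            self._trace(y, np.full(20_000, 90.0)))
        assert frac[90.0] == pytest.approx(0.5, abs=0.02)

    def test_all_below(self):
        frac = st.gaze_below_fixation_fraction(
            self._trace(np.full(500, -1.0), np.full(500, 15.0)))
        assert frac[15.0] == 1.0

    def test_upward_shift_reduces_fraction(self, rng):
        y = rng.normal(1.0, 1.0, 20_000)
        frac = st.gaze_below_fixation_fraction(
            self._trace(y, np.full(20_000, 0.0)))
        assert frac[0.0] < 0.5
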