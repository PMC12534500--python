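"""Paired contrasts with FDR, rm-ANOVA, correlation, sample size."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import ctbseeg as c
from ctbseeg.errors import DegenerateDataError, ValidationError


# ---------------------------------------------------------------------------
# BH-FDR
# ---------------------------------------------------------------------------

def bh_stepup_oracle(pvals):
    """Hand step-up definition: q_i = min_{k: p_k >= p_i} (p_k * m / rank_k),
    with monotonicity enforced from the largest p downwards."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


def test_bh_worked_example():
    """p = {0.01, 0.02, 0.03, 0.04}: every q = 0.04, all pass at 0.05."""
    q = c.bh_fdr([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(q, 0.04)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=50))
def test_bh_matches_stepup_oracle(pvals):
    q = c.bh_fdr(pvals)
    np.testing.assert_allclose(q, bh_stepup_oracle(pvals), atol=1e-12)
    p = np.asarray(pvals)
    assert np.all(q >= p - 1e-15)
    # monotone: larger p never gets smaller q
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-15)


# ---------------------------------------------------------------------------
# Paired t families
# ---------------------------------------------------------------------------

def _table(values, units=("F4", "O1")):
    return pd.DataFrame(values, columns=list(units))


class TestPairedTFdr:
    def test_identical_conditions_degenerate_nothing_significant(self):
        a = _table(np.arange(10.0).reshape(5, 2))
        res = c.paired_t_fdr(a, a.copy())
        assert all(r.degenerate for r in res)
        assert not any(r.significant for r in res)

    def test_matches_one_sample_t_on_differences(self):
        rng = np.random.default_rng(21)
        a = _table(rng.normal(size=(12, 2)))
        b = _table(rng.normal(size=(12, 2)) + 0.5)
        res = c.paired_t_fdr(a, b)
        for j, r in enumerate(res):
            t1, p1 = sps.ttest_1samp(b.iloc[:, j] - a.iloc[:, j], 0.0)
            assert r.t == pytest.approx(t1, rel=1e-12)
            assert r.p == pytest.approx(p1, rel=1e-12)
            assert r.df == 11

    def test_mixed_degenerate_unit_excluded_from_family(self):
        rng = np.random.default_rng(22)
        a = _table(rng.normal(size=(8, 3)), units=("u1", "u2", "u3"))
        b = a.copy()
        b["u1"] += 1.0  # constant shift: zero within-pair variance
        b["u2"] += rng.normal(0.8, 0.3, size=8)
        b["u3"] += rng.normal(0.0, 0.3, size=8)
        res = {r.unit: r for r in c.paired_t_fdr(a, b)}
        assert res["u1"].degenerate and np.isnan(res["u1"].p)
        qs = c.bh_fdr([res["u2"].p, res["u3"].p])  # m=2 family, not 3
        assert res["u2"].q == pytest.approx(qs[0])
        assert res["u3"].q == pytest.approx(qs[1])

    def test_too_few_pairs_rejected(self):
        a = _table(np.zeros((2, 2)))
        with pytest.raises(ValidationError, match="3"):
            c.paired_t_fdr(a, a)

    def test_type_one_error_controlled_under_generator_null(self):
        """Sham-vs-sham contrasts on scaled-down synthetic studies: the
        pooled share of FDR-significant electrodes stays near or below
        the nominal 5 % level."""
        cfg_kwargs = dict(wake_duration=15.0, artifact_rate=0.0,
                          line_noise_amplitude=0.0, coupling_pairs=(),
                          channel_set=("F4", "Cz", "O1"),
                          subject_effect_sd=0.2, baseline_power_sd=0.2)
        n_subjects, n_studies = 6, 50
        hits = total = 0
        for study in range(n_studies):
            cfg = c.SimConfig(n_subjects=n_subjects, seed=1000 + study,
                              **cfg_kwargs)
            rows = {}
            for tp in ("T1", "T6"):
                vals = []
                for s in range(n_subjects):
                    rec, _ = c.simulate_wake_recording(cfg, s, "sham", tp)
                    es = c.segment_and_reject(rec, 5.0)
                    bp = c.band_power_from_epochs(es)
                    vals.append(bp.values["theta"].to_numpy())
                rows[tp] = pd.DataFrame(vals, columns=cfg.channel_set)
            res = c.paired_t_fdr(rows["T1"], rows["T6"])
            hits += sum(r.significant for r in res)
            total += len(res)
        rate = hits / total
        margin = 2 * np.sqrt(0.05 * 0.95 / total)
        assert rate <= 0.05 + margin


# ---------------------------------------------------------------------------
# rm-ANOVA
# ---------------------------------------------------------------------------

def _long(y, subjects, arms, times):
    rows = []
    for i, s in enumerate(subjects):
        for j, a in enumerate(arms):
            for k, t in enumerate(times):
                rows.append({"subject": s, "arm": a, "timepoint": t,
                             "value": float(y[i, j, k])})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_constant_cells_give_zero_f(self):
        y = np.full((4, 2, 6), 3.7)
        res = c.rm_anova_2x6(_long(y, range(4), "AB", range(6)))
        assert all(r.F == 0.0 and r.p == 1.0 for r in res)

    def test_additive_subject_offsets_absorbed(self):
        y = np.zeros((5, 2, 6)) + np.arange(5)[:, None, None]
        res = c.rm_anova_2x6(_long(y, range(5), "AB", range(6)))
        assert all(r.F == pytest.approx(0.0, abs=1e-9) for r in res)

    def test_2x2_matches_brute_force_sums_of_squares(self):
        """3-subject 2×2: F from the explicit SS decomposition."""
        y = np.array([[[1.0, 2.0], [2.0, 4.0]],
                      [[2.0, 1.0], [3.0, 5.0]],
                      [[0.5, 2.5], [1.5, 3.0]]])
        res = {r.effect: r for r in c.rm_anova_2x6(
            _long(y, range(3), "AB", range(2)))}
        n, a, b = y.shape
        m = y.mean()
        m_a = y.mean(axis=(0, 2)); m_b = y.mean(axis=(0, 1))
        m_s = y.mean(axis=(1, 2))
        ss_a = n * b * ((m_a - m) ** 2).sum()
        ss_as = b * sum((y[i].mean(axis=1)[j] - m_a[j] - m_s[i] + m) ** 2
                        for i in range(n) for j in range(a))
        F_a = (ss_a / (a - 1)) / (ss_as / ((a - 1) * (n - 1)))
        assert res["arm"].F == pytest.approx(F_a, rel=1e-12)
        ss_b = n * a * ((m_b - m) ** 2).sum()
        ss_bs = a * sum((y[i].mean(axis=0)[k] - m_b[k] - m_s[i] + m) ** 2
                        for i in range(n) for k in range(b))
        F_b = (ss_b / (b - 1)) / (ss_bs / ((b - 1) * (n - 1)))
        assert res["timepoint"].F == pytest.approx(F_b, rel=1e-12)

    def test_matches_statsmodels_on_random_data(self):
        from statsmodels.stats.anova import AnovaRM
        rng = np.random.default_rng(23)
        y = rng.normal(size=(7, 2, 6)) + 0.3 * np.arange(6)
        df = _long(y, range(7), "AB", range(6))
        mine = {r.effect: r for r in c.rm_anova_2x6(df)}
        ref = AnovaRM(df, "value", "subject",
                      within=["arm", "timepoint"]).fit().anova_table
        assert mine["arm"].F == pytest.approx(ref.loc["arm", "F Value"])
        assert mine["timepoint"].F == pytest.approx(
            ref.loc["timepoint", "F Value"])
        assert mine["arm:timepoint"].F == pytest.approx(
            ref.loc["arm:timepoint", "F Value"])
        assert mine["arm:timepoint"].p == pytest.approx(
            ref.loc["arm:timepoint", "Pr > F"])

    def test_two_level_single_factor_equals_squared_paired_t(self):
        rng = np.random.default_rng(24)
        y = rng.normal(size=(10, 2))
        df = pd.DataFrame([{"subject": s, "cond": cnd, "value": y[s, j]}
                           for s in range(10)
                           for j, cnd in enumerate("ab")])
        res = c.rm_anova(df, "value", "subject", ["cond"])[0]
        t, p = sps.ttest_rel(y[:, 1], y[:, 0])
        assert res.F == pytest.approx(t ** 2, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)

    def test_missing_cell_rejected(self):
        y = np.zeros((3, 2, 2))
        df = _long(y, range(3), "AB", range(2)).iloc[:-1]
        with pytest.raises(ValidationError, match="balanced"):
            c.rm_anova_2x6(df)


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

class TestCorrelation:
    def test_exact_line(self):
        x = np.arange(10.0)
        r, p, n = c.wake_sleep_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert n == 10

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(25)
        rejections = 0
        n_sims = 1000
        for _ in range(n_sims):
            x, y = rng.normal(size=(2, 25))
            _, p, _ = c.wake_sleep_correlation(x, y)
            rejections += p < 0.05
        rate = rejections / n_sims
        assert abs(rate - 0.05) <= 2.5 * np.sqrt(0.05 * 0.95 / n_sims)

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateDataError):
            c.wake_sleep_correlation(np.ones(5), np.arange(5.0))

    def test_spearman_flag(self):
        x = np.arange(8.0)
        r, _, _ = c.wake_sleep_correlation(x, np.exp(x), method="spearman")
        assert r == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Sample size
# ---------------------------------------------------------------------------

class TestSampleSize:
    def test_monotone_in_effect_size(self):
        ns = [c.paired_t_sample_size(d).n_required
              for d in (0.2, 0.5, 1.0, 3.0)]
        assert ns == sorted(ns, reverse=True)
        assert ns[-1] <= 4

    def test_statsmodels_cross_check(self):
        import statsmodels.stats.power as smp
        for d, power in ((0.5, 0.9), (0.8, 0.8), (0.3, 0.95)):
            mine = c.paired_t_sample_size(d, power=power).n_required
            ref = smp.TTestPower().solve_power(effect_size=d, alpha=0.05,
                                               power=power)
            assert mine == int(np.ceil(ref))

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            c.paired_t_sample_size(0.5, alpha=0.5, power=0.4)
        with pytest.raises(ValidationError):
            c.paired_t_sample_size(-1.0)
        with pytest.raises(ValidationError):
            c.paired_t_sample_size(0.5, tails=3)
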