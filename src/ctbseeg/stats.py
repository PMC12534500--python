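"""Statistical battery for the crossover study.

* per-unit paired two-tailed t-tests with Benjamini–Hochberg FDR across
  one family (one band × one comparison: 21 electrodes or 210 edges);
* two-way repeated-measures ANOVA (intervention × timepoint, both
  within-subject), each effect tested against its own subject-interaction
  error term;
* Pearson (optionally Spearman) correlation between wakefulness ΔPSD
  z-scores and first-cycle NREM band power;
* a priori paired-t sample size via noncentral-t power iteration.

Degenerate units (zero within-pair variance) are excluded from the FDR
family and reported, never assigned p = 1.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Paired t with FDR
# ---------------------------------------------------------------------------

@dataclass
class PairedTestResult:
    """One unit (electrode or edge) of a paired-contrast family."""

    unit: str
    t: float
    df: int
    p: float
    q: float
    significant: bool
    band: str | None = None
    comparison: tuple | None = None
    degenerate: bool = False


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone q ≥ p)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def paired_t_fdr(cond_a: pd.DataFrame, cond_b: pd.DataFrame,
                 alpha: float = 0.05,
                 band: str | None = None,
                 comparison: tuple | None = None) -> list[PairedTestResult]:
    """Per-unit paired two-tailed t-tests, BH-FDR across the family.

    ``cond_a`` and ``cond_b`` are subject × unit tables (same index and
    columns); one call is one FDR family (e.g. one band × one timepoint
    comparison across its 21 electrodes). Units with zero within-pair
    variance are reported as degenerate and excluded from the family.
    """
    if list(cond_a.columns) != list(cond_b.columns):
        raise ValidationError("condition tables must share unit columns")
    a, b = cond_a.align(cond_b, join="inner", axis=0)
    n = len(a)
    if n < 3:
        raise ValidationError(f"need >= 3 complete pairs, got {n}")
    diffs = b.to_numpy() - a.to_numpy()
    results: list[PairedTestResult] = []
    testable: list[int] = []
    stats_p: list[float] = []
    for j, unit in enumerate(a.columns):
        d = diffs[:, j]
        if np.allclose(d.std(ddof=1), 0.0):
            logger.info("paired_t_fdr: unit %s degenerate (zero variance)", unit)
            results.append(PairedTestResult(
                unit=str(unit), t=np.nan, df=n - 1, p=np.nan, q=np.nan,
                significant=False, band=band, comparison=comparison,
                degenerate=True))
            continue
        t, p = sps.ttest_rel(b.iloc[:, j], a.iloc[:, j])
        results.append(PairedTestResult(
            unit=str(unit), t=float(t), df=n - 1, p=float(p), q=np.nan,
            significant=False, band=band, comparison=comparison))
        testable.append(len(results) - 1)
        stats_p.append(float(p))
    q = bh_fdr(stats_p)
    for idx, qv in zip(testable, q):
        results[idx].q = float(qv)
        results[idx].significant = bool(qv < alpha)
    return results


def results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float


def _f_ratio(ss_eff: float, df_eff: int, ss_err: float, df_err: int,
             tol: float) -> tuple[float, float]:
    """F and p with a degeneracy guard: when both the effect and its
    error sum of squares vanish to numerical noise (constant or
    perfectly additive data), the ratio is 0/0 and reported as F=0, p=1;
    a nonzero effect over a vanishing error term is F=inf, p=0."""
    if ss_err <= tol:
        if ss_eff <= tol:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ss_eff / df_eff) / (ss_err / df_err)
    return float(F), float(sps.f.sf(F, df_eff, df_err))


def rm_anova(df: pd.DataFrame, dv: str, subject: str,
             within: list[str]) -> list[AnovaResult]:
    """Within-subject ANOVA (one or two factors) on a complete balanced
    long-form table, via the classical sums-of-squares decomposition;
    each effect is tested against its own subject-interaction error term
    (MS_effect / MS_effect×subject). No sphericity correction is applied.
    """
    if len(within) not in (1, 2):
        raise ValidationError("rm_anova supports 1 or 2 within factors")
    cells = df.groupby([subject] + within, observed=True).size()
    n_expected = df[subject].nunique() * int(
        np.prod([df[w].nunique() for w in within]))
    if (cells != 1).any() or len(cells) != n_expected:
        raise ValidationError(
            "design must be complete and balanced with one observation per "
            f"subject × {' × '.join(within)} cell "
            f"(found {len(cells)} of {n_expected} cells; "
            f"duplicated: {cells[cells != 1].index.tolist()})"
        )
    wide = df.pivot_table(index=subject, columns=within, values=dv)
    y = wide.to_numpy()
    n = y.shape[0]
    if len(within) == 1:
        y = y[:, :, None]           # subjects × A × 1
        a_levels, b_levels = y.shape[1], 1
    else:
        a_levels = df[within[0]].nunique()
        b_levels = df[within[1]].nunique()
        y = y.reshape(n, a_levels, b_levels)
    m = y.mean()
    # numerical-noise floor for sums of squared deviations of cell means
    tol = y.size * (1e-10 * max(1.0, float(np.abs(y).max()))) ** 2
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_as = y.mean(axis=2)
    m_bs = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    out: list[AnovaResult] = []
    ss_a = float(b_levels * n * ((m_a - m) ** 2).sum())
    ss_as = float(b_levels * ((m_as - m_a[None, :] - m_s[:, None] + m) ** 2).sum())
    F, p = _f_ratio(ss_a, a_levels - 1, ss_as, (a_levels - 1) * (n - 1), tol)
    out.append(AnovaResult(effect=within[0], F=F, df_num=a_levels - 1,
                           df_den=(a_levels - 1) * (n - 1), p=p))
    if len(within) == 2:
        ss_b = float(a_levels * n * ((m_b - m) ** 2).sum())
        ss_bs = float(a_levels * ((m_bs - m_b[None, :] - m_s[:, None] + m) ** 2).sum())
        F, p = _f_ratio(ss_b, b_levels - 1, ss_bs, (b_levels - 1) * (n - 1), tol)
        out.append(AnovaResult(effect=within[1], F=F, df_num=b_levels - 1,
                               df_den=(b_levels - 1) * (n - 1), p=p))
        resid_ab = (m_ab[None] - m_a[None, :, None] - m_b[None, None, :] + m)
        ss_ab = float(n * (resid_ab ** 2).sum())
        full_resid = (y - m_ab[None] - m_as[:, :, None] - m_bs[:, None, :]
                      + m_a[None, :, None] + m_b[None, None, :]
                      + m_s[:, None, None] - m)
        ss_abs = float((full_resid ** 2).sum())
        F, p = _f_ratio(ss_ab, (a_levels - 1) * (b_levels - 1), ss_abs,
                        (a_levels - 1) * (b_levels - 1) * (n - 1), tol)
        out.append(AnovaResult(
            effect=f"{within[0]}:{within[1]}", F=F,
            df_num=(a_levels - 1) * (b_levels - 1),
            df_den=(a_levels - 1) * (b_levels - 1) * (n - 1), p=p))
    return out


def rm_anova_2x6(df: pd.DataFrame, dv: str = "value",
                 subject: str = "subject", arm: str = "arm",
                 time: str = "timepoint") -> list[AnovaResult]:
    """Two-way repeated-measures ANOVA: intervention × timepoint."""
    return rm_anova(df, dv=dv, subject=subject, within=[arm, time])


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def wake_sleep_correlation(wake_scores, sleep_power,
                           method: str = "pearson"):
    """Correlate wakefulness ΔPSD z-scores with first-cycle NREM power.

    Returns ``(r, p, n)`` with a two-tailed p from the t transform of r.
    """
    x = np.asarray(wake_scores, dtype=float)
    y = np.asarray(sleep_power, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be 1-D arrays of equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValidationError(f"need >= 3 paired observations, got {n}")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateDataError("zero variance in one of the inputs")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return float(r), float(p), int(n)


# ---------------------------------------------------------------------------
# Sample size
# ---------------------------------------------------------------------------

@dataclass
class PowerSpec:
    d: float
    alpha: float
    power: float
    tails: int
    n_required: int


def paired_t_power(n: int, d: float, alpha: float = 0.05,
                   tails: int = 2) -> float:
    """Power of the paired t-test at n pairs, effect size dz, via the
    noncentral t distribution with noncentrality d·√n and df n−1."""
    df = n - 1
    nc = d * np.sqrt(n)
    if tails == 2:
        tc = sps.t.ppf(1 - alpha / 2, df)
        return float(1 - sps.nct.cdf(tc, df, nc) + sps.nct.cdf(-tc, df, nc))
    tc = sps.t.ppf(1 - alpha, df)
    return float(1 - sps.nct.cdf(tc, df, nc))


def paired_t_sample_size(d: float, alpha: float = 0.05,
                         power: float = 0.9, tails: int = 2,
                         n_max: int = 100000) -> PowerSpec:
    """Smallest n pairs giving the paired t-test the target power.

    Iterates n upward from 2 evaluating the noncentral-t power; raises if
    the target is unattainable (power ≤ alpha or d ≤ 0).
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValidationError("alpha and power must lie in (0, 1)")
    if power <= alpha:
        raise ValidationError(f"target power {power} not above alpha {alpha}")
    if d <= 0:
        raise ValidationError("effect size d must be positive")
    if tails not in (1, 2):
        raise ValidationError("tails must be 1 or 2")
    for n in range(2, n_max + 1):
        if paired_t_power(n, d, alpha, tails) >= power:
            return PowerSpec(d=d, alpha=alpha, power=power, tails=tails,
                             n_required=n)
    raise ValidationError(f"no n <= {n_max} attains power {power} at d={d}")
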