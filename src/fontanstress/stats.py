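"""Cohort statistics: nonparametric tests, FDR adjustment, survival models.

Small samples get exact conditional null distributions — signed-rank and
rank-sum via tie-aware dynamic programming over midrank sums, Spearman via
full permutation enumeration, and a Freeman-Halton exact test for 2xk
contingency tables containing zeros (scipy's exact paths either refuse ties
or only cover 2x2).  Larger samples use the standard normal/t
approximations with continuity and tie corrections.  Survival analysis
wraps lifelines (Cox partial likelihood with Efron tie handling;
Kaplan-Meier with Greenwood variance and log-log confidence intervals).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "paired_wilcoxon",
    "ranksum_test",
    "chi2_or_fisher",
    "spearman",
    "bh_adjust",
    "cox_ph",
    "km_event_free",
]


@dataclass(frozen=True)
class StatResult:
    """One test: estimate, 95% CI, raw and (optionally) BH-adjusted p."""

    name: str
    estimate: float
    ci_low: float
    ci_high: float
    p_raw: float
    n: int
    p_adjusted: float = float("nan")
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "n": self.n,
            "flags": ";".join(self.flags),
        }


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def _median_ci(d: np.ndarray) -> tuple[float, float]:
    """Distribution-free (binomial order-statistic) ~95% CI for the median."""
    n = d.size
    if n < 6:
        return float("nan"), float("nan")
    ds = np.sort(d)
    k = int(sps.binom.ppf(0.025, n, 0.5))
    k = max(k, 0)
    return float(ds[k]), float(ds[n - 1 - k])


# ---------------------------------------------------------------------------
# Exact null distributions (tie-aware, over midrank sums doubled to integers)
# ---------------------------------------------------------------------------

def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p of the signed-rank statistic by DP over sign flips."""
    w = np.rint(2.0 * ranks).astype(np.int64)
    total = int(w.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for wi in w:
        if wi > 0:
            counts[wi:] += counts[: total + 1 - wi]
        else:
            counts *= 2.0
    denom = counts.sum()
    obs = int(np.rint(2.0 * w_plus))
    p_le = counts[: obs + 1].sum() / denom
    p_ge = counts[obs:].sum() / denom
    return min(1.0, 2.0 * min(p_le, p_ge))


def _ranksum_exact_p(all_ranks: np.ndarray, n_a: int, w_a: float) -> float:
    """Two-sided exact p of the rank-sum statistic by subset-sum DP."""
    w = np.rint(2.0 * all_ranks).astype(np.int64)
    total = int(w.sum())
    dp = np.zeros((n_a + 1, total + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for wi in w:
        for k in range(min(n_a, 1_000_000), 0, -1):
            dp[k, wi:] += dp[k - 1, : total + 1 - wi]
    counts = dp[n_a]
    denom = counts.sum()
    obs = int(np.rint(2.0 * w_a))
    p_le = counts[: obs + 1].sum() / denom
    p_ge = counts[obs:].sum() / denom
    return min(1.0, 2.0 * min(p_le, p_ge))


def paired_wilcoxon(
    x,
    y,
    zero_method: str = "wilcox",
    exact_max_n: int = 25,
    name: str = "paired_wilcoxon",
) -> StatResult:
    """Paired Wilcoxon signed-rank test on differences ``x - y``.

    Zero differences are dropped by default (Wilcoxon's convention; ``pratt``
    keeps them in the ranking).  Exact tie-aware null distribution for
    n <= ``exact_max_n`` effective pairs, normal approximation with
    continuity and tie correction otherwise.  The estimate is the median
    difference with a distribution-free CI.
    """
    x, y = _pairwise_complete(x, y)
    d = x - y
    flags: list[str] = []
    if d.size == 0:
        return StatResult(name, float("nan"), float("nan"), float("nan"), 1.0, 0,
                          flags=("no_complete_pairs",))
    estimate = float(np.median(d))
    ci_low, ci_high = _median_ci(d)
    nonzero = d != 0.0
    if not nonzero.any():
        return StatResult(name, estimate, ci_low, ci_high, 1.0, int(d.size),
                          flags=("degenerate_all_zero_differences",))
    if zero_method == "wilcox":
        dd = d[nonzero]
        ranks = sps.rankdata(np.abs(dd))
    elif zero_method == "pratt":
        ranks_all = sps.rankdata(np.abs(d))
        dd = d[nonzero]
        ranks = ranks_all[nonzero]
    else:
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")
    n_eff = int(dd.size)
    if n_eff < 5:
        flags.append("fewer_than_5_nonzero_pairs")
    w_plus = float(ranks[dd > 0].sum())
    if n_eff <= exact_max_n:
        p = _signed_rank_exact_p(ranks, w_plus)
    else:
        p = float(
            sps.wilcoxon(
                dd, zero_method="wilcox", correction=True, method="approx"
            ).pvalue
        )
    return StatResult(name, estimate, ci_low, ci_high, p, int(d.size), flags=tuple(flags))


def ranksum_test(
    group_a,
    group_b,
    exact_max_n: int = 10,
    name: str = "ranksum",
) -> StatResult:
    """Two-sample Wilcoxon rank-sum test.

    Exact (tie-aware) when both groups have <= ``exact_max_n`` observations,
    normal approximation with continuity and tie correction otherwise.  The
    estimate is the Hodges-Lehmann shift (median of pairwise differences).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    flags: list[str] = []
    if min(a.size, b.size) < 3:
        flags.append("group_smaller_than_3")
    estimate = float(np.median(np.subtract.outer(a, b)))
    ranks = sps.rankdata(np.concatenate([a, b]))
    w_a = float(ranks[: a.size].sum())
    if max(a.size, b.size) <= exact_max_n:
        p = _ranksum_exact_p(ranks, int(a.size), w_a)
    else:
        p = float(
            sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
    return StatResult(
        name, estimate, float("nan"), float("nan"), p, int(a.size + b.size),
        flags=tuple(flags),
    )


def _freeman_halton_p(table: np.ndarray) -> float:
    """Exact conditional p for a 2 x k count table (Freeman-Halton).

    Enumerates all first-row fillings compatible with the fixed margins; the
    p-value sums the conditional probabilities ``prod_j C(col_j, x_j) /
    C(n, row_1)`` of every table no more probable than the observed one.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.shape[0] != 2:
        raise NotImplementedError("exact test implemented for 2 x k tables")
    col = table.sum(axis=0)
    n = int(table.sum())
    r1 = int(table[0].sum())
    log_denom = _log_choose(n, r1)
    logp_obs = sum(
        _log_choose(int(col[j]), int(table[0, j])) for j in range(len(col))
    ) - log_denom

    total = 0.0

    def recurse(j: int, remaining: int, logc: float) -> None:
        nonlocal total
        if j == len(col) - 1:
            if 0 <= remaining <= col[j]:
                logp = logc + _log_choose(int(col[j]), remaining) - log_denom
                if logp <= logp_obs + 1e-9:
                    total += math.exp(logp)
            return
        lo = max(0, remaining - int(col[j + 1 :].sum()))
        hi = min(int(col[j]), remaining)
        for x in range(lo, hi + 1):
            recurse(j + 1, remaining - x, logc + _log_choose(int(col[j]), x))

    recurse(0, r1, 0.0)
    return min(1.0, total)


def _log_choose(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def chi2_or_fisher(table, name: str = "contingency") -> StatResult:
    """Pearson chi-square, or Fisher's exact test when any cell is zero.

    Continuity correction is not applied to the chi-square.  The estimate is
    the sample odds ratio for 2x2 tables (NaN for wider tables).
    """
    t = np.asarray(table)
    if t.ndim != 2 or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = np.asarray(table, dtype=float)
        if np.any(t < 0) or np.any(t != np.rint(t)):
            raise ValueError("table must contain nonnegative integer counts")
        t = t.astype(np.int64)
    if t.sum() == 0:
        raise ValueError("table must contain at least one nonzero count")
    flags: list[str] = []
    est = float("nan")
    if t.shape == (2, 2) and t[0, 1] * t[1, 0] > 0:
        est = float(t[0, 0] * t[1, 1]) / float(t[0, 1] * t[1, 0])
    if (t == 0).any():
        flags.append("fisher_exact")
        if t.shape == (2, 2):
            p = float(sps.fisher_exact(t, alternative="two-sided")[1])
        else:
            p = _freeman_halton_p(t)
    else:
        p = float(sps.chi2_contingency(t, correction=False)[1])
    return StatResult(name, est, float("nan"), float("nan"), p, int(t.sum()),
                      flags=tuple(flags))


def spearman(x, y, exact_max_n: int = 9, name: str = "spearman") -> StatResult:
    """Spearman rank correlation with exact permutation p for small n.

    rho is the Pearson correlation of midranks; the p-value enumerates all
    n! permutations for n <= ``exact_max_n`` and uses the t approximation
    otherwise.  The CI is a Fisher-z interval with the Bonett-Wright
    standard error.
    """
    x, y = _pairwise_complete(x, y)
    n = int(x.size)
    flags: list[str] = []
    if n < 5:
        flags.append("fewer_than_5_pairs")
    if n < 2:
        return StatResult(name, float("nan"), float("nan"), float("nan"),
                          float("nan"), n, flags=tuple(flags) + ("undefined",))
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return StatResult(name, float("nan"), float("nan"), float("nan"),
                          float("nan"), n, flags=tuple(flags) + ("zero_rank_variance",))
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        norm_prod = math.sqrt(float((rxc**2).sum() * (ryc**2).sum()))
        perms = np.array(list(itertools.permutations(ryc)))
        rho_perm = perms @ rxc / norm_prod
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    if n > 3 and abs(rho) < 1.0:
        se = math.sqrt((1.0 + rho**2 / 2.0) / (n - 3))
        z = math.atanh(rho)
        ci_low, ci_high = math.tanh(z - 1.96 * se), math.tanh(z + 1.96 * se)
    else:
        ci_low = ci_high = float("nan")
    return StatResult(name, rho, ci_low, ci_high, p, n, flags=tuple(flags))


def bh_adjust(p_values, family_labels=None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, separately within families.

    NaN entries are passed through and do not count toward the family size.
    The returned array is aligned with the input order.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if family_labels is None:
        labels = np.zeros(p.size, dtype=int)
    else:
        labels = np.asarray(family_labels)
        if labels.shape != p.shape:
            raise ValueError("family_labels must match p_values in length")
    adjusted = np.full_like(p, np.nan)
    for fam in pd.unique(labels):
        mask = (labels == fam) & finite
        if mask.sum():
            adjusted[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return adjusted


def cox_ph(covariate, time, event, name: str = "cox") -> StatResult:
    """Univariable Cox proportional-hazards model (Efron tie handling).

    Returns the hazard ratio per unit of the covariate with Wald CI and p.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    x = np.asarray(covariate, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    keep = np.isfinite(x) & np.isfinite(t)
    x, t, e = x[keep], t[keep], e[keep]
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    n_events = int(e.sum())
    if n_events == 0:
        raise ValueError("no events: the Cox model is not identifiable")
    flags: list[str] = []
    if x.size < 20 or n_events < 5:
        flags.append("small_sample")
    df = pd.DataFrame({"time": t, "event": e.astype(int), "x": x})
    fitter = CoxPHFitter()
    try:
        import warnings

        from lifelines.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            # degenerate fits are reported through flags, not warnings
            warnings.simplefilter("ignore", ConvergenceWarning)
            fitter.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        return StatResult(name, float("nan"), float("nan"), float("nan"),
                          float("nan"), int(x.size),
                          flags=tuple(flags) + ("non_convergence",))
    coef = float(fitter.params_["x"])
    se = float(fitter.standard_errors_["x"])
    p = float(fitter.summary.loc["x", "p"])
    if abs(coef) > 50 or not np.isfinite(se):
        flags.append("unstable_fit")
    return StatResult(
        name,
        float(np.exp(coef)),
        float(np.exp(coef - 1.96 * se)),
        float(np.exp(coef + 1.96 * se)),
        p,
        int(x.size),
        flags=tuple(flags),
    )


def km_event_free(time, event, horizons) -> pd.DataFrame:
    """Kaplan-Meier event-free survival at the requested horizons.

    Product-limit estimate with Greenwood variance and log-log (exponential
    Greenwood) 95% CI.  Horizons beyond follow-up yield NaN with a flag.
    """
    from lifelines import KaplanMeierFitter

    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    kmf = KaplanMeierFitter(alpha=0.05)
    kmf.fit(t, event_observed=e)
    ci = kmf.confidence_interval_survival_function_
    rows = []
    tmax = float(t.max())
    for h in np.atleast_1d(np.asarray(horizons, dtype=float)):
        if h > tmax and float(kmf.predict(tmax)) > 0.0:
            # beyond follow-up with survivors remaining: undefined
            rows.append(
                {"horizon": h, "estimate": np.nan, "ci_low": np.nan,
                 "ci_high": np.nan, "flag": "no_subjects_at_risk"}
            )
            continue
        est = float(kmf.predict(h))
        idx = ci.index.to_numpy(dtype=float)
        pos = int(np.searchsorted(idx, h, side="right")) - 1
        pos = max(pos, 0)
        rows.append(
            {
                "horizon": float(h),
                "estimate": est,
                "ci_low": float(ci.iloc[pos, 0]),
                "ci_high": float(ci.iloc[pos, 1]),
                "flag": "",
            }
        )
    return pd.DataFrame(rows)
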