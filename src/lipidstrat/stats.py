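"""Nonparametric comparison toolkit with exact small-sample behaviour.

Conventions fixed here so every downstream number is reproducible:

* Mann-Whitney: midrank ties; exact permutation p-value when the combined
  sample size is <= ``EXACT_CUTOFF`` (full enumeration of labelings),
  tie-corrected normal approximation otherwise (no continuity correction,
  so the two-group Kruskal-Wallis identity H = z^2 holds without ties).
* Fisher exact: two-sided by the point-probability rule (sum of the
  probabilities of all tables no more likely than the observed one).
  r x c tables are fully enumerated when the table space is small enough,
  otherwise a seeded Monte-Carlo estimate with reported standard error.
* Quantiles: linear interpolation (numpy default, R type 7).
* Holm-Bonferroni step-down for all pairwise families.
* Minimal detectable difference by root-finding on the noncentral-t
  two-sample power function.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "ComparisonResult",
    "GroupSummary",
    "PowerSpec",
    "adjusted_pairwise_contrasts",
    "detectable_difference",
    "fisher_exact",
    "holm_adjust",
    "kruskal_wallis",
    "mann_whitney",
    "power_two_sample_t",
    "single_factor_comparison",
    "summarize",
    "summarize_categorical",
]

EXACT_CUTOFF = 20  # combined n at or below which Mann-Whitney enumerates
RXC_ENUM_LIMIT = 1_000_000  # max tables enumerated for r x c Fisher
MC_TABLES = 20_000  # Monte-Carlo tables beyond the enumeration limit


@dataclass
class ComparisonResult:
    contrast: tuple
    method: str
    statistic: float
    p_raw: float
    p_adjusted: Optional[float] = None
    fallback_used: bool = False
    mc_standard_error: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0):
            raise ValueError(f"p_raw {self.p_raw} outside [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p_raw - 1e-12:
            raise ValueError("adjusted p below raw p")


@dataclass
class GroupSummary:
    n: int
    median: Optional[float] = None
    q1: Optional[float] = None
    q3: Optional[float] = None
    count: Optional[int] = None
    percent: Optional[float] = None

    def __post_init__(self) -> None:
        if self.median is not None and not (self.q1 <= self.median <= self.q3):
            raise ValueError("need q1 <= median <= q3")


@dataclass(frozen=True)
class PowerSpec:
    n1: int
    n2: int
    sd: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need n1, n2 >= 2")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")


# ---------------------------------------------------------------------------
# rank tests


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    ranks = _midranks(np.concatenate([x, y]))
    n1 = len(x)
    r1 = ranks[:n1].sum()
    return r1 - n1 * (n1 + 1) / 2.0


def mann_whitney(
    x: Sequence[float], y: Sequence[float], exact_cutoff: int = EXACT_CUTOFF
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    Exact path: enumerate every C(n, n1) assignment of the pooled sample,
    p = fraction of assignments whose U deviates from its null mean at
    least as much as observed.  Approximate path: tie-corrected normal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    u = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= exact_cutoff:
        pooled = np.concatenate([x, y])
        ranks = _midranks(pooled)
        obs_dev = abs(u - mu)
        total = 0
        hits = 0
        offset = n1 * (n1 + 1) / 2.0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u_perm = ranks[list(idx)].sum() - offset
            total += 1
            if abs(u_perm - mu) >= obs_dev - 1e-9:
                hits += 1
        p = hits / total
        return ComparisonResult(("x", "y"), "MANN_WHITNEY", u, min(p, 1.0))

    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        warnings.warn("no rank variance (all values tied); reporting p = 1")
        return ComparisonResult(("x", "y"), "MANN_WHITNEY", u, 1.0)
    z = (u - mu) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return ComparisonResult(("x", "y"), "MANN_WHITNEY", u, min(p, 1.0))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> ComparisonResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p on k-1 df."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = _midranks(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start : start + a.size]
        h += r.sum() ** 2 / a.size
        start += a.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if correction <= 0:
        warnings.warn("all observations identical; reporting p = 1")
        return ComparisonResult(tuple(range(len(groups))), "KRUSKAL_WALLIS", 0.0, 1.0)
    h /= correction
    p = sps.chi2.sf(h, df=len(groups) - 1)
    return ComparisonResult(tuple(range(len(groups))), "KRUSKAL_WALLIS", h, float(p))


# ---------------------------------------------------------------------------
# Fisher exact


def _fisher_2x2(table: np.ndarray) -> float:
    a = table[0, 0]
    r1 = table[0].sum()
    c1 = table[:, 0].sum()
    n = table.sum()
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = sps.hypergeom.pmf(a, n, r1, c1)
    return float(min(pmf[pmf <= p_obs * (1 + 1e-7)].sum(), 1.0))


def _log_table_prob(table: np.ndarray, lgam_margins: float) -> float:
    return lgam_margins - gammaln(table + 1).sum()


def _enumerate_rxc(row_sums, col_sums, limit):
    """Yield all contingency tables with the given margins; None if > limit."""
    r, c = len(row_sums), len(col_sums)
    tables: list[np.ndarray] = []

    def fill(i, remaining_cols, current):
        if len(tables) > limit:
            raise _EnumOverflow
        if i == r - 1:
            row = np.asarray(remaining_cols)
            if (row >= 0).all():
                tables.append(np.vstack(current + [row]))
            return
        target = row_sums[i]

        def rec(j, left, row):
            if j == c - 1:
                if 0 <= left <= remaining_cols[j]:
                    fill(i + 1,
                         [rc - rv for rc, rv in zip(remaining_cols, row + [left])],
                         current + [np.asarray(row + [left])])
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                rec(j + 1, left - v, row + [v])

        rec(0, target, [])

    try:
        fill(0, list(col_sums), [])
    except _EnumOverflow:
        return None
    return tables


class _EnumOverflow(Exception):
    pass


def _fisher_rxc_exact(table: np.ndarray) -> Optional[float]:
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    n = table.sum()
    lgam_margins = (
        gammaln(row_sums + 1).sum()
        + gammaln(col_sums + 1).sum()
        - gammaln(n + 1)
    )
    tables = _enumerate_rxc(row_sums.tolist(), col_sums.tolist(), RXC_ENUM_LIMIT)
    if tables is None:
        return None
    lp_obs = _log_table_prob(table, lgam_margins)
    p = 0.0
    for t in tables:
        lp = _log_table_prob(t, lgam_margins)
        if lp <= lp_obs + 1e-9:
            p += math.exp(lp)
    return min(p, 1.0)


def _fisher_rxc_mc(table: np.ndarray, seed: int, n_mc: int):
    rng = np.random.default_rng(seed)
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    n = int(table.sum())
    r, c = table.shape
    lgam_margins = (
        gammaln(row_sums + 1).sum()
        + gammaln(col_sums + 1).sum()
        - gammaln(n + 1)
    )
    lp_obs = _log_table_prob(table, lgam_margins)
    row_labels = np.repeat(np.arange(r), row_sums)
    col_labels = np.repeat(np.arange(c), col_sums)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(col_labels)
        t = np.zeros((r, c), dtype=int)
        np.add.at(t, (row_labels, perm), 1)
        if _log_table_prob(t, lgam_margins) <= lp_obs + 1e-9:
            hits += 1
    p = (hits + 1) / (n_mc + 1)
    se = math.sqrt(p * (1 - p) / n_mc)
    return p, se


def fisher_exact(
    table, seed: int = 0, n_mc: int = MC_TABLES
) -> ComparisonResult:
    """Two-sided Fisher exact test (point-probability rule).

    2x2 tables use the hypergeometric support directly.  Larger tables are
    fully enumerated while the table space stays below ``RXC_ENUM_LIMIT``,
    else estimated by seeded Monte-Carlo with a reported standard error.
    """
    t = np.asarray(table, dtype=int)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    method = "FISHER_2x2" if t.shape == (2, 2) else "FISHER_RxC"
    stat = float(t[0, 0])
    if t.sum() == 0:
        return ComparisonResult(("rows", "cols"), method, stat, 1.0)
    if t.shape == (2, 2):
        return ComparisonResult(("rows", "cols"), method, stat, _fisher_2x2(t))
    p = _fisher_rxc_exact(t)
    if p is not None:
        return ComparisonResult(("rows", "cols"), method, stat, p)
    p, se = _fisher_rxc_mc(t, seed, n_mc)
    return ComparisonResult(
        ("rows", "cols"), method, stat, p, mc_standard_error=se
    )


# ---------------------------------------------------------------------------
# multiplicity


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm-Bonferroni step-down adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, min(1.0, (m - i) * p[idx]))
        adjusted[idx] = running
    return adjusted.tolist()


# ---------------------------------------------------------------------------
# covariate-adjusted contrasts


@dataclass
class AdjustedModelSpec:
    discretize_at_median: bool = True
    min_events: int = 5
    max_iter: int = 200
    separation_tol: float = 1e-8
    coef_bound: float = 20.0


def _fit_pair_logit(y, dummy, covariates, spec):
    """Wald p for the pair dummy; None signals fallback."""
    import statsmodels.api as sm

    X = pd.DataFrame({"group": dummy})
    if covariates is not None:
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    X = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X.astype(float)).fit(disp=0, maxiter=spec.max_iter)
    except Exception:
        return None
    if not fit.mle_retvals.get("converged", False):
        return None
    if np.abs(fit.params).max() > spec.coef_bound:
        return None
    fitted = fit.predict()
    if ((fitted < spec.separation_tol) | (fitted > 1 - spec.separation_tol)).any():
        return None
    return float(fit.pvalues["group"])


def adjusted_pairwise_contrasts(
    outcome: Sequence[float],
    group_labels: Sequence,
    covariates: Optional[pd.DataFrame] = None,
    spec: Optional[AdjustedModelSpec] = None,
) -> list[ComparisonResult]:
    """Median-discretized logistic contrasts for every group pair.

    The continuous outcome is turned into an indicator (> overall median);
    each pair gets a logistic model with a pair-membership dummy plus the
    covariates, Wald p on the dummy, Holm over the pairwise family.  On
    non-convergence, separation, or too few events the pair falls back to
    an unadjusted Mann-Whitney on the raw outcome.
    """
    spec = spec or AdjustedModelSpec()
    outcome = np.asarray(outcome, dtype=float)
    labels = np.asarray(group_labels)
    if outcome.size != labels.size:
        raise ValueError("outcome and labels length mismatch")
    if covariates is not None:
        covariates = pd.DataFrame(covariates).reset_index(drop=True)
        keep = ~(np.isnan(outcome) | covariates.isna().any(axis=1).to_numpy())
        dropped = int((~keep).sum())
        if dropped:
            warnings.warn(f"listwise deletion removed {dropped} rows")
        outcome, labels = outcome[keep], labels[keep]
        covariates = covariates.loc[keep].reset_index(drop=True)
    uniq = sorted(pd.unique(labels).tolist())
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if spec.discretize_at_median:
        med = float(np.median(outcome))
        y_all = (outcome > med).astype(int)
    else:
        y_all = outcome.astype(int)
    if y_all.min() == y_all.max():
        raise ValueError("constant outcome after discretization")

    results = []
    for a, b in itertools.combinations(uniq, 2):
        mask = (labels == a) | (labels == b)
        y = y_all[mask]
        dummy = (labels[mask] == b).astype(int)
        cov = covariates.loc[mask].reset_index(drop=True) if covariates is not None else None
        events = min(int(y.sum()), int((1 - y).sum()))
        p = None
        if events >= spec.min_events:
            p = _fit_pair_logit(y, dummy, cov, spec)
        if p is None:
            mw = mann_whitney(outcome[labels == a], outcome[labels == b])
            results.append(
                ComparisonResult((a, b), "MANN_WHITNEY", mw.statistic, mw.p_raw,
                                 fallback_used=True)
            )
        else:
            results.append(ComparisonResult((a, b), "LOGISTIC_WALD", float("nan"), p))
    adj = holm_adjust([r.p_raw for r in results])
    for r, pa in zip(results, adj):
        r.p_adjusted = pa
    return results


def single_factor_comparison(
    outcome: Sequence,
    group_labels: Sequence,
    control_label,
    categorical: bool = False,
) -> list[ComparisonResult]:
    """Each study group vs control: Mann-Whitney (continuous) or Fisher 2x2
    (binary categorical), Holm-adjusted over the family."""
    outcome = np.asarray(outcome)
    labels = np.asarray(group_labels)
    if control_label not in labels:
        raise ValueError(f"control label {control_label!r} absent")
    others = [g for g in sorted(pd.unique(labels).tolist()) if g != control_label]
    ctrl = outcome[labels == control_label]
    results = []
    for g in others:
        grp = outcome[labels == g]
        if categorical:
            tbl = np.array(
                [
                    [int(np.sum(grp == 1)), int(np.sum(grp == 0))],
                    [int(np.sum(ctrl == 1)), int(np.sum(ctrl == 0))],
                ]
            )
            fr = fisher_exact(tbl)
            results.append(
                ComparisonResult((g, control_label), "FISHER_2x2", fr.statistic, fr.p_raw)
            )
        else:
            mw = mann_whitney(grp.astype(float), ctrl.astype(float))
            results.append(
                ComparisonResult((g, control_label), "MANN_WHITNEY", mw.statistic, mw.p_raw)
            )
    adj = holm_adjust([r.p_raw for r in results])
    for r, pa in zip(results, adj):
        r.p_adjusted = pa
    return results


# ---------------------------------------------------------------------------
# power analysis


def power_two_sample_t(delta: float, spec: PowerSpec) -> float:
    """Power of the two-sided two-sample t test at true difference delta."""
    df = spec.n1 + spec.n2 - 2
    ncp = delta / (spec.sd * math.sqrt(1.0 / spec.n1 + 1.0 / spec.n2))
    tcrit = sps.t.ppf(1 - spec.alpha / 2, df)
    upper = sps.nct.sf(tcrit, df, ncp)
    lower = sps.nct.cdf(-tcrit, df, ncp)
    # scipy's noncentral t underflows to NaN at large ncp; those tails are ~0/1
    if math.isnan(lower):
        lower = 0.0
    if math.isnan(upper):
        upper = 1.0
    return float(min(upper + lower, 1.0))


def detectable_difference(spec: PowerSpec) -> float:
    """Smallest difference detectable with the requested power."""
    from scipy.optimize import brentq

    lo, hi = 1e-9, 1.0
    while power_two_sample_t(hi, spec) < spec.power:
        hi *= 2.0
        if hi > 1e9:
            raise ValueError("infeasible power specification")
    return float(brentq(lambda d: power_two_sample_t(d, spec) - spec.power,
                        lo, hi, xtol=1e-12))


# ---------------------------------------------------------------------------
# descriptive summaries


def summarize(values: Sequence[float]) -> GroupSummary:
    """Median and interquartile range (linear-interpolation quantiles)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return GroupSummary(n=int(v.size), median=float(med), q1=float(q1), q3=float(q3))


def summarize_categorical(count: int, n: int) -> GroupSummary:
    """Count and percent of non-missing observations."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= count <= n):
        raise ValueError("count must lie in [0, n]")
    return GroupSummary(n=n, count=count, percent=100.0 * count / n)
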