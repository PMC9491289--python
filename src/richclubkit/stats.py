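"""Group statistics: permutation tests, ordered-trend test, FDR, effect
sizes, partial correlations and summary-statistics ANOVA.

Group differences in network measures are tested nonparametrically: the
difference of group means is referred to an empirical null distribution
obtained by permuting group labels (exact enumeration is used automatically
whenever the number of distinct assignments does not exceed the requested
permutation count). An ordered three-group alternative (e.g. a monotone
trend across controls, patients and unaffected siblings) is tested with the
Jonckheere-Terpstra statistic. Families of per-k p-values are corrected by
Benjamini-Hochberg FDR, and standardized effect sizes are reported as
Hedges' g.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "TrendResult",
    "PartialCorrelation",
    "permutation_test",
    "jonckheere_terpstra",
    "bh_fdr",
    "hedges_g",
    "spearman_partial",
    "oneway_anova",
    "compare_cohort",
]


@dataclass
class GroupComparison:
    measure: str
    group_a: str
    group_b: str
    observed_diff: float
    p_perm: float
    hedges_g: float
    n_permutations: int
    q: float | None = None
    k: int | None = None


@dataclass
class TrendResult:
    """Jonckheere-Terpstra statistic (concordant pair count, ties counted
    half) and its one-sided p-value for the hypothesized group order."""

    statistic: float
    p: float
    order: tuple[str, ...]
    method: str  # "exact" | "normal" | "degenerate"


@dataclass
class PartialCorrelation:
    rho: float
    p: float
    n: int
    covariates: tuple[str, ...]


# ---------------------------------------------------------------------------
# Permutation test


def permutation_test(x, y, n_perm: int = 50_000, seed: int = 0) -> tuple[float, float]:
    """Two-sided permutation test on the difference of group means.

    Returns ``(p, observed_diff)`` with observed_diff = mean(x) - mean(y).
    When the number of distinct label assignments C(n, len(x)) is at most
    ``n_perm`` the null is enumerated exactly (p = proportion of
    assignments with |diff| >= |observed|, which includes the identity);
    otherwise ``n_perm`` random permutations are drawn and the add-one
    smoothed estimate (1 + b) / (n_perm + 1) is reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    obs = float(x.mean() - y.mean())
    tol = 1e-12 * max(1.0, abs(obs))

    n_total = math.comb(n, nx)
    if n_total <= n_perm:
        count = 0
        for idx in combinations(range(n), nx):
            sel = np.zeros(n, dtype=bool)
            sel[list(idx)] = True
            diff = pooled[sel].mean() - pooled[~sel].mean()
            if abs(diff) >= abs(obs) - tol:
                count += 1
        return count / n_total, obs

    rng = np.random.default_rng(seed)
    # vectorized label shuffles: argsort of uniform draws gives permutations
    batch = 2000
    b = 0
    done = 0
    base = pooled.sum()
    while done < n_perm:
        m = min(batch, n_perm - done)
        perm_idx = np.argsort(rng.random((m, n)), axis=1)[:, :nx]
        sx = pooled[perm_idx].sum(axis=1)
        diffs = sx / nx - (base - sx) / (n - nx)
        b += int((np.abs(diffs) >= abs(obs) - tol).sum())
        done += m
    return (1.0 + b) / (n_perm + 1.0), obs


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra


def _jt_statistic(groups: list[np.ndarray]) -> float:
    jt = 0.0
    for a, b in combinations(range(len(groups)), 2):
        u, v = groups[a][:, None], groups[b][None, :]
        jt += float((v > u).sum()) + 0.5 * float((v == u).sum())
    return jt


def jonckheere_terpstra(groups, order: tuple[str, ...] | None = None,
                        exact_limit: int = 100_000, mc_total_limit: int = 36,
                        n_mc: int = 9999, seed: int = 0) -> TrendResult:
    """Jonckheere-Terpstra test for a monotone increase across ordered groups.

    ``groups`` is the ordered list of value arrays (earliest hypothesized
    lowest). The one-sided p is exact (full enumeration of label
    assignments) when the multinomial arrangement count is at most
    ``exact_limit``; for small samples (total n at most ``mc_total_limit``)
    where enumeration is infeasible, a seeded Monte Carlo permutation null
    of ``n_mc`` draws is used (the normal tail is too thin there);
    otherwise a normal approximation with tie-corrected variance. All-tied
    data yield p = 0.5 by symmetry.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 3:
        raise ValueError("need at least 3 ordered groups")
    if any(len(g) == 0 for g in gs):
        raise ValueError("empty group")
    names = order or tuple(f"group_{i}" for i in range(len(gs)))
    jt = _jt_statistic(gs)
    pooled = np.concatenate(gs)
    sizes = [len(g) for g in gs]
    n = len(pooled)

    if np.all(pooled == pooled[0]):
        return TrendResult(statistic=jt, p=0.5, order=names, method="degenerate")

    n_arrangements = math.factorial(n)
    for sz in sizes:
        n_arrangements //= math.factorial(sz)
    if n_arrangements <= exact_limit:
        count = 0
        total = 0
        tol = 1e-9
        for assignment in _label_assignments(n, sizes):
            stat = _jt_statistic([pooled[list(ix)] for ix in assignment])
            total += 1
            if stat >= jt - tol:
                count += 1
        return TrendResult(statistic=jt, p=count / total, order=names, method="exact")

    if n <= mc_total_limit:
        null = _jt_monte_carlo(pooled, sizes, n_mc, seed)
        p = (1.0 + float((null >= jt - 1e-9).sum())) / (n_mc + 1.0)
        return TrendResult(statistic=jt, p=p, order=names, method="monte_carlo")

    # normal approximation with tie correction (Hollander & Wolfe)
    ns = np.array(sizes, dtype=float)
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    mean = (n * n - (ns ** 2).sum()) / 4.0
    a = (n * (n - 1) * (2 * n + 5)
         - (ns * (ns - 1) * (2 * ns + 5)).sum()
         - (t * (t - 1) * (2 * t + 5)).sum())
    b = (ns * (ns - 1) * (ns - 2)).sum() * (t * (t - 1) * (t - 2)).sum()
    c = (ns * (ns - 1)).sum() * (t * (t - 1)).sum()
    var = a / 72.0 + b / (36.0 * n * (n - 1) * (n - 2)) + c / (8.0 * n * (n - 1))
    if var <= 0:
        return TrendResult(statistic=jt, p=0.5, order=names, method="degenerate")
    z = (jt - mean) / math.sqrt(var)
    return TrendResult(statistic=jt, p=float(sps.norm.sf(z)), order=names, method="normal")


def _jt_monte_carlo(pooled: np.ndarray, sizes: list[int], n_mc: int,
                    seed: int) -> np.ndarray:
    """Vectorized Monte Carlo null distribution of the JT statistic."""
    rng = np.random.default_rng(seed)
    n = len(pooled)
    null = np.zeros(n_mc)
    bounds = np.cumsum([0] + list(sizes))
    batch = 500
    done = 0
    while done < n_mc:
        m = min(batch, n_mc - done)
        perm = pooled[np.argsort(rng.random((m, n)), axis=1)]
        tot = np.zeros(m)
        for a in range(len(sizes)):
            ga = perm[:, bounds[a]:bounds[a + 1]]
            for b in range(a + 1, len(sizes)):
                gb = perm[:, bounds[b]:bounds[b + 1]]
                gt = (gb[:, :, None] > ga[:, None, :]).sum(axis=(1, 2))
                eq = (gb[:, :, None] == ga[:, None, :]).sum(axis=(1, 2))
                tot += gt + 0.5 * eq
        null[done:done + m] = tot
        done += m
    return null


def _label_assignments(n: int, sizes: list[int]):
    """Yield all ways to partition indices 0..n-1 into ordered groups of the
    given sizes (each assignment as a tuple of index tuples)."""
    def rec(remaining: tuple[int, ...], sizes_left: list[int]):
        if not sizes_left:
            yield ()
            return
        k = sizes_left[0]
        for chosen in combinations(remaining, k):
            rest = tuple(x for x in remaining if x not in set(chosen))
            for tail in rec(rest, sizes_left[1:]):
                yield (chosen,) + tail
    yield from rec(tuple(range(n)), list(sizes))


# ---------------------------------------------------------------------------
# FDR, effect size, partial correlation, ANOVA


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up. Returns (adjusted q-values, reject flags)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty p-value list")
    reject, q_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return q_adj, reject


def hedges_g(x, y) -> float:
    """Pooled-SD standardized mean difference with the small-sample
    correction J = 1 - 3 / (4 (n_x + n_y) - 9)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("both groups need n >= 2")
    s2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if s2 == 0:
        if x.mean() == y.mean():
            return 0.0
        raise ValueError("zero pooled variance with unequal means")
    j = 1.0 - 3.0 / (4.0 * (nx + ny) - 9.0)
    return float((x.mean() - y.mean()) / math.sqrt(s2) * j)


def spearman_partial(x, y, covariates: pd.DataFrame | np.ndarray | None = None) -> PartialCorrelation:
    """Spearman partial correlation by rank residualization.

    Ranks of x and y are residualized on the ranks of the covariates by
    least squares (with intercept); the Pearson correlation of the
    residuals is reported with a t-approximation p-value on
    n - 2 - #covariates degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y length mismatch")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values not supported")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    cov_names: tuple[str, ...] = ()
    k = 0
    if covariates is not None:
        Z = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if isinstance(covariates, pd.DataFrame):
            cov_names = tuple(covariates.columns)
        k = Z.shape[1]
        RZ = np.column_stack([np.ones(n)] + [sps.rankdata(Z[:, c]) for c in range(k)])
        if np.linalg.matrix_rank(RZ) < RZ.shape[1]:
            raise ValueError("rank-deficient covariates")
        rx = rx - RZ @ np.linalg.lstsq(RZ, rx, rcond=None)[0]
        ry = ry - RZ @ np.linalg.lstsq(RZ, ry, rcond=None)[0]
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    # residual sums of squares far below the scale of untied ranks
    # (n(n^2-1)/12) are least-squares round-off, not signal; correlating
    # that noise would fabricate arbitrary rho (e.g. when x or y is an
    # exact monotone function of the covariates)
    floor = (n ** 3) * 1e-20
    if (rx ** 2).sum() <= floor or (ry ** 2).sum() <= floor:
        return PartialCorrelation(rho=0.0, p=1.0, n=n, covariates=cov_names)
    denom = math.sqrt(float((rx ** 2).sum() * (ry ** 2).sum()))
    rho = float(np.clip((rx * ry).sum() / denom, -1.0, 1.0))
    df = n - 2 - k
    if df <= 0:
        raise ValueError("not enough observations for the covariate count")
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        tstat = rho * math.sqrt(df / (1.0 - rho ** 2))
        p = float(2.0 * sps.t.sf(abs(tstat), df))
    return PartialCorrelation(rho=rho, p=p, n=n, covariates=cov_names)


def oneway_anova(groups=None, summaries=None) -> tuple[float, tuple[int, int], float]:
    """One-way fixed-effects ANOVA from raw data or (n, mean, sd) summaries.

    Exactly one of ``groups`` (list of value arrays) or ``summaries``
    (list of (n, mean, sd) triples) must be given. Returns (F, (df1, df2), p).
    Summary mode reconstructs the sums of squares exactly:
    SS_within = sum (n_i - 1) sd_i^2, SS_between from group means.
    """
    if (groups is None) == (summaries is None):
        raise ValueError("provide exactly one of groups or summaries")
    if groups is not None:
        gs = [np.asarray(g, dtype=float) for g in groups]
        if len(gs) < 2:
            raise ValueError("need >= 2 groups")
        summaries = [(len(g), float(g.mean()), float(g.std(ddof=1)) if len(g) > 1 else 0.0)
                     for g in gs]
        for g in gs:
            if len(g) < 2:
                raise ValueError("each group needs n >= 2")
    ns = np.array([s[0] for s in summaries], dtype=float)
    means = np.array([s[1] for s in summaries], dtype=float)
    sds = np.array([s[2] for s in summaries], dtype=float)
    if len(ns) < 2:
        raise ValueError("need >= 2 groups")
    if np.any((ns < 2) & (sds > 0)):
        raise ValueError("summary group with n < 2 cannot carry an SD")
    n_total = ns.sum()
    grand = (ns * means).sum() / n_total
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds ** 2).sum())
    df1 = len(ns) - 1
    df2 = int(n_total) - len(ns)
    if df2 <= 0:
        raise ValueError("no within-group degrees of freedom")
    ms_between = ss_between / df1
    ms_within = ss_within / df2
    if ms_within == 0:
        f = math.inf if ms_between > 0 else 0.0
    else:
        f = ms_between / ms_within
    p = float(sps.f.sf(f, df1, df2)) if math.isfinite(f) else 0.0
    return f, (df1, df2), p


# ---------------------------------------------------------------------------
# Cohort-level orchestration


def compare_cohort(measures: pd.DataFrame, groups: pd.Series,
                   group_levels: tuple[str, ...],
                   n_perm: int = 50_000, seed: int = 0,
                   fdr_q: float = 0.05) -> tuple[pd.DataFrame, dict[str, TrendResult]]:
    """All pairwise permutation comparisons plus the ordered trend test.

    ``measures`` is a subjects x measures frame (columns may be per-k
    variables named ``<measure>@k<k>``; each measure's per-k family is
    FDR-corrected jointly within each pairwise comparison). ``groups``
    aligns with the frame's index. Returns a long-format comparison table
    and one TrendResult per measure family when >= 3 groups are present.
    """
    rng = np.random.SeedSequence(seed)
    rows = []
    families: dict[str, list[str]] = {}
    for col in measures.columns:
        fam = col.split("@k")[0]
        families.setdefault(fam, []).append(col)

    pairs = list(combinations(group_levels, 2))
    seed_iter = iter(rng.spawn(len(pairs) * len(measures.columns)))
    for a, b in pairs:
        ia, ib = groups == a, groups == b
        if ia.sum() == 0 or ib.sum() == 0:
            continue
        for fam, cols in families.items():
            fam_rows = []
            for col in cols:
                x = measures.loc[ia, col].to_numpy()
                y = measures.loc[ib, col].to_numpy()
                sub_seed = int(next(seed_iter).generate_state(1)[0] % (2 ** 31))
                p, obs = permutation_test(x, y, n_perm=n_perm, seed=sub_seed)
                try:
                    g = hedges_g(x, y)
                except ValueError:
                    g = float("nan")
                k = int(col.split("@k")[1]) if "@k" in col else None
                fam_rows.append(GroupComparison(measure=col, group_a=a, group_b=b,
                                                observed_diff=obs, p_perm=p, hedges_g=g,
                                                n_permutations=n_perm, k=k))
            qs, _ = bh_fdr([r.p_perm for r in fam_rows], q=fdr_q)
            for r, qv in zip(fam_rows, qs):
                r.q = float(qv)
            rows.extend(fam_rows)

    trends: dict[str, TrendResult] = {}
    if len(group_levels) >= 3 and all((groups == g).sum() > 0 for g in group_levels):
        for fam, cols in families.items():
            for col in cols:
                vals = [measures.loc[groups == g, col].to_numpy() for g in group_levels]
                trends[col] = jonckheere_terpstra(vals, order=group_levels)

    table = pd.DataFrame([{
        "measure": r.measure, "group_a": r.group_a, "group_b": r.group_b,
        "k": r.k, "observed_diff": r.observed_diff, "p_perm": r.p_perm,
        "q": r.q, "hedges_g": r.hedges_g, "n_permutations": r.n_permutations,
    } for r in rows])
    return table, trends
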