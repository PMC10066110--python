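"""Nonparametric statistical battery for the morphometry study.

Descriptive five-number summaries, Kruskal-Wallis with Dunn's post hoc
(Bonferroni-adjusted), Hodges-Lehmann location differences with
Moses-style order-statistic confidence intervals, Spearman correlation,
inter-rater ICC(2,1), ROC analysis with the Youden-index cutoff, and
Clopper-Pearson binomial intervals.

Exact small-sample paths: Kruskal-Wallis and Dunn report an exhaustive
permutation p-value when the pooled sample size is at most 8, and Spearman
switches to the exact permutation p for n <= 9; the asymptotic
approximations are used above those sizes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import (
    DegenerateDataError,
    InvalidLabelsError,
    InvalidParameterError,
)

EXACT_POOLED_N = 8   # exhaustive permutation limit for KW / Dunn
EXACT_SPEARMAN_N = 9


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    statistic: float
    df: int | None
    p_value: float
    method: str
    p_exact: float | None = None


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float
    adjustment: str
    p_exact: float | None = None


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    youden: np.ndarray
    cutoff: float
    cutoff_sensitivity: float
    cutoff_specificity: float
    cutoff_youden: float


def _validate_groups(groups: dict) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise InvalidParameterError("need at least 2 groups")
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float).ravel()
        if arr.size == 0:
            raise InvalidParameterError(f"group {name!r} is empty")
        out[str(name)] = arr
    return out


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------

def five_number_summary(values) -> tuple[float, float, float, float, float]:
    """(min, Q1, median, Q3, max), quartiles by linear interpolation between
    order statistics (numpy's inclusive 'linear' convention)."""
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise InvalidParameterError("empty input")
    q = np.percentile(arr, [0, 25, 50, 75, 100], method="linear")
    return tuple(float(v) for v in q)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

def _kw_h_from_ranksums(rank_sums, sizes, N, tie_factor) -> float:
    h = 12.0 / (N * (N + 1)) * np.sum(rank_sums**2 / sizes) - 3.0 * (N + 1)
    return h / tie_factor


def _tie_factor(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    N = pooled.size
    return 1.0 - np.sum(counts**3 - counts) / (N**3 - N)


def _group_assignments(N: int, sizes: list[int]):
    """Yield index tuples per group for every distinct assignment of the
    pooled indices to groups of the given sizes."""

    def rec(remaining: frozenset, k: int):
        if k == len(sizes) - 1:
            yield (tuple(sorted(remaining)),)
            return
        for combo in itertools.combinations(sorted(remaining), sizes[k]):
            for rest in rec(remaining - set(combo), k + 1):
                yield (combo,) + rest

    yield from rec(frozenset(range(N)), 0)


def kruskal_wallis(groups: dict) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p-value.

    When the pooled size is <= 8 the exact permutation p-value (probability
    of H at least as large under random assignment) is also reported.
    """
    g = _validate_groups(groups)
    arrs = list(g.values())
    pooled = np.concatenate(arrs)
    N = pooled.size
    if N < 3:
        raise InvalidParameterError("pooled sample size must be >= 3")
    if np.all(pooled == pooled[0]):
        raise DegenerateDataError("all pooled values identical")
    h, p = sps.kruskal(*arrs)
    df = len(arrs) - 1
    p_exact = None
    if N <= EXACT_POOLED_N:
        ranks = sps.rankdata(pooled)
        sizes = [a.size for a in arrs]
        tie = _tie_factor(pooled)
        count = 0
        total = 0
        for assign in _group_assignments(N, sizes):
            rs = np.array([ranks[list(ix)].sum() for ix in assign])
            h_perm = _kw_h_from_ranksums(rs, np.array(sizes, dtype=float), N, tie)
            if h_perm >= h - 1e-12:
                count += 1
            total += 1
        p_exact = count / total
    return TestResult(float(h), df, float(p), "kruskal_wallis", p_exact)


def dunn_posthoc(groups: dict, adjust: str = "bonferroni") -> list[PairwiseResult]:
    """Dunn's rank-based pairwise comparisons after Kruskal-Wallis.

    z for pair (i, j) is the mean-rank difference over
    sqrt((N(N+1)/12 - tie term) * (1/n_i + 1/n_j)); the raw two-sided
    normal p is multiplied by the number of pairs (Bonferroni; 'holm' and
    'none' also available). For pooled n <= 8 an exhaustive permutation
    p-value per pair is reported alongside.
    """
    if adjust not in ("bonferroni", "holm", "none"):
        raise InvalidParameterError(f"unknown adjustment {adjust!r}")
    g = _validate_groups(groups)
    names = list(g)
    arrs = [g[n] for n in names]
    pooled = np.concatenate(arrs)
    N = pooled.size
    if np.all(pooled == pooled[0]):
        raise DegenerateDataError("all pooled values identical")
    ranks = sps.rankdata(pooled)
    sizes = np.array([a.size for a in arrs])
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array(
        [ranks[bounds[i]: bounds[i + 1]].mean() for i in range(len(arrs))]
    )
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(range(len(arrs)), 2))
    n_pairs = len(pairs)

    exact_ps: dict[tuple[int, int], float] = {}
    if N <= EXACT_POOLED_N:
        denom = {
            (i, j): math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            for i, j in pairs
        }
        obs_z = {
            (i, j): (mean_ranks[i] - mean_ranks[j]) / denom[(i, j)] for i, j in pairs
        }
        counts_ge = {p: 0 for p in pairs}
        total = 0
        for assign in _group_assignments(N, sizes.tolist()):
            mr = np.array([ranks[list(ix)].mean() for ix in assign])
            for i, j in pairs:
                z_perm = (mr[i] - mr[j]) / denom[(i, j)]
                if abs(z_perm) >= abs(obs_z[(i, j)]) - 1e-12:
                    counts_ge[(i, j)] += 1
            total += 1
        exact_ps = {p: counts_ge[p] / total for p in pairs}

    raws = []
    for i, j in pairs:
        denom_ij = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if denom_ij == 0:
            raise DegenerateDataError("zero rank variance")
        z = (mean_ranks[i] - mean_ranks[j]) / denom_ij
        raws.append((i, j, z, 2.0 * sps.norm.sf(abs(z))))

    if adjust == "holm":
        order = np.argsort([r[3] for r in raws])  # ascending raw p
        adj = [0.0] * n_pairs
        running = 0.0
        for rank, pos in enumerate(order):
            val = min(1.0, (n_pairs - rank) * raws[pos][3])
            running = max(running, val)
            adj[pos] = running
    elif adjust == "bonferroni":
        adj = [min(1.0, r[3] * n_pairs) for r in raws]
    else:
        adj = [r[3] for r in raws]

    return [
        PairwiseResult(
            names[i], names[j], float(z), float(p_raw), float(adj[k]), adjust,
            exact_ps.get((i, j)),
        )
        for k, (i, j, z, p_raw) in enumerate(raws)
    ]


# ---------------------------------------------------------------------------
# Hodges-Lehmann
# ---------------------------------------------------------------------------

def _mannwhitney_cdf(m: int, n: int) -> np.ndarray:
    """Exact null CDF of the Mann-Whitney U statistic for sizes (m, n).

    Counts partitions in an m x n box via the standard recurrence
    G(m, n, u) = G(m, n-1, u) + G(m-1, n, u-n).
    """
    size = m * n + 1
    # G[i, j, u]: partitions of u into at most i parts, each part <= j
    G = np.zeros((m + 1, n + 1, size), dtype=float)
    G[:, :, 0] = 1.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            G[i, j] = G[i, j - 1]
            G[i, j, j:] += G[i - 1, j, :-j]
    pmf = G[m, n]
    pmf /= pmf.sum()
    return np.cumsum(pmf)


@dataclass
class HodgesLehmannResult:
    estimate: float
    ci_low: float
    ci_high: float
    confidence: float


def hodges_lehmann(a, b, confidence: float = 0.95) -> HodgesLehmannResult:
    """Hodges-Lehmann shift estimate for b relative to a (median of all
    pairwise differences b_j - a_i) with the Moses order-statistic CI.

    The CI endpoints are elements of the pairwise-difference multiset,
    bracketed by the exact Mann-Whitney critical value (normal
    approximation above 20000 pairwise differences).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("both samples must be non-empty")
    diffs = np.sort((b[None, :] - a[:, None]).ravel())
    est = float(np.median(diffs))
    m, n = a.size, b.size
    mn = m * n
    alpha = 1.0 - confidence
    if mn <= 20000:
        cdf = _mannwhitney_cdf(m, n)
        below = np.flatnonzero(cdf <= alpha / 2.0)
        crit = int(below[-1]) + 1 if below.size else 0
    else:  # pragma: no cover - large-sample branch
        z = sps.norm.ppf(1.0 - alpha / 2.0)
        crit = int(math.floor(mn / 2.0 - z * math.sqrt(mn * (m + n + 1) / 12.0)))
        crit = max(crit, 0)
    lo_idx = min(max(crit, 0), mn - 1)
    hi_idx = max(mn - 1 - crit, 0)
    return HodgesLehmannResult(est, float(diffs[lo_idx]), float(diffs[hi_idx]), confidence)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def spearman(x, y) -> CorrelationResult:
    """Spearman rho with midrank ties; exact permutation p for n <= 9."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise InvalidParameterError("x and y must have equal length >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise DegenerateDataError("zero variance in a ranked vector")
    n = x.size
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_SPEARMAN_N:
        xc = rx - rx.mean()
        yc = ry - ry.mean()
        denom = math.sqrt(float((xc**2).sum() * (yc**2).sum()))
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = (yc[perms] @ xc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        method = "spearman_exact"
    else:
        _, p = sps.spearmanr(x, y)
        p = float(p)
        method = "spearman_t"
    return CorrelationResult(rho, p, n, method)


# ---------------------------------------------------------------------------
# ICC(2,1)
# ---------------------------------------------------------------------------

def icc_agreement(ratings) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``ratings`` is a complete n-subjects x k-raters matrix.
    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InvalidParameterError("ratings must be an n x k matrix with n, k >= 2")
    if np.isnan(x).any():
        raise InvalidParameterError("ratings must be complete (no missing values)")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        raise DegenerateDataError("zero total variance in ratings")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

def roc_youden(scores, labels) -> ROCResult:
    """ROC over candidate thresholds with the Youden-maximal cutoff.

    Candidate thresholds are the unique observed scores plus -inf; a case
    is called positive when its score is strictly greater than the
    threshold. Ties in J resolve toward maximum sensitivity, then the
    smallest threshold.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    if scores.size != labels.size or scores.size == 0:
        raise InvalidParameterError("scores and labels must be equal-length, non-empty")
    if labels.all() or not labels.any():
        raise InvalidLabelsError("both classes must be present")
    pos = scores[labels]
    neg = scores[~labels]
    thresholds = np.concatenate([[-np.inf], np.unique(scores)])
    sens = np.array([(pos > t).mean() for t in thresholds])
    spec = np.array([(neg <= t).mean() for t in thresholds])
    youden = sens + spec - 1.0
    best_j = youden.max()
    cand = np.flatnonzero(youden >= best_j - 1e-12)
    cand = cand[sens[cand] >= sens[cand].max() - 1e-12]
    best = int(cand[np.argmin(thresholds[cand])])
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        youden=youden,
        cutoff=float(thresholds[best]),
        cutoff_sensitivity=float(sens[best]),
        cutoff_specificity=float(spec[best]),
        cutoff_youden=float(youden[best]),
    )


# ---------------------------------------------------------------------------
# binomial CI
# ---------------------------------------------------------------------------

def binomial_ci(
    successes: int, n: int, confidence: float = 0.95, method: str = "clopper_pearson"
) -> tuple[float, float]:
    """Clopper-Pearson exact interval for a binomial proportion."""
    if method != "clopper_pearson":
        raise InvalidParameterError(f"unknown method {method!r}")
    if n < 1 or not (0 <= successes <= n):
        raise InvalidParameterError(f"invalid counts: {successes}/{n}")
    alpha = 1.0 - confidence
    lower = 0.0 if successes == 0 else float(sps.beta.ppf(alpha / 2.0, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(sps.beta.ppf(1.0 - alpha / 2.0, successes + 1, n - successes))
    return lower, upper
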