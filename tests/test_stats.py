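import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from vamorph.errors import (
    DegenerateDataError,
    InvalidLabelsError,
    InvalidParameterError,
)
from vamorph.stats import (
    binomial_ci,
    dunn_posthoc,
    five_number_summary,
    hodges_lehmann,
    icc_agreement,
    kruskal_wallis,
    roc_youden,
    spearman,
)


# -- independent oracles ----------------------------------------------------

def brute_force_kw_p(groups):
    """Exact permutation p by enumerating permutations of the pooled data."""
    arrs = [np.asarray(v, float) for v in groups.values()]
    sizes = [len(a) for a in arrs]
    pooled = np.concatenate(arrs)
    h_obs = sps.kruskal(*arrs).statistic
    count = total = 0
    for perm in itertools.permutations(pooled):
        parts, start = [], 0
        for s in sizes:
            parts.append(np.array(perm[start:start + s]))
            start += s
        h = sps.kruskal(*parts).statistic
        count += h >= h_obs - 1e-12
        total += 1
    return count / total


def brute_force_dunn_p(groups):
    """Exact permutation p per pair for the Dunn z statistic."""
    arrs = [np.asarray(v, float) for v in groups.values()]
    sizes = [len(a) for a in arrs]
    pooled = np.concatenate(arrs)
    N = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term

    def zs(values):
        ranks = sps.rankdata(values)
        start, means = 0, []
        for s in sizes:
            means.append(ranks[start:start + s].mean())
            start += s
        out = {}
        for i, j in itertools.combinations(range(len(sizes)), 2):
            denom = math.sqrt(var_base * (1 / sizes[i] + 1 / sizes[j]))
            out[(i, j)] = (means[i] - means[j]) / denom
        return out

    obs = zs(pooled)
    tallies = {p: 0 for p in obs}
    total = 0
    for perm in itertools.permutations(pooled):
        z = zs(np.array(perm))
        for p in obs:
            tallies[p] += abs(z[p]) >= abs(obs[p]) - 1e-12
        total += 1
    return {p: tallies[p] / total for p in obs}


# -- descriptives -----------------------------------------------------------

class TestFiveNumber:
    def test_identity_on_1_to_5(self):
        assert five_number_summary([1, 2, 3, 4, 5]) == (1, 2, 3, 4, 5)

    def test_singleton(self):
        assert five_number_summary([7]) == (7, 7, 7, 7, 7)

    def test_quartiles_linear_interpolation(self):
        mn, q1, med, q3, mx = five_number_summary([1, 2, 3, 4])
        # inclusive linear interpolation between order statistics
        assert (mn, q1, med, q3, mx) == (1, 1.75, 2.5, 3.25, 4)

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            five_number_summary([])


# -- Kruskal-Wallis ---------------------------------------------------------

class TestKruskalWallis:
    def test_h_hand_value(self):
        res = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        assert res.statistic == pytest.approx(7.2)
        assert res.df == 2

    def test_exact_path_matches_brute_force(self):
        groups = {"a": [1.2, 3.4, 0.5], "b": [2.2, 5.1], "c": [4.4, 0.9, 6.0]}
        res = kruskal_wallis(groups)
        assert res.p_exact is not None
        assert res.p_exact == pytest.approx(brute_force_kw_p(groups), abs=1e-9)

    def test_rank_invariance_under_monotone_transform(self):
        g = {"a": [0.1, 0.7, 0.3], "b": [0.9, 0.5], "c": [0.2, 0.8]}
        h1 = kruskal_wallis(g).statistic
        g2 = {k: np.exp(np.asarray(v) * 3) for k, v in g.items()}
        assert kruskal_wallis(g2).statistic == pytest.approx(h1, rel=1e-12)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(400):
            g = {"a": rng.normal(size=25), "b": rng.normal(size=25)}
            ps.append(kruskal_wallis(g).p_value)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateDataError):
            kruskal_wallis({"a": [1, 1], "b": [1, 1]})


# -- Dunn -------------------------------------------------------------------

class TestDunn:
    def test_hand_worked_pair(self):
        res = dunn_posthoc({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        ac = [p for p in res if (p.group_a, p.group_b) == ("a", "c")][0]
        assert ac.z == pytest.approx(-2.683, abs=1e-3)
        assert ac.p_raw == pytest.approx(0.0073, abs=2e-4)
        assert ac.p_adjusted == pytest.approx(0.0219, abs=5e-4)

    def test_identical_groups_z_zero(self):
        res = dunn_posthoc({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res[0].z == pytest.approx(0.0)
        assert res[0].p_adjusted == 1.0

    def test_bonferroni_bound(self):
        res = dunn_posthoc({"a": [1, 5, 3], "b": [2, 8], "c": [9, 4]})
        for p in res:
            assert p.p_adjusted >= p.p_raw - 1e-15

    def test_exact_path_matches_brute_force(self):
        groups = {"a": [3.0, 1.0, 4.0], "b": [1.5, 5.0], "c": [9.0, 2.6, 5.3]}
        res = dunn_posthoc(groups)
        oracle = brute_force_dunn_p(groups)
        names = list(groups)
        for p in res:
            key = (names.index(p.group_a), names.index(p.group_b))
            assert p.p_exact == pytest.approx(oracle[key], abs=1e-9)

    def test_holm_dominated_by_bonferroni(self):
        g = {"a": [1, 2, 9], "b": [4, 5], "c": [7, 8, 3]}
        bon = {(p.group_a, p.group_b): p.p_adjusted for p in dunn_posthoc(g)}
        holm = {(p.group_a, p.group_b): p.p_adjusted for p in dunn_posthoc(g, adjust="holm")}
        for k in bon:
            assert holm[k] <= bon[k] + 1e-15


# -- Hodges-Lehmann ---------------------------------------------------------

class TestHodgesLehmann:
    def test_worked_example(self):
        assert hodges_lehmann([1, 2], [3, 4]).estimate == pytest.approx(2.0)

    def test_identical_samples_zero(self):
        a = [1.0, 2.5, 3.5]
        assert hodges_lehmann(a, a).estimate == pytest.approx(0.0)

    def test_ci_endpoints_are_pairwise_differences(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=8)
        b = rng.normal(1.0, size=9)
        res = hodges_lehmann(a, b)
        diffs = (np.asarray(b)[None, :] - np.asarray(a)[:, None]).ravel()
        assert np.min(np.abs(diffs - res.ci_low)) < 1e-12
        assert np.min(np.abs(diffs - res.ci_high)) < 1e-12
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_ci_coverage_against_known_shift(self):
        rng = np.random.default_rng(11)
        cover = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.normal(size=12)
            b = rng.normal(1.5, size=12)
            res = hodges_lehmann(a, b)
            cover += res.ci_low <= 1.5 <= res.ci_high
        assert cover / n_rep > 0.88  # nominal 95%


# -- Spearman ---------------------------------------------------------------

class TestSpearman:
    def test_perfect_anticorrelation(self):
        assert spearman([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    def test_monotone_transform_gives_plus_one(self):
        x = [0.3, 1.1, 2.0, 5.0, 9.2]
        y = np.exp(x)
        assert spearman(x, y).rho == pytest.approx(1.0)

    def test_exact_p_equals_enumeration(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        res = spearman(x, y)
        # enumeration oracle over all 120 orderings of y
        rx = sps.rankdata(x)
        rho_obs = res.rho
        count = total = 0
        for perm in itertools.permutations(sps.rankdata(y)):
            rho = np.corrcoef(rx, perm)[0, 1]
            count += abs(rho) >= abs(rho_obs) - 1e-12
            total += 1
        assert res.p_value == pytest.approx(count / total, abs=1e-12)
        assert res.method == "spearman_exact"

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = spearman(x, y)
        assert res.method == "spearman_t"
        assert res.rho == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateDataError):
            spearman([1, 1, 1], [2, 3, 4])


# -- ICC --------------------------------------------------------------------

class TestICC:
    def test_identical_raters_give_one(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        assert icc_agreement(x) == pytest.approx(1.0)

    def test_hand_anova_worked_matrix(self):
        assert icc_agreement([[1, 2], [3, 4], [5, 6]]) == pytest.approx(8 / 9)

    def test_constant_rater_offset_lowers_icc(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(12, 1))
        x = np.hstack([base, base])
        shifted = np.hstack([base, base + 1.0])
        assert icc_agreement(shifted) < icc_agreement(x)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(9)
        x = rng.normal(size=(10, 2)) + rng.normal(size=(10, 1))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(10), 2),
                "rater": np.tile(["r1", "r2"], 10),
                "score": x.ravel(),
            }
        )
        icc_tab = pg.intraclass_corr(df, "subject", "rater", "score")
        # ICC(A,1): absolute agreement, single measures == ICC(2,1)
        ref = float(icc_tab.loc[icc_tab.Type == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_agreement(x) == pytest.approx(ref, abs=1e-9)

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateDataError):
            icc_agreement(np.full((4, 2), 3.0))


# -- ROC / Youden -----------------------------------------------------------

def brute_force_cutoff_j(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    best = -2.0
    cands = np.concatenate([[-np.inf], np.unique(scores),
                            (np.sort(np.unique(scores))[:-1] + np.sort(np.unique(scores))[1:]) / 2
                            if len(np.unique(scores)) > 1 else []])
    for t in cands:
        j = (scores[labels] > t).mean() + (scores[~labels] <= t).mean() - 1
        best = max(best, j)
    return best


class TestROC:
    def test_separable_example(self):
        res = roc_youden([1, 2, 3, 5, 6], [0, 0, 0, 1, 1])
        assert res.cutoff == 3
        assert res.cutoff_sensitivity == 1.0
        assert res.cutoff_specificity == 1.0
        assert res.cutoff_youden == 1.0

    def test_interleaved_scores_degenerate(self):
        res = roc_youden([1, 2, 3, 4], [1, 0, 1, 0])
        assert res.cutoff_youden == pytest.approx(0.0)

    def test_cutoff_j_equals_brute_force_scan(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 25))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.integers(0, 2, size=n).astype(bool)
            if labels.all() or not labels.any():
                continue
            res = roc_youden(scores, labels)
            assert res.cutoff_youden == pytest.approx(
                brute_force_cutoff_j(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(InvalidLabelsError):
            roc_youden([1, 2, 3], [1, 1, 1])

    def test_youden_in_range(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40).astype(bool)
        res = roc_youden(scores, labels)
        assert np.all(res.youden >= -1 - 1e-12) and np.all(res.youden <= 1 + 1e-12)


# -- binomial CI ------------------------------------------------------------

class TestBinomialCI:
    def test_all_successes_closed_form(self):
        lo, hi = binomial_ci(15, 15)
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** (1 / 15), abs=1e-12)

    def test_zero_successes(self):
        lo, hi = binomial_ci(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-12)

    def test_half_brackets_point_and_matches_beta(self):
        lo, hi = binomial_ci(5, 10)
        assert lo < 0.5 < hi
        assert lo == pytest.approx(sps.beta.ppf(0.025, 5, 6), abs=1e-12)
        assert hi == pytest.approx(sps.beta.ppf(0.975, 6, 5), abs=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            binomial_ci(11, 10)
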