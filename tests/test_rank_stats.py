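"""Statistical battery: closed-form identities, independent oracles, and
null-calibration simulations."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from vusworm import (
    GroupedSamples,
    ValidationError,
    anova_tukey,
    dunn_posthoc,
    kruskal_wallis,
    run_test_battery,
    schaich_hammerle_posthoc,
    shapiro_wilk_gate,
)
from vusworm.rank_stats import posthoc_table, significance_stars


def naive_midranks(pooled):
    """Independent O(n^2) mid-rank computation: rank of x is the count of
    smaller values plus half the ties, offset to 1-based ranks."""
    return np.array(
        [
            sum(1.0 for y in pooled if y < x) + (sum(1.0 for y in pooled if y == x) + 1.0) / 2.0
            for x in pooled
        ]
    )


def naive_kw_h(groups):
    pooled = np.concatenate(groups)
    ranks = naive_midranks(pooled)
    N = len(pooled)
    start, h = 0, 0.0
    for g in groups:
        rbar = ranks[start : start + len(g)].mean()
        h += len(g) * (rbar - (N + 1) / 2.0) ** 2
        start += len(g)
    h *= 12.0 / (N * (N + 1))
    _, counts = np.unique(pooled, return_counts=True)
    return h / (1.0 - np.sum(counts**3 - counts) / (N**3 - N))


class TestShapiroGate:
    def test_uniform_draws_routed_nonparametric(self):
        rng = np.random.default_rng(11)
        assert shapiro_wilk_gate(rng.uniform(size=500)) == "nonparametric"

    def test_constant_sample_flagged_nonnormal(self):
        assert shapiro_wilk_gate(np.full(20, 3.0)) == "nonparametric"

    def test_all_groups_must_pass(self):
        rng = np.random.default_rng(12)
        grouped = GroupedSamples.from_dict(
            {"normal": rng.normal(size=200), "uniform": rng.uniform(size=500)}
        )
        assert shapiro_wilk_gate(grouped) == "nonparametric"

    def test_type_one_error_rate_near_alpha(self):
        rng = np.random.default_rng(13)
        reps = 1000
        rejections = sum(
            sps.shapiro(rng.normal(size=5000)).pvalue < 0.05 for _ in range(reps)
        )
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) < 3 * se

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValidationError):
            shapiro_wilk_gate(np.array([1.0, 2.0]))


class TestKruskalWallis:
    def test_equal_rank_means_give_zero(self):
        grouped = GroupedSamples.from_dict({"a": [1, 2, 3], "b": [1, 2, 3]})
        result = kruskal_wallis(grouped)
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "groups",
        [
            {"a": [1, 2, 3], "b": [4, 5, 6]},
            {"a": [1, 1, 2, 5], "b": [2, 2, 3], "c": [0, 4, 4, 4]},
            {"a": [3.5, 3.5, 1], "b": [2, 2], "c": [9, 0, 2]},
        ],
    )
    def test_matches_naive_midrank_oracle(self, groups):
        grouped = GroupedSamples.from_dict(groups)
        expected = naive_kw_h([np.asarray(g, float) for g in groups.values()])
        assert kruskal_wallis(grouped).statistic == pytest.approx(expected)

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(21)
        groups = {f"g{i}": rng.normal(i * 0.3, 1, size=12) for i in range(4)}
        grouped = GroupedSamples.from_dict(groups)
        result = kruskal_wallis(grouped)
        h_ref, p_ref = sps.kruskal(*groups.values())
        assert result.statistic == pytest.approx(h_ref)
        assert result.p_value == pytest.approx(p_ref)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(22)
        groups = {f"g{i}": rng.gamma(2, size=10) for i in range(3)}
        h_raw = kruskal_wallis(GroupedSamples.from_dict(groups)).statistic
        h_log = kruskal_wallis(
            GroupedSamples.from_dict({k: np.log(v) for k, v in groups.items()})
        ).statistic
        assert h_raw == pytest.approx(h_log)

    def test_two_groups_equal_wilcoxon_z_squared(self):
        a = np.array([1.0, 4.0, 6.0, 9.0])
        b = np.array([2.0, 3.0, 7.0, 11.0, 13.0])
        h = kruskal_wallis(GroupedSamples.from_dict({"a": a, "b": b})).statistic
        z = sps.ranksums(a, b).statistic
        assert h == pytest.approx(z**2)

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(23)
        reps = 2000
        rejections = 0
        for _ in range(reps):
            grouped = GroupedSamples.from_dict(
                {f"g{i}": rng.normal(size=10) for i in range(3)}
            )
            rejections += kruskal_wallis(grouped).p_value < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) < 3 * se

    def test_all_tied_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis(GroupedSamples.from_dict({"a": [1, 1], "b": [1, 1]}))


def dunn_permutation_p(groups, pair=(0, 1)):
    """Exhaustive permutation mid-p for the rank-mean difference of one
    pair, permuting group assignments of the pooled sample.  Ties at the
    observed statistic count half (the usual convention when a discrete
    permutation null is compared against a continuous approximation)."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    ranks = sps.rankdata(pooled)
    idx = np.arange(len(pooled))

    def rankmean_diff(assignment):
        bounds = np.cumsum([0] + sizes)
        i, j = pair
        ri = ranks[assignment[bounds[i] : bounds[i + 1]]].mean()
        rj = ranks[assignment[bounds[j] : bounds[j + 1]]].mean()
        return abs(ri - rj)

    observed = rankmean_diff(idx)
    greater = equal = total = 0
    for combo1 in itertools.combinations(range(len(pooled)), sizes[0]):
        rest = [i for i in idx if i not in combo1]
        for combo2 in itertools.combinations(rest, sizes[1]):
            tail = [i for i in rest if i not in combo2]
            diff = rankmean_diff(np.array(list(combo1) + list(combo2) + tail))
            greater += diff > observed + 1e-12
            equal += abs(diff - observed) <= 1e-12
            total += 1
    return (greater + 0.5 * equal) / total


class TestDunn:
    def test_identical_groups(self):
        grouped = GroupedSamples.from_dict({"a": [1, 2, 3], "b": [1, 2, 3]})
        result = dunn_posthoc(grouped)[0]
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_antisymmetry_under_group_order(self):
        data = {"a": [1.0, 5.0, 7.0], "b": [2.0, 3.0, 9.0], "c": [4.0, 6.0, 8.0]}
        forward = dunn_posthoc(GroupedSamples.from_dict(data))
        reverse = dunn_posthoc(
            GroupedSamples.from_dict(dict(reversed(list(data.items()))))
        )
        fwd = {frozenset(r.pair): r for r in forward}
        rev = {frozenset(r.pair): r for r in reverse}
        for key in fwd:
            assert abs(fwd[key].statistic) == pytest.approx(abs(rev[key].statistic))
            assert fwd[key].p_value == pytest.approx(rev[key].p_value)

    def test_unadjusted_p_close_to_exhaustive_permutation(self):
        rng = np.random.default_rng(31)
        groups = [rng.normal(size=4), rng.normal(0.8, 1, size=4), rng.normal(size=4)]
        grouped = GroupedSamples.from_dict({"a": groups[0], "b": groups[1], "c": groups[2]})
        result = next(
            r for r in dunn_posthoc(grouped, adjustment="none") if set(r.pair) == {"a", "b"}
        )
        exact = dunn_permutation_p(groups, pair=(0, 1))
        assert abs(result.p_value - exact) < 0.02

    def test_bonferroni_never_below_unadjusted(self):
        rng = np.random.default_rng(32)
        grouped = GroupedSamples.from_dict({f"g{i}": rng.normal(i, 1, 8) for i in range(3)})
        raw = {r.pair: r.p_value for r in dunn_posthoc(grouped, adjustment="none")}
        adj = {r.pair: r.p_value for r in dunn_posthoc(grouped, adjustment="bonferroni")}
        assert all(adj[pair] >= raw[pair] - 1e-12 for pair in raw)


class TestSchaichHammerle:
    def test_identical_groups_never_significant(self):
        grouped = GroupedSamples.from_dict({"a": [1, 2, 3], "b": [1, 2, 3]})
        for alpha in (0.5, 0.05, 0.001):
            assert not schaich_hammerle_posthoc(grouped, alpha=alpha)[0].significant

    def test_two_group_closed_form(self):
        a, b = [1.0, 4.0, 6.0], [2.0, 3.0, 7.0, 9.0]
        grouped = GroupedSamples.from_dict({"a": a, "b": b})
        result = schaich_hammerle_posthoc(grouped, alpha=0.05)[0]
        ranks = sps.rankdata(np.concatenate([a, b]))
        diff = ranks[:3].mean() - ranks[3:].mean()
        N = 7.0
        crit = np.sqrt(sps.chi2.ppf(0.95, 1) * N * (N + 1) / 12.0 * (1 / 3 + 1 / 4))
        assert result.statistic == pytest.approx(diff)
        assert result.critical_difference == pytest.approx(crit)
        assert result.significant == (abs(diff) > crit)

    def test_significant_set_monotone_in_alpha(self):
        rng = np.random.default_rng(41)
        grouped = GroupedSamples.from_dict(
            {f"g{i}": rng.normal(i * 0.8, 1, size=12) for i in range(4)}
        )
        previous = None
        for alpha in (0.2, 0.1, 0.05, 0.01, 0.001):
            current = {
                r.pair for r in schaich_hammerle_posthoc(grouped, alpha=alpha) if r.significant
            }
            if previous is not None:
                assert current <= previous
            previous = current

    def test_tie_corrected_variant_is_less_conservative(self):
        rng = np.random.default_rng(42)
        groups = {f"g{i}": rng.integers(0, 5, size=30).astype(float) for i in range(3)}
        grouped = GroupedSamples.from_dict(groups)
        plain = schaich_hammerle_posthoc(grouped, tie_corrected=False)
        corrected = schaich_hammerle_posthoc(grouped, tie_corrected=True)
        for p, c in zip(plain, corrected):
            assert c.critical_difference <= p.critical_difference

    def test_all_tied_rejected(self):
        with pytest.raises(ValidationError):
            schaich_hammerle_posthoc(GroupedSamples.from_dict({"a": [2, 2], "b": [2, 2]}))


class TestAnovaTukey:
    def test_zero_variance_everywhere_rejected(self):
        grouped = GroupedSamples.from_dict({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        with pytest.raises(ValidationError):
            anova_tukey(grouped)

    def test_two_group_tukey_equals_t_test(self):
        rng = np.random.default_rng(51)
        a, b = rng.normal(size=10), rng.normal(0.5, 1, size=10)
        result = anova_tukey(GroupedSamples.from_dict({"a": a, "b": b}))
        t_p = sps.ttest_ind(a, b).pvalue
        assert result.posthoc[0].p_value == pytest.approx(t_p, rel=1e-6)

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(52)
        reps = 2000
        rejections = 0
        for _ in range(reps):
            f, p = sps.f_oneway(*(rng.normal(size=10) for _ in range(3)))
            rejections += p < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) < 3 * se


class TestBattery:
    @pytest.mark.parametrize(
        "assay, expected_method",
        [
            ("dyefill", "kruskal-wallis + schaich-hammerle"),
            ("roaming", "kruskal-wallis + dunn"),
            ("chemotaxis", "anova + tukey"),
        ],
    )
    def test_routing(self, assay, expected_method):
        rng = np.random.default_rng(61)
        grouped = GroupedSamples.from_dict(
            {f"g{i}": rng.normal(i, 1, size=15) for i in range(3)}
        )
        result = run_test_battery(grouped, assay)
        assert result.method == expected_method
        assert len(result.posthoc) == 3

    def test_unknown_assay_rejected(self):
        grouped = GroupedSamples.from_dict({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        with pytest.raises(ValidationError):
            run_test_battery(grouped, "lifespan")

    def test_stars_thresholds(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == "ns"

    def test_posthoc_table_columns(self):
        rng = np.random.default_rng(62)
        grouped = GroupedSamples.from_dict({"a": rng.normal(size=20), "b": rng.normal(2, 1, 20)})
        table = posthoc_table(run_test_battery(grouped, "dyefill"))
        assert {"group_i", "group_j", "statistic", "significant", "stars"} <= set(table.columns)
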