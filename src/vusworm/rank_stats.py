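"""Rank-based statistical battery for multi-strain assay comparisons.

The assays are compared across strains with the tests conventional for each
data type: heavily tied ordinal dye-fill counts get Kruskal–Wallis followed
by the Schaich–Hammerle post hoc (pairwise rank-mean differences against a
chi-squared-based critical difference); roaming gets Kruskal–Wallis followed
by Dunn's z tests with multiplicity adjustment; approximately normal
chemotaxis indices and GFP intensities get one-way ANOVA followed by Tukey's
HSD.  A Shapiro–Wilk gate decides the parametric vs nonparametric route.

Kruskal–Wallis, Dunn and Schaich–Hammerle are implemented here from the
rank formulas (all three share the global mid-rank computation, and the
Schaich–Hammerle procedure has no implementation in the scientific Python
stack); Shapiro–Wilk, ANOVA and Tukey are delegated to scipy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import ValidationError

__all__ = [
    "GroupedSamples",
    "PosthocResult",
    "OmnibusResult",
    "shapiro_wilk_gate",
    "kruskal_wallis",
    "dunn_posthoc",
    "schaich_hammerle_posthoc",
    "anova_tukey",
    "run_test_battery",
    "significance_stars",
]

#: Routing of each assay to its statistical procedure.
ASSAY_TESTS = {
    "dyefill": "kruskal-wallis + schaich-hammerle",
    "roaming": "kruskal-wallis + dunn",
    "chemotaxis": "anova + tukey",
    "gfp": "anova + tukey",
}


@dataclass(frozen=True)
class GroupedSamples:
    """k >= 2 labelled groups of real-valued observations."""

    labels: tuple[str, ...]
    groups: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.groups):
            raise ValidationError("labels and groups must align")
        if len(self.groups) < 2:
            raise ValidationError("need at least 2 groups")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("group labels must be unique")
        if any(len(g) == 0 for g in self.groups):
            raise ValidationError("every group must be nonempty")

    @classmethod
    def from_dict(cls, data: dict[str, "np.typing.ArrayLike"]) -> "GroupedSamples":
        labels = tuple(data)
        groups = tuple(np.asarray(v, dtype=float) for v in data.values())
        return cls(labels, groups)

    @classmethod
    def from_records(
        cls, frame: pd.DataFrame, group_col: str = "strain", value_col: str = "value"
    ) -> "GroupedSamples":
        grouped = {
            str(g): sub[value_col].to_numpy(dtype=float)
            for g, sub in frame.groupby(group_col, sort=False)
        }
        return cls.from_dict(grouped)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(g) for g in self.groups])

    @property
    def total(self) -> int:
        return int(self.sizes.sum())

    def pooled(self) -> np.ndarray:
        return np.concatenate(self.groups)


@dataclass
class PosthocResult:
    """One pairwise comparison from a post hoc procedure.

    ``statistic`` is signed (group_i minus group_j on the method's scale);
    ``p_value`` is the adjusted p where the method produces one, otherwise
    ``None`` and ``significant`` carries the decision at the stated alpha.
    """

    pair: tuple[str, str]
    statistic: float
    method: str
    p_value: float | None = None
    significant: bool | None = None
    critical_difference: float | None = None

    @property
    def stars(self) -> str:
        if self.p_value is not None:
            return significance_stars(self.p_value)
        return "*" if self.significant else "ns"


@dataclass
class OmnibusResult:
    method: str
    statistic: float
    df: float
    p_value: float
    posthoc: list[PosthocResult] = field(default_factory=list)


def significance_stars(p: float) -> str:
    """Star notation: *** p<0.001, ** p<0.01, * p<0.05, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def shapiro_wilk_gate(data: GroupedSamples | np.ndarray, alpha: float = 0.05) -> str:
    """Decide the analysis route from per-group Shapiro–Wilk normality tests.

    Returns ``"parametric"`` when every group passes at ``alpha`` (no
    evidence against normality) and ``"nonparametric"`` otherwise.  A
    zero-variance group cannot be tested and is treated as non-normal.
    Accepts a single sample as well, in which case the gate applies to it
    alone.
    """
    groups = data.groups if isinstance(data, GroupedSamples) else (np.asarray(data, float),)
    for g in groups:
        if len(g) < 3:
            raise ValidationError("Shapiro-Wilk requires n >= 3 per group")
        if np.ptp(g) == 0:
            return "nonparametric"
        if stats.shapiro(g).pvalue < alpha:
            return "nonparametric"
    return "parametric"


def _midranks(data: GroupedSamples) -> tuple[list[np.ndarray], float]:
    """Global mid-ranks per group and the tie term sum(t^3 - t)."""
    pooled = data.pooled()
    ranks = stats.rankdata(pooled)
    out, start = [], 0
    for g in data.groups:
        out.append(ranks[start : start + len(g)])
        start += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    return out, tie_term


def kruskal_wallis(data: GroupedSamples) -> OmnibusResult:
    """Kruskal–Wallis H with mid-ranks and tie correction.

    H = [12 / (N(N+1))] * sum n_i (Rbar_i - (N+1)/2)^2, divided by the tie
    factor 1 - sum(t^3 - t)/(N^3 - N); p is the upper chi-squared tail with
    k - 1 degrees of freedom.
    """
    ranks, tie_term = _midranks(data)
    n = data.sizes.astype(float)
    N = float(data.total)
    tie_factor = 1.0 - tie_term / (N**3 - N)
    if tie_factor <= 0:
        raise ValidationError("all observations identical; Kruskal-Wallis undefined")
    rank_means = np.array([r.mean() for r in ranks])
    h = 12.0 / (N * (N + 1.0)) * np.sum(n * (rank_means - (N + 1.0) / 2.0) ** 2)
    h /= tie_factor
    df = len(data.groups) - 1
    p = float(stats.chi2.sf(h, df))
    return OmnibusResult("kruskal-wallis", float(h), df, p)


def dunn_posthoc(data: GroupedSamples, adjustment: str = "bonferroni") -> list[PosthocResult]:
    """Dunn's pairwise z tests on global mid-ranks after Kruskal–Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - sum(t^3 - t)/(12(N-1))]
    (1/n_i + 1/n_j)); two-sided normal p-values adjusted by ``adjustment``
    (any method statsmodels' ``multipletests`` accepts; "none" disables).
    """
    ranks, tie_term = _midranks(data)
    n = data.sizes.astype(float)
    N = float(data.total)
    variance = N * (N + 1.0) / 12.0 - tie_term / (12.0 * (N - 1.0))
    if variance <= 0:
        raise ValidationError("all observations identical; Dunn's test undefined")
    rank_means = np.array([r.mean() for r in ranks])
    pairs = list(itertools.combinations(range(len(data.groups)), 2))
    zs, raw_ps = [], []
    for i, j in pairs:
        z = (rank_means[i] - rank_means[j]) / np.sqrt(variance * (1.0 / n[i] + 1.0 / n[j]))
        zs.append(float(z))
        raw_ps.append(float(2.0 * stats.norm.sf(abs(z))))
    if adjustment.lower() in ("none", "unadjusted"):
        adj_ps = raw_ps
    else:
        adj_ps = multipletests(raw_ps, method=adjustment)[1]
    return [
        PosthocResult(
            pair=(data.labels[i], data.labels[j]),
            statistic=z,
            method=f"dunn[{adjustment}]",
            p_value=float(min(p, 1.0)),
        )
        for (i, j), z, p in zip(pairs, zs, adj_ps)
    ]


def schaich_hammerle_posthoc(
    data: GroupedSamples, alpha: float = 0.05, tie_corrected: bool = False
) -> list[PosthocResult]:
    """Schaich–Hammerle pairwise comparisons after Kruskal–Wallis.

    Pair (i, j) is significant iff |Rbar_i - Rbar_j| exceeds
    sqrt(chi2_{1-alpha, k-1} * [N(N+1)/12] * (1/n_i + 1/n_j)), with global
    mid-ranks.  The classic procedure uses the untied variance term
    N(N+1)/12; ``tie_corrected=True`` swaps in the tie-corrected term
    N(N+1)/12 - sum(t^3 - t)/(12(N-1)) for heavily tied data.  Because the
    critical value comes from the full k-1 df chi-squared, the procedure
    controls the familywise error conservatively.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    ranks, tie_term = _midranks(data)
    n = data.sizes.astype(float)
    N = float(data.total)
    variance = N * (N + 1.0) / 12.0
    if tie_corrected:
        variance -= tie_term / (12.0 * (N - 1.0))
    if variance <= 0 or tie_term >= N**3 - N:
        raise ValidationError("all observations identical; post hoc undefined")
    k = len(data.groups)
    chi2_crit = float(stats.chi2.ppf(1.0 - alpha, k - 1))
    rank_means = np.array([r.mean() for r in ranks])
    results = []
    for i, j in itertools.combinations(range(k), 2):
        diff = float(rank_means[i] - rank_means[j])
        crit = float(np.sqrt(chi2_crit * variance * (1.0 / n[i] + 1.0 / n[j])))
        results.append(
            PosthocResult(
                pair=(data.labels[i], data.labels[j]),
                statistic=diff,
                method="schaich-hammerle" + ("[tie-corrected]" if tie_corrected else ""),
                significant=abs(diff) > crit,
                critical_difference=crit,
            )
        )
    return results


def anova_tukey(data: GroupedSamples, alpha: float = 0.05) -> OmnibusResult:
    """One-way ANOVA F test followed by Tukey's HSD pairwise comparisons."""
    if any(len(g) < 2 for g in data.groups):
        raise ValidationError("ANOVA requires n_i >= 2 in every group")
    if all(np.ptp(g) == 0 for g in data.groups):
        raise ValidationError("zero within-group variance everywhere; F undefined")
    f, p = stats.f_oneway(*data.groups)
    tukey = stats.tukey_hsd(*data.groups)
    posthoc = []
    for i, j in itertools.combinations(range(len(data.groups)), 2):
        posthoc.append(
            PosthocResult(
                pair=(data.labels[i], data.labels[j]),
                statistic=float(tukey.statistic[i, j]),
                method="tukey-hsd",
                p_value=float(tukey.pvalue[i, j]),
            )
        )
    df = len(data.groups) - 1
    return OmnibusResult("anova", float(f), df, float(p), posthoc)


def run_test_battery(
    data: GroupedSamples,
    assay: str,
    alpha: float = 0.05,
    dunn_adjustment: str = "bonferroni",
) -> OmnibusResult:
    """Route one assay's per-strain records to its statistical procedure.

    dyefill -> Kruskal–Wallis + Schaich–Hammerle; roaming -> Kruskal–Wallis +
    Dunn; chemotaxis and GFP quantification -> ANOVA + Tukey.
    """
    if assay not in ASSAY_TESTS:
        raise ValidationError(f"unknown assay {assay!r}; expected one of {sorted(ASSAY_TESTS)}")
    if assay == "dyefill":
        result = kruskal_wallis(data)
        result.posthoc = schaich_hammerle_posthoc(data, alpha=alpha)
    elif assay == "roaming":
        result = kruskal_wallis(data)
        result.posthoc = dunn_posthoc(data, adjustment=dunn_adjustment)
    else:
        result = anova_tukey(data, alpha=alpha)
    result.method = ASSAY_TESTS[assay]
    return result


def posthoc_table(result: OmnibusResult) -> pd.DataFrame:
    """Flatten a battery result into a tidy pairwise table with stars."""
    rows = []
    for r in result.posthoc:
        rows.append(
            {
                "group_i": r.pair[0],
                "group_j": r.pair[1],
                "method": r.method,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "significant": r.significant if r.significant is not None else (r.p_value < 0.05),
                "stars": r.stars,
            }
        )
    return pd.DataFrame(rows)
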