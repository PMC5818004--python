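"""Group-comparison statistics for islet morphometry cohorts.

Covers the tests the quantitation pipeline feeds: unpaired two-sample
t-tests computable directly from printed summary statistics (mean ± s.d.
and n, both pooled-variance and Welch variants), Mann-Whitney U (exact
for small samples, normal approximation with tie correction otherwise),
Kruskal-Wallis with Dunn's multiple-comparison post-hoc, and one-way
ANOVA with Dunnett's many-to-one post-test.  One-tailed directions are
always explicit arguments — there is no silent default sidedness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "t_test_from_summary",
    "mann_whitney",
    "kruskal_dunn",
    "anova_dunnett",
]


@dataclass
class GroupSummary:
    """Printed summary of one group: n, mean and standard deviation."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: need n >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    test: str
    statistic: float
    p_value: float
    degrees_of_freedom: float | None = None
    sidedness: str = "two-sided"
    comparison: tuple[str, ...] = ()
    flag: str | None = None
    adjusted: bool = False

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value out of range: {self.p_value}")


def t_test_from_summary(
    a: GroupSummary,
    b: GroupSummary,
    variant: str = "welch",
    alternative: str = "two-sided",
) -> TestResult:
    """Unpaired two-sample t-test from summary statistics alone.

    ``variant="pooled"`` uses the classic equal-variance statistic with
    df = n_a + n_b − 2; ``variant="welch"`` uses the unequal-variance
    statistic with Welch-Satterthwaite df.  Identical to the raw-data
    test whenever raw data match the summaries exactly.
    """
    va, vb = a.sd**2, b.sd**2
    if variant == "pooled":
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    elif variant == "welch":
        se2a, se2b = va / a.n, vb / b.n
        se = np.sqrt(se2a + se2b)
        df = (se2a + se2b) ** 2 / (
            se2a**2 / (a.n - 1) + se2b**2 / (b.n - 1)
        )
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if se == 0:
        t = 0.0 if a.mean == b.mean else np.inf * np.sign(a.mean - b.mean)
    else:
        t = (a.mean - b.mean) / se
    if alternative == "two-sided":
        p = 2.0 * sps.t.sf(abs(t), df)
    elif alternative == "greater":
        p = sps.t.sf(t, df)
    elif alternative == "less":
        p = sps.t.cdf(t, df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(
        test=f"t ({variant})",
        statistic=float(t),
        p_value=float(min(p, 1.0)),
        degrees_of_freedom=float(df),
        sidedness=alternative,
        comparison=(a.label, b.label),
    )


def mann_whitney(
    a: np.ndarray,
    b: np.ndarray,
    alternative: str = "two-sided",
    labels: tuple[str, str] = ("A", "B"),
) -> TestResult:
    """Mann-Whitney U test; exact null distribution for small untied samples.

    One-tailed use requires stating ``alternative="greater"`` (first
    sample tends larger) or ``"less"`` explicitly.  If every value is
    tied across both groups the test carries no information; p = 1 is
    returned with a flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(np.unique(np.concatenate([a, b]))) == 1:
        return TestResult(
            test="mann-whitney",
            statistic=float(len(a) * len(b) / 2.0),
            p_value=1.0,
            sidedness=alternative,
            comparison=labels,
            flag="all values tied; test uninformative",
        )
    res = sps.mannwhitneyu(a, b, alternative=alternative, method="auto")
    flag = None
    if alternative != "two-sided" and res.pvalue >= 0.5:
        flag = "one-tailed p >= 0.5: effect opposite to the declared direction"
    return TestResult(
        test="mann-whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        sidedness=alternative,
        comparison=labels,
        flag=flag,
    )


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> list[TestResult]:
    """Dunn's rank-based many-pair comparisons with tie correction and
    Bonferroni adjustment over the tested pairs."""
    labels = sorted(groups)
    data = [np.asarray(groups[g], dtype=float) for g in labels]
    all_vals = np.concatenate(data)
    N = len(all_vals)
    ranks = sps.rankdata(all_vals)
    mean_ranks = {}
    i = 0
    for g, d in zip(labels, data):
        mean_ranks[g] = ranks[i : i + len(d)].mean()
        i += len(d)
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    pairs = list(combinations(labels, 2))
    out = []
    for g1, g2 in pairs:
        n1, n2 = len(groups[g1]), len(groups[g2])
        se = np.sqrt(var_base * (1.0 / n1 + 1.0 / n2))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)) * len(pairs))
        out.append(
            TestResult(
                test="dunn",
                statistic=float(z),
                p_value=float(p),
                sidedness="two-sided",
                comparison=(g1, g2),
                adjusted=True,
            )
        )
    return out


def kruskal_dunn(groups: dict[str, np.ndarray]) -> tuple[TestResult, list[TestResult]]:
    """Kruskal-Wallis H test across >= 3 groups plus Dunn's post-hoc.

    Returns ``(omnibus, pairwise)``.  All-tied data across groups is
    flagged with p = 1 rather than raised.
    """
    if len(groups) < 3:
        raise ValueError("Kruskal-Wallis with Dunn's post-hoc requires >= 3 groups")
    data = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(np.unique(np.concatenate(data))) == 1:
        omnibus = TestResult(
            test="kruskal-wallis", statistic=0.0, p_value=1.0,
            comparison=tuple(sorted(groups)), flag="all values tied",
        )
        return omnibus, []
    H, p = sps.kruskal(*data)
    omnibus = TestResult(
        test="kruskal-wallis",
        statistic=float(H),
        p_value=float(p),
        degrees_of_freedom=float(len(groups) - 1),
        comparison=tuple(sorted(groups)),
    )
    return omnibus, _dunn_posthoc(groups)


def anova_dunnett(
    groups: dict[str, np.ndarray],
    control: str,
    seed: int | None = None,
) -> tuple[TestResult, list[TestResult]]:
    """One-way ANOVA plus Dunnett's many-to-one comparisons vs a control.

    Dunnett p-values come from the multivariate-t reference distribution
    (quantiles are evaluated by seeded numerical integration, so results
    are reproducible for a fixed seed).  Groups of all-identical values
    across the board make F undefined (zero within-group variance); that
    degenerate case is flagged, not raised.
    """
    if control not in groups:
        raise KeyError(f"control group {control!r} not in groups")
    treatments = [g for g in sorted(groups) if g != control]
    if not treatments:
        raise ValueError("need at least one treatment group")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has n < 2")
    data = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    within_var = sum(np.var(v, ddof=1) for v in data.values())
    if within_var == 0:
        omnibus = TestResult(
            test="anova", statistic=np.nan, p_value=np.nan,
            comparison=tuple(sorted(groups)),
            flag="zero within-group variance; F undefined",
        )
        return omnibus, []
    F, p = sps.f_oneway(*data.values())
    k = len(groups)
    N = sum(len(v) for v in data.values())
    omnibus = TestResult(
        test="anova",
        statistic=float(F),
        p_value=float(p),
        degrees_of_freedom=float(N - k),
        comparison=tuple(sorted(groups)),
    )
    rng = np.random.default_rng(seed)
    res = sps.dunnett(
        *[data[g] for g in treatments], control=data[control], random_state=rng
    )
    pairwise = [
        TestResult(
            test="dunnett",
            statistic=float(res.statistic[i]),
            p_value=float(res.pvalue[i]),
            sidedness="two-sided",
            comparison=(t, control),
            adjusted=True,
        )
        for i, t in enumerate(treatments)
    ]
    return omnibus, pairwise
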