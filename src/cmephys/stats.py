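"""Group-comparison decision tree and significance reporting.

Each group's values are first checked for normality with a one-sample
Kolmogorov-Smirnov test against a normal distribution with estimated mean
and SD (a Lilliefors-corrected variant is available; the plain
estimated-parameter KS test is anti-conservative as a normality test, which
is documented rather than silently corrected).  If every group is normal the
parametric branch is taken (one-way ANOVA with Tukey's post hoc for >= 3
groups, Student's t for 2); otherwise the non-parametric branch
(Kruskal-Wallis for >= 3 groups, Mann-Whitney for 2).  No multiple-testing
correction is applied across features by default; Holm adjustment is
available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import CohortTable

__all__ = ["GroupComparison", "compare_groups", "significance_stars", "compare_features"]


@dataclass
class GroupComparison:
    feature: str
    groups: tuple[str, ...]
    group_n: dict[str, int]
    normal_by_group: dict[str, bool]
    all_normal: bool
    branch: str                    # anova_tukey | kruskal_wallis | t_test | mann_whitney
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None = None
    alpha: float = 0.05
    stars: str = field(init=False)

    def __post_init__(self) -> None:
        self.stars = significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    """Figure-legend star notation."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _is_normal(x: np.ndarray, alpha: float, lilliefors: bool) -> bool:
    if np.std(x) == 0:
        return False  # constant group: force the non-parametric branch
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        _, p = _lf(x, dist="norm")
    else:
        _, p = sps.kstest(x, "norm", args=(np.mean(x), np.std(x, ddof=1)))
    return p >= alpha


def compare_groups(table: CohortTable,
                   feature: str,
                   alpha: float = 0.05,
                   lilliefors: bool = False,
                   post_hoc: bool = True) -> GroupComparison:
    """Run the normality-gated parametric/non-parametric comparison.

    ``post_hoc=False`` skips the (comparatively expensive) Tukey pairwise
    table; the omnibus decision is unaffected.
    """
    values = table.group_values(feature)
    groups = tuple(g for g in table.groups if values[g].size > 0)
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")
    for g in groups:
        if values[g].size < 3:
            raise ValueError(f"group {g!r} has fewer than 3 values")

    normal = {}
    for g in groups:
        if np.std(values[g]) == 0:
            warnings.warn(f"group {g!r} is constant; non-parametric branch forced",
                          stacklevel=2)
        normal[g] = _is_normal(values[g], alpha, lilliefors)
    all_normal = all(normal.values())
    arrays = [values[g] for g in groups]

    pairwise = None
    if len(groups) >= 3:
        if all_normal:
            branch = "anova_tukey"
            stat, p = sps.f_oneway(*arrays)
            if post_hoc:
                tk = sps.tukey_hsd(*arrays)
                rows = []
                for i in range(len(groups)):
                    for j in range(i + 1, len(groups)):
                        rows.append({"group_a": groups[i], "group_b": groups[j],
                                     "p_value": float(tk.pvalue[i, j]),
                                     "stars": significance_stars(float(tk.pvalue[i, j]))})
                pairwise = pd.DataFrame(rows)
        else:
            branch = "kruskal_wallis"
            stat, p = sps.kruskal(*arrays)
    else:
        if all_normal:
            branch = "t_test"
            stat, p = sps.ttest_ind(*arrays)
        else:
            branch = "mann_whitney"
            stat, p = sps.mannwhitneyu(*arrays, alternative="two-sided")

    return GroupComparison(feature, groups, {g: int(values[g].size) for g in groups},
                           normal, all_normal, branch, float(stat), float(p),
                           pairwise, alpha)


def compare_features(table: CohortTable,
                     features: list[str] | None = None,
                     alpha: float = 0.05,
                     holm: bool = False,
                     lilliefors: bool = False) -> pd.DataFrame:
    """Comparison table over several features (optional Holm adjustment)."""
    features = features if features is not None else \
        [f for f in table.feature_names if f != "is_arrhythmogenic"]
    comps = [compare_groups(table, f, alpha, lilliefors) for f in features]
    df = pd.DataFrame({
        "feature": [c.feature for c in comps],
        "branch": [c.branch for c in comps],
        "statistic": [c.statistic for c in comps],
        "p_value": [c.p_value for c in comps],
        "stars": [c.stars for c in comps],
    })
    if holm:
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests(df["p_value"], alpha=alpha, method="holm")
        df["p_holm"] = p_adj
        df["stars"] = [significance_stars(p) for p in p_adj]
    return df
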