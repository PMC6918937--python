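"""One-way ANOVA across time points and significance-based rhythm selection.

The unit of analysis is the subject: each of the five time-point groups
holds one value per subject (a fatigue ratio, a mean MI, or a graph
metric).  Repeated measures on the same subjects are deliberately analysed
with independent-groups one-way ANOVA and no multiple-testing correction,
matching the original analysis workflow this package re-implements; both
choices are documented caveats, not recommendations.

Rhythm selection: ANOVA on the mean MI per (rhythm, condition) across the
five time points; only pairs with p < 0.05 are carried into network
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["AnovaResult", "RhythmSelection", "one_way_anova", "pairwise_anova", "select_rhythm"]


@dataclass(frozen=True)
class AnovaResult:
    """F statistic, degrees of freedom, upper-tail p, and group summaries.

    ``flag`` is ``None`` for a regular fit, ``"degenerate"`` when all
    groups are the same constant (F undefined), and
    ``"zero_within_variance"`` when groups are internally constant but
    differ (F infinite, p reported as 0).
    """

    F: float
    df_between: int
    df_within: int
    p: float
    group_means: tuple[float, ...]
    group_sds: tuple[float, ...]
    flag: Optional[str] = None

    @property
    def significant(self) -> bool:
        return self.flag != "degenerate" and self.p < 0.05


def one_way_anova(groups: Sequence[np.ndarray]) -> AnovaResult:
    """Fixed-effects one-way ANOVA from sums of squares.

    ``F = (SS_between / df_between) / (SS_within / df_within)`` with
    ``df_between = k - 1`` and ``df_within = N - k``; p is the upper tail
    of the F distribution.

    Raises
    ------
    ValueError
        With fewer than two groups, or any group of fewer than two values.
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    if any(not np.all(np.isfinite(a)) for a in arrays):
        raise ValueError("groups must be finite")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    means = [a.mean() for a in arrays]
    sds = [a.std(ddof=1) for a in arrays]
    ss_between = sum(a.size * (m - grand) ** 2 for a, m in zip(arrays, means))
    ss_within = sum(((a - m) ** 2).sum() for a, m in zip(arrays, means))
    df_between = k - 1
    df_within = n_total - k
    if ss_within <= 0:
        if ss_between <= 0:
            return AnovaResult(
                F=float("nan"), df_between=df_between, df_within=df_within,
                p=float("nan"), group_means=tuple(means), group_sds=tuple(sds),
                flag="degenerate",
            )
        return AnovaResult(
            F=float("inf"), df_between=df_between, df_within=df_within, p=0.0,
            group_means=tuple(means), group_sds=tuple(sds),
            flag="zero_within_variance",
        )
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f_stat, df_between, df_within))
    return AnovaResult(
        F=float(f_stat), df_between=df_between, df_within=df_within, p=p,
        group_means=tuple(means), group_sds=tuple(sds),
    )


def pairwise_anova(
    groups: Sequence[np.ndarray], labels: Sequence[str]
) -> pd.DataFrame:
    """Two-group ANOVAs between consecutive groups (T0-T1, T1-T2, ...).

    Mirrors the pairwise time-point comparison tables of fatigue studies.
    """
    if len(groups) != len(labels):
        raise ValueError("one label per group required")
    rows = []
    for (ga, la), (gb, lb) in zip(
        zip(groups, labels), zip(groups[1:], labels[1:])
    ):
        res = one_way_anova([ga, gb])
        rows.append(
            {
                "comparison": f"{la}-{lb}",
                "F": res.F,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "p": res.p,
                "flag": res.flag,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RhythmSelection:
    """ANOVA per (rhythm, condition) on mean MI, and the p < 0.05 subset."""

    results: dict[tuple[str, str], AnovaResult]
    selected: tuple[tuple[str, str], ...]
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (rhythm, cond), res in self.results.items():
            rows.append(
                {
                    "rhythm": rhythm,
                    "condition": cond,
                    "F": res.F,
                    "df_between": res.df_between,
                    "df_within": res.df_within,
                    "p": res.p,
                    "selected": (rhythm, cond) in self.selected,
                }
            )
        return pd.DataFrame(rows)


def select_rhythm(
    mean_mi: pd.DataFrame,
    time_points: Sequence[str],
    alpha: float = 0.05,
) -> RhythmSelection:
    """ANOVA across time points per (rhythm, condition); select p < alpha.

    Parameters
    ----------
    mean_mi : DataFrame
        Long table with columns ``rhythm, condition, subject, time_point,
        mean_mi`` -- one row per cell of the design and rhythm.
    time_points : sequence of str
        Group order for the ANOVA.

    Every (rhythm, condition) pair present is reported whether or not it is
    selected.  Missing (subject, time point) cells raise.
    """
    required = {"rhythm", "condition", "subject", "time_point", "mean_mi"}
    if not required.issubset(mean_mi.columns):
        raise ValueError(f"mean_mi table must have columns {sorted(required)}")
    results: dict[tuple[str, str], AnovaResult] = {}
    for (rhythm, cond), block in mean_mi.groupby(["rhythm", "condition"], sort=True):
        groups = []
        n_subjects = block["subject"].nunique()
        for tp in time_points:
            vals = block.loc[block["time_point"] == tp, "mean_mi"].to_numpy()
            if vals.size != n_subjects:
                raise ValueError(
                    f"incomplete table: {rhythm}/{cond} at {tp} has "
                    f"{vals.size} of {n_subjects} subjects"
                )
            groups.append(vals)
        results[(str(rhythm), str(cond))] = one_way_anova(groups)
    selected = tuple(
        key
        for key, res in results.items()
        if res.flag != "degenerate" and res.p < alpha
    )
    return RhythmSelection(results=results, selected=selected, alpha=alpha)
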