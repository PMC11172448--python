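"""Group-comparison statistics: one-way ANOVA with Tukey's HSD post hoc
test, and mean/SD/SEM summaries.

The F and studentized-range statistics are computed here with explicit
degrees-of-freedom bookkeeping (which also lets the degenerate
zero-within-variance case be handled deliberately); tail probabilities come
from scipy's F and studentized-range distributions. Unequal group sizes use
the Tukey-Kramer standard error. Significance is called at α = 0.05 by
default, with the usual star convention (* < 0.05, ** < 0.01, *** < 0.001).
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .datatypes import AnovaResult, GroupSummary, TukeyPair
from .errors import ValidationError


def _check_groups(groups: Mapping[str, Sequence[float]], min_n: int = 2) -> None:
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    for label, vals in groups.items():
        if len(vals) < min_n:
            raise ValidationError(
                f"group {label!r} has {len(vals)} observation(s); need >= {min_n}"
            )


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA: F = MS_between / MS_within with
    df_between = k−1, df_within = N−k.

    If every observation is identical, F = 0 and p = 1. If within-group
    variance is zero but group means differ, the analytic limit p = 0 is
    reported with ``degenerate=True``.
    """
    _check_groups(groups)
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    k = len(arrays)
    n_total = sum(len(a) for a in arrays.values())
    grand = sum(a.sum() for a in arrays.values()) / n_total
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        if ss_between == 0:
            return AnovaResult(0.0, df_b, df_w, 1.0)
        return AnovaResult(math.inf, df_b, df_w, 0.0, degenerate=True)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, p)


def tukey_hsd(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> list[TukeyPair]:
    """All-pairs Tukey HSD after a one-way layout.

    q = |mean_i − mean_j| / sqrt(MS_within/2 · (1/n_i + 1/n_j)); the
    adjusted p is the studentized-range tail P(Q_{k, df_w} ≥ q). With
    identical data in all groups every p_adj is 1.
    """
    _check_groups(groups)
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    k = len(arrays)
    n_total = sum(len(a) for a in arrays.values())
    df_w = n_total - k
    ms_within = (
        sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df_w
    )
    pairs: list[TukeyPair] = []
    for (la, a), (lb, b) in itertools.combinations(arrays.items(), 2):
        diff = float(a.mean() - b.mean())
        se = math.sqrt(ms_within / 2 * (1 / len(a) + 1 / len(b)))
        if se == 0:
            q = 0.0 if diff == 0 else math.inf
            p = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_w))
            p = min(max(p, 0.0), 1.0)
        pairs.append(
            TukeyPair(
                group_a=la,
                group_b=lb,
                mean_diff=diff,
                q_stat=q,
                p_adj=p,
                significant=p < alpha,
            )
        )
    return pairs


def group_summaries(groups: Mapping[str, Sequence[float]]) -> list[GroupSummary]:
    """n, mean, sample SD and SEM per group. For a singleton group the SD
    and SEM are NaN (undefined), never reported as 0."""
    out: list[GroupSummary] = []
    for label, vals in groups.items():
        a = np.asarray(vals, float)
        if a.size == 0:
            raise ValidationError(f"group {label!r} is empty")
        if a.size == 1:
            sd = sem = math.nan
        else:
            sd = float(a.std(ddof=1))
            sem = sd / math.sqrt(a.size)
        out.append(
            GroupSummary(
                group_label=str(label),
                n=int(a.size),
                mean=float(a.mean()),
                sd=sd,
                sem=sem,
            )
        )
    return out


def significance_stars(p: float) -> str:
    """Figure-legend star convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if not 0 <= p <= 1:
        raise ValidationError(f"p value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
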