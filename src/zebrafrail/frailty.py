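"""Deficit-accumulation frailty index with SD-binned scoring.

Each fish is scored against the youngest (reference) cohort. For every
variable v with reference mean μ_v and SD σ_v, the standardized deviation
is z = (x − μ_v)/σ_v; its magnitude (or, in directional mode, only the
frailty-direction part) is binned into a deficit score:

    d ≤ 1        → 0
    1 < d ≤ 2    → 0.25
    2 < d < 3    → 0.5
    d = 3        → 0.75
    d > 3        → 1         (``bins="literal"``, the default)

``bins="practical"`` merges the measure-zero d = 3 band into 0.5:
(2, 3] → 0.5 and (3, ∞) → 1. The frailty index is the plain mean of the
per-variable scores, so it is always a rational multiple of 0.25 divided
by the variable count and lies in [0, 1].

Scoring modes:

* ``absolute`` (default) — any deviation counts, in either direction.
* ``directional`` — only deviations toward frailty count: lower total
  distance / speeds, higher BMI. A fish *better* than the reference on a
  variable scores 0 there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    FRAILTY_VARIABLES,
    CohortTable,
    FrailtyResult,
    GroupSummary,
    ReferenceStats,
    format_age_group,
)
from .errors import ConfigError, ValidationError
from .groupstats import group_summaries

#: which direction is "frail" for each default variable (directional mode)
DEFAULT_DIRECTIONS: dict[str, str] = {
    "total_distance_cm": "lower_is_frail",
    "max_speed_cms": "lower_is_frail",
    "mean_speed_cms": "lower_is_frail",
    "bmi_gcm2": "higher_is_frail",
}

_SCORES = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class FrailtyConfig:
    """Scoring configuration; defaults follow the study protocol."""

    variables: tuple[str, ...] = FRAILTY_VARIABLES
    reference_group: str = "2"
    mode: str = "absolute"  # or "directional"
    bins: str = "literal"  # or "practical"
    directions: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_DIRECTIONS)
    )
    allow_missing: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "directional"):
            raise ConfigError(f"unknown scoring mode {self.mode!r}")
        if self.bins not in ("literal", "practical"):
            raise ConfigError(f"unknown bin configuration {self.bins!r}")
        if not self.variables:
            raise ConfigError("at least one variable must be scored")
        if self.mode == "directional":
            missing = [v for v in self.variables if v not in self.directions]
            if missing:
                raise ConfigError(
                    f"directional mode needs a direction for {missing}"
                )


def compute_reference(
    cohort: CohortTable | pd.DataFrame,
    variables: Sequence[str] = FRAILTY_VARIABLES,
    reference_group: str = "2",
) -> ReferenceStats:
    """Per-variable sample mean and SD (n−1 denominator) of the reference
    group — the yardstick every fish is scored against.

    A zero-SD or missing variable is an error naming the variable; a
    degenerate reference cannot define deficit bins.
    """
    df = (
        cohort.variables_frame() if isinstance(cohort, CohortTable) else cohort
    )
    ref = df[df["group"] == reference_group]
    if len(ref) < 2:
        raise ValidationError(
            f"reference group {reference_group!r} needs n >= 2, got {len(ref)}"
        )
    stats: dict[str, tuple[float, float]] = {}
    for v in variables:
        if v not in ref.columns or ref[v].isna().any():
            raise ValidationError(
                f"variable {v!r} missing for some reference fish"
            )
        mean = float(ref[v].mean())
        sd = float(ref[v].std(ddof=1))
        if sd == 0:
            raise ValidationError(
                f"variable {v!r}: reference SD is 0; deficit bins undefined"
            )
        stats[v] = (mean, sd)
    return ReferenceStats(variables=stats)


def deficit_score(
    value: float,
    mean: float,
    sd: float,
    mode: str = "absolute",
    direction: str = "lower_is_frail",
    bins: str = "literal",
) -> float:
    """Score one measurement against the reference law.

    Returns one of {0, 0.25, 0.5, 0.75, 1}; see the module docstring for
    the bin layout.
    """
    if sd <= 0:
        raise ValidationError(f"reference SD must be > 0, got {sd}")
    z = (value - mean) / sd
    if mode == "absolute":
        d = abs(z)
    elif mode == "directional":
        if direction == "lower_is_frail":
            d = max(0.0, -z)
        elif direction == "higher_is_frail":
            d = max(0.0, z)
        else:
            raise ConfigError(f"unknown direction {direction!r}")
    else:
        raise ConfigError(f"unknown scoring mode {mode!r}")
    return _bin(d, bins)


def _bin(d: float, bins: str) -> float:
    if d <= 1:
        return 0.0
    if d <= 2:
        return 0.25
    if bins == "literal":
        if d < 3:
            return 0.5
        if d == 3:
            return 0.75
        return 1.0
    if bins == "practical":
        return 0.5 if d <= 3 else 1.0
    raise ConfigError(f"unknown bin configuration {bins!r}")


def frailty_index(
    fish_values: Mapping[str, float],
    ref: ReferenceStats,
    config: FrailtyConfig | None = None,
    fish_id: str = "",
) -> FrailtyResult:
    """Score one fish: per-variable deficits averaged into the index.

    FI = (Σ scores) / (number of scored variables), exactly. A missing
    variable is an error unless ``config.allow_missing``, which
    renormalizes by the available count and flags the result.
    """
    config = config or FrailtyConfig()
    scores: dict[str, float] = {}
    zmap: dict[str, float] = {}
    missing: list[str] = []
    for v in config.variables:
        if v not in fish_values or v not in ref:
            missing.append(v)
            continue
        mean, sd = ref[v]
        zmap[v] = (fish_values[v] - mean) / sd
        scores[v] = deficit_score(
            fish_values[v],
            mean,
            sd,
            mode=config.mode,
            direction=config.directions.get(v, "lower_is_frail"),
            bins=config.bins,
        )
    if missing and not config.allow_missing:
        raise ValidationError(
            f"fish {fish_id!r}: missing variable(s) {missing}; "
            "no silent renormalization"
        )
    if not scores:
        raise ValidationError(f"fish {fish_id!r}: no scorable variables")
    return FrailtyResult(
        fish_id=fish_id,
        scores=scores,
        z=zmap,
        fi=sum(scores.values()) / len(scores),
        renormalized=bool(missing),
    )


def cohort_frailty(
    cohort: CohortTable | pd.DataFrame,
    config: FrailtyConfig | None = None,
) -> tuple[list[FrailtyResult], list[GroupSummary]]:
    """Score every fish against the reference group and summarize the FI
    per age group (n, mean, SD, SEM).

    Reference fish are scored too, against their own group's statistics;
    their scores are generically nonzero unless a fish sits within 1 SD of
    the reference mean on every variable.
    """
    config = config or FrailtyConfig()
    df = (
        cohort.variables_frame() if isinstance(cohort, CohortTable) else cohort
    )
    if config.reference_group not in set(df["group"]):
        raise ValidationError(
            f"reference group {config.reference_group!r} absent from cohort"
        )
    ref = compute_reference(df, config.variables, config.reference_group)
    results: list[FrailtyResult] = []
    for fish_id, row in df.iterrows():
        values = {v: row[v] for v in config.variables if v in row.index}
        results.append(
            frailty_index(values, ref, config, fish_id=str(fish_id))
        )
    groups: dict[str, list[float]] = {}
    for res, (_, row) in zip(results, df.iterrows()):
        groups.setdefault(row["group"], []).append(res.fi)
    summaries = group_summaries(groups)
    return results, summaries


def results_frame(
    results: Sequence[FrailtyResult], df: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Tidy per-fish table: group, per-variable z and score, FI."""
    rows = []
    for r in results:
        row: dict[str, object] = {"fish_id": r.fish_id}
        if df is not None and r.fish_id in df.index:
            row["group"] = df.loc[r.fish_id, "group"]
        for v, z in r.z.items():
            row[f"z_{v}"] = z
        for v, s in r.scores.items():
            row[f"score_{v}"] = s
        row["fi"] = r.fi
        rows.append(row)
    return pd.DataFrame(rows)
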