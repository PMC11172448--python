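"""Core domain types for the zebrafish sarcopenia pipeline.

The study design has four age groups (2, 10, 30 and 60 months). Each animal
carries biometry (weight in g, total length in cm), an open-field trajectory
summarized into locomotor variables, and — for subsets — histology, TEM and
confocal field annotations. All units are fixed by schema: cm, g, s, µm,
µm²; nothing infers units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError

#: variables scored by the frailty index, in canonical order
FRAILTY_VARIABLES = (
    "total_distance_cm",
    "max_speed_cms",
    "mean_speed_cms",
    "bmi_gcm2",
)

#: mitochondrion spatial pools: intermyofibrillar and subsarcolemmal
MITO_CLASSES = ("IFM", "SSM")

#: side length of the square TEM morphometry field (µm)
TEM_FIELD_UM = 5.15


@dataclass(frozen=True)
class FishRecord:
    """Biometry for one animal."""

    fish_id: str
    age_months: float
    weight_g: float
    length_cm: float

    def __post_init__(self) -> None:
        if not self.fish_id:
            raise ValidationError("fish_id must be a non-empty string")
        for name in ("age_months", "weight_g", "length_cm"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"fish {self.fish_id!r}: {name} must be finite and > 0, got {v!r}"
                )

    @property
    def bmi_gcm2(self) -> float:
        """Body mass index, weight (g) / length² (cm²)."""
        return self.weight_g / self.length_cm**2


@dataclass(frozen=True)
class LocomotorSummary:
    """Open-field summary of one trajectory: total distance (cm), mean and
    maximum speed (cm/s) over the recorded window."""

    fish_id: str
    total_distance_cm: float
    mean_speed_cms: float
    max_speed_cms: float
    duration_s: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValidationError(
                f"fish {self.fish_id!r}: a locomotor summary needs >= 2 samples"
            )
        if self.duration_s <= 0:
            raise ValidationError(f"fish {self.fish_id!r}: duration must be > 0")
        for name in ("total_distance_cm", "mean_speed_cms", "max_speed_cms"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"fish {self.fish_id!r}: {name} must be finite and >= 0"
                )
        if not math.isclose(
            self.total_distance_cm,
            self.mean_speed_cms * self.duration_s,
            rel_tol=1e-9,
            abs_tol=1e-9,
        ):
            raise ValidationError(
                f"fish {self.fish_id!r}: total distance inconsistent with "
                "mean speed x duration"
            )


class Trajectory:
    """Time-ordered planar positions of one fish.

    Times are seconds, coordinates calibrated cm. Times must be strictly
    increasing and everything finite; construction validates, it never
    re-sorts.
    """

    __slots__ = ("fish_id", "t_s", "x_cm", "y_cm")

    def __init__(
        self,
        fish_id: str,
        t_s: Sequence[float] | np.ndarray,
        x_cm: Sequence[float] | np.ndarray,
        y_cm: Sequence[float] | np.ndarray,
    ) -> None:
        t = np.asarray(t_s, dtype=float)
        x = np.asarray(x_cm, dtype=float)
        y = np.asarray(y_cm, dtype=float)
        if not (t.ndim == x.ndim == y.ndim == 1) or not (len(t) == len(x) == len(y)):
            raise ValidationError(
                f"fish {fish_id!r}: t/x/y must be 1-D and equally long"
            )
        if len(t) == 0:
            raise ValidationError(f"fish {fish_id!r}: empty trajectory")
        if not (np.isfinite(t).all() and np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValidationError(f"fish {fish_id!r}: non-finite sample values")
        dt = np.diff(t)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            raise ValidationError(
                f"fish {fish_id!r}: time not strictly increasing at index {bad[0] + 1}"
            )
        self.fish_id = fish_id
        self.t_s = t
        self.x_cm = x
        self.y_cm = y

    def __len__(self) -> int:
        return len(self.t_s)

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])


@dataclass
class CohortTable:
    """An ordered cohort of fish, optionally joined with their locomotor
    summaries by fish_id."""

    records: list[FishRecord]
    summaries: dict[str, LocomotorSummary] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.fish_id for r in self.records]
        seen: set[str] = set()
        for fid in ids:
            if fid in seen:
                raise ValidationError(f"duplicate fish_id {fid!r} in cohort")
            seen.add(fid)
        for fid in self.summaries:
            if fid not in seen:
                raise ValidationError(
                    f"locomotor summary for unknown fish_id {fid!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def fish_ids(self) -> list[str]:
        return [r.fish_id for r in self.records]

    def group_labels(self) -> list[str]:
        """Age-group labels in first-appearance order (e.g. '2', '10')."""
        out: list[str] = []
        for r in self.records:
            lab = format_age_group(r.age_months)
            if lab not in out:
                out.append(lab)
        return out

    def variables_frame(self):
        """Per-fish frailty-variable table (pandas DataFrame indexed by
        fish_id, with an age-group column). Requires joined summaries."""
        import pandas as pd

        rows = []
        for r in self.records:
            s = self.summaries.get(r.fish_id)
            row = {
                "fish_id": r.fish_id,
                "group": format_age_group(r.age_months),
                "age_months": r.age_months,
                "bmi_gcm2": r.bmi_gcm2,
                "weight_g": r.weight_g,
                "length_cm": r.length_cm,
            }
            if s is not None:
                row.update(
                    total_distance_cm=s.total_distance_cm,
                    max_speed_cms=s.max_speed_cms,
                    mean_speed_cms=s.mean_speed_cms,
                )
            rows.append(row)
        return pd.DataFrame(rows).set_index("fish_id")


def format_age_group(age_months: float) -> str:
    """Canonical group label for an age: '2', '10', '30', '60', ..."""
    if float(age_months).is_integer():
        return str(int(age_months))
    return str(age_months)


# ---------------------------------------------------------------------------
# field annotations (histology / TEM / confocal)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CollagenMask:
    """Binary segmentation of one Van Gieson field: 1 = collagen pixel."""

    field_id: str
    mask: np.ndarray  # 2-D uint8 array of {0, 1}, row-major, 0-based

    def __post_init__(self) -> None:
        m = self.mask
        if m.ndim != 2:
            raise ValidationError(
                f"field {self.field_id!r}: mask must be single-channel 2-D, "
                f"got shape {m.shape}"
            )
        if m.size == 0:
            raise ValidationError(f"field {self.field_id!r}: zero-area mask")
        vals = np.unique(m)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError(
                f"field {self.field_id!r}: mask pixels must be 0/1, "
                f"found {vals[:5].tolist()}"
            )


@dataclass(frozen=True)
class MyocyteField:
    """One light-microscopy field: myocyte count, field area and widths."""

    field_id: str
    myocyte_count: int
    field_area_um2: float
    widths_um: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.myocyte_count < 0 or self.myocyte_count != int(self.myocyte_count):
            raise ValidationError(
                f"field {self.field_id!r}: myocyte_count must be a non-negative integer"
            )
        if not self.field_area_um2 > 0:
            raise ValidationError(f"field {self.field_id!r}: field area must be > 0")
        if any(w < 0 for w in self.widths_um):
            raise ValidationError(f"field {self.field_id!r}: widths must be >= 0")


@dataclass(frozen=True)
class MitoRecord:
    """One mitochondrion in a TEM field: spatial class, cross-sectional
    area (µm²) and whether it shows damage (swelling, vacuolation, depleted
    or disorganized cristae — annotated upstream, never detected here)."""

    mito_id: str
    mito_class: str
    csa_um2: float
    damaged: bool

    def __post_init__(self) -> None:
        if self.mito_class not in MITO_CLASSES:
            raise ValidationError(
                f"mitochondrion {self.mito_id!r}: class {self.mito_class!r} "
                f"not in allowed labels {MITO_CLASSES}"
            )
        if not (math.isfinite(self.csa_um2) and self.csa_um2 >= 0):
            raise ValidationError(
                f"mitochondrion {self.mito_id!r}: CSA must be finite and >= 0"
            )


@dataclass(frozen=True)
class MitoField:
    """One TEM morphometry field (default 5.15 µm x 5.15 µm)."""

    field_id: str
    mitochondria: tuple[MitoRecord, ...]
    width_um: float = TEM_FIELD_UM
    height_um: float = TEM_FIELD_UM

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValidationError(
                f"field {self.field_id!r}: field dimensions must be > 0"
            )


@dataclass(frozen=True)
class SarcomereField:
    """Sarcomere and band lengths (µm) measured on one TEM longitudinal
    section. Only h <= a is enforced (the H band lies inside the A band);
    no other band arithmetic is assumed."""

    field_id: str
    sarcomere_length_um: float
    a_band_um: float
    h_band_um: float
    i_band_um: float

    def __post_init__(self) -> None:
        for name in ("sarcomere_length_um", "a_band_um", "h_band_um", "i_band_um"):
            if getattr(self, name) < 0:
                raise ValidationError(
                    f"field {self.field_id!r}: {name} must be >= 0"
                )
        if self.h_band_um > self.a_band_um:
            raise ValidationError(
                f"field {self.field_id!r}: H band ({self.h_band_um} um) cannot "
                f"exceed A band ({self.a_band_um} um)"
            )


@dataclass(frozen=True)
class ConfocalField:
    """One confocal field: mean GFP intensity and DAPI nucleus count."""

    field_id: str
    gfp_mean_intensity: float
    dapi_count: int

    def __post_init__(self) -> None:
        if self.gfp_mean_intensity < 0:
            raise ValidationError(
                f"field {self.field_id!r}: GFP mean intensity must be >= 0"
            )
        if self.dapi_count < 0 or self.dapi_count != int(self.dapi_count):
            raise ValidationError(
                f"field {self.field_id!r}: dapi_count must be a non-negative integer"
            )


#: union of per-kind annotation types, keyed by the schema `kind`
ANNOTATION_KINDS = {
    "collagen_mask": CollagenMask,
    "myocyte": MyocyteField,
    "mito": MitoField,
    "sarcomere": SarcomereField,
    "confocal": ConfocalField,
}


# ---------------------------------------------------------------------------
# statistics containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSummary:
    """n, mean, sample SD and SEM of one variable in one group.

    SD is undefined (NaN) for a singleton group and flagged, never 0.
    """

    group_label: str
    n: int
    mean: float
    sd: float
    sem: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"group {self.group_label!r}: empty group")


@dataclass(frozen=True)
class ReferenceStats:
    """Per-variable mean and SD of the reference (youngest) cohort, the
    yardstick for deficit scoring."""

    variables: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.variables:
            raise ValidationError("reference statistics need >= 1 variable")
        for name, (mean, sd) in self.variables.items():
            if not (math.isfinite(mean) and math.isfinite(sd)):
                raise ValidationError(f"reference variable {name!r}: non-finite stats")
            if sd <= 0:
                raise ValidationError(
                    f"reference variable {name!r}: SD must be > 0, got {sd}"
                )

    def __contains__(self, name: str) -> bool:
        return name in self.variables

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.variables[name]

    def names(self) -> tuple[str, ...]:
        return tuple(self.variables)


@dataclass(frozen=True)
class FrailtyResult:
    """Per-variable deficit scores and their mean (the frailty index)."""

    fish_id: str
    scores: Mapping[str, float]
    z: Mapping[str, float]
    fi: float
    renormalized: bool = False

    def __post_init__(self) -> None:
        if not self.scores:
            raise ValidationError(f"fish {self.fish_id!r}: no scored variables")
        if not 0.0 <= self.fi <= 1.0:
            raise ValidationError(f"fish {self.fish_id!r}: FI outside [0, 1]")


@dataclass(frozen=True)
class AnovaResult:
    """Classical one-way ANOVA: F = MS_between / MS_within."""

    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    degenerate: bool = False  # zero within-group variance with unequal means


@dataclass(frozen=True)
class TukeyPair:
    """One unordered pair from Tukey's HSD (Tukey-Kramer for unequal n)."""

    group_a: str
    group_b: str
    mean_diff: float
    q_stat: float
    p_adj: float
    significant: bool
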