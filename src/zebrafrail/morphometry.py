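"""Biometric, histological, TEM and confocal measurement formulas.

All operations here are arithmetic on upstream annotations — segmented
collagen masks, per-field myocyte tallies, per-mitochondrion TEM records,
confocal field summaries. Nothing segments or detects; damage calls and
masks arrive as data.

Formulas:

* BMI = weight (g) / length² (cm²)
* collagen % = 100 · (collagen pixels) / (total field pixels)
* myocyte density = myocyte count / field area (myocytes/µm²)
* damaged mitochondria % = 100 · damaged count / total count
* GFP per nucleus = mean GFP intensity / DAPI nucleus count
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datatypes import (
    CollagenMask,
    ConfocalField,
    MitoField,
    MyocyteField,
    SarcomereField,
)
from .errors import ValidationError


def bmi(weight_g: float, length_cm: float) -> float:
    """Body mass index in g/cm²."""
    if not (weight_g > 0 and length_cm > 0):
        raise ValidationError(
            f"BMI needs positive weight and length, got {weight_g} g, {length_cm} cm"
        )
    return weight_g / length_cm**2


def collagen_percent(mask: CollagenMask | np.ndarray) -> float:
    """Collagen area fraction of a binary field mask, in percent."""
    m = mask.mask if isinstance(mask, CollagenMask) else np.asarray(mask)
    if m.size == 0:
        raise ValidationError("zero-area mask")
    if not np.isin(np.unique(m), (0, 1)).all():
        raise ValidationError("mask pixels must be 0/1")
    return 100.0 * float(np.count_nonzero(m)) / m.size


@dataclass(frozen=True)
class MyocyteFieldStats:
    field_id: str
    density_per_um2: float
    mean_width_um: float | None  # None when the field has no width measures
    sd_width_um: float | None


def myocyte_stats(fields: list[MyocyteField]) -> list[MyocyteFieldStats]:
    """Per-field myocyte density (myocytes/µm²) and width summary (µm)."""
    out = []
    for f in fields:
        if f.field_area_um2 <= 0:
            raise ValidationError(f"field {f.field_id!r}: zero field area")
        widths = np.asarray(f.widths_um, float)
        mean_w = float(widths.mean()) if widths.size else None
        sd_w = float(widths.std(ddof=1)) if widths.size > 1 else None
        out.append(
            MyocyteFieldStats(
                field_id=f.field_id,
                density_per_um2=f.myocyte_count / f.field_area_um2,
                mean_width_um=mean_w,
                sd_width_um=sd_w,
            )
        )
    return out


@dataclass(frozen=True)
class MitoFieldStats:
    """Per-field TEM tallies. ``damaged_percent`` is None (flagged
    undefined) for a field with no mitochondria: 0/0 must not read as
    "no damage"."""

    field_id: str
    n_ifm: int
    n_ssm: int
    mean_csa_ifm_um2: float | None
    mean_csa_ssm_um2: float | None
    damaged_percent: float | None
    field_area_um2: float


def mito_field_stats(field: MitoField) -> MitoFieldStats:
    """IFM/SSM counts, mean CSA per class, and damaged-mitochondria
    percentage (100 · damaged / total) for one TEM field."""
    ifm = [m for m in field.mitochondria if m.mito_class == "IFM"]
    ssm = [m for m in field.mitochondria if m.mito_class == "SSM"]
    total = len(field.mitochondria)
    damaged = sum(m.damaged for m in field.mitochondria)
    return MitoFieldStats(
        field_id=field.field_id,
        n_ifm=len(ifm),
        n_ssm=len(ssm),
        mean_csa_ifm_um2=(
            float(np.mean([m.csa_um2 for m in ifm])) if ifm else None
        ),
        mean_csa_ssm_um2=(
            float(np.mean([m.csa_um2 for m in ssm])) if ssm else None
        ),
        damaged_percent=(100.0 * damaged / total) if total else None,
        field_area_um2=field.width_um * field.height_um,
    )


@dataclass(frozen=True)
class SarcomereStats:
    """Plain mean ± SD of sarcomere and band lengths over a set of fields.

    No band arithmetic (e.g. sarcomere = A + I) is derived or enforced.
    """

    n: int
    sarcomere_length_um: tuple[float, float]
    a_band_um: tuple[float, float]
    h_band_um: tuple[float, float]
    i_band_um: tuple[float, float]


def sarcomere_stats(fields: list[SarcomereField]) -> SarcomereStats:
    if not fields:
        raise ValidationError("no sarcomere fields to aggregate")

    def agg(name: str) -> tuple[float, float]:
        vals = np.array([getattr(f, name) for f in fields], float)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        return float(vals.mean()), sd

    return SarcomereStats(
        n=len(fields),
        sarcomere_length_um=agg("sarcomere_length_um"),
        a_band_um=agg("a_band_um"),
        h_band_um=agg("h_band_um"),
        i_band_um=agg("i_band_um"),
    )


def gfp_per_nucleus(field: ConfocalField) -> float:
    """Mitochondrial-reporter signal normalized per cell: mean GFP
    intensity divided by the DAPI nucleus count."""
    if field.dapi_count < 1:
        raise ValidationError(
            f"field {field.field_id!r}: ratio undefined with 0 nuclei"
        )
    return field.gfp_mean_intensity / field.dapi_count
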