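"""CSV and image readers/writers for the pipeline's on-disk contract.

One dialect everywhere: comma-separated, UTF-8, header row required, '.'
decimal separator. Units are fixed by schema (g, cm, s, µm, µm²). Masks are
single-channel PNG/TIFF, binarized by pixel > 0; multi-channel images are
rejected rather than converted.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .datatypes import (
    ANNOTATION_KINDS,
    CohortTable,
    CollagenMask,
    ConfocalField,
    FishRecord,
    LocomotorSummary,
    MitoField,
    MitoRecord,
    MyocyteField,
    SarcomereField,
    Trajectory,
)
from .errors import SchemaError, ValidationError

COHORT_COLUMNS = ("fish_id", "age_months", "weight_g", "length_cm")
TRAJECTORY_COLUMNS = ("t_s", "x_cm", "y_cm")
LOCOMOTION_COLUMNS = (
    "fish_id",
    "total_distance_cm",
    "mean_speed_cms",
    "max_speed_cms",
    "duration_s",
    "n_samples",
)


def _read_csv(path: str | os.PathLike, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def read_cohort(path: str | os.PathLike) -> CohortTable:
    """Read a cohort biometry table (fish_id, age_months, weight_g,
    length_cm), preserving row order. Invariant violations raise
    :class:`ValidationError` naming the offending fish."""
    df = _read_csv(path, COHORT_COLUMNS)
    records = [
        FishRecord(
            fish_id=str(row.fish_id),
            age_months=float(row.age_months),
            weight_g=float(row.weight_g),
            length_cm=float(row.length_cm),
        )
        for row in df.itertuples(index=False)
    ]
    return CohortTable(records=records)


def write_cohort(cohort: CohortTable, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [
            (r.fish_id, r.age_months, r.weight_g, r.length_cm)
            for r in cohort.records
        ],
        columns=list(COHORT_COLUMNS),
    )
    df.to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def read_trajectory(path: str | os.PathLike, fish_id: str | None = None) -> Trajectory:
    """Read one trajectory (t_s, x_cm, y_cm, optional fish_id column).

    Ordering is checked, never silently repaired; < 2 samples is an error.
    """
    df = _read_csv(path, TRAJECTORY_COLUMNS)
    if fish_id is None:
        if "fish_id" in df.columns and len(df):
            fish_id = str(df["fish_id"].iloc[0])
        else:
            fish_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    if len(df) < 2:
        raise ValidationError(
            f"{path}: a trajectory needs >= 2 samples, got {len(df)}"
        )
    return Trajectory(
        fish_id=fish_id,
        t_s=df["t_s"].to_numpy(float),
        x_cm=df["x_cm"].to_numpy(float),
        y_cm=df["y_cm"].to_numpy(float),
    )


def write_trajectory(traj: Trajectory, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "fish_id": traj.fish_id,
            "t_s": traj.t_s,
            "x_cm": traj.x_cm,
            "y_cm": traj.y_cm,
        }
    ).to_csv(path, index=False, encoding="utf-8")


def write_locomotion(
    summaries: Iterable[LocomotorSummary], path: str | os.PathLike
) -> None:
    pd.DataFrame(
        [
            (
                s.fish_id,
                s.total_distance_cm,
                s.mean_speed_cms,
                s.max_speed_cms,
                s.duration_s,
                s.n_samples,
            )
            for s in summaries
        ],
        columns=list(LOCOMOTION_COLUMNS),
    ).to_csv(path, index=False, encoding="utf-8")


def read_locomotion(path: str | os.PathLike) -> list[LocomotorSummary]:
    df = _read_csv(path, LOCOMOTION_COLUMNS)
    return [
        LocomotorSummary(
            fish_id=str(r.fish_id),
            total_distance_cm=float(r.total_distance_cm),
            mean_speed_cms=float(r.mean_speed_cms),
            max_speed_cms=float(r.max_speed_cms),
            duration_s=float(r.duration_s),
            n_samples=int(r.n_samples),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


def read_mask(path: str | os.PathLike, field_id: str | None = None) -> CollagenMask:
    """Read a single-channel PNG/TIFF mask, binarized by pixel > 0 -> 1.

    Multi-channel (RGB/RGBA) input is rejected: collagen quantification
    operates on an already-segmented region, not on raw stain colors.
    """
    img = iio.imread(path)
    if img.ndim != 2:
        raise ValidationError(
            f"{path}: expected a single-channel mask, got shape {img.shape}"
        )
    if field_id is None:
        field_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return CollagenMask(field_id=field_id, mask=(img > 0).astype(np.uint8))


def write_mask(mask: CollagenMask, path: str | os.PathLike) -> None:
    iio.imwrite(path, (mask.mask * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# field annotation tables
# ---------------------------------------------------------------------------


def _read_mito(path: str | os.PathLike) -> list[MitoField]:
    df = _read_csv(path, ("field_id", "mito_id", "class", "csa_um2", "damaged"))
    fields: list[MitoField] = []
    df = df.rename(columns={"class": "mito_class"})
    for fid, sub in df.groupby("field_id", sort=False):
        mitos = tuple(
            MitoRecord(
                mito_id=str(r.mito_id),
                mito_class=str(r.mito_class),
                csa_um2=float(r.csa_um2),
                damaged=_parse_bool(r.damaged),
            )
            for r in sub.itertuples(index=False)
        )
        fields.append(MitoField(field_id=str(fid), mitochondria=mitos))
    return fields


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValidationError(f"cannot parse boolean damaged flag from {v!r}")


def _read_sarcomere(path: str | os.PathLike) -> list[SarcomereField]:
    df = _read_csv(
        path,
        ("field_id", "sarcomere_length_um", "a_band_um", "h_band_um", "i_band_um"),
    )
    return [
        SarcomereField(
            field_id=str(r.field_id),
            sarcomere_length_um=float(r.sarcomere_length_um),
            a_band_um=float(r.a_band_um),
            h_band_um=float(r.h_band_um),
            i_band_um=float(r.i_band_um),
        )
        for r in df.itertuples(index=False)
    ]


def _read_confocal(path: str | os.PathLike) -> list[ConfocalField]:
    df = _read_csv(path, ("field_id", "gfp_mean_intensity", "dapi_count"))
    return [
        ConfocalField(
            field_id=str(r.field_id),
            gfp_mean_intensity=float(r.gfp_mean_intensity),
            dapi_count=int(r.dapi_count),
        )
        for r in df.itertuples(index=False)
    ]


def _read_myocyte(path: str | os.PathLike) -> list[MyocyteField]:
    df = _read_csv(path, ("field_id", "myocyte_count", "field_area_um2"))
    out = []
    for r in df.itertuples(index=False):
        widths: tuple[float, ...] = ()
        raw = getattr(r, "widths_um", None)
        if raw is not None and not (isinstance(raw, float) and np.isnan(raw)):
            s = str(raw).strip()
            if s:
                widths = tuple(float(w) for w in s.split(";"))
        out.append(
            MyocyteField(
                field_id=str(r.field_id),
                myocyte_count=int(r.myocyte_count),
                field_area_um2=float(r.field_area_um2),
                widths_um=widths,
            )
        )
    return out


_READERS = {
    "mito": _read_mito,
    "sarcomere": _read_sarcomere,
    "confocal": _read_confocal,
    "myocyte": _read_myocyte,
    "collagen_mask": lambda path: [read_mask(path)],
}


def read_field_annotations(path: str | os.PathLike, kind: str):
    """Read field annotations of the given kind (one of
    ``collagen_mask``, ``myocyte``, ``mito``, ``sarcomere``, ``confocal``)."""
    if kind not in ANNOTATION_KINDS:
        raise SchemaError(
            f"unknown annotation kind {kind!r}; expected one of "
            f"{sorted(ANNOTATION_KINDS)}"
        )
    return _READERS[kind](path)


def write_mito_fields(fields: Iterable[MitoField], path: str | os.PathLike) -> None:
    rows = [
        (f.field_id, m.mito_id, m.mito_class, m.csa_um2, m.damaged)
        for f in fields
        for m in f.mitochondria
    ]
    pd.DataFrame(
        rows, columns=["field_id", "mito_id", "class", "csa_um2", "damaged"]
    ).to_csv(path, index=False, encoding="utf-8")


def write_confocal_fields(
    fields: Iterable[ConfocalField], path: str | os.PathLike
) -> None:
    pd.DataFrame(
        [(f.field_id, f.gfp_mean_intensity, f.dapi_count) for f in fields],
        columns=["field_id", "gfp_mean_intensity", "dapi_count"],
    ).to_csv(path, index=False, encoding="utf-8")


def write_sarcomere_fields(
    fields: Iterable[SarcomereField], path: str | os.PathLike
) -> None:
    pd.DataFrame(
        [
            (
                f.field_id,
                f.sarcomere_length_um,
                f.a_band_um,
                f.h_band_um,
                f.i_band_um,
            )
            for f in fields
        ],
        columns=[
            "field_id",
            "sarcomere_length_um",
            "a_band_um",
            "h_band_um",
            "i_band_um",
        ],
    ).to_csv(path, index=False, encoding="utf-8")


def write_myocyte_fields(
    fields: Iterable[MyocyteField], path: str | os.PathLike
) -> None:
    pd.DataFrame(
        [
            (
                f.field_id,
                f.myocyte_count,
                f.field_area_um2,
                ";".join(format(w, "g") for w in f.widths_um),
            )
            for f in fields
        ],
        columns=["field_id", "myocyte_count", "field_area_um2", "widths_um"],
    ).to_csv(path, index=False, encoding="utf-8")
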