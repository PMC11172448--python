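"""Synthetic aging-cohort generator.

Emulates the study's four age groups (2, 10, 30, 60 months) so the whole
pipeline — locomotion, morphometry, frailty, statistics — can be exercised
without animal data. The packaged per-group laws for the four frailty
variables (total distance, maximum speed, mean speed, BMI) are the printed
group means and dispersions, the dispersions interpreted as SD (set
``dispersion="sem"`` with a group n to convert, SD = SEM·√n). Variables are
drawn independently per fish from normal laws truncated at zero (negative
draws are resampled, not clipped); an optional correlation matrix enables
sensitivity tests, since the true covariance of the study population is
unknown.

The 30-month maximum speed was never printed; it is deliberately left
unset, and generating that group with the default variable set is an error
rather than an interpolation.

Every generator is a pure function of its config and seed: the same
SimConfig yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .datatypes import (
    FRAILTY_VARIABLES,
    CohortTable,
    CollagenMask,
    ConfocalField,
    FishRecord,
    LocomotorSummary,
    MitoField,
    MitoRecord,
    SarcomereField,
    Trajectory,
)
from .errors import ConfigError, ValidationError

#: per-group (mean, sd) for the scored variables; None = not printed, no default
AGE_GROUP_PARAMS: dict[str, dict[str, tuple[float, float] | None]] = {
    "2": {
        "total_distance_cm": (4667.738, 1386.530),
        "max_speed_cms": (35.302, 11.625),
        "mean_speed_cms": (4.182, 1.017),
        "bmi_gcm2": (0.019, 0.004),
    },
    "10": {
        "total_distance_cm": (5143.711, 1186.039),
        "max_speed_cms": (31.961, 6.469),
        "mean_speed_cms": (4.607, 0.553),
        "bmi_gcm2": (0.025, 0.003),
    },
    "30": {
        "total_distance_cm": (3164.341, 1420.143),
        "max_speed_cms": None,  # not printed for this group
        "mean_speed_cms": (2.635, 1.183),
        "bmi_gcm2": (0.029, 0.006),
    },
    "60": {
        "total_distance_cm": (2958.518, 723.492),
        "max_speed_cms": (18.552, 7.651),
        "mean_speed_cms": (2.464, 0.603),
        "bmi_gcm2": (0.040, 0.016),
    },
}

#: group label -> age in months
GROUP_AGES = {"2": 2.0, "10": 10.0, "30": 30.0, "60": 60.0}

#: synthetic total-length laws (cm): lognormal, increasing with age.
#: Stand-ins — the study shows length increasing with age but prints no
#: numbers; weight is derived as BMI × length² so BMI follows its printed law.
LENGTH_LAWS_CM = {"2": (2.9, 0.23), "10": (3.4, 0.27), "30": (3.7, 0.30), "60": (4.2, 0.34)}


@dataclass(frozen=True)
class SimConfig:
    """Reproducible simulation settings."""

    n_per_group: int = 10
    seed: int = 0
    sampling_hz: float = 10.0
    duration_s: float = 1200.0
    mask_size: tuple[int, int] = (100, 100)
    truncation: bool = True  # resample negative draws

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be >= 1")
        if self.sampling_hz <= 0 or self.duration_s <= 0:
            raise ConfigError("sampling_hz and duration_s must be > 0")


def _spawn(seed: int, key: str) -> np.random.Generator:
    """Deterministic named child stream of the master seed."""
    digest = int.from_bytes(key.encode(), "big") % (2**31 - 1)
    return np.random.default_rng(np.random.SeedSequence((seed, digest)))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int, truncation: bool
) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    if truncation:
        bad = out <= 0
        while bad.any():
            out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
            bad = out <= 0
    return out


def generate_cohort(
    params: Mapping[str, Mapping[str, tuple[float, float] | None]] | None = None,
    cfg: SimConfig = SimConfig(),
    variables: Sequence[str] = FRAILTY_VARIABLES,
    groups: Sequence[str] | None = None,
    correlation: np.ndarray | None = None,
    dispersion: str = "sd",
    dispersion_n: int | None = None,
):
    """Draw a cohort and its per-fish variable table.

    Returns ``(CohortTable, DataFrame)``; the table carries biometry plus
    joined locomotor summaries, the frame one row per fish with the scored
    variables. A requested group/variable with no (mean, sd) raises,
    naming it.
    """
    params = params if params is not None else AGE_GROUP_PARAMS
    if groups is None:
        groups = list(params)
    if dispersion not in ("sd", "sem"):
        raise ConfigError("dispersion must be 'sd' or 'sem'")
    if dispersion == "sem" and not dispersion_n:
        raise ConfigError("dispersion='sem' needs dispersion_n to convert to SD")

    records: list[FishRecord] = []
    summaries: dict[str, LocomotorSummary] = {}
    rows: list[dict] = []
    counter = 0
    for g in groups:
        if g not in params:
            raise ConfigError(f"no parameters for group {g!r}")
        gp = params[g]
        laws: dict[str, tuple[float, float]] = {}
        for v in variables:
            law = gp.get(v)
            if law is None:
                raise ConfigError(
                    f"group {g!r}: variable {v!r} has no (mean, sd); "
                    "supply one explicitly (no interpolation is done)"
                )
            mean, disp = law
            sd = disp * math.sqrt(dispersion_n) if dispersion == "sem" else disp
            laws[v] = (mean, sd)
        rng = _spawn(cfg.seed, f"cohort:{g}")
        draws = _draw_group(rng, laws, variables, cfg, correlation)
        lengths = _truncated_normal(
            rng, *LENGTH_LAWS_CM[g] if g in LENGTH_LAWS_CM else (3.5, 0.3),
            cfg.n_per_group, True,
        )
        for i in range(cfg.n_per_group):
            counter += 1
            fid = f"fish_{g}m_{i + 1:03d}"
            bmi = float(draws["bmi_gcm2"][i]) if "bmi_gcm2" in draws else 0.02
            length = float(lengths[i])
            records.append(
                FishRecord(
                    fish_id=fid,
                    age_months=GROUP_AGES.get(g, float(g)),
                    weight_g=float(bmi * length**2),
                    length_cm=length,
                )
            )
            row = {
                "fish_id": fid,
                "group": g,
                "age_months": GROUP_AGES.get(g, float(g)),
                "weight_g": float(bmi * length**2),
                "length_cm": length,
                "bmi_gcm2": bmi,
            }
            for v in variables:
                row[v] = float(draws[v][i])
            rows.append(row)
            if {"total_distance_cm", "mean_speed_cms", "max_speed_cms"} <= set(draws):
                dist = float(draws["total_distance_cm"][i])
                mean_v = float(draws["mean_speed_cms"][i])
                # duration implied by the drawn pair keeps the summary
                # internally consistent (distance = mean speed x duration)
                summaries[fid] = LocomotorSummary(
                    fish_id=fid,
                    total_distance_cm=dist,
                    mean_speed_cms=mean_v,
                    max_speed_cms=float(
                        max(draws["max_speed_cms"][i], mean_v)
                    ),
                    duration_s=dist / mean_v,
                    n_samples=int(cfg.duration_s * cfg.sampling_hz) + 1,
                )
    import pandas as pd

    cohort = CohortTable(records=records, summaries=summaries)
    return cohort, pd.DataFrame(rows).set_index("fish_id")


def _draw_group(
    rng: np.random.Generator,
    laws: Mapping[str, tuple[float, float]],
    variables: Sequence[str],
    cfg: SimConfig,
    correlation: np.ndarray | None,
) -> dict[str, np.ndarray]:
    k = len(variables)
    if correlation is None:
        return {
            v: _truncated_normal(rng, *laws[v], cfg.n_per_group, cfg.truncation)
            for v in variables
        }
    corr = np.asarray(correlation, float)
    if corr.shape != (k, k):
        raise ConfigError(f"correlation matrix must be {k}x{k}")
    means = np.array([laws[v][0] for v in variables])
    sds = np.array([laws[v][1] for v in variables])
    cov = corr * np.outer(sds, sds)
    draws = rng.multivariate_normal(means, cov, size=cfg.n_per_group)
    if cfg.truncation:
        bad = (draws <= 0).any(axis=1)
        while bad.any():
            draws[bad] = rng.multivariate_normal(means, cov, size=int(bad.sum()))
            bad = (draws <= 0).any(axis=1)
    return {v: draws[:, j] for j, v in enumerate(variables)}


def generate_trajectory(
    target_mean_speed: float,
    target_max_speed: float,
    cfg: SimConfig = SimConfig(),
    fish_id: str = "sim",
) -> Trajectory:
    """Correlated-random-walk path realizing the requested speed summary.

    The per-step speed series is an AR(1) fluctuation around the target
    mean, rescaled so the time-weighted mean speed is *exact*, with a
    3-step plateau at the target maximum so a median-3 smoother preserves
    it. Headings perform a bounded-turn random walk.
    """
    if not 0 < target_mean_speed <= target_max_speed:
        raise ValidationError(
            f"need 0 < mean <= max, got mean {target_mean_speed}, "
            f"max {target_max_speed}"
        )
    rng = _spawn(cfg.seed, f"traj:{fish_id}")
    dt = 1.0 / cfg.sampling_hz
    n = int(round(cfg.duration_s * cfg.sampling_hz))
    if n < 10:
        raise ConfigError("trajectory too short; increase duration or rate")
    t = np.arange(n + 1) * dt

    if target_mean_speed == target_max_speed:
        speeds = np.full(n, target_mean_speed)
    else:
        # AR(1) fluctuation, bounded away from the max so only the plateau
        # attains it
        e = rng.normal(size=n)
        ar = np.empty(n)
        ar[0] = e[0]
        phi = 0.95
        for i in range(1, n):
            ar[i] = phi * ar[i - 1] + math.sqrt(1 - phi**2) * e[i]
        speeds = target_mean_speed * (1 + 0.25 * ar)
        cap = 0.9 * target_max_speed
        speeds = np.clip(speeds, 0.05 * target_mean_speed, cap)
        plateau = rng.integers(1, n - 4)
        mask = np.zeros(n, bool)
        mask[plateau : plateau + 3] = True
        budget = target_mean_speed * n - 3 * target_max_speed
        if budget <= 0:
            raise ConfigError("targets infeasible for this trajectory length")
        speeds[~mask] *= budget / speeds[~mask].sum()
        if speeds[~mask].max() > cap:  # pragma: no cover - defensive
            speeds[~mask] = np.clip(speeds[~mask], None, cap)
            speeds[~mask] *= budget / speeds[~mask].sum()
        speeds[mask] = target_max_speed

    turns = rng.normal(0.0, 0.35, size=n)
    theta = np.cumsum(turns) + rng.uniform(0, 2 * math.pi)
    x = np.concatenate([[0.0], np.cumsum(speeds * dt * np.cos(theta))])
    y = np.concatenate([[0.0], np.cumsum(speeds * dt * np.sin(theta))])
    return Trajectory(fish_id, t, x, y)


def generate_collagen_mask(
    fraction: float, cfg: SimConfig = SimConfig(), field_id: str = "mask"
) -> CollagenMask:
    """Binary mask with *exactly* ``round(fraction · N)`` collagen pixels,
    laid out as smooth random blobs (thresholded filtered noise)."""
    if not 0 <= fraction <= 1:
        raise ValidationError(f"fraction must be in [0, 1], got {fraction}")
    h, w = cfg.mask_size
    if h < 1 or w < 1:
        raise ValidationError("mask must have >= 1 pixel")
    n = h * w
    k = int(round(fraction * n))
    rng = _spawn(cfg.seed, f"mask:{field_id}")
    mask = np.zeros(n, dtype=np.uint8)
    if k > 0:
        noise = rng.normal(size=(h, w))
        smooth = ndimage.gaussian_filter(noise, sigma=max(min(h, w) / 25, 1.0))
        # infinitesimal jitter breaks ties so exactly k pixels are selected
        flat = smooth.ravel() + rng.uniform(0, 1e-9, size=n)
        mask[np.argpartition(flat, -k)[-k:]] = 1
    return CollagenMask(field_id=field_id, mask=mask.reshape(h, w))


def generate_mito_field(
    n_ifm: int,
    n_ssm: int,
    damaged_fraction: float,
    csa_law: tuple[float, float] = (0.83, 0.12),
    cfg: SimConfig = SimConfig(),
    field_id: str = "tem",
) -> MitoField:
    """TEM field with exactly ``round(damaged_fraction · total)`` damaged
    mitochondria; CSAs drawn from a normal law truncated at 0."""
    if n_ifm < 0 or n_ssm < 0:
        raise ValidationError("counts must be >= 0")
    if not 0 <= damaged_fraction <= 1:
        raise ValidationError("damaged_fraction must be in [0, 1]")
    total = n_ifm + n_ssm
    rng = _spawn(cfg.seed, f"mito:{field_id}")
    n_damaged = int(round(damaged_fraction * total))
    damaged = np.zeros(total, bool)
    damaged[rng.permutation(total)[:n_damaged]] = True
    csa = _truncated_normal(rng, csa_law[0], csa_law[1], total, cfg.truncation)
    classes = ["IFM"] * n_ifm + ["SSM"] * n_ssm
    mitos = tuple(
        MitoRecord(
            mito_id=f"{field_id}_m{i + 1:03d}",
            mito_class=classes[i],
            csa_um2=float(csa[i]),
            damaged=bool(damaged[i]),
        )
        for i in range(total)
    )
    return MitoField(field_id=field_id, mitochondria=mitos)


# -- per-group defaults for the non-frailty tissue read-outs ----------------
# Printed group values where the study reports them; the rest are synthetic
# stand-ins on the reported scale, used only to exercise the pipeline.

COLLAGEN_FRACTIONS = {"2": 0.06023, "10": 0.07944, "30": 0.09272, "60": 0.1501}
MITO_COUNTS = {  # (n_ifm mean, n_ssm mean); SSM printed only at 30 months
    "2": (5.0, 5.5),
    "10": (5.5, 6.0),
    "30": (4.25, 8.286),
    "60": (3.286, 7.0),
}
DAMAGED_FRACTIONS = {"2": 0.10, "10": 0.20, "30": 0.50, "60": 1.0}
IFM_CSA_LAWS = {  # 60-month CSA printed (about half the younger groups')
    "2": (0.83, 0.12),
    "10": (0.83, 0.12),
    "30": (0.83, 0.12),
    "60": (0.4139, 0.120),
}
SARCOMERE_LAWS = {  # (sarcomere, A, H, I) printed means, printed SDs
    "2": ((2.342, 0.3794), (1.488, 0.044), (0.105, 0.014), (0.488, 0.219)),
    "10": ((1.888, 0.098), (1.309, 0.122), (0.099, 0.010), (0.364, 0.069)),
    "30": ((1.837, 0.069), (1.451, 0.053), (0.113, 0.021), (0.3729, 0.052)),
    "60": ((1.744, 0.098), (1.666, 0.255), (0.146, 0.012), (0.300, 0.066)),
}
CONFOCAL_LAWS = {  # synthetic stand-ins: GFP intensity declines with age
    "2": (55.0, 6.0),
    "10": (50.0, 6.0),
    "30": (40.0, 6.0),
    "60": (28.0, 6.0),
}


def generate_sarcomere_fields(
    group: str, n_fields: int, cfg: SimConfig = SimConfig()
) -> list[SarcomereField]:
    """Sarcomere/band measurements for one group, from the printed laws."""
    laws = SARCOMERE_LAWS[group]
    rng = _spawn(cfg.seed, f"sarc:{group}")
    out = []
    for i in range(n_fields):
        s = float(_truncated_normal(rng, *laws[0], 1, True)[0])
        a = float(_truncated_normal(rng, *laws[1], 1, True)[0])
        h = min(float(_truncated_normal(rng, *laws[2], 1, True)[0]), a)
        ib = float(_truncated_normal(rng, *laws[3], 1, True)[0])
        out.append(
            SarcomereField(
                field_id=f"sarc_{group}m_{i + 1:03d}",
                sarcomere_length_um=s,
                a_band_um=a,
                h_band_um=h,
                i_band_um=ib,
            )
        )
    return out


def generate_confocal_fields(
    group: str, n_fields: int, cfg: SimConfig = SimConfig()
) -> list[ConfocalField]:
    """Confocal field summaries for one group (synthetic intensity law)."""
    rng = _spawn(cfg.seed, f"conf:{group}")
    mean, sd = CONFOCAL_LAWS[group]
    out = []
    for i in range(n_fields):
        out.append(
            ConfocalField(
                field_id=f"conf_{group}m_{i + 1:03d}",
                gfp_mean_intensity=float(_truncated_normal(rng, mean, sd, 1, True)[0]),
                dapi_count=int(rng.integers(20, 41)),
            )
        )
    return out
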