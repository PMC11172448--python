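import numpy as np
import pytest

from zebrafrail.datatypes import CohortTable, FishRecord, LocomotorSummary, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def straight_trajectory():
    """Straight line at a constant 2 cm/s, sampled at 10 Hz for 10 s."""
    t = np.arange(0, 10.1, 0.1)
    return Trajectory("straight", t, 2.0 * t, np.zeros_like(t))


def make_cohort(groups, n_per_group=4, jitter=None):
    """Small cohort with locomotor summaries; per-group variable means are
    given, optionally jittered per fish by the `jitter` callable."""
    records, summaries = [], {}
    for label, vals in groups.items():
        for i in range(n_per_group):
            fid = f"f{label}_{i}"
            v = dict(vals)
            if jitter:
                v = jitter(v, i)
            bmi = v["bmi_gcm2"]
            length = 3.0
            records.append(
                FishRecord(fid, float(label), weight_g=bmi * length**2,
                           length_cm=length)
            )
            summaries[fid] = LocomotorSummary(
                fish_id=fid,
                total_distance_cm=v["total_distance_cm"],
                mean_speed_cms=v["mean_speed_cms"],
                max_speed_cms=max(v["max_speed_cms"], v["mean_speed_cms"]),
                duration_s=v["total_distance_cm"] / v["mean_speed_cms"],
                n_samples=1000,
            )
    return CohortTable(records=records, summaries=summaries)


@pytest.fixture
def two_group_cohort():
    """A young reference group with spread and an old group far from it."""
    young = {"total_distance_cm": 4600.0, "max_speed_cms": 35.0,
             "mean_speed_cms": 4.2, "bmi_gcm2": 0.019}
    old = {"total_distance_cm": 1500.0, "max_speed_cms": 15.0,
           "mean_speed_cms": 1.5, "bmi_gcm2": 0.045}

    def jitter(v, i):
        # deterministic spread so the reference SD is nonzero
        f = 1.0 + 0.05 * (i - 1.5)
        return {k: val * f for k, val in v.items()}

    return make_cohort({"2": young, "60": old}, n_per_group=4, jitter=jitter)
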