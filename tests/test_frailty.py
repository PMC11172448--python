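"""SD-binned deficit scoring and the frailty index: bin layout in both
configurations, both scoring modes, exact-arithmetic index, and the
invariances that make the score unit-free."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zebrafrail.datatypes import ReferenceStats
from zebrafrail.errors import ConfigError, ValidationError
from zebrafrail.frailty import (
    FrailtyConfig,
    cohort_frailty,
    compute_reference,
    deficit_score,
    frailty_index,
)


class TestDeficitScore:
    @pytest.mark.parametrize("d,expected", [
        (0.0, 0.0), (0.5, 0.0), (1.0, 0.0),          # within 1 SD
        (1.0000001, 0.25), (1.5, 0.25), (2.0, 0.25),  # (1, 2]
        (2.0000001, 0.5), (2.5, 0.5), (2.9999, 0.5),  # (2, 3)
        (3.0, 0.75),                                   # exactly 3
        (3.0000001, 1.0), (5.0, 1.0), (100.0, 1.0),   # beyond 3
    ])
    def test_literal_bins(self, d, expected):
        assert deficit_score(d, 0.0, 1.0) == expected
        assert deficit_score(-d, 0.0, 1.0) == expected  # two-sided

    @pytest.mark.parametrize("d,expected", [
        (1.5, 0.25), (2.5, 0.5), (3.0, 0.5), (3.1, 1.0), (5.0, 1.0),
    ])
    def test_practical_bins_merge_the_exact_3_band(self, d, expected):
        assert deficit_score(d, 0.0, 1.0, bins="practical") == expected

    def test_general_mean_and_sd(self):
        # 1.5 SD from a non-trivial reference law
        assert deficit_score(4667.738 + 1.5 * 1386.530, 4667.738, 1386.530) == 0.25

    @settings(derandomize=True, max_examples=60)
    @given(delta=st.floats(-10, 10, allow_nan=False),
           mean=st.floats(-100, 100), sd=st.floats(0.01, 50))
    def test_even_function_of_deviation(self, delta, mean, sd):
        up = deficit_score(mean + delta * sd, mean, sd)
        down = deficit_score(mean - delta * sd, mean, sd)
        assert up == down

    def test_directional_mode_scores_only_frail_direction(self):
        # faster than the reference is not frail
        assert deficit_score(5.0, 0.0, 1.0, mode="directional",
                             direction="higher_is_frail") == 1.0
        assert deficit_score(5.0, 0.0, 1.0, mode="directional",
                             direction="lower_is_frail") == 0.0
        assert deficit_score(-2.5, 0.0, 1.0, mode="directional",
                             direction="lower_is_frail") == 0.5

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            deficit_score(1.0, 0.0, 0.0)
        with pytest.raises(ConfigError):
            deficit_score(1.0, 0.0, 1.0, mode="sideways")


class TestComputeReference:
    def test_closed_form(self):
        df = pd.DataFrame({
            "group": ["2"] * 3,
            "bmi_gcm2": [0.018, 0.019, 0.020],
        }, index=["a", "b", "c"])
        ref = compute_reference(df, variables=["bmi_gcm2"])
        mean, sd = ref["bmi_gcm2"]
        assert mean == pytest.approx(0.019)
        assert sd == pytest.approx(0.001)

    def test_zero_sd_names_variable(self):
        df = pd.DataFrame({"group": ["2"] * 3, "bmi_gcm2": [0.02] * 3})
        with pytest.raises(ValidationError, match="bmi_gcm2"):
            compute_reference(df, variables=["bmi_gcm2"])

    def test_large_sample_matches_two_pass_oracle(self, rng):
        vals = rng.normal(4.2, 1.0, 1000)
        df = pd.DataFrame({"group": ["2"] * 1000, "mean_speed_cms": vals})
        ref = compute_reference(df, variables=["mean_speed_cms"])
        mean, sd = ref["mean_speed_cms"]
        # independent two-pass computation
        m = sum(vals) / len(vals)
        s = (sum((v - m) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
        assert mean == pytest.approx(m, rel=1e-12)
        assert sd == pytest.approx(s, rel=1e-12)

    def test_reference_too_small_or_missing_variable(self):
        df = pd.DataFrame({"group": ["2"], "bmi_gcm2": [0.02]})
        with pytest.raises(ValidationError, match="n >= 2"):
            compute_reference(df, variables=["bmi_gcm2"])
        df = pd.DataFrame({"group": ["2"] * 3, "bmi_gcm2": [1, 2, np.nan]})
        with pytest.raises(ValidationError, match="missing"):
            compute_reference(df, variables=["bmi_gcm2"])


REF = ReferenceStats({
    "total_distance_cm": (4667.738, 1386.530),
    "max_speed_cms": (35.302, 11.625),
    "mean_speed_cms": (4.182, 1.017),
    "bmi_gcm2": (0.019, 0.004),
})


class TestFrailtyIndex:
    def test_fish_at_reference_means_scores_zero(self):
        values = {v: REF[v][0] for v in REF.names()}
        res = frailty_index(values, REF)
        assert res.fi == 0.0
        assert all(s == 0.0 for s in res.scores.values())

    def test_one_variable_in_second_bin(self):
        values = {v: REF[v][0] for v in REF.names()}
        mean, sd = REF["mean_speed_cms"]
        values["mean_speed_cms"] = mean + 1.5 * sd
        res = frailty_index(values, REF)
        assert res.fi == 0.0625  # mean of (0.25, 0, 0, 0), exact

    def test_saturation_at_one(self):
        values = {v: REF[v][0] + 10 * REF[v][1] for v in REF.names()}
        assert frailty_index(values, REF).fi == 1.0

    def test_index_is_exact_quarter_arithmetic(self):
        """FI is sums of quarters over the variable count, exactly."""
        values = {v: REF[v][0] for v in REF.names()}
        m, s = REF["total_distance_cm"]
        values["total_distance_cm"] = m - 2.5 * s  # score 0.5
        m, s = REF["bmi_gcm2"]
        values["bmi_gcm2"] = m + 1.5 * s  # score 0.25
        res = frailty_index(values, REF)
        assert Fraction(res.fi) == Fraction(1, 2) * Fraction(1, 4) + \
            Fraction(1, 4) * Fraction(1, 4)

    def test_missing_variable_errors_unless_allowed(self):
        values = {v: REF[v][0] for v in REF.names() if v != "bmi_gcm2"}
        with pytest.raises(ValidationError, match="bmi_gcm2"):
            frailty_index(values, REF, fish_id="x")
        res = frailty_index(values, REF,
                            FrailtyConfig(allow_missing=True), fish_id="x")
        assert res.renormalized
        assert res.fi == 0.0

    @settings(derandomize=True, max_examples=60)
    @given(z=st.lists(st.floats(-6, 6), min_size=4, max_size=4),
           scale=st.floats(0.001, 1000), shift=st.floats(-100, 100))
    def test_affine_rescaling_invariance(self, z, scale, shift):
        """Changing a variable's units never changes the index."""
        from hypothesis import assume

        # stay clear of bin boundaries, where the score is discontinuous
        # and float rounding of the rescale could legitimately flip a bin
        assume(all(min(abs(abs(zi) - b) for b in (1, 2, 3)) > 1e-6 for zi in z))
        names = list(REF.names())
        values = {v: REF[v][0] + z[i] * REF[v][1] for i, v in enumerate(names)}
        base = frailty_index(values, REF)

        v0 = names[0]
        ref2 = dict(REF.variables)
        ref2[v0] = (REF[v0][0] * scale + shift, REF[v0][1] * scale)
        values2 = dict(values)
        values2[v0] = values[v0] * scale + shift
        rescaled = frailty_index(values2, ReferenceStats(ref2))
        assert rescaled.fi == base.fi

    @settings(derandomize=True, max_examples=60)
    @given(z=st.floats(0, 6), bump=st.floats(0, 3))
    def test_monotone_in_each_deviation(self, z, bump):
        names = list(REF.names())
        values = {v: REF[v][0] for v in names}
        values[names[0]] = REF[names[0]][0] + z * REF[names[0]][1]
        lo = frailty_index(values, REF).fi
        values[names[0]] = REF[names[0]][0] + (z + bump) * REF[names[0]][1]
        hi = frailty_index(values, REF).fi
        assert hi >= lo
        assert 0.0 <= lo <= hi <= 1.0


class TestCohortFrailty:
    def test_reference_only_spread_cohort(self, two_group_cohort):
        results, groups = cohort_frailty(two_group_cohort.variables_frame())
        by_label = {g.group_label: g for g in groups}
        assert set(by_label) == {"2", "60"}
        assert by_label["60"].mean > by_label["2"].mean
        for r in results:
            assert 0.0 <= r.fi <= 1.0

    def test_every_fish_at_reference_means_gives_zero_group(self):
        df = pd.DataFrame({
            "group": ["2"] * 3 + ["60"] * 3,
            "mean_speed_cms": [4.0, 4.2, 4.4] + [4.2] * 3,
        }, index=[f"f{i}" for i in range(6)])
        cfg = FrailtyConfig(variables=("mean_speed_cms",))
        results, groups = cohort_frailty(df, cfg)
        old = next(g for g in groups if g.group_label == "60")
        assert old.mean == 0.0 and old.sd == 0.0

    def test_forced_single_bin_arithmetic(self):
        """Every old fish exactly one variable in (1, 2] SD -> FI 0.0625."""
        ref_rows = {
            "total_distance_cm": [4000.0, 4600.0, 5200.0],
            "max_speed_cms": [30.0, 35.0, 40.0],
            "mean_speed_cms": [3.6, 4.2, 4.8],
            "bmi_gcm2": [0.016, 0.019, 0.022],
        }
        df_ref = pd.DataFrame({"group": "2", **ref_rows},
                              index=["r0", "r1", "r2"])
        ref = compute_reference(df_ref)
        old = []
        for i in range(4):
            row = {v: ref[v][0] for v in ref.names()}
            v = list(ref.names())[i % 4]
            row[v] = ref[v][0] - 1.5 * ref[v][1]
            old.append({"group": "60", **row})
        df = pd.concat([df_ref, pd.DataFrame(old, index=[f"o{i}" for i in range(4)])])
        results, groups = cohort_frailty(df)
        old_summary = next(g for g in groups if g.group_label == "60")
        assert old_summary.mean == pytest.approx(0.0625)
        assert old_summary.sd == pytest.approx(0.0)

    def test_missing_reference_group_errors(self):
        df = pd.DataFrame({"group": ["60"] * 3, "bmi_gcm2": [1, 2, 3.0]})
        with pytest.raises(ValidationError, match="reference group"):
            cohort_frailty(df, FrailtyConfig(variables=("bmi_gcm2",)))
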