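"""Half-life estimation: normalization, regression, formula and bounds."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import decayatlas as da
from decayatlas.decay import (
    STATUS_NONPOSITIVE,
    STATUS_OK,
    STATUS_OVER_CAP,
    STATUS_UNUSABLE,
    ChaseProfile,
    HalfLifeEstimate,
    apply_half_life_bounds,
    build_chase_profile,
    estimate_half_lives,
    fit_decay,
    half_life_from_fit,
    normalize_to_reference,
)

T048 = (0.0, 4.0, 8.0)


def make_manifest(samples_per_tp):
    rows = []
    for t, samples in samples_per_tp.items():
        for r, sid in enumerate(samples, 1):
            rows.append(
                {"sample_id": sid, "condition": "control", "assay": "chase",
                 "timepoint_h": t, "replicate": r}
            )
    return pd.DataFrame(rows)


class TestNormalizeToReference:
    def test_ratio_and_self_normalization(self):
        fpkm = pd.DataFrame({"s1": [4.0, 2.0], "s2": [6.0, 3.0]}, index=["g1", "ref"])
        ratios = normalize_to_reference(fpkm, "ref")
        assert ratios.loc["g1", "s1"] == 2.0
        assert (ratios.loc["ref"] == 1.0).all()

    def test_hand_division_table(self):
        fpkm = pd.DataFrame(
            {"s1": [1.0, 3.0, 2.0], "s2": [5.0, 10.0, 4.0]}, index=["a", "b", "ref"]
        )
        ratios = normalize_to_reference(fpkm, "ref")
        expected = pd.DataFrame(
            {"s1": [0.5, 1.5, 1.0], "s2": [1.25, 2.5, 1.0]}, index=["a", "b", "ref"]
        )
        pd.testing.assert_frame_equal(ratios, expected)

    def test_zero_reference_names_the_sample(self):
        fpkm = pd.DataFrame({"s1": [1.0, 2.0], "bad": [1.0, 0.0]}, index=["g1", "ref"])
        with pytest.raises(ValueError, match="bad"):
            normalize_to_reference(fpkm, "ref")


class TestChaseProfile:
    def test_replicate_means_and_zero_hour_scaling(self):
        manifest = make_manifest({0.0: ["a1", "a2"], 4.0: ["b1", "b2"], 8.0: ["c1"]})
        ratios = pd.DataFrame(
            [[2.0, 2.0, 0.4, 0.6, 0.5]], index=["g1"], columns=["a1", "a2", "b1", "b2", "c1"]
        )
        profile = build_chase_profile(ratios, manifest, "g1")
        assert profile.means == (2.0, 0.5, 0.5)
        assert profile.scaled == (1.0, 0.25, 0.25)
        assert profile.scaled[0] == 1.0

    def test_zero_timepoint_mean_flags_unusable(self):
        manifest = make_manifest({0.0: ["a1"], 4.0: ["b1"], 8.0: ["c1"]})
        ratios = pd.DataFrame([[1.0, 0.0, 0.5]], index=["g1"], columns=["a1", "b1", "c1"])
        assert not build_chase_profile(ratios, manifest, "g1").usable

    def test_missing_zero_hour_is_error(self):
        manifest = make_manifest({4.0: ["b1"], 8.0: ["c1"]})
        ratios = pd.DataFrame([[1.0, 0.5]], index=["g1"], columns=["b1", "c1"])
        with pytest.raises(ValueError, match="0 h"):
            build_chase_profile(ratios, manifest, "g1")


class TestFitDecay:
    def test_exact_exponential(self):
        profile = ChaseProfile("g", T048, (1.0, 0.5, 0.25), (1.0, 0.5, 0.25))
        intercept, slope = fit_decay(profile)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert slope == pytest.approx(-math.log(2) / 4)

    def test_flat_series(self):
        profile = ChaseProfile("g", T048, (1.0, 1.0, 1.0), (1.0, 1.0, 1.0))
        assert fit_decay(profile) == (pytest.approx(0.0), pytest.approx(0.0))

    def test_matches_normal_equations_oracle(self):
        values = (1.0, 0.7, 0.45)
        profile = ChaseProfile("g", T048, values, values)
        intercept, slope = fit_decay(profile)
        # independent normal-equations solve on ln(values)
        t = np.array(T048)
        y = np.log(values)
        n = len(t)
        slope_exp = (n * (t * y).sum() - t.sum() * y.sum()) / (n * (t**2).sum() - t.sum() ** 2)
        intercept_exp = (y.sum() - slope_exp * t.sum()) / n
        assert slope == pytest.approx(slope_exp, rel=1e-12)
        assert intercept == pytest.approx(intercept_exp, rel=1e-12)

    def test_nonpositive_profile_rejected(self):
        profile = ChaseProfile("g", T048, (1.0, 0.0, 0.1), (1.0, 0.0, 0.1))
        with pytest.raises(ValueError):
            fit_decay(profile)


class TestHalfLifeFormula:
    def test_formula_identity(self):
        assert half_life_from_fit(0.0, -math.log(2) / 4) == pytest.approx(4.0)
        assert half_life_from_fit(math.log(2), -math.log(2) / 4) == pytest.approx(8.0)

    def test_positive_slope_gives_negative_half_life(self):
        hl = half_life_from_fit(0.0, 0.1)
        assert hl == pytest.approx(-6.93, abs=0.01)
        est = apply_half_life_bounds(HalfLifeEstimate("g", 0.0, 0.1, hl, STATUS_OK))
        assert est.status == STATUS_NONPOSITIVE

    def test_zero_slope_maps_to_over_cap(self):
        hl = half_life_from_fit(0.0, 0.0)
        assert math.isinf(hl)
        est = apply_half_life_bounds(HalfLifeEstimate("g", 0.0, 0.0, hl, STATUS_OK))
        assert est.status == STATUS_OVER_CAP

    @pytest.mark.parametrize(
        "hl, status",
        [(4.0, STATUS_OK), (50.0, STATUS_OK), (55.0, STATUS_OVER_CAP), (-2.0, STATUS_NONPOSITIVE)],
    )
    def test_bounds(self, hl, status):
        est = apply_half_life_bounds(HalfLifeEstimate("g", 0.0, -0.1, hl, STATUS_OK))
        assert est.status == status


class TestEstimateHalfLives:
    def _table(self, series_by_gene, ref_series=(2.0, 2.0, 2.0)):
        manifest = make_manifest({0.0: ["s0"], 4.0: ["s4"], 8.0: ["s8"]})
        data = dict(series_by_gene)
        data["ref"] = ref_series
        fpkm = pd.DataFrame(data, index=["s0", "s4", "s8"]).T
        fpkm.columns = ["s0", "s4", "s8"]
        return estimate_half_lives(fpkm, manifest, "ref")

    def test_recovers_two_point_closed_form(self):
        # degenerate 2-timepoint design: t * ln2 / ln(M0/Mt)
        manifest = make_manifest({0.0: ["s0"], 6.0: ["s6"]})
        fpkm = pd.DataFrame(
            {"g1": [8.0, 1.0], "ref": [2.0, 2.0]}, index=["s0", "s6"]
        ).T
        fpkm.columns = ["s0", "s6"]
        table = estimate_half_lives(fpkm, manifest, "ref")
        expected = 6.0 * math.log(2) / math.log(8.0)
        assert table.loc["g1", "half_life_h"] == pytest.approx(expected, rel=1e-12)

    def test_statuses(self):
        table = self._table(
            {
                "fast": (8.0, 4.0, 2.0),      # t1/2 = 4 h
                "flat": (3.0, 3.0, 3.0),      # no decay -> over cap
                "rising": (1.0, 2.0, 4.0),    # negative half-life
                "zeroed": (1.0, 0.0, 0.5),    # log undefined
            }
        )
        assert table.loc["fast", "status"] == STATUS_OK
        assert table.loc["fast", "half_life_h"] == pytest.approx(4.0)
        assert table.loc["flat", "status"] == STATUS_OVER_CAP
        assert table.loc["rising", "status"] == STATUS_NONPOSITIVE
        assert table.loc["zeroed", "status"] == STATUS_UNUSABLE

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, c):
        base = self._table({"g": (8.0, 4.0, 2.0)})
        scaled = self._table({"g": (8.0 * c, 4.0 * c, 2.0 * c)})
        for col in ("intercept", "slope", "half_life_h"):
            assert scaled.loc["g", col] == pytest.approx(base.loc["g", col], rel=1e-9)

    def test_monotonicity_over_noiseless_profiles(self):
        k = np.linspace(0.05, 0.6, 12)
        series = {f"g{i}": tuple(np.exp(-ki * np.array(T048))) for i, ki in enumerate(k)}
        table = self._table(series)
        hl = table.loc[[f"g{i}" for i in range(12)], "half_life_h"].to_numpy()
        assert (np.diff(hl) < 0).all()


def test_exact_recovery_on_noiseless_simulation(expectation_dataset, expectation_fpkm):
    table = estimate_half_lives(
        expectation_fpkm, expectation_dataset.manifest, "Rplp0", condition="control"
    )
    truth = expectation_dataset.truth
    ok = table["status"] == STATUS_OK
    rel = np.abs(
        table.loc[ok, "half_life_h"] - truth.loc[ok[ok].index, "half_life_h"]
    ) / truth.loc[ok[ok].index, "half_life_h"]
    assert ok.sum() >= 190
    assert rel.max() < 1e-9
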