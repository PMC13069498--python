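import datetime
import math

import pytest
from hypothesis import given, settings, strategies as st

from nlcsp import (
    GrowthStatusLabel,
    NoduleHistory,
    ValidationError,
    assess_growth,
    classify_diameter_change,
    classify_volumetric_change,
    relative_volume_change,
    volume_doubling_time,
)

BASE = datetime.date(2025, 7, 1)


def volume_history(make_obs, volumes, days, **kwargs):
    """Build a history from parallel (volume, day-offset) sequences."""
    obs = [
        make_obs(scan_date=BASE + datetime.timedelta(days=d), volume_mm3=v)
        for v, d in zip(volumes, days)
    ]
    return NoduleHistory(nodule_id="N1", observations=obs, **kwargs)


def diameter_history(make_obs, diameters, days, **kwargs):
    obs = [
        make_obs(
            scan_date=BASE + datetime.timedelta(days=d),
            long_axis_mm=dd,
            short_axis_mm=dd,
        )
        for dd, d in zip(diameters, days)
    ]
    return NoduleHistory(nodule_id="N1", observations=obs, **kwargs)


class TestPrimitives:
    @pytest.mark.parametrize(
        "v_ref, v_cur, expected",
        [(100, 125, 25.0), (200, 150, -25.0), (100, 100, 0.0)],
    )
    def test_relative_volume_change(self, v_ref, v_cur, expected):
        assert relative_volume_change(v_ref, v_cur) == expected

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValidationError):
            relative_volume_change(0, 100)

    @pytest.mark.parametrize(
        "v_ref, v_cur, days, expected",
        [(100, 200, 300, 300.0), (100, 400, 600, 300.0)],
    )
    def test_vdt_exact_doublings(self, v_ref, v_cur, days, expected):
        assert volume_doubling_time(v_ref, v_cur, days) == pytest.approx(expected)

    def test_vdt_general_case(self):
        # 170 * ln2 / ln 1.5, evaluated independently
        expected = 170 * math.log(2) / math.log(1.5)
        assert volume_doubling_time(100, 150, 170) == pytest.approx(expected)
        assert expected == pytest.approx(290.6, abs=0.05)

    def test_vdt_absent_for_unchanged_or_shrinking(self):
        assert volume_doubling_time(100, 100, 365) is None
        assert volume_doubling_time(100, 60, 365) is None

    def test_vdt_nonpositive_interval_rejected(self):
        with pytest.raises(ValidationError):
            volume_doubling_time(100, 150, 0)


class TestVolumetricClassification:
    def test_fast_growth(self, make_obs):
        hist = volume_history(make_obs, [100, 150], [0, 170])  # VDT ~ 291
        status = classify_volumetric_change(hist)
        assert status.status is GrowthStatusLabel.growing
        assert status.method.value == "volumetry"
        assert status.vdt_days == pytest.approx(290.6, abs=0.05)

    def test_increase_below_corridor_is_stable(self, make_obs):
        hist = volume_history(make_obs, [100, 120], [0, 365])
        assert classify_volumetric_change(hist).status is GrowthStatusLabel.stable

    def test_decrease(self, make_obs):
        hist = volume_history(make_obs, [100, 60], [0, 365])
        assert classify_volumetric_change(hist).status is GrowthStatusLabel.decreased

    def test_exact_minus_25_is_decreased(self, make_obs):
        # "decrease of 25% or more" is inclusive
        hist = volume_history(make_obs, [200, 150], [0, 365])
        assert classify_volumetric_change(hist).status is GrowthStatusLabel.decreased

    def test_exact_plus_25_is_stable(self, make_obs):
        # "increase greater than 25%" is strict
        hist = volume_history(make_obs, [100, 125], [0, 90])
        assert classify_volumetric_change(hist).status is GrowthStatusLabel.stable

    def test_slow_increase_first_seen_is_stable(self, make_obs):
        # >25% from baseline with VDT >= 600 but no earlier qualifying interval
        hist = volume_history(make_obs, [100, 132], [0, 731])  # VDT ~ 1824
        assert classify_volumetric_change(hist).status is GrowthStatusLabel.stable

    def test_slow_growth_needs_persistence(self, make_obs):
        # qualifies at the intermediate AND the current assessment
        v1 = 100 * 2 ** (365 / 900)  # ~32% at 1y, VDT 900
        v2 = 100 * 2 ** (730 / 900)
        hist = volume_history(make_obs, [100, v1, v2], [0, 365, 730])
        status = classify_volumetric_change(hist)
        assert status.status is GrowthStatusLabel.slowly_growing
        assert status.vdt_days == pytest.approx(900, rel=1e-9)

    def test_vdt_boundary_at_600_days(self, make_obs):
        """With a >25% increase fixed, 'growing' switches off exactly at
        VDT 600: the boundary itself lands on the non-growing side."""
        from nlcsp.growth import classify_volume_pair

        for target_vdt, expect_growing in [(599, True), (600, False), (601, False)]:
            interval = target_vdt * math.log(1.5) / math.log(2)
            status = classify_volume_pair(100.0, 150.0, interval)
            assert (status.status is GrowthStatusLabel.growing) is expect_growing

    def test_volumes_required(self, make_obs):
        hist = volume_history(make_obs, [100, None], [0, 365])
        with pytest.raises(ValidationError):
            classify_volumetric_change(hist)


class TestDiameterClassification:
    @pytest.mark.parametrize(
        "d_ref, d_cur, days, expected",
        [
            (6.0, 7.7, 730, GrowthStatusLabel.growing),  # +1.7 mm over 24 mo
            (6.0, 7.5, 365, GrowthStatusLabel.stable),  # threshold is strict
            (6.0, 8.0, 913, GrowthStatusLabel.slowly_growing),  # +2.0 over 30 mo
            (8.0, 6.5, 365, GrowthStatusLabel.decreased),  # -1.5 inclusive
            (8.0, 6.6, 365, GrowthStatusLabel.stable),
            (6.0, 7.6, 731, GrowthStatusLabel.slowly_growing),  # just past 24 mo
        ],
    )
    def test_rules(self, make_obs, d_ref, d_cur, days, expected):
        hist = diameter_history(make_obs, [d_ref, d_cur], [0, days])
        status = classify_diameter_change(hist)
        assert status.status is expected
        assert status.method.value == "diameter"

    def test_float_artefact_does_not_cross_threshold(self, make_obs):
        # 7.6 - 6.1 is 1.5000000000000002 in binary; quantization keeps it stable
        hist = diameter_history(make_obs, [6.1, 7.6], [0, 365])
        assert classify_diameter_change(hist).status is GrowthStatusLabel.stable


class TestMethodSelection:
    def test_volumetry_preferred(self, make_obs):
        hist = volume_history(make_obs, [100, 160], [0, 365])
        assert assess_growth(hist).method.value == "volumetry"

    def test_mixed_methods_fall_back_to_diameter(self, make_obs):
        obs = [
            make_obs(scan_date=BASE, long_axis_mm=6.0, short_axis_mm=6.0),
            make_obs(
                scan_date=BASE + datetime.timedelta(days=365),
                long_axis_mm=8.0,
                short_axis_mm=8.0,
                volume_mm3=268.0,
            ),
        ]
        hist = NoduleHistory(nodule_id="N1", observations=obs)
        status = assess_growth(hist)
        assert status.method.value == "diameter"
        assert status.status is GrowthStatusLabel.growing


class TestHistoryInvariants:
    def test_dates_strictly_increasing(self, make_obs):
        with pytest.raises(ValueError):
            volume_history(make_obs, [100, 110], [0, 0])

    def test_reference_must_precede_current(self, make_obs):
        with pytest.raises(ValueError):
            volume_history(make_obs, [100, 110], [0, 100], reference_index=1)


@settings(derandomize=True, max_examples=500)
@given(
    v_ref=st.floats(min_value=20, max_value=3000),
    ratio=st.floats(min_value=0.2, max_value=5.0),
    days=st.integers(min_value=30, max_value=1500),
)
def test_volumetric_partition(make_obs_factory, v_ref, ratio, days):
    """Every two-scan volumetric history gets exactly one of the four calls."""
    hist = volume_history(make_obs_factory, [v_ref, v_ref * ratio], [0, days])
    status = classify_volumetric_change(hist)
    assert status.status in {
        GrowthStatusLabel.growing,
        GrowthStatusLabel.slowly_growing,
        GrowthStatusLabel.stable,
        GrowthStatusLabel.decreased,
    }


@pytest.fixture(scope="module")
def make_obs_factory():
    import nlcsp

    def _make(**overrides):
        fields = dict(
            nodule_id="N1",
            scan_date=BASE,
            composition="solid",
            long_axis_mm=5.5,
            short_axis_mm=4.5,
            lobe="RUL",
        )
        fields.update(overrides)
        return nlcsp.NoduleObservation(**fields)

    return _make
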