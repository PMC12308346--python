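"""Unit conversions and QC filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from countersignal import (DEFAULT_CONSTANTS, DataError, DomainError,
                           apply_qc_filters, included_records,
                           mass_for_molarity, molarity_from_rate,
                           post_exposure_rate, rate_from_molarity,
                           release_rate)
from countersignal.synthetic import QC_FIXTURE_EXPECTED

positive = st.floats(min_value=1e-6, max_value=1e6,
                     allow_nan=False, allow_infinity=False)


class TestReleaseRate:
    @pytest.mark.parametrize("conc, vol, dur, expected", [
        (0.5, 3.0, 30.0, 0.003),
        (0.0, 3.0, 30.0, 0.0),
        (0.0416667, 3.0, 30.0, 0.00025),  # water-threshold concentration
    ])
    def test_known_values(self, conc, vol, dur, expected):
        assert release_rate(conc, vol, dur) == pytest.approx(expected, rel=1e-4)

    @given(conc=positive, vol=positive, dur=positive, c=positive)
    @settings(max_examples=100, deadline=None)
    def test_homogeneity(self, conc, vol, dur, c):
        """Linear in concentration and volume, inverse in duration."""
        base = release_rate(conc, vol, dur)
        assert release_rate(c * conc, vol, dur) == pytest.approx(c * base, rel=1e-9)
        assert release_rate(conc, c * vol, dur) == pytest.approx(c * base, rel=1e-9)
        assert release_rate(conc, vol, c * dur) == pytest.approx(base / c, rel=1e-9)

    @pytest.mark.parametrize("kwargs", [
        dict(conc_ng_per_ml=1.0, volume_l=0.0, duration_min=30.0),
        dict(conc_ng_per_ml=1.0, volume_l=3.0, duration_min=-1.0),
        dict(conc_ng_per_ml=-0.1, volume_l=3.0, duration_min=30.0),
    ])
    def test_domain_errors(self, kwargs):
        with pytest.raises(DomainError):
            release_rate(**kwargs)


class TestPostExposureRate:
    def test_incremental_mass_bookkeeping(self):
        """0.5 ng/ml in 3 l then 0.7 ng/ml in 2.951 l over 10 min."""
        res = post_exposure_rate(0.5, 0.7, 3.0, 2.951, 10.0)
        assert res.increased
        assert res.rate_mg_per_h == pytest.approx(0.0035442, rel=1e-6)

    def test_no_increase_flagged(self):
        res = post_exposure_rate(0.5, 0.45, 3.0, 2.951, 10.0)
        assert not res.increased

    def test_zero_baseline_reduces_to_release_rate(self):
        res = post_exposure_rate(0.0, 0.3, 3.0, 3.0, 10.0, sample_volume_ml=0.0)
        assert res.rate_mg_per_h == pytest.approx(release_rate(0.3, 3.0, 10.0))
        assert res.rate_mg_per_h == pytest.approx(0.0054)


class TestMolarConversions:
    def test_average_bucket_state_to_mass_rate(self):
        """7e-8 M accumulated over 30 min in 3 l is roughly 60 ng/s."""
        rate = rate_from_molarity(7e-8, 1800.0, 3.0, 472.64)
        assert rate == pytest.approx(55.14, abs=0.01)

    def test_molarity_from_rate(self):
        assert molarity_from_rate(60.0, 1800.0, 3.0, 472.64) == pytest.approx(7.62e-8, rel=1e-3)
        assert molarity_from_rate(60.0, 1.0, 3.0, 472.64) == pytest.approx(4.23e-11, rel=1e-2)

    @given(rate=positive, dur=positive, vol=positive, mm=positive)
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, rate, dur, vol, mm):
        m = molarity_from_rate(rate, dur, vol, mm)
        assert rate_from_molarity(m, dur, vol, mm) == pytest.approx(rate, rel=1e-12)

    @pytest.mark.parametrize("molarity, vol, mm, expected", [
        (5e-13, 3.0, 494.62, 0.742),   # sodium salt reproduces the printed mass
        (5e-7, 3.0, 494.62, 7.419e5),  # 1e6 x the 5e-13 M mass
        (1.0, 1.0, 1.0, 1e9),
    ])
    def test_mass_for_molarity(self, molarity, vol, mm, expected):
        assert mass_for_molarity(molarity, vol, mm) == pytest.approx(expected, rel=1e-3)

    def test_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            mass_for_molarity(0.0, 3.0, 494.62)
        with pytest.raises(DomainError):
            molarity_from_rate(60.0, -1.0, 3.0, 472.64)


class TestQcFilters:
    def test_fixture_reason_counts(self, qc_fixture):
        records, audit = apply_qc_filters(qc_fixture)
        assert (records["qc_status"] == "included").sum() == 6
        counts = records[records["qc_status"] == "excluded"]["exclusion_reason"].value_counts()
        assert counts.to_dict() == {"is_not_detected": 2, "no_increase": 2,
                                    "below_water_threshold": 2}
        for male, reason in QC_FIXTURE_EXPECTED.items():
            row = records[records["male_id"] == male].iloc[0]
            assert row["exclusion_reason"] == reason

    def test_threshold_filter_disabled_gains_two_survivors(self, qc_fixture):
        tiny = DEFAULT_CONSTANTS.__class__(water_threshold_mg_per_h=1e-30)
        records, _ = apply_qc_filters(qc_fixture, constants=tiny)
        assert (records["qc_status"] == "included").sum() == 8

    def test_below_threshold_example(self):
        # baseline rate 0.0002, post rate 0.00024: both under 0.00025 -> excluded
        conc_b = 0.0002 / (3.0 * 1000 * 2 * 1e-6)
        post_mass = conc_b * 2950 + 0.00024 / (6 * 1e-6)
        conc_p = post_mass / 2951
        df = pd.DataFrame([
            ("m1", "S", 5e-9, "baseline", conc_b, 1, 3.0, 30.0),
            ("m1", "S", 5e-9, "post", conc_p, 1, 2.951, 10.0),
        ], columns=["male_id", "series", "treatment_molar", "timepoint",
                    "conc_ng_per_ml", "is_detected", "volume_l", "duration_min"])
        records, _ = apply_qc_filters(df)
        assert records.iloc[0]["exclusion_reason"] == "below_water_threshold"

    def test_empty_input(self):
        records, audit = apply_qc_filters(pd.DataFrame(
            columns=["male_id", "timepoint", "series", "treatment_molar",
                     "conc_ng_per_ml", "is_detected", "volume_l", "duration_min"]))
        assert records.empty and audit.counts.empty

    def test_missing_pair_is_sample_lost(self, qc_fixture):
        df = qc_fixture[~((qc_fixture["male_id"] == "QC_M01")
                          & (qc_fixture["timepoint"] == "post"))]
        records, _ = apply_qc_filters(df)
        assert records.set_index("male_id").loc["QC_M01", "exclusion_reason"] == "sample_lost"

    def test_duplicate_rows_rejected(self, qc_fixture):
        with pytest.raises(DataError):
            apply_qc_filters(pd.concat([qc_fixture, qc_fixture.head(2)]))

    def test_idempotent_on_included_set(self, qc_fixture):
        records, _ = apply_qc_filters(qc_fixture)
        keep = set(included_records(records)["male_id"])
        again, _ = apply_qc_filters(qc_fixture[qc_fixture["male_id"].isin(keep)])
        assert (again["qc_status"] == "included").all()
        pd.testing.assert_frame_equal(
            again.reset_index(drop=True),
            included_records(records).reset_index(drop=True))

    def test_reasons_partition_input(self, small_series):
        _, samples, _ = small_series
        records, audit = apply_qc_filters(samples)
        n_males = samples["male_id"].nunique()
        assert len(records) == n_males
        n_inc = (records["qc_status"] == "included").sum()
        assert n_inc + int(audit.counts.values.sum() if not audit.counts.empty else 0) == n_males
        assert (records.groupby("male_id").size() == 1).all()
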