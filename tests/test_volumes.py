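"""Volume reconstruction, QC filtering and time-course summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gifluid import (
    ValidationError,
    apparent_volume,
    closed_form_vgi,
    qc_filter,
    records_to_volumes,
    remaining_water_volume,
    summarize_timecourse,
)
from gifluid.datagen import FIXTURE_K_ABS, FIXTURE_K_SEC, generate_worked_fixture
from gifluid.kinetics import ModelParams


class TestApparentVolume:
    @pytest.mark.parametrize(
        "x_umol,c_um,expected_ml",
        [
            (0.01, 10.0, 1.0),   # initial dose, no concentration change
            (0.01, 20.0, 0.5),   # 2x concentrated -> half volume
            (0.008, 16.0, 0.5),  # ratio invariant to partial recovery
        ],
    )
    def test_dilution_examples(self, x_umol, c_um, expected_ml):
        assert apparent_volume(x_umol, c_um) == pytest.approx(expected_ml)

    @settings(deadline=None, derandomize=True)
    @given(c=st.floats(1e-6, 1e3), v=st.floats(0.0, 100.0))
    def test_roundtrip_exact(self, c, v):
        """apparent_volume(c*v, c) == v: dilution inverts concentration."""
        x_umol = c * v / 1000.0  # amount dissolved in v mL at c uM
        assert apparent_volume(x_umol, c) == pytest.approx(v, rel=1e-12, abs=1e-12)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValidationError):
            apparent_volume(0.01, 0.0)


class TestRemainingWater:
    @pytest.mark.parametrize(
        "x_uci,expected_ml", [(1.0, 1.0), (0.0169, 0.0169), (0.0, 0.0)]
    )
    def test_activity_to_volume(self, x_uci, expected_ml):
        assert remaining_water_volume(x_uci, c0=1.0) == pytest.approx(expected_ml)

    def test_nonpositive_c0_rejected(self):
        with pytest.raises(ValidationError):
            remaining_water_volume(1.0, c0=0.0)


def _records(recoveries, flags=None, marker="FD4"):
    n = len(recoveries)
    flags = flags or {}
    return pd.DataFrame(
        {
            "animal_id": [f"a{i}" for i in range(n)],
            "region": "jejunum",
            "marker": marker,
            "time_min": 5.0,
            "dose": 0.01,
            "v0_ml": 1.0,
            "x_out": [0.01 * r for r in recoveries],
            "c_out": 10.0,
            "recovery": recoveries,
            "flag_blood": flags.get("blood", [False] * n),
            "flag_loop": flags.get("loop", [False] * n),
            "flag_low_recovery": [False] * n,
        }
    )


class TestQcFilter:
    def test_low_recovery_rule(self):
        inc, exc = qc_filter(_records([0.95, 0.79, 0.85]), recovery_threshold=0.80)
        assert len(inc) == 2 and len(exc) == 1
        assert exc["exclusion_reason"].tolist() == ["low_recovery"]

    def test_blood_flag_trumps_good_recovery(self):
        inc, exc = qc_filter(_records([0.99], flags={"blood": [True]}))
        assert len(inc) == 0
        assert exc["exclusion_reason"].tolist() == ["blood"]

    def test_loop_length_flag(self):
        _, exc = qc_filter(_records([0.9], flags={"loop": [True]}))
        assert exc["exclusion_reason"].tolist() == ["loop_length"]

    def test_all_clean_all_included(self):
        inc, exc = qc_filter(_records([1.0, 1.0, 1.0]))
        assert len(inc) == 3 and len(exc) == 0

    def test_tracer_never_excluded_on_recovery(self):
        # tracer recovery is the measurement itself, not a QC quantity
        inc, _ = qc_filter(_records([0.05, 0.10], marker="H3_WATER"))
        assert len(inc) == 2

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        recs=st.lists(st.floats(0.0, 1.2), min_size=1, max_size=12),
        blood=st.data(),
    )
    def test_partition_and_idempotence(self, recs, blood):
        flags = {"blood": blood.draw(st.lists(st.booleans(), min_size=len(recs), max_size=len(recs)))}
        records = _records(recs, flags=flags)
        inc, exc = qc_filter(records)
        assert len(inc) + len(exc) == len(records)
        inc2, exc2 = qc_filter(inc)
        assert len(exc2) == 0 and len(inc2) == len(inc)

    def test_empty_input(self):
        inc, exc = qc_filter(_records([]).iloc[0:0])
        assert inc.empty and exc.empty

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValidationError):
            qc_filter(_records([1.0]), recovery_threshold=0.0)


class TestRecordsToVolumes:
    def test_noiseless_fd4_matches_closed_form(self, fixture_records):
        vols = records_to_volumes(fixture_records)
        fd4 = vols[vols["marker"] == "FD4"]
        for row in fd4.itertuples():
            p = ModelParams(
                k_abs=FIXTURE_K_ABS[row.region], k_sec=FIXTURE_K_SEC[row.region]
            )
            assert row.remaining_fraction == pytest.approx(
                closed_form_vgi(p, row.time_min) / p.v0, rel=1e-12
            )

    def test_noiseless_tracer_matches_exponential(self, fixture_records):
        vols = records_to_volumes(fixture_records)
        tr = vols[vols["marker"] == "H3_WATER"]
        for row in tr.itertuples():
            expected = np.exp(-FIXTURE_K_ABS[row.region] * row.time_min)
            assert row.remaining_fraction == pytest.approx(expected, rel=1e-12)

    def test_surface_normalisation(self, fixture_records):
        vols = records_to_volumes(fixture_records, surface_area_cm2=11.2)
        np.testing.assert_allclose(
            vols["volume_per_cm2"], vols["volume_ml"] / 11.2, rtol=1e-12
        )

    def test_per_region_surface_mapping(self, fixture_records):
        s_map = {"jejunum": 11.2, "ileum": 11.2, "colon": 7.84}
        vols = records_to_volumes(fixture_records, surface_area_cm2=s_map)
        colon = vols[vols["region"] == "colon"]
        np.testing.assert_allclose(
            colon["volume_per_cm2"], colon["volume_ml"] / 7.84, rtol=1e-12
        )


class TestSummarize:
    def test_mean_and_sem_hand_computed(self):
        obs = pd.DataFrame(
            {
                "region": "jejunum",
                "marker": "FD4",
                "time_min": 5.0,
                "remaining_fraction": [0.5, 0.6, 0.7],
            }
        )
        out = summarize_timecourse(obs)
        assert out.loc[0, "mean_fraction"] == pytest.approx(0.6)
        assert out.loc[0, "sem_fraction"] == pytest.approx(0.1 / np.sqrt(3), rel=1e-9)
        assert out.loc[0, "n"] == 3

    def test_single_animal_sem_undefined_not_zero(self):
        obs = pd.DataFrame(
            {"region": "colon", "marker": "FD4", "time_min": 10.0,
             "remaining_fraction": [0.42]}
        )
        out = summarize_timecourse(obs)
        assert out.loc[0, "mean_fraction"] == pytest.approx(0.42)
        assert np.isnan(out.loc[0, "sem_fraction"])

    def test_identical_values_sem_zero(self):
        obs = pd.DataFrame(
            {"region": "ileum", "marker": "FD4", "time_min": 20.0,
             "remaining_fraction": [0.3, 0.3, 0.3]}
        )
        assert summarize_timecourse(obs).loc[0, "sem_fraction"] == pytest.approx(0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            summarize_timecourse(pd.DataFrame(columns=["region", "marker", "time_min", "remaining_fraction"]))
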