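"""Generator tests: morphology model, waveform rendering, cohort simulation, IO."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgaging.synthetic import (
    INTERVAL_MODEL,
    LEAD_NAMES,
    CohortConfig,
    EcgRecord,
    MorphologyParams,
    beat_fiducials,
    generator_r_times,
    morphology_from_age,
    read_cohort,
    simulate_cohort,
    simulate_ecg,
    write_cohort,
)


class TestMorphology:
    def test_affine_interval_model_no_jitter(self):
        m = morphology_from_age(60.0, "male", rng=None, heart_rate=60.0)
        assert m.p_duration == pytest.approx(85.0 + 0.35 * 60.0)
        assert m.pr_interval == pytest.approx(130.0 + 0.60 * 60.0)
        assert m.qrs_duration == pytest.approx(80.0 + 0.25 * 60.0)
        # at 60 bpm RR = 1 s so QT equals the QTc model value
        assert m.qt_interval == pytest.approx(360.0 + 0.70 * 60.0)

    def test_female_qtc_offset(self):
        mm = morphology_from_age(50.0, "male", heart_rate=60.0)
        mf = morphology_from_age(50.0, "female", heart_rate=60.0)
        assert mf.qt_interval - mm.qt_interval == pytest.approx(10.0)

    def test_qt_scales_with_sqrt_rr(self):
        slow = morphology_from_age(50.0, "male", heart_rate=50.0)
        fast = morphology_from_age(50.0, "male", heart_rate=100.0)
        assert slow.qt_interval / fast.qt_interval == pytest.approx(np.sqrt(2.0))

    def test_r_progression_increases_with_age(self):
        young = morphology_from_age(20.0, "male")
        old = morphology_from_age(95.0, "male")
        assert young.r_progression < old.r_progression
        assert young.r_progression == pytest.approx((20.0 - 18.0) / 82.0)

    def test_age_range_enforced(self):
        with pytest.raises(ValueError):
            morphology_from_age(10.0, "male")
        with pytest.raises(ValueError):
            morphology_from_age(101.0, "female")
        with pytest.raises(ValueError):
            morphology_from_age(50.0, "other")

    def test_jitter_is_seeded(self):
        a = morphology_from_age(50.0, "male", rng=np.random.default_rng(5))
        b = morphology_from_age(50.0, "male", rng=np.random.default_rng(5))
        assert a.p_duration == b.p_duration and a.heart_rate == b.heart_rate

    def test_invalid_params_rejected(self):
        m = morphology_from_age(50.0, "male")
        bad = {**m.__dict__}
        bad["pr_interval"] = bad["p_duration"] - 1.0
        with pytest.raises(ValueError):
            MorphologyParams(**bad)

    @given(age=st.floats(18.0, 100.0), female=st.booleans())
    @settings(max_examples=50, deadline=None)
    def test_intervals_ordered_across_ages(self, age, female):
        m = morphology_from_age(age, "female" if female else "male", heart_rate=65.0)
        assert 0 < m.p_duration <= m.pr_interval
        assert m.qrs_duration < m.qt_interval
        assert 0.0 <= m.r_progression <= 1.0


class TestWaveform:
    def test_r_peak_times_and_amplitudes(self):
        m = morphology_from_age(50.0, "male", heart_rate=60.0)
        rec = simulate_ecg(m, fs=400.0, duration_s=10.0)
        truth = generator_r_times(m, 10.0)
        assert truth.size == 10  # 60 bpm, first R at 0.4 s, tail 0.45 s
        lead_ii = rec.signals[1]
        for r in truth:
            i = int(round(r * 400.0))
            # R bump peaks at the nominal time with the template amplitude
            assert lead_ii[i] == pytest.approx(m.lead_amplitudes["R"][1], abs=0.02)

    def test_five_percent_amplitude_at_nominal_qrs_boundary(self):
        # sigma = W / (2 sqrt(2 ln 20)) puts the envelope at exactly 5% of the
        # peak at W/2 from the centre
        m = morphology_from_age(50.0, "male", heart_rate=60.0)
        rec = simulate_ecg(m, fs=2000.0, duration_s=2.0)
        fid = beat_fiducials(m)
        r = generator_r_times(m, 2.0)[0]
        i_on = int(round((r + fid["qrs_onset"]) * 2000.0))
        i_peak = int(round(r * 2000.0))
        ratio = rec.signals[1, i_on] / rec.signals[1, i_peak]
        assert ratio == pytest.approx(0.05, abs=0.01)

    def test_noise_free_is_deterministic(self):
        m = morphology_from_age(40.0, "female", heart_rate=70.0)
        a = simulate_ecg(m, noise_sd=0.0)
        b = simulate_ecg(m, noise_sd=0.0)
        np.testing.assert_array_equal(a.signals, b.signals)

    def test_noise_is_seeded(self):
        m = morphology_from_age(40.0, "female", heart_rate=70.0)
        a = simulate_ecg(m, noise_sd=0.02, seed=3)
        b = simulate_ecg(m, noise_sd=0.02, seed=3)
        c = simulate_ecg(m, noise_sd=0.02, seed=4)
        np.testing.assert_array_equal(a.signals, b.signals)
        assert not np.array_equal(a.signals, c.signals)

    def test_record_shape_validation(self):
        with pytest.raises(ValueError):
            EcgRecord(np.zeros((3, 100)), fs=400.0)
        with pytest.raises(ValueError):
            EcgRecord(np.zeros((12, 100)), fs=-1.0)

    def test_record_too_short(self):
        m = morphology_from_age(50.0, "male")
        with pytest.raises(ValueError):
            simulate_ecg(m, duration_s=0.5)


class TestCohort:
    def test_reproducible_and_schema(self, table_cohort):
        cfg, table = table_cohort
        again, _ = simulate_cohort(CohortConfig(n_subjects=cfg.n_subjects, seed=cfg.seed),
                                   with_records=False)
        pd.testing.assert_frame_equal(table, again)
        for col in ("subject_id", "exam_index", "age_at_exam", "is_female", "died",
                    "time_at_risk", "group_true", "hypertension", "will_develop_af"):
            assert col in table.columns

    def test_exam_structure(self, table_cohort):
        _, table = table_cohort
        base = table[table["exam_index"] == 0]
        fup = table[table["exam_index"] == 1]
        assert len(base) == 2000
        # follow-up exams happen 5-6 years after baseline for survivors only
        assert fup["exam_time_years"].between(5.0, 6.0).all()
        gap = fup.set_index("subject_id")["age_at_exam"] - base.set_index("subject_id")[
            "age_at_exam"
        ].loc[fup["subject_id"]]
        assert gap.between(5.0, 6.0).all()
        # anyone missing a follow-up exam died before it
        missing = set(base["subject_id"]) - set(fup["subject_id"])
        died_early = base[base["subject_id"].isin(missing)]
        assert (died_early["died"] == 1).all()
        assert (died_early["death_time_years"] <= 6.0).all()

    def test_time_at_risk_anchored_per_exam(self, table_cohort):
        _, table = table_cohort
        assert (table["time_at_risk"] >= 0).all()
        merged = table.pivot_table(index="subject_id", columns="exam_index",
                                   values="time_at_risk")
        both = merged.dropna()
        np.testing.assert_allclose(
            both[0] - both[1],
            table[table["exam_index"] == 1].set_index("subject_id")["exam_time_years"].loc[
                both.index
            ],
        )

    def test_group_matches_offset(self, table_cohort):
        _, table = table_cohort
        d = table["aging_offset_true"]
        expect = np.where(d > 8.0, "over", np.where(d < -8.0, "under", "correct"))
        assert (table["group_true"] == expect).all()

    def test_offset_mixture_proportions(self, table_cohort):
        _, table = table_cohort
        base = table[table["exam_index"] == 0]
        frac = base["group_true"].value_counts(normalize=True)
        # thirds mixture at +/-14 with sds 4-5 puts roughly a third in each group
        for g in ("over", "correct", "under"):
            assert 0.22 < frac[g] < 0.45

    def test_covariate_prevalences(self, table_cohort):
        cfg, table = table_cohort
        base = table[table["exam_index"] == 0]
        for name, p in cfg.covariate_prevalence.items():
            assert base[name].mean() == pytest.approx(p, abs=0.05)
        assert base["is_female"].mean() == pytest.approx(cfg.female_fraction, abs=0.04)

    def test_mortality_gradient_across_groups(self, table_cohort):
        _, table = table_cohort
        base = table[table["exam_index"] == 0]
        rate = base.groupby("group_true")["died"].mean()
        assert rate["over"] > rate["correct"] > rate["under"]

    def test_incidence_undefined_when_prevalent_or_no_followup(self, table_cohort):
        _, table = table_cohort
        base = table[table["exam_index"] == 0]
        assert base.loc[base["af_prevalent"] == 1, "will_develop_af"].isna().all()
        no_fup = ~base["subject_id"].isin(table.loc[table["exam_index"] == 1, "subject_id"])
        assert base.loc[no_fup, "will_develop_af"].isna().all()

    def test_serial_hazard_multipliers_change_late_mortality(self):
        base_cfg = CohortConfig(n_subjects=1500, seed=9)
        hot = {(a, b): 1.0 for a in ("over", "correct", "under")
               for b in ("over", "correct", "under")}
        hot[("over", "over")] = 4.0
        alt_cfg = CohortConfig(n_subjects=1500, seed=9, serial_hazard_multipliers=hot)
        t0, _ = simulate_cohort(base_cfg, with_records=False)
        t1, _ = simulate_cohort(alt_cfg, with_records=False)
        oo = (t1["exam_index"] == 1) & (t1["group_true"] == "over")
        base_oo = (t0["exam_index"] == 1) & (t0["group_true"] == "over")
        assert t1.loc[oo, "died"].mean() > t0.loc[base_oo, "died"].mean()


class TestIO:
    def test_wfdb_roundtrip(self, tmp_path, small_cohort):
        _, table, records = small_cohort
        out = write_cohort(table, records, tmp_path / "cohort")
        table2, records2 = read_cohort(out)
        assert len(records2) == len(records)
        by_key = {(r.subject_id, r.exam_index): r for r in records2}
        for rec in records:
            got = by_key[(rec.subject_id, rec.exam_index)]
            assert got.fs == rec.fs
            # format-16 storage quantises to 1/adc_gain mV = 1 uV
            np.testing.assert_allclose(got.signals, rec.signals, atol=5.1e-4)
            assert got.age_at_exam == pytest.approx(rec.age_at_exam, abs=1e-3)
        assert sorted(table2.columns) == sorted(table.columns)
        assert len(table2) == len(table)

    def test_lead_names_order(self):
        assert LEAD_NAMES[1] == "II" and LEAD_NAMES[6] == "V1" and LEAD_NAMES[10] == "V5"
        assert len(LEAD_NAMES) == 12
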