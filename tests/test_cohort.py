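"""Cohort data model: I/O round trips, PTA, effective N, aggregation, filters."""

import numpy as np
import pytest

import bimodal_shift as bs
from bimodal_shift.cohort import (CohortValidationError, MissingFrequencyError,
                                  NotTestableError)
from conftest import make_session


MINIMAL_SUBJECTS = "subject_id,site_id,gender\nA,site1,female\n"
MINIMAL_SESSIONS = (
    "subject_id,phase,months_since_surgery,ha_verification,"
    "thr_500hz,thr_1000hz,thr_2000hz,"
    "nonimplanted_test_id,nonimplanted_percent_correct,nonimplanted_n_lists\n"
    "A,pre,0,aided_unaided_thresholds,60,70,80,cnc_words,44,1\n"
    "A,post,12,aided_unaided_thresholds,60,70,80,cnc_words,34,1\n"
)


def write_files(tmp_path, subjects=MINIMAL_SUBJECTS, sessions=MINIMAL_SESSIONS):
    sp, xp = tmp_path / "subjects.csv", tmp_path / "sessions.csv"
    sp.write_text(subjects)
    xp.write_text(sessions)
    return sp, xp


class TestReadWrite:
    def test_minimal_cohort(self, tmp_path):
        cohort = bs.read_cohort(*write_files(tmp_path))
        assert len(cohort) == 1
        assert len(cohort.sessions_for("A", "pre")) == 1
        assert len(cohort.sessions_for("A", "post")) == 1
        rec = cohort.pre_session("A").score_for("nonimplanted")
        assert rec.percent_correct == 44.0
        assert cohort.pre_session("A").audiogram_nonimplanted[1000] == 70.0

    def test_out_of_range_percent_named_with_row(self, tmp_path):
        bad = MINIMAL_SESSIONS.replace(",44,", ",101,")
        with pytest.raises(CohortValidationError) as exc:
            bs.read_cohort(*write_files(tmp_path, sessions=bad))
        assert any("row 2" in e and "percent_correct" in e
                   for e in exc.value.errors)

    def test_duplicate_session_key_rejected(self, tmp_path):
        dup = MINIMAL_SESSIONS + "A,post,12,aided_unaided_thresholds,60,70,80,cnc_words,30,1\n"
        with pytest.raises(CohortValidationError) as exc:
            bs.read_cohort(*write_files(tmp_path, sessions=dup))
        assert any("duplicate" in e for e in exc.value.errors)

    def test_unknown_subject_rejected(self, tmp_path):
        extra = MINIMAL_SESSIONS + "ZZ,pre,0,unknown,60,70,80,cnc_words,10,1\n"
        with pytest.raises(CohortValidationError) as exc:
            bs.read_cohort(*write_files(tmp_path, sessions=extra))
        assert any("unknown subject_id" in e for e in exc.value.errors)

    def test_synthetic_round_trip(self, tmp_path):
        cohort = bs.generate(bs.study_like_config(seed=5, n_subjects=40))
        sp, xp = tmp_path / "s.csv", tmp_path / "x.csv"
        bs.write_cohort(cohort, sp, xp)
        back = bs.read_cohort(sp, xp)
        assert back.subjects == cohort.subjects
        assert back.sessions == cohort.sessions


class TestPureToneAverage:
    def test_arithmetic_mean(self):
        assert bs.pure_tone_average({500: 60, 1000: 70, 2000: 80}) == 70.0

    def test_constant_thresholds(self):
        assert bs.pure_tone_average({500: 55, 1000: 55, 2000: 55}) == 55.0

    def test_missing_frequency_is_an_error(self):
        with pytest.raises(MissingFrequencyError):
            bs.pure_tone_average({500: 60, 2000: 80}, (500, 1000, 2000))


class TestEffectiveN:
    def test_word_test_counts_items(self, registry):
        rec = bs.SpeechScoreRecord("nonimplanted", "cnc_words", 50.0, 1)
        assert bs.effective_n(rec, registry) == 50

    def test_sentence_keywords_use_conservative_override(self, registry):
        rec = bs.SpeechScoreRecord("nonimplanted", "cuny_sentences", 50.0, 3)
        assert bs.effective_n(rec, registry) == 40

    def test_multiple_word_lists_sum(self, registry):
        rec = bs.SpeechScoreRecord("nonimplanted", "monosyllable_25", 50.0, 2)
        assert bs.effective_n(rec, registry) == 50

    def test_unregistered_test_rejected(self, registry):
        rec = bs.SpeechScoreRecord("nonimplanted", "mystery", 50.0, 1)
        with pytest.raises(KeyError):
            bs.effective_n(rec, registry)


class TestAggregatePost:
    def _cohort(self, triples):
        sessions = [make_session("A", "pre", 0.0, ha_score=44.0)]
        sessions += [make_session("A", "post", m, ha_score=s, n_lists=nl)
                     for m, s, nl in triples]
        return bs.Cohort(subjects={"A": bs.Subject("A")}, sessions=sessions)

    def test_average_of_three_lists(self, registry):
        cohort = self._cohort([(6, 40.0, 1), (12, 50.0, 1), (24, 60.0, 1)])
        obs = bs.aggregate_post(cohort, "A", "nonimplanted", "average", registry)
        assert obs.p == pytest.approx(0.50)
        assert obs.n == 150

    def test_latest_single_session(self, registry):
        cohort = self._cohort([(6, 34.0, 1)])
        obs = bs.aggregate_post(cohort, "A", "nonimplanted", "latest", registry)
        assert (obs.p, obs.n) == (0.34, 50)

    def test_latest_picks_chronologically_last(self, registry):
        cohort = self._cohort([(1, 60.0, 1), (24, 30.0, 1)])
        obs = bs.aggregate_post(cohort, "A", "nonimplanted", "latest", registry)
        assert obs.p == 0.30

    def test_average_of_identical_scores_is_that_score(self, registry):
        cohort = self._cohort([(6, 42.0, 1), (12, 42.0, 1)])
        obs = bs.aggregate_post(cohort, "A", "nonimplanted", "average", registry)
        assert obs.p == pytest.approx(0.42)

    def test_no_usable_score_signals(self, registry):
        cohort = bs.Cohort(subjects={"A": bs.Subject("A")},
                           sessions=[make_session("A", "pre", 0.0, ha_score=44.0)])
        with pytest.raises(NotTestableError):
            bs.aggregate_post(cohort, "A", "nonimplanted", "average", registry)


class TestFilters:
    def test_pta_rise_excluded_at_10_kept_at_20(self, tiny_cohort):
        # subject B's post session rose by 12 dB PTA
        crit10 = bs.FilterCriteria(False, 10.0, "increase")
        crit20 = bs.FilterCriteria(False, 20.0, "increase")
        f10, log10 = bs.apply_filters(tiny_cohort, crit10)
        f20, log20 = bs.apply_filters(tiny_cohort, crit20)
        post_b10 = f10.sessions_for("B", "post")[0]
        post_b20 = f20.sessions_for("B", "post")[0]
        assert post_b10.score_for("nonimplanted") is None
        assert post_b20.score_for("nonimplanted") is not None
        assert any(e.reason == "pta_change_exceeded" for e in log10)
        assert not log20

    def test_absolute_mode_excludes_improvements_too(self):
        base = {500: 60.0, 1000: 70.0, 2000: 80.0}
        better = {500: 30.0, 1000: 40.0, 2000: 50.0}  # -30 dB change
        cohort = bs.Cohort(
            subjects={"A": bs.Subject("A")},
            sessions=[make_session("A", "pre", 0.0, ha_score=40.0, audiogram=base),
                      make_session("A", "post", 6.0, ha_score=42.0,
                                   audiogram=better)])
        f_abs, _ = bs.apply_filters(cohort, bs.FilterCriteria(False, 25.0, "absolute"))
        f_inc, _ = bs.apply_filters(cohort, bs.FilterCriteria(False, 25.0, "increase"))
        assert f_abs.sessions_for("A", "post")[0].score_for("nonimplanted") is None
        assert f_inc.sessions_for("A", "post")[0].score_for("nonimplanted") is not None

    def test_unverified_session_dropped_when_required(self, tiny_cohort):
        crit = bs.FilterCriteria(require_ha_verified=True)
        filtered, log = bs.apply_filters(tiny_cohort, crit)
        assert filtered.sessions_for("B", "post") == []
        assert any(e.reason == "ha_verification_unknown" for e in log)
        # subject A's verified sessions survive
        assert len(filtered.sessions_for("A", "post")) == 2

    def test_original_cohort_untouched(self, tiny_cohort):
        before = len([s for s in tiny_cohort.sessions if s.phase == "post"])
        bs.apply_filters(tiny_cohort, bs.FilterCriteria(True, 5.0, "increase"))
        after = len([s for s in tiny_cohort.sessions if s.phase == "post"])
        assert before == after

    def test_cascade_monotone_on_synthetic_cohort(self, study_cohort, registry):
        survivors = []
        for _, criteria in bs.study_subsets():
            filtered, _ = bs.apply_filters(study_cohort, criteria)
            n = 0
            for sid in filtered.subjects:
                try:
                    bs.aggregate_post(filtered, sid, "nonimplanted", "average",
                                      registry)
                    n += 1
                except NotTestableError:
                    pass
            survivors.append(n)
        assert survivors == sorted(survivors, reverse=True)
        assert survivors[0] == 132
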