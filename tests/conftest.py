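import pytest
from hypothesis import settings

import bimodal_shift as bs

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return bs.default_registry()


@pytest.fixture(scope="session")
def study_cohort():
    """One study-shaped synthetic cohort (132 subjects), shared read-only."""
    return bs.generate(bs.study_like_config(seed=11))


def make_session(subject_id, phase, months, ha_score=None, ci_score=None,
                 bi_score=None, audiogram=None, verification="aided_unaided_thresholds",
                 test_id="cnc_words", n_lists=1, ha_cnt=False, ci_cnt=False):
    """Hand-build a session with any subset of the three conditions."""
    scores = []
    if ci_score is not None or ci_cnt:
        scores.append(bs.SpeechScoreRecord("implanted", test_id,
                                           None if ci_cnt else ci_score,
                                           n_lists, could_not_test=ci_cnt))
    if ha_score is not None or ha_cnt:
        scores.append(bs.SpeechScoreRecord("nonimplanted", test_id,
                                           None if ha_cnt else ha_score,
                                           n_lists, could_not_test=ha_cnt))
    if bi_score is not None:
        scores.append(bs.SpeechScoreRecord("bilateral", test_id, bi_score,
                                           n_lists))
    return bs.SessionRecord(
        subject_id=subject_id, phase=phase, months_since_surgery=months,
        audiogram_nonimplanted=audiogram or {500: 60.0, 1000: 70.0, 2000: 80.0},
        ha_verification=verification, scores=scores)


@pytest.fixture
def tiny_cohort():
    """Two subjects: one clean, one with unknown verification + PTA rise."""
    subjects = {
        "A": bs.Subject(subject_id="A", gender="female", age_at_implant=60.0),
        "B": bs.Subject(subject_id="B", gender="male", age_at_implant=55.0),
    }
    base = {500: 60.0, 1000: 70.0, 2000: 80.0}
    risen = {500: 72.0, 1000: 82.0, 2000: 92.0}  # +12 dB PTA
    sessions = [
        make_session("A", "pre", 0.0, ha_score=44.0, ci_score=10.0,
                     bi_score=50.0, audiogram=base),
        make_session("A", "post", 6.0, ha_score=40.0, ci_score=70.0,
                     bi_score=72.0, audiogram=base),
        make_session("A", "post", 24.0, ha_score=34.0, ci_score=80.0,
                     bi_score=78.0, audiogram=base),
        make_session("B", "pre", 0.0, ha_score=50.0, ci_cnt=True,
                     audiogram=base, verification="unknown"),
        make_session("B", "post", 12.0, ha_score=30.0, ci_score=60.0,
                     audiogram=risen, verification="unknown"),
    ]
    return bs.Cohort(subjects=subjects, sessions=sessions)
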