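"""Longitudinal cohort data model, CSV I/O, and the inclusion-filter cascade.

A cohort is a set of subjects (demographics, device metadata) plus a list of
evaluation sessions.  Each session carries the phase (pre- or postoperative),
time since surgery, the unaided audiogram of the nonimplanted ear, how the
hearing aid's function was verified, and speech scores in up to three
conditions: implanted ear alone, nonimplanted (hearing-aid) ear alone, and
both together (bilateral).

Scores are percent correct on a named test.  The effective number of
statistically independent items behind a score drives all significance
computations: word tests contribute ``n_lists * items_per_list`` items;
sentence tests scored by keywords are assigned a conservative effective N
(40) regardless of the nominal keyword count, because keywords within a
sentence are not independent.

The filter cascade mirrors the study design: postoperative nonimplanted-ear
datapoints are dropped when the pure-tone average (PTA) moved too far from
the preoperative baseline, and whole sessions are dropped when hearing-aid
function could not be verified.  Every removal is logged with its reason so
that every N in downstream tables is auditable.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .critdiff import ScoreObservation

log = logging.getLogger(__name__)

__all__ = [
    "CONDITIONS",
    "VERIFICATION_METHODS",
    "Subject",
    "SpeechScoreRecord",
    "SessionRecord",
    "Cohort",
    "TestRegistryEntry",
    "default_registry",
    "FilterCriteria",
    "Exclusion",
    "CohortValidationError",
    "MissingFrequencyError",
    "NotTestableError",
    "read_cohort",
    "write_cohort",
    "pure_tone_average",
    "effective_n",
    "aggregate_post",
    "apply_filters",
    "DEFAULT_PTA_FREQUENCIES",
]

CONDITIONS = ("implanted", "nonimplanted", "bilateral")
VERIFICATION_METHODS = (
    "in_ear",
    "aided_unaided_thresholds",
    "aided_unaided_speech",
    "clinician_report",
    "unknown",
)
#: Conventional three-frequency pure-tone average.
DEFAULT_PTA_FREQUENCIES = (500, 1000, 2000)

_THRESHOLD_RANGE = (-10.0, 130.0)


class CohortValidationError(ValueError):
    """Raised with the full list of row-level validation problems."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("cohort validation failed:\n" + "\n".join(self.errors))


class MissingFrequencyError(KeyError):
    """A PTA was requested at a frequency absent from the audiogram."""


class NotTestableError(ValueError):
    """No usable score exists for the requested subject/condition/phase."""


@dataclass
class Subject:
    subject_id: str
    site_id: str = "site1"
    gender: str = ""
    age_at_implant: float | None = None
    age_at_moderate_loss: float | None = None
    age_at_profound_loss: float | None = None
    etiology: str = ""
    device_brand: str = ""
    electrode: str = ""
    processor: str = ""
    implanted_side: str = ""          # "left" | "right"
    surgical_approach: str = ""       # "cochleostomy" | "round_window"
    preop_ha_in_implanted_ear: bool | None = None
    education_years: float | None = None
    # Preoperative PTAs not derivable from the session audiograms (which
    # cover the nonimplanted ear only); used by the demographic screen.
    preop_aided_pta_implanted: float | None = None
    preop_unaided_pta_implanted: float | None = None
    preop_aided_pta_nonimplanted: float | None = None


@dataclass
class SpeechScoreRecord:
    condition: str
    test_id: str
    percent_correct: float | None = None
    n_lists: int = 1
    could_not_test: bool = False

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.could_not_test == (self.percent_correct is not None):
            raise ValueError(
                "exactly one of percent_correct / could_not_test must be set")
        if self.percent_correct is not None and not 0 <= self.percent_correct <= 100:
            raise ValueError(f"percent_correct out of [0, 100]: {self.percent_correct}")
        if self.n_lists < 1:
            raise ValueError("n_lists must be >= 1")


@dataclass
class SessionRecord:
    subject_id: str
    phase: str                       # "pre" | "post"
    months_since_surgery: float
    audiogram_nonimplanted: dict[int, float] = field(default_factory=dict)
    ha_verification: str = "unknown"
    scores: list[SpeechScoreRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.phase not in ("pre", "post"):
            raise ValueError(f"phase must be pre/post, got {self.phase!r}")
        if self.phase == "pre" and self.months_since_surgery != 0:
            raise ValueError("preoperative sessions must have months_since_surgery=0")
        if self.months_since_surgery < 0:
            raise ValueError("months_since_surgery must be >= 0")
        if self.ha_verification not in VERIFICATION_METHODS:
            raise ValueError(f"unknown ha_verification {self.ha_verification!r}")
        for f, thr in self.audiogram_nonimplanted.items():
            if not _THRESHOLD_RANGE[0] <= thr <= _THRESHOLD_RANGE[1]:
                raise ValueError(f"threshold {thr} dB HL at {f} Hz out of range")

    def score_for(self, condition: str) -> SpeechScoreRecord | None:
        for s in self.scores:
            if s.condition == condition:
                return s
        return None


@dataclass
class Cohort:
    subjects: dict[str, Subject]
    sessions: list[SessionRecord]

    def __len__(self) -> int:
        return len(self.subjects)

    def sessions_for(self, subject_id: str, phase: str | None = None
                     ) -> list[SessionRecord]:
        out = [s for s in self.sessions if s.subject_id == subject_id]
        if phase is not None:
            out = [s for s in out if s.phase == phase]
        return out

    def pre_session(self, subject_id: str) -> SessionRecord | None:
        pres = self.sessions_for(subject_id, "pre")
        return pres[0] if pres else None

    def copy(self) -> "Cohort":
        return Cohort(subjects=copy.deepcopy(self.subjects),
                      sessions=copy.deepcopy(self.sessions))


@dataclass(frozen=True)
class TestRegistryEntry:
    test_id: str
    scoring_unit: str                # "words" | "keywords"
    items_per_list: int
    effective_n_override: int | None = None

    def __post_init__(self) -> None:
        if self.scoring_unit not in ("words", "keywords"):
            raise ValueError(f"unknown scoring_unit {self.scoring_unit!r}")
        if self.scoring_unit == "keywords" and self.effective_n_override is None:
            raise ValueError(
                f"keyword test {self.test_id!r} needs an effective_n_override")


def default_registry() -> dict[str, TestRegistryEntry]:
    """Registry of the test materials the synthetic cohort draws from.

    Sentence keyword tests carry an effective-N override of 40 items — the
    conservative convention for keyword scoring — no matter how many
    keywords a list nominally contains.
    """
    entries = [
        TestRegistryEntry("cnc_words", "words", 50),
        TestRegistryEntry("monosyllable_25", "words", 25),
        TestRegistryEntry("cuny_sentences", "keywords", 102, effective_n_override=40),
        TestRegistryEntry("tam_sentences", "keywords", 120, effective_n_override=40),
        TestRegistryEntry("azbio_sentences", "keywords", 142, effective_n_override=40),
    ]
    return {e.test_id: e for e in entries}


def effective_n(score: SpeechScoreRecord,
                registry: Mapping[str, TestRegistryEntry]) -> int:
    """Effective number of independent items behind a score."""
    try:
        entry = registry[score.test_id]
    except KeyError:
        raise KeyError(f"test_id {score.test_id!r} not in registry") from None
    if entry.scoring_unit == "keywords":
        return int(entry.effective_n_override)
    return int(score.n_lists * entry.items_per_list)


def pure_tone_average(audiogram: Mapping[int, float],
                      frequencies: Sequence[int] = DEFAULT_PTA_FREQUENCIES) -> float:
    """Arithmetic mean of thresholds (dB HL) at the requested frequencies.

    Missing frequencies raise; thresholds are never imputed.
    """
    missing = [f for f in frequencies if f not in audiogram]
    if missing:
        raise MissingFrequencyError(
            f"audiogram lacks thresholds at {missing} Hz")
    return float(np.mean([audiogram[f] for f in frequencies]))


def aggregate_post(cohort: Cohort, subject_id: str, condition: str,
                   method: str, registry: Mapping[str, TestRegistryEntry]
                   ) -> ScoreObservation:
    """Collapse a subject's postoperative scores for one condition.

    ``method="latest"`` returns the chronologically last score with its own
    effective n.  ``method="average"`` returns the unweighted mean of the
    per-session proportions with an effective n equal to the sum of the
    per-session effective n (one 50-word list per session over three
    sessions yields n = 150).
    """
    if method not in ("average", "latest"):
        raise ValueError(f"method must be average/latest, got {method!r}")
    usable: list[tuple[float, float, int]] = []  # (months, proportion, n)
    for sess in cohort.sessions_for(subject_id, "post"):
        rec = sess.score_for(condition)
        if rec is None or rec.could_not_test:
            continue
        usable.append((sess.months_since_surgery,
                       rec.percent_correct / 100.0,
                       effective_n(rec, registry)))
    if not usable:
        raise NotTestableError(
            f"no usable postoperative {condition} score for {subject_id}")
    if method == "latest":
        latest_month = max(m for m, _, _ in usable)
        candidates = [(m, p, n) for m, p, n in usable if m == latest_month]
        if len(candidates) > 1:
            log.warning("subject %s: %d sessions tie for latest (month %.3g); "
                        "keeping the last in file order",
                        subject_id, len(candidates), latest_month)
        _, p, n = candidates[-1]
        return ScoreObservation(p=p, n=n)
    props = [p for _, p, _ in usable]
    total_n = int(sum(n for _, _, n in usable))
    return ScoreObservation(p=float(np.mean(props)), n=total_n)


# ---------------------------------------------------------------------------
# Inclusion filters


@dataclass(frozen=True)
class FilterCriteria:
    """Declarative inclusion rules for postoperative datapoints.

    ``pta_change_mode="absolute"`` drops a datapoint when |post PTA − pre
    PTA| exceeds the bound (the study's baseline 25 dB design rule);
    ``"increase"`` drops only when the PTA *worsened* by more than the bound
    (the 20/10/5 dB follow-up rules).
    """

    require_ha_verified: bool = False
    max_pta_increase_db: float = 25.0
    pta_change_mode: str = "absolute"      # "absolute" | "increase"
    pta_frequencies: tuple[int, ...] = DEFAULT_PTA_FREQUENCIES

    def __post_init__(self) -> None:
        if self.pta_change_mode not in ("absolute", "increase"):
            raise ValueError(f"unknown pta_change_mode {self.pta_change_mode!r}")


@dataclass(frozen=True)
class Exclusion:
    subject_id: str
    months_since_surgery: float
    scope: str       # "session" | "nonimplanted_datapoint"
    reason: str
    detail: str = ""


def apply_filters(cohort: Cohort, criteria: FilterCriteria
                  ) -> tuple[Cohort, list[Exclusion]]:
    """Apply the inclusion rules; return the surviving cohort + exclusion log.

    Verification failures remove the whole postoperative session (the
    hearing aid is involved in both the nonimplanted and bilateral
    conditions); PTA violations remove only the session's nonimplanted-ear
    datapoint, matching datapoint-level exclusion.  Filters are total: an
    unevaluable PTA (missing audiogram frequencies) excludes the datapoint
    with its own logged reason rather than passing it silently.
    """
    out = cohort.copy()
    exclusions: list[Exclusion] = []
    pre_pta: dict[str, float | None] = {}
    for sid in out.subjects:
        pre = out.pre_session(sid)
        try:
            pre_pta[sid] = (pure_tone_average(pre.audiogram_nonimplanted,
                                              criteria.pta_frequencies)
                            if pre is not None else None)
        except MissingFrequencyError:
            pre_pta[sid] = None

    kept_sessions: list[SessionRecord] = []
    for sess in out.sessions:
        if sess.phase == "pre":
            kept_sessions.append(sess)
            continue
        if criteria.require_ha_verified and sess.ha_verification == "unknown":
            exclusions.append(Exclusion(
                sess.subject_id, sess.months_since_surgery, "session",
                "ha_verification_unknown"))
            continue
        if sess.score_for("nonimplanted") is not None:
            baseline = pre_pta.get(sess.subject_id)
            try:
                post_pta = pure_tone_average(sess.audiogram_nonimplanted,
                                             criteria.pta_frequencies)
            except MissingFrequencyError:
                post_pta = None
            if baseline is None or post_pta is None:
                sess.scores = [s for s in sess.scores
                               if s.condition != "nonimplanted"]
                exclusions.append(Exclusion(
                    sess.subject_id, sess.months_since_surgery,
                    "nonimplanted_datapoint", "pta_unevaluable"))
            else:
                change = post_pta - baseline
                violated = (abs(change) > criteria.max_pta_increase_db
                            if criteria.pta_change_mode == "absolute"
                            else change > criteria.max_pta_increase_db)
                if violated:
                    sess.scores = [s for s in sess.scores
                                   if s.condition != "nonimplanted"]
                    exclusions.append(Exclusion(
                        sess.subject_id, sess.months_since_surgery,
                        "nonimplanted_datapoint", "pta_change_exceeded",
                        detail=f"change={change:+.1f} dB, "
                               f"bound={criteria.max_pta_increase_db} dB "
                               f"({criteria.pta_change_mode})"))
        kept_sessions.append(sess)
    out.sessions = kept_sessions
    return out, exclusions


# ---------------------------------------------------------------------------
# Delimited-text I/O
#
# subjects.csv: one row per subject.
# sessions.csv: one row per session; audiogram in wide columns thr_<freq>hz;
# per-condition score columns <condition>_test_id / _percent_correct /
# _n_lists / _could_not_test.  Percentages are on the 0-100 scale.

SUBJECT_COLUMNS = [
    "subject_id", "site_id", "gender", "age_at_implant",
    "age_at_moderate_loss", "age_at_profound_loss", "etiology",
    "device_brand", "electrode", "processor", "implanted_side",
    "surgical_approach", "preop_ha_in_implanted_ear", "education_years",
    "preop_aided_pta_implanted", "preop_unaided_pta_implanted",
    "preop_aided_pta_nonimplanted",
]
SESSION_BASE_COLUMNS = ["subject_id", "phase", "months_since_surgery",
                        "ha_verification"]

_SUBJECT_OPTIONAL_FLOATS = [
    "age_at_implant", "age_at_moderate_loss", "age_at_profound_loss",
    "education_years", "preop_aided_pta_implanted",
    "preop_unaided_pta_implanted", "preop_aided_pta_nonimplanted",
]


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def read_cohort(subjects_path, sessions_path) -> Cohort:
    """Read the two-file CSV schema; raise with all row-numbered problems."""
    errors: list[str] = []
    sdf = pd.read_csv(subjects_path)
    missing = [c for c in ("subject_id",) if c not in sdf.columns]
    if missing:
        raise CohortValidationError(
            [f"subjects file lacks mandatory column(s) {missing}"])
    subjects: dict[str, Subject] = {}
    for i, row in sdf.iterrows():
        rowno = i + 2  # header is line 1
        sid = str(row["subject_id"])
        if sid in subjects:
            errors.append(f"subjects row {rowno}: duplicate subject_id {sid!r}")
            continue
        try:
            kwargs = {}
            for col in _SUBJECT_OPTIONAL_FLOATS:
                if col in sdf.columns:
                    kwargs[col] = _opt_float(row[col])
            for col in ("site_id", "gender", "etiology", "device_brand",
                        "electrode", "processor", "implanted_side",
                        "surgical_approach"):
                if col in sdf.columns and not pd.isna(row[col]):
                    kwargs[col] = str(row[col])
            if "preop_ha_in_implanted_ear" in sdf.columns:
                kwargs["preop_ha_in_implanted_ear"] = _opt_bool(
                    row["preop_ha_in_implanted_ear"])
            subj = Subject(subject_id=sid, **kwargs)
            a_mod, a_prof = subj.age_at_moderate_loss, subj.age_at_profound_loss
            if a_mod is not None and a_mod < 0:
                raise ValueError("age_at_moderate_loss negative")
            if a_mod is not None and a_prof is not None and a_mod > a_prof:
                raise ValueError("age_at_moderate_loss > age_at_profound_loss")
            subjects[sid] = subj
        except (ValueError, TypeError) as exc:
            errors.append(f"subjects row {rowno}: {exc}")

    xdf = pd.read_csv(sessions_path)
    missing = [c for c in SESSION_BASE_COLUMNS if c not in xdf.columns]
    if missing:
        raise CohortValidationError(
            errors + [f"sessions file lacks mandatory column(s) {missing}"])
    thr_cols = {c: int(c[len("thr_"):-len("hz")])
                for c in xdf.columns
                if c.startswith("thr_") and c.endswith("hz")}
    sessions: list[SessionRecord] = []
    seen_keys: set[tuple[str, str, float]] = set()
    for i, row in xdf.iterrows():
        rowno = i + 2
        sid = str(row["subject_id"])
        if sid not in subjects:
            errors.append(f"sessions row {rowno}: unknown subject_id {sid!r}")
            continue
        try:
            key = (sid, str(row["phase"]), float(row["months_since_surgery"]))
            if key in seen_keys:
                raise ValueError(f"duplicate session key {key}")
            seen_keys.add(key)
            audiogram = {}
            for col, freq in thr_cols.items():
                v = _opt_float(row[col])
                if v is not None:
                    audiogram[freq] = v
            scores = []
            for cond in CONDITIONS:
                tcol = f"{cond}_test_id"
                if tcol not in xdf.columns or pd.isna(row[tcol]):
                    continue
                cnt = False
                if f"{cond}_could_not_test" in xdf.columns:
                    cnt = bool(_opt_bool(row[f"{cond}_could_not_test"]) or False)
                pc = _opt_float(row.get(f"{cond}_percent_correct"))
                nl = row.get(f"{cond}_n_lists")
                nl = 1 if nl is None or pd.isna(nl) else int(nl)
                scores.append(SpeechScoreRecord(
                    condition=cond, test_id=str(row[tcol]),
                    percent_correct=pc, n_lists=nl, could_not_test=cnt))
            sessions.append(SessionRecord(
                subject_id=sid, phase=str(row["phase"]),
                months_since_surgery=float(row["months_since_surgery"]),
                audiogram_nonimplanted=audiogram,
                ha_verification=str(row["ha_verification"]),
                scores=scores))
        except (ValueError, TypeError) as exc:
            errors.append(f"sessions row {rowno}: {exc}")
    if errors:
        raise CohortValidationError(errors)
    return Cohort(subjects=subjects, sessions=sessions)


def write_cohort(cohort: Cohort, subjects_path, sessions_path) -> None:
    """Write the two-file CSV schema; read_cohort() round-trips the result."""
    srows = []
    for s in cohort.subjects.values():
        srows.append({
            "subject_id": s.subject_id, "site_id": s.site_id,
            "gender": s.gender, "age_at_implant": s.age_at_implant,
            "age_at_moderate_loss": s.age_at_moderate_loss,
            "age_at_profound_loss": s.age_at_profound_loss,
            "etiology": s.etiology, "device_brand": s.device_brand,
            "electrode": s.electrode, "processor": s.processor,
            "implanted_side": s.implanted_side,
            "surgical_approach": s.surgical_approach,
            "preop_ha_in_implanted_ear": s.preop_ha_in_implanted_ear,
            "education_years": s.education_years,
            "preop_aided_pta_implanted": s.preop_aided_pta_implanted,
            "preop_unaided_pta_implanted": s.preop_unaided_pta_implanted,
            "preop_aided_pta_nonimplanted": s.preop_aided_pta_nonimplanted,
        })
    pd.DataFrame(srows, columns=SUBJECT_COLUMNS).to_csv(subjects_path, index=False)

    freqs = sorted({f for sess in cohort.sessions
                    for f in sess.audiogram_nonimplanted})
    cols = list(SESSION_BASE_COLUMNS) + [f"thr_{f}hz" for f in freqs]
    for cond in CONDITIONS:
        cols += [f"{cond}_test_id", f"{cond}_percent_correct",
                 f"{cond}_n_lists", f"{cond}_could_not_test"]
    xrows = []
    for sess in cohort.sessions:
        row: dict = {
            "subject_id": sess.subject_id, "phase": sess.phase,
            "months_since_surgery": sess.months_since_surgery,
            "ha_verification": sess.ha_verification,
        }
        for f in freqs:
            row[f"thr_{f}hz"] = sess.audiogram_nonimplanted.get(f)
        for rec in sess.scores:
            row[f"{rec.condition}_test_id"] = rec.test_id
            row[f"{rec.condition}_percent_correct"] = rec.percent_correct
            row[f"{rec.condition}_n_lists"] = rec.n_lists
            row[f"{rec.condition}_could_not_test"] = rec.could_not_test
        xrows.append(row)
    pd.DataFrame(xrows, columns=cols).to_csv(sessions_path, index=False)


def exclusions_frame(exclusions: Iterable[Exclusion]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"subject_id": e.subject_id,
          "months_since_surgery": e.months_since_surgery,
          "scope": e.scope, "reason": e.reason, "detail": e.detail}
         for e in exclusions],
        columns=["subject_id", "months_since_surgery", "scope", "reason",
                 "detail"])
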