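"""Synthetic bimodal-cohort generator.

The multicenter data behind the analysis are not publicly deposited, so the
pipeline is exercised on synthetic cohorts that reproduce the *statistical
structure* the analysis assumes:

* per-subject latent (true) proportion-correct scores per condition, with a
  preoperative hearing-aid-ear mean around 0.44;
* observed percent-correct scores that are binomial draws at the session
  test's effective item count — exactly the noise model the
  critical-difference procedure assumes;
* 1-11 postoperative sessions per subject (mean ≈ 2.5) over a follow-up
  averaging ≈ 37 months;
* a latent postoperative change in the hearing-aid ear,
  ``change_i = β0 + β1·advantage_i + ε_i`` in percentage points (post − pre,
  so a decline is negative; advantage-linked decline means β1 < 0);
* slow unaided-threshold progression with a heavy right tail (mean ≈ 2.5 dB,
  occasional subjects exceeding 20 dB), so the PTA filter cascade has work
  to do;
* preoperative could-not-test rates for the implanted-ear and bilateral
  conditions, and the study's mix of hearing-aid verification methods.

``study_like_config`` targets those figures; ``null_config`` switches off
every true change so that flagged subjects are pure false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cohort import Cohort, SessionRecord, SpeechScoreRecord, Subject

__all__ = ["SimConfig", "generate", "null_config", "study_like_config"]

_ETIOLOGIES = {  # study-shaped etiology mix
    "unknown": 52, "genetic": 19, "noise": 14, "otosclerosis": 13,
    "menieres": 4, "meningitis": 4, "progressive": 4, "ssnhl": 4,
    "chronic_otitis_media": 3, "head_trauma": 3, "ototoxicity": 3, "other": 9,
}
_BRANDS = {"cochlear": 76, "medel": 25, "ab": 21, "neurelec": 10}
_AUDIOGRAM_SLOPE = {250: -15.0, 500: -7.0, 1000: 0.0, 2000: 7.0, 4000: 12.0}


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the generator.

    Score parameters are proportions in [0, 1]; change-model parameters are
    percentage points; thresholds are dB HL; times are months.
    """

    n_subjects: int = 132
    seed: int = 0

    # session structure: 1 + min(Poisson(rate), max_sessions - 1) sessions
    session_rate: float = 1.5
    max_sessions: int = 11
    followup_mean_months: float = 37.1
    followup_log_sd: float = 0.8
    followup_min_months: float = 1.0
    followup_max_months: float = 132.0

    # latent true scores (proportions)
    preop_ha_score_mean: float = 0.44
    preop_ha_score_sd: float = 0.22
    preop_ci_score_mean: float = 0.08
    preop_ci_score_sd: float = 0.07
    postop_ci_score_mean: float = 0.65
    postop_ci_score_sd: float = 0.18

    # hearing-aid-ear change model (percentage points; decline is negative)
    decline_intercept: float = -3.5
    decline_advantage_slope: float = -0.18
    decline_noise_sd: float = 8.0

    # unaided-threshold progression: zero-inflated exponential total rise
    pta_zero_prob: float = 0.6
    pta_progression_mean_db: float = 6.25
    audiogram_base_mean_db: float = 70.0
    audiogram_base_sd_db: float = 10.0
    audiogram_jitter_sd_db: float = 1.0
    audiogram_frequencies: tuple[int, ...] = (250, 500, 1000, 2000, 4000)

    # test material mix
    word_test_prob: float = 0.75
    word_test_id: str = "cnc_words"
    sentence_test_id: str = "cuny_sentences"
    n_lists: int = 1

    # preoperative could-not-test probabilities
    p_cnt_ci: float = 29 / 132
    p_cnt_bilateral: float = 41 / 132

    # hearing-aid verification mix (thresholds / report / unknown)
    verification_probs: tuple[float, float, float] = (81 / 132, 41 / 132, 10 / 132)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("preop_ha_score_sd", "preop_ci_score_sd",
                     "postop_ci_score_sd", "decline_noise_sd",
                     "audiogram_base_sd_db", "audiogram_jitter_sd_db",
                     "followup_log_sd", "pta_progression_mean_db"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("word_test_prob", "p_cnt_ci", "p_cnt_bilateral",
                     "pta_zero_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(sum(self.verification_probs) - 1) > 1e-9:
            raise ValueError("verification_probs must sum to 1")
        if not 1 <= self.max_sessions:
            raise ValueError("max_sessions must be >= 1")


def study_like_config(**overrides) -> SimConfig:
    """Preset emulating the study cohort's summary structure.

    132 subjects; sessions 1-11 with mean ≈ 2.5; follow-up mean ≈ 37 months;
    preoperative hearing-aid-ear true scores with mean ≈ 0.44; mean PTA
    progression ≈ 2.5 dB with a heavy right tail; preoperative
    could-not-test rates 29/132 (implanted) and 41/132 (bilateral);
    verification mix 81/41/10 of 132.  The change-model defaults give a
    group-mean decline near the observed scale with an advantage-linked
    component.
    """
    return replace(SimConfig(), **overrides)


def null_config(**overrides) -> SimConfig:
    """No true change anywhere: decline model and PTA progression zeroed.

    Any subject flagged significant on such a cohort is a false positive,
    which makes this the calibration preset.
    """
    base = SimConfig(decline_intercept=0.0, decline_advantage_slope=0.0,
                     decline_noise_sd=0.0, pta_zero_prob=1.0,
                     audiogram_jitter_sd_db=0.0)
    return replace(base, **overrides)


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    return np.clip(rng.normal(mean, sd, size=size), lo, hi)


def _observed(rng, true_p: float, n_eff: int) -> float:
    """Observed percent correct: binomial measurement error at n_eff items."""
    return rng.binomial(n_eff, true_p) / n_eff * 100.0


def generate(config: SimConfig) -> Cohort:
    """Draw one cohort; byte-identical for identical config (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    subjects: dict[str, Subject] = {}
    sessions: list[SessionRecord] = []

    etio_names = list(_ETIOLOGIES)
    etio_p = np.array(list(_ETIOLOGIES.values()), dtype=float)
    etio_p /= etio_p.sum()
    brand_names = list(_BRANDS)
    brand_p = np.array(list(_BRANDS.values()), dtype=float)
    brand_p /= brand_p.sum()
    sites = ["nyu"] + [f"site{i}" for i in range(2, 9)]
    site_p = np.array([53.0] + [79.0 / 7] * 7)
    site_p /= site_p.sum()
    verification_levels = ("aided_unaided_thresholds", "clinician_report",
                           "unknown")

    for i in range(config.n_subjects):
        sid = f"S{i + 1:03d}"
        age_implant = float(_truncnorm(rng, 56.8, 15.0, 15.0, 89.0))
        age_moderate = max(0.0, age_implant - float(rng.uniform(5, 35)))
        age_profound = float(rng.uniform(age_moderate, age_implant))
        subj = Subject(
            subject_id=sid,
            site_id=str(rng.choice(sites, p=site_p)),
            gender="male" if rng.random() < 68 / 132 else "female",
            age_at_implant=round(age_implant, 1),
            age_at_moderate_loss=round(age_moderate, 1),
            age_at_profound_loss=round(age_profound, 1),
            etiology=str(rng.choice(etio_names, p=etio_p)),
            device_brand=str(rng.choice(brand_names, p=brand_p)),
            electrode="std", processor="std",
            implanted_side="left" if rng.random() < 0.5 else "right",
            surgical_approach=("cochleostomy" if rng.random() < 0.5
                               else "round_window"),
            preop_ha_in_implanted_ear=bool(rng.random() < 0.5),
            education_years=round(float(_truncnorm(rng, 14, 3, 6, 22)), 1),
            preop_aided_pta_implanted=round(float(_truncnorm(rng, 45, 10, 20, 90)), 1),
            preop_unaided_pta_implanted=round(float(_truncnorm(rng, 95, 12, 60, 120)), 1),
            preop_aided_pta_nonimplanted=round(float(_truncnorm(rng, 40, 8, 15, 80)), 1),
        )
        subjects[sid] = subj

        test_id = (config.word_test_id if rng.random() < config.word_test_prob
                   else config.sentence_test_id)
        verification = str(rng.choice(verification_levels,
                                      p=config.verification_probs))

        # latent scores
        s_ha_pre = float(_truncnorm(rng, config.preop_ha_score_mean,
                                    config.preop_ha_score_sd, 0.01, 0.99))
        s_ci_pre = float(_truncnorm(rng, config.preop_ci_score_mean,
                                    config.preop_ci_score_sd, 0.0, 0.6))
        s_ci_post = float(_truncnorm(rng, config.postop_ci_score_mean,
                                     config.postop_ci_score_sd, 0.02, 0.98))
        advantage_pct = 100.0 * (s_ci_post - s_ha_pre)
        eps = float(rng.normal(0.0, config.decline_noise_sd)) \
            if config.decline_noise_sd > 0 else 0.0
        change_pct = (config.decline_intercept
                      + config.decline_advantage_slope * advantage_pct + eps)
        s_ha_post = float(np.clip(s_ha_pre + change_pct / 100.0, 0.005, 0.995))
        s_bi_pre = float(np.clip(max(s_ha_pre, s_ci_pre)
                                 + rng.uniform(0.0, 0.05), 0.0, 0.99))
        s_bi_post = float(np.clip(max(s_ci_post, s_ha_post)
                                  + rng.uniform(0.0, 0.08), 0.0, 0.995))

        cnt_ci = rng.random() < config.p_cnt_ci
        cnt_bi = rng.random() < config.p_cnt_bilateral

        # timeline
        n_post = 1 + int(min(rng.poisson(config.session_rate),
                             config.max_sessions - 1))
        followup = float(np.clip(
            rng.lognormal(np.log(config.followup_mean_months)
                          - config.followup_log_sd ** 2 / 2,
                          config.followup_log_sd),
            config.followup_min_months, config.followup_max_months))
        if n_post == 1:
            months = np.round(np.array([followup]), 2)
        else:
            months = np.sort(rng.uniform(config.followup_min_months, followup,
                                         size=n_post - 1))
            months = np.round(np.append(months, followup), 2)
            months = np.unique(months)  # collapse coincident visits

        # audiograms
        base = {f: float(np.clip(
            rng.normal(config.audiogram_base_mean_db,
                       config.audiogram_base_sd_db) + _AUDIOGRAM_SLOPE[f],
            -10.0, 120.0)) for f in config.audiogram_frequencies}
        pta_rise = 0.0 if rng.random() < config.pta_zero_prob \
            else float(rng.exponential(config.pta_progression_mean_db))

        def audiogram_at(month: float) -> dict[int, float]:
            frac = month / followup if followup > 0 else 0.0
            out = {}
            for f, thr in base.items():
                jitter = (rng.normal(0.0, config.audiogram_jitter_sd_db)
                          if config.audiogram_jitter_sd_db > 0 else 0.0)
                out[f] = round(float(np.clip(thr + pta_rise * frac + jitter,
                                             -10.0, 130.0)), 1)
            return out

        def score(condition, true_p, cnt=False) -> SpeechScoreRecord:
            if cnt:
                return SpeechScoreRecord(condition=condition, test_id=test_id,
                                         n_lists=config.n_lists,
                                         could_not_test=True)
            n_eff = _effective_n_for(test_id, config.n_lists)
            return SpeechScoreRecord(condition=condition, test_id=test_id,
                                     percent_correct=_observed(rng, true_p, n_eff),
                                     n_lists=config.n_lists)

        sessions.append(SessionRecord(
            subject_id=sid, phase="pre", months_since_surgery=0.0,
            audiogram_nonimplanted=audiogram_at(0.0),
            ha_verification=verification,
            scores=[score("implanted", s_ci_pre, cnt=cnt_ci),
                    score("nonimplanted", s_ha_pre),
                    score("bilateral", s_bi_pre, cnt=cnt_bi)]))
        for m in months:
            sessions.append(SessionRecord(
                subject_id=sid, phase="post", months_since_surgery=float(m),
                audiogram_nonimplanted=audiogram_at(float(m)),
                ha_verification=verification,
                scores=[score("implanted", s_ci_post),
                        score("nonimplanted", s_ha_post),
                        score("bilateral", s_bi_post)]))
    return Cohort(subjects=subjects, sessions=sessions)


def _effective_n_for(test_id: str, n_lists: int) -> int:
    from .cohort import SpeechScoreRecord, default_registry, effective_n
    rec = SpeechScoreRecord(condition="nonimplanted", test_id=test_id,
                            percent_correct=0.0, n_lists=n_lists)
    return effective_n(rec, default_registry())
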