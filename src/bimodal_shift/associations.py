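"""Correlates of the nonimplanted-ear speech-score change.

The change in the nonimplanted (hearing-aid) ear's speech score (post − pre,
percentage points; a drop is negative) is correlated with candidate
explanatory variables:

* the change in unaided pure-tone average of the same ear (progressive
  hearing loss would predict a negative association between PTA increase
  and score change);
* the postoperative speech score in the implanted ear and the implanted-ear
  advantage (implanted minus nonimplanted score) — central "neglect" of the
  poorer ear would predict larger drops when the implant side dominates;
* a screen of preoperative demographic variables.

Pearson product-moment correlations carry two-tailed p-values from the t
distribution on n−2 degrees of freedom.  The first-order partial
correlation removes a shared driver (e.g. the postoperative hearing-aid
score) via

    r_xy.z = (r_xy − r_xz·r_yz) / sqrt((1 − r_xz²)(1 − r_yz²))

with p from t on n−3 degrees of freedom.  All change variables are built
from hearing-aid-verified datapoints only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (Cohort, DEFAULT_PTA_FREQUENCIES, FilterCriteria,
                     MissingFrequencyError, NotTestableError,
                     TestRegistryEntry, aggregate_post, apply_filters,
                     pure_tone_average)

log = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "UndefinedCorrelationError",
    "pearson",
    "partial_correlation",
    "build_change_variables",
    "demographic_screen",
]


class UndefinedCorrelationError(ValueError):
    """A correlation was requested on data with zero variance."""


@dataclass(frozen=True)
class AssociationResult:
    x_label: str
    y_label: str
    r: float
    p_value: float
    n: int
    control_label: str | None = None


def _clean_pairs(*vectors):
    arrs = [np.asarray(v, dtype=float) for v in vectors]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("vectors must be paired (equal length)")
    mask = np.all(np.isfinite(np.vstack(arrs)), axis=0)
    return [a[mask] for a in arrs]


def pearson(x: Sequence[float], y: Sequence[float],
            x_label: str = "x", y_label: str = "y") -> AssociationResult:
    """Product-moment correlation, two-tailed p on n−2 df."""
    x, y = _clean_pairs(x, y)
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError(
            f"zero variance in {x_label if np.std(x) == 0 else y_label}")
    r, p = stats.pearsonr(x, y)
    return AssociationResult(x_label=x_label, y_label=y_label,
                             r=float(r), p_value=float(p), n=n)


def partial_correlation(x: Sequence[float], y: Sequence[float],
                        control: Sequence[float],
                        x_label: str = "x", y_label: str = "y",
                        control_label: str = "control") -> AssociationResult:
    """First-order partial correlation of x and y given one control."""
    x, y, z = _clean_pairs(x, y, control)
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 complete triples, got {n}")
    for v, lbl in ((x, x_label), (y, y_label), (z, control_label)):
        if np.std(v) == 0:
            raise UndefinedCorrelationError(f"zero variance in {lbl}")
    r_xy = float(stats.pearsonr(x, y).statistic)
    r_xz = float(stats.pearsonr(x, z).statistic)
    r_yz = float(stats.pearsonr(y, z).statistic)
    denom = (1 - r_xz ** 2) * (1 - r_yz ** 2)
    if min(1 - r_xz ** 2, 1 - r_yz ** 2) <= 1e-12:
        # An input perfectly collinear with the control leaves a zero
        # residual, which supports no remaining association.
        return AssociationResult(x_label=x_label, y_label=y_label, r=0.0,
                                 p_value=1.0, n=n, control_label=control_label)
    r = (r_xy - r_xz * r_yz) / math.sqrt(denom)
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1 - r ** 2))
        p = float(2 * stats.t.sf(abs(t), df))
    return AssociationResult(x_label=x_label, y_label=y_label, r=r,
                             p_value=p, n=n, control_label=control_label)


def build_change_variables(cohort: Cohort,
                           registry: Mapping[str, TestRegistryEntry],
                           method: str = "average",
                           pta_frequencies=DEFAULT_PTA_FREQUENCIES
                           ) -> pd.DataFrame:
    """Per-subject change variables from hearing-aid-verified datapoints.

    Columns (percent scale for scores, dB for PTA):
      ha_pre, ha_post, ha_change (post − pre), pta_change,
      ci_post (postoperative implanted-ear score, aggregated by ``method``),
      advantage (ci_post − ha_post).
    Subjects missing any constituent are omitted with a log entry.
    """
    verified, _ = apply_filters(
        cohort, FilterCriteria(require_ha_verified=True,
                               max_pta_increase_db=25.0,
                               pta_change_mode="absolute",
                               pta_frequencies=tuple(pta_frequencies)))
    rows = []
    for sid in verified.subjects:
        pre_sess = verified.pre_session(sid)
        if pre_sess is None:
            log.info("change variables: %s dropped (no pre session)", sid)
            continue
        rec = pre_sess.score_for("nonimplanted")
        if rec is None or rec.could_not_test:
            log.info("change variables: %s dropped (no pre HA score)", sid)
            continue
        try:
            ha_post = aggregate_post(verified, sid, "nonimplanted", method,
                                     registry)
        except NotTestableError:
            log.info("change variables: %s dropped (no post HA score)", sid)
            continue
        try:
            ci_post = aggregate_post(verified, sid, "implanted", method,
                                     registry)
            ci_post_pct = ci_post.p * 100.0
        except NotTestableError:
            ci_post_pct = np.nan
        # PTA change over the sessions that still carry a HA-ear datapoint
        try:
            pre_pta = pure_tone_average(pre_sess.audiogram_nonimplanted,
                                        pta_frequencies)
            post_ptas = [
                (s.months_since_surgery,
                 pure_tone_average(s.audiogram_nonimplanted, pta_frequencies))
                for s in verified.sessions_for(sid, "post")
                if s.score_for("nonimplanted") is not None]
            if not post_ptas:
                raise MissingFrequencyError("no post audiogram")
            if method == "latest":
                pta_change = max(post_ptas)[1] - pre_pta
            else:
                pta_change = float(np.mean([p for _, p in post_ptas])) - pre_pta
        except MissingFrequencyError:
            pta_change = np.nan
        ha_post_pct = ha_post.p * 100.0
        rows.append({
            "subject_id": sid,
            "ha_pre": rec.percent_correct,
            "ha_post": ha_post_pct,
            "ha_change": ha_post_pct - rec.percent_correct,
            "pta_change": pta_change,
            "ci_post": ci_post_pct,
            "advantage": ci_post_pct - ha_post_pct,
        })
    return pd.DataFrame(rows, columns=["subject_id", "ha_pre", "ha_post",
                                       "ha_change", "pta_change", "ci_post",
                                       "advantage"])


#: Demographic variables screened against ha_change, with binary codings.
_BINARY_CODINGS = {
    "surgical_approach": {"cochleostomy": 0, "round_window": 1},
    "implanted_side": {"left": 0, "right": 1},
    "gender": {"male": 0, "female": 1},
}


def demographic_screen(cohort: Cohort,
                       registry: Mapping[str, TestRegistryEntry],
                       method: str = "average",
                       pta_frequencies=DEFAULT_PTA_FREQUENCIES
                       ) -> list[AssociationResult]:
    """Correlate the HA-ear score change with preoperative demographics.

    Binary variables are coded 0/1 (point-biserial correlation); missing
    values are dropped pairwise; variables with no usable data or zero
    variance are skipped with a log entry.
    """
    change = build_change_variables(cohort, registry, method=method,
                                    pta_frequencies=pta_frequencies)
    y = change.set_index("subject_id")["ha_change"]

    def subject_value(sid: str, var: str):
        subj = cohort.subjects[sid]
        if var == "preop_unaided_pta_nonimplanted":
            pre = cohort.pre_session(sid)
            if pre is None:
                return np.nan
            try:
                return pure_tone_average(pre.audiogram_nonimplanted,
                                         pta_frequencies)
            except MissingFrequencyError:
                return np.nan
        if var in _BINARY_CODINGS:
            return _BINARY_CODINGS[var].get(getattr(subj, var), np.nan)
        if var == "preop_ha_in_implanted_ear":
            v = subj.preop_ha_in_implanted_ear
            return np.nan if v is None else int(v)
        v = getattr(subj, var)
        return np.nan if v is None else float(v)

    variables = [
        "age_at_implant", "age_at_moderate_loss", "age_at_profound_loss",
        "preop_aided_pta_implanted", "preop_unaided_pta_implanted",
        "preop_aided_pta_nonimplanted", "preop_unaided_pta_nonimplanted",
        "surgical_approach", "implanted_side", "preop_ha_in_implanted_ear",
        "education_years", "gender",
    ]
    out: list[AssociationResult] = []
    for var in variables:
        x = np.array([subject_value(sid, var) for sid in y.index], dtype=float)
        try:
            out.append(pearson(x, y.to_numpy(), x_label=var,
                               y_label="ha_change"))
        except (ValueError, UndefinedCorrelationError) as exc:
            log.info("demographic screen: %s skipped (%s)", var, exc)
    return out
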