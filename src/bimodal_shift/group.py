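"""Group-level pre/post comparisons and the nested-subset analysis.

The group analysis asks whether mean speech scores changed from the
preoperative evaluation to the postoperative ones, on the 0-100 percent
scale.  Paired differences are tested two-tailed with a paired t-test when
they look normal and with the Wilcoxon signed-rank test otherwise; the
normality gate is Shapiro-Wilk on the differences at a configurable alpha.

The nested-subset analysis repeats the comparison under increasingly strict
inclusion rules — all subjects, hearing-aid-verified sessions only, then
postoperative datapoints whose pure-tone average rose by no more than 20,
10, and 5 dB — for both postoperative aggregation methods (average of all
sessions, and latest session).  Surviving-subject counts are non-increasing
down the cascade.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (Cohort, FilterCriteria, NotTestableError,
                     TestRegistryEntry, aggregate_post, apply_filters)

__all__ = [
    "GroupComparison",
    "SubsetSpec",
    "study_subsets",
    "paired_group_test",
    "nested_subset_analysis",
]


@dataclass(frozen=True)
class GroupComparison:
    subset_label: str
    method: str
    n: int
    pre_mean: float
    post_mean: float
    difference: float               # post − pre, percentage points
    test_used: str                  # "paired-t" | "wilcoxon"
    statistic: float
    p_value: float
    normality_p: float | None = None


#: Ordered (label, criteria) pairs defining a nested inclusion cascade.
SubsetSpec = Sequence[tuple[str, FilterCriteria]]


def study_subsets(pta_frequencies=(500, 1000, 2000)) -> list[tuple[str, FilterCriteria]]:
    """The five-row cascade: all subjects (25 dB absolute-change design
    rule), verified hearing aid, then PTA increases capped at 20/10/5 dB."""
    f = pta_frequencies
    return [
        ("All subjects", FilterCriteria(False, 25.0, "absolute", f)),
        ("HA working", FilterCriteria(True, 25.0, "absolute", f)),
        ("<=20 PTA", FilterCriteria(True, 20.0, "increase", f)),
        ("<=10 PTA", FilterCriteria(True, 10.0, "increase", f)),
        ("<=5 PTA", FilterCriteria(True, 5.0, "increase", f)),
    ]


def paired_group_test(pre: Sequence[float], post: Sequence[float],
                      gate_alpha: float = 0.05,
                      subset_label: str = "", method: str = "") -> GroupComparison:
    """Two-tailed paired test of post − pre with a normality gate.

    All-zero differences short-circuit to p = 1 (no evidence of change, no
    test distribution needed); constant nonzero differences short-circuit
    the other way (every subject moved by the same amount).  Wilcoxon drops
    zero differences per the signed-rank convention.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired (equal length)")
    n = len(pre)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    d = post - pre
    base = dict(subset_label=subset_label, method=method, n=n,
                pre_mean=float(pre.mean()), post_mean=float(post.mean()),
                difference=float(d.mean()))
    if np.all(d == 0):
        return GroupComparison(**base, test_used="paired-t", statistic=0.0,
                               p_value=1.0, normality_p=None)
    if np.ptp(d) == 0:
        # identical nonzero shift for every subject: certain change
        return GroupComparison(**base, test_used="paired-t",
                               statistic=float(np.inf) * np.sign(d[0]),
                               p_value=0.0, normality_p=None)
    norm_p = float(stats.shapiro(d).pvalue)
    if norm_p < gate_alpha:
        nz = d[d != 0]
        res = stats.wilcoxon(nz, alternative="two-sided")
        return GroupComparison(**base, test_used="wilcoxon",
                               statistic=float(res.statistic),
                               p_value=float(res.pvalue), normality_p=norm_p)
    res = stats.ttest_rel(post, pre)
    return GroupComparison(**base, test_used="paired-t",
                           statistic=float(res.statistic),
                           p_value=float(res.pvalue), normality_p=norm_p)


def _paired_vectors(cohort: Cohort, condition: str, method: str,
                    registry: Mapping[str, TestRegistryEntry]
                    ) -> tuple[list[str], np.ndarray, np.ndarray]:
    sids, pre_v, post_v = [], [], []
    for sid in cohort.subjects:
        pre_sess = cohort.pre_session(sid)
        if pre_sess is None:
            continue
        rec = pre_sess.score_for(condition)
        if rec is None or rec.could_not_test:
            continue
        try:
            post = aggregate_post(cohort, sid, condition, method, registry)
        except NotTestableError:
            continue
        sids.append(sid)
        pre_v.append(rec.percent_correct)
        post_v.append(post.p * 100.0)
    return sids, np.asarray(pre_v), np.asarray(post_v)


def nested_subset_analysis(cohort: Cohort, subset_spec: SubsetSpec,
                           registry: Mapping[str, TestRegistryEntry],
                           condition: str = "nonimplanted",
                           methods: Sequence[str] = ("average", "latest"),
                           gate_alpha: float = 0.05) -> pd.DataFrame:
    """Run the cascade; one row per subset × method.

    Rows with fewer than 3 surviving pairs are marked not-computable
    (NaN statistics) rather than raising, so a sparse cohort still yields a
    complete table.
    """
    rows = []
    for label, criteria in subset_spec:
        filtered, exclusions = apply_filters(cohort, criteria)
        for method in methods:
            _, pre_v, post_v = _paired_vectors(filtered, condition, method,
                                               registry)
            if len(pre_v) < 3:
                rows.append({"subset_label": label, "method": method,
                             "n": len(pre_v), "pre_mean": np.nan,
                             "post_mean": np.nan, "difference": np.nan,
                             "test_used": "none", "statistic": np.nan,
                             "p_value": np.nan, "n_excluded": len(exclusions)})
                continue
            gc = paired_group_test(pre_v, post_v, gate_alpha=gate_alpha,
                                   subset_label=label, method=method)
            rows.append({"subset_label": gc.subset_label, "method": gc.method,
                         "n": gc.n, "pre_mean": gc.pre_mean,
                         "post_mean": gc.post_mean,
                         "difference": gc.difference,
                         "test_used": gc.test_used,
                         "statistic": gc.statistic, "p_value": gc.p_value,
                         "n_excluded": len(exclusions)})
    return pd.DataFrame(rows)
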