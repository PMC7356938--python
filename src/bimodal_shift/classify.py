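"""Per-subject significance classification and the chance-expectation count.

Each subject contributes one pre/post comparison per condition and
aggregation method: the preoperative score is compared against either the
average of all postoperative scores or the latest one, using the binomial
critical-difference statistic at the scores' effective item counts.  The
verdict is "higher", "lower", or "no_change"; subjects with no preoperative
score (could-not-test) or no surviving postoperative datapoint are
"not_testable" and are excluded from percentage denominators.

Because many subjects are tested at the 5% level without correction, some
flagged changes are expected by chance: ``expected_false_positives`` gives
the expected per-direction count, (alpha/2)·N rounded to the nearest
integer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .cohort import (Cohort, CONDITIONS, NotTestableError, TestRegistryEntry,
                     aggregate_post, effective_n)
from .critdiff import CritDiffConfig, CritDiffResult, ScoreObservation, compare_scores

__all__ = [
    "SubjectVerdict",
    "ClassificationSummary",
    "classify_subject",
    "classify_cohort",
    "expected_false_positives",
    "VERDICT_CATEGORIES",
]

VERDICT_CATEGORIES = ("higher", "lower", "no_change", "not_testable")


@dataclass(frozen=True)
class SubjectVerdict:
    subject_id: str
    condition: str
    method: str
    status: str                      # "classified" | "not_testable"
    pre: ScoreObservation | None = None
    post: ScoreObservation | None = None
    result: CritDiffResult | None = None
    reason: str = ""                 # why not testable, when applicable

    @property
    def category(self) -> str:
        if self.status == "not_testable":
            return "not_testable"
        if self.result.significant:
            return self.result.direction
        return "no_change"


@dataclass(frozen=True)
class ClassificationSummary:
    """Counts of verdicts by condition × method; counts sum to cohort size."""

    n_subjects: int
    counts: Mapping[tuple[str, str], Mapping[str, int]]

    def count(self, condition: str, method: str, category: str) -> int:
        return self.counts[(condition, method)].get(category, 0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (cond, method), c in self.counts.items():
            row = {"condition": cond, "method": method}
            row.update({cat: c.get(cat, 0) for cat in VERDICT_CATEGORIES})
            rows.append(row)
        return pd.DataFrame(rows)


def _not_testable(sid, condition, method, reason) -> SubjectVerdict:
    return SubjectVerdict(subject_id=sid, condition=condition, method=method,
                          status="not_testable", reason=reason)


def classify_subject(cohort: Cohort, subject_id: str, condition: str,
                     method: str, registry: Mapping[str, TestRegistryEntry],
                     cfg: CritDiffConfig = CritDiffConfig()) -> SubjectVerdict:
    """Classify one subject's pre-to-post change in one condition."""
    pre_sess = cohort.pre_session(subject_id)
    if pre_sess is None:
        return _not_testable(subject_id, condition, method, "no_pre_session")
    rec = pre_sess.score_for(condition)
    if rec is None:
        return _not_testable(subject_id, condition, method, "no_pre_score")
    if rec.could_not_test:
        return _not_testable(subject_id, condition, method, "pre_could_not_test")
    pre = ScoreObservation(p=rec.percent_correct / 100.0,
                           n=effective_n(rec, registry))
    try:
        post = aggregate_post(cohort, subject_id, condition, method, registry)
    except NotTestableError:
        return _not_testable(subject_id, condition, method, "no_post_score")
    result = compare_scores(pre, post, cfg)
    return SubjectVerdict(subject_id=subject_id, condition=condition,
                          method=method, status="classified",
                          pre=pre, post=post, result=result)


def classify_cohort(cohort: Cohort, registry: Mapping[str, TestRegistryEntry],
                    cfg: CritDiffConfig = CritDiffConfig(),
                    conditions: Sequence[str] = CONDITIONS,
                    methods: Sequence[str] = ("average", "latest"),
                    ) -> tuple[pd.DataFrame, ClassificationSummary]:
    """Classify every subject; return the per-subject table and the summary.

    The table carries pre/post proportions, effective n, z and verdict per
    subject — the data behind a pre-vs-post scatterplot colored by verdict.
    """
    rows = []
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for cond in conditions:
        for method in methods:
            c = {cat: 0 for cat in VERDICT_CATEGORIES}
            for sid in cohort.subjects:
                v = classify_subject(cohort, sid, cond, method, registry, cfg)
                c[v.category] += 1
                rows.append({
                    "subject_id": sid, "condition": cond, "method": method,
                    "pre_p": v.pre.p if v.pre else None,
                    "pre_n": v.pre.n if v.pre else None,
                    "post_p": v.post.p if v.post else None,
                    "post_n": v.post.n if v.post else None,
                    "z": v.result.z if v.result else None,
                    "category": v.category,
                    "reason": v.reason,
                })
            counts[(cond, method)] = c
    return pd.DataFrame(rows), ClassificationSummary(
        n_subjects=len(cohort), counts=counts)


def expected_false_positives(n_subjects: int, two_tailed_alpha: float = 0.05) -> int:
    """Expected count of per-direction chance flags: round((alpha/2)·N).

    With N subjects each tested two-tailed at level alpha and no true
    change, alpha/2 of them are expected to flag in each direction; the
    expectation is reported rounded to the nearest integer (half away from
    zero).
    """
    if n_subjects < 0:
        raise ValueError("n_subjects must be >= 0")
    if not 0 < two_tailed_alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    import math
    return int(math.floor(two_tailed_alpha / 2 * n_subjects + 0.5))
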