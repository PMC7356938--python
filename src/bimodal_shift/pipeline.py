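"""One-command orchestration: validate → filter → classify → group → assoc.

``run_full_analysis`` reads (or receives) a cohort, classifies every
subject's pre/post change per condition, runs the nested-subset group
analysis, builds the change variables and the correlation program, and
writes everything as CSV plus a machine-readable run manifest.  The run is
deterministic given the config (including its seed), and every excluded
datapoint appears exactly once per subset in the exclusion log.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .associations import (build_change_variables, demographic_screen,
                           partial_correlation, pearson)
from .classify import classify_cohort, expected_false_positives
from .cohort import (Cohort, DEFAULT_PTA_FREQUENCIES, apply_filters,
                     default_registry, exclusions_frame, read_cohort)
from .critdiff import CritDiffConfig
from .group import nested_subset_analysis, study_subsets

__all__ = ["RunConfig", "run_full_analysis"]


@dataclass(frozen=True)
class RunConfig:
    subjects_path: str
    sessions_path: str
    output_dir: str
    seed: int = 0
    iterations: int = 40_000
    critical_z: float = 1.96
    alpha: float = 0.05
    methods: tuple[str, ...] = ("average", "latest")
    association_method: str = "average"
    pta_frequencies: tuple[int, ...] = DEFAULT_PTA_FREQUENCIES
    gate_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("methods", "pta_frequencies"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _association_table(change: pd.DataFrame) -> pd.DataFrame:
    """The correlation program on the change-variable table."""
    rows = []

    def push(res):
        rows.append({"x": res.x_label, "y": res.y_label,
                     "control": res.control_label or "",
                     "r": res.r, "p_value": res.p_value, "n": res.n})

    c = change.dropna(subset=["ha_change"])
    push(pearson(c["pta_change"], c["ha_change"],
                 "pta_change", "ha_change"))
    push(pearson(c["advantage"], c["ha_change"],
                 "advantage", "ha_change"))
    push(partial_correlation(c["advantage"], c["ha_change"], c["ha_post"],
                             "advantage", "ha_change", "ha_post"))
    push(pearson(c["ci_post"], c["ha_change"],
                 "ci_post", "ha_change"))
    return pd.DataFrame(rows)


def run_full_analysis(config: RunConfig,
                      cohort: Cohort | None = None) -> dict[str, object]:
    """Run every stage; write outputs under config.output_dir.

    Returns the in-memory results keyed like the files it writes.  Any
    stage failure aborts with the stage name attached to the exception.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    registry = default_registry()
    cfg = CritDiffConfig(iterations=config.iterations,
                         critical_z=config.critical_z, seed=config.seed)
    subsets = study_subsets(config.pta_frequencies)
    stage = "read"
    try:
        if cohort is None:
            cohort = read_cohort(config.subjects_path, config.sessions_path)

        stage = "classify"
        per_subject, summary = classify_cohort(cohort, registry, cfg,
                                               methods=config.methods)
        summary_df = summary.to_frame()
        summary_df["expected_false_positives_per_direction"] = [
            expected_false_positives(summary.n_subjects, config.alpha)
        ] * len(summary_df)

        stage = "group"
        group_df = nested_subset_analysis(cohort, subsets, registry,
                                          methods=config.methods,
                                          gate_alpha=config.gate_alpha)

        stage = "filter-log"
        logs = []
        for label, criteria in subsets:
            _, exclusions = apply_filters(cohort, criteria)
            df = exclusions_frame(exclusions)
            df.insert(0, "subset_label", label)
            logs.append(df)
        nonempty = [df for df in logs if not df.empty]
        exclusion_df = (pd.concat(nonempty, ignore_index=True) if nonempty
                        else logs[0])

        stage = "assoc"
        change_df = build_change_variables(
            cohort, registry, method=config.association_method,
            pta_frequencies=config.pta_frequencies)
        assoc_df = _association_table(change_df)
        demo = demographic_screen(cohort, registry,
                                  method=config.association_method,
                                  pta_frequencies=config.pta_frequencies)
        demo_df = pd.DataFrame(
            [{"x": r.x_label, "y": r.y_label, "control": "",
              "r": r.r, "p_value": r.p_value, "n": r.n} for r in demo])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    outputs = {
        "classification_subjects": per_subject,
        "classification_summary": summary_df,
        "group_table": group_df,
        "exclusions": exclusion_df,
        "change_variables": change_df,
        "associations": assoc_df,
        "demographic_screen": demo_df,
    }
    for name, df in outputs.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    manifest = {
        "package": "bimodal-shift",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "n_subjects": len(cohort),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    with open(out_dir / "summary.txt", "w") as fh:
        fh.write("bimodal-shift run summary\n")
        fh.write(f"subjects: {len(cohort)}  seed: {config.seed}\n\n")
        fh.write("classification counts:\n")
        fh.write(summary_df.to_string(index=False) + "\n\n")
        fh.write("group table:\n")
        fh.write(group_df.to_string(index=False) + "\n\n")
        fh.write("associations:\n")
        fh.write(assoc_df.to_string(index=False) + "\n")
    outputs["manifest"] = manifest
    return outputs
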