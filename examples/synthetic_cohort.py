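"""Generate a study-shaped synthetic cohort and write the two CSV files.

132 bimodal cochlear-implant users with preoperative and 1-11 postoperative
sessions, binomial speech-score noise, slow threshold progression, and a
built-in advantage-linked decline in the hearing-aid ear.
"""

import numpy as np

from bimodal_shift import generate, study_like_config, pure_tone_average, write_cohort

cohort = generate(study_like_config(seed=42))
write_cohort(cohort, "cohort_subjects.csv", "cohort_sessions.csv")

n_post = [len(cohort.sessions_for(s, "post")) for s in cohort.subjects]
pre_ha = [s.score_for("nonimplanted").percent_correct
          for s in cohort.sessions if s.phase == "pre"]
pre_pta = [pure_tone_average(cohort.pre_session(s).audiogram_nonimplanted)
           for s in cohort.subjects]
print(f"subjects: {len(cohort)}")
print(f"postoperative sessions per subject: mean {np.mean(n_post):.2f}, "
      f"range {min(n_post)}-{max(n_post)}")
print(f"mean preoperative HA-ear score: {np.mean(pre_ha):.1f}%")
print(f"mean preoperative HA-ear PTA: {np.mean(pre_pta):.1f} dB HL")
print("Wrote cohort_subjects.csv / cohort_sessions.csv — the inputs every "
      "other stage consumes.")
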