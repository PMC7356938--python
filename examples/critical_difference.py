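"""Is a drop from 44% to 30% on a 50-word test a real change?

Compares two proportion-correct scores under binomial measurement error,
then prints one row of the critical-range table: the span of second scores
statistically compatible with a first score of 44% on 50 words.
"""

from bimodal_shift import (CritDiffConfig, ScoreObservation, build_table,
                           compare_scores)

pre = ScoreObservation(p=0.44, n=50)
post = ScoreObservation(p=0.30, n=50)
res = compare_scores(pre, post, CritDiffConfig(seed=0))
print(f"44% -> 30% on 50 words: z = {res.z:.3f}, "
      f"significant = {res.significant}, direction = {res.direction}")

# one 50-word list against the average of three (effective n = 150)
post3 = ScoreObservation(p=0.30, n=150)
res3 = compare_scores(pre, post3, CritDiffConfig(seed=0))
print(f"44% -> 30% (avg of three lists): z = {res3.z:.3f}, "
      f"significant = {res3.significant}")

table = build_table(50, 50)
row = table.rows[0.44]
print(f"scores compatible with 44/100 on 50 words: "
      f"{row[0]:.0%} to {row[-1]:.0%} (contiguous: {table.row_contiguous(0.44)})")
print("Anything outside that span would be flagged as a significant change.")
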