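"""Generate the synthetic phosphide-poisoning cohort and check it against
the published tables.

The exact mode rebuilds all 2518 admissions so that every predictor-by-
outcome and predictor-by-poison crosstab matches the published cell counts
bit-exactly; the sampled mode draws i.i.d. records from the same raked
probabilities.
"""

import pandas as pd

from borvm import load_printed_margins, sample_cohort, write_cohort_csv

spec = load_printed_margins()
cohort = sample_cohort(spec, mode="exact", seed=0)

print(f"records: {len(cohort)} (published total {spec.total})")
print(f"deaths:  {(cohort['outcome'] == 'died').sum()} (published 682)")
print()
print("outcome x poison crosstab (published: 708/1128 recovered, 622/60 died):")
print(pd.crosstab(cohort["outcome"], cohort["poison_type"]))
print()
print("silver nitrate x outcome (published: 1145/129 negative, 691/553 positive):")
print(pd.crosstab(cohort["silver_nitrate"], cohort["outcome"]))

write_cohort_csv(cohort, "cohort.csv")
print("\nwrote cohort.csv — a crosstab-exact patient-level reconstruction")
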