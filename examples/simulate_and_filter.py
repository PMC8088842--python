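"""Generate a synthetic cohort and apply the study eligibility filters.

The generator emulates a 16-week mobile weight-loss program: ~92% female,
age ~43, initial weight ~93 kg, BMI >= 25, with five weekly
weight-trajectory archetypes and a known linear outcome model.
"""

import numpy as np

from retainwl import GeneratorConfig, generate_cohort, filter_eligible, outcome_category

cohort = generate_cohort(GeneratorConfig(n_users=300, seed=7))

ages = np.array([p.age for p in cohort.profiles])
weights = np.array([p.initial_weight for p in cohort.profiles])
female = np.mean([p.gender == "female" for p in cohort.profiles])
print(f"cohort: {len(cohort.profiles)} users")
print(f"  age           {ages.mean():5.1f} +- {ages.std():.1f} years")
print(f"  initial weight {weights.mean():5.1f} +- {weights.std():.1f} kg")
print(f"  female         {100 * female:5.1f} %")

eligible, report = filter_eligible(cohort.profiles, cohort.logs)
print("\nexclusion report (every generated user satisfies the filters):")
print(report.summary())

outcomes = {}
for p in eligible:
    final = cohort.weight_series(p.user_id)[-1]
    cat = outcome_category(p.initial_weight, final)
    outcomes[cat] = outcomes.get(cat, 0) + 1
print("\n16-week outcomes (share of users per weight-change band):")
for cat, n in sorted(outcomes.items(), key=lambda kv: -kv[1]):
    print(f"  {cat:12s} {n:4d}  ({100 * n / len(eligible):.1f}%)")
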