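"""Simulate one cohort's natural history and value it.

Builds synthetic parameters for 65-year-old women with CVD and a prior hip
fracture, runs the lifetime Markov trace under usual care, and prints the
discounted lifetime cost and QALYs.  The trace rows are annual state-occupancy
probabilities; cost/QALY are half-cycle-corrected sums discounted at 3.5%/yr.
"""

from exocea import (
    CohortProfile,
    SyntheticSpec,
    generate_parameter_set,
    lifetime_outcomes,
    simulate_cohort,
)

profile = CohortProfile(start_age=65, sex="female", comorbidity="cvd")
bundle = generate_parameter_set(SyntheticSpec(seed=0), profile)

trace = simulate_cohort(bundle.transitions, profile, arm="usual_care")
print(f"cycles simulated: {trace.cycles} (to age {profile.start_age + trace.cycles})")
print("occupancy at years 0, 5, 10 (rows sum to 1):")
print(trace.to_frame().iloc[[0, 5, 10]].round(3).to_string())

out = lifetime_outcomes(
    trace, bundle.utility, bundle.cost, bundle.discount, comorbidity=profile.comorbidity
)
print(f"\nusual care, discounted lifetime: cost £{out.cost:,.0f}, {out.qaly:.2f} QALYs")
print("(synthetic parameters: magnitudes are illustrative, not cohort estimates)")
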