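"""Uncertainty analysis: how certain must the frontier requirements be?

Around each frontier scenario (frozen HR, UR medians) an 8 x 10 grid of
standard errors re-introduces lognormal uncertainty.  For each of the 80
combinations the 95% CIs of HR and UR and the population EVPI (per-person
EVPI x 10-year incident patients in the stratum) are computed; quantile
regressions then describe the CI bounds as a function of population EVPI —
the curves a decision-maker reads to trade acceptable parameter uncertainty
against the value of further research.
"""

from exocea import (
    CohortProfile,
    CostScenario,
    PSASpec,
    SyntheticSpec,
    build_threshold_grid,
    extract_frontier,
    generate_incidence,
    generate_parameter_set,
    run_threshold_sweep,
    run_uncertainty_sweep,
    summarise_ci_vs_evpi,
)

spec = SyntheticSpec(seed=0)
profile = CohortProfile(start_age=65, sex="female", comorbidity="cvd")
bundle = generate_parameter_set(spec, profile)
cost = CostScenario("leasing", 4000.0)
psa = PSASpec(n_draws=200, seed=1)

grid = build_threshold_grid(strata=[profile], cost_scenarios=[cost])
frontier = extract_frontier(
    run_threshold_sweep({profile.label: bundle}, grid, psa)
).head(2)  # two frontier scenarios keep this example quick
print(f"uncertainty sweep: {len(frontier)} frontier scenarios x 80 SE combinations")

unc = run_uncertainty_sweep({profile.label: bundle}, frontier, psa, generate_incidence(spec))
cols = ["hr_median", "ur_median", "hr_se", "ur_se", "hr_ci_lo", "hr_ci_hi",
        "ur_ci_lo", "ur_ci_hi", "population_evpi"]
print(unc[cols].head(4).round(3).to_string(index=False))

fits = summarise_ci_vs_evpi(unc)  # regressor in GBP millions
print("\nmedian-quantile regressions of CI bounds on population EVPI (£m):")
print(fits.round(4).to_string(index=False))
print("\nreading: positive slopes mean wider acceptable intervals come at the")
print("price of a larger expected value of (i.e. need for) further research.")
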