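"""Threshold analysis: which exoskeleton requirements are cost-effective?

The exoskeleton's hazard ratio of falling (HR) and quality-of-life
utility-ratio (UR) are frozen on a 6 x 17 grid; each combination is run
probabilistically (all other parameters drawn) and its ICER computed.  The
frontier lists, per HR, the smallest UR still giving an ICER at or below
£20,000/QALY — the minimum requirements the device must meet.  The heat map
is the probability of cost-effectiveness per grid cell.
"""

from exocea import (
    CohortProfile,
    CostScenario,
    PSASpec,
    SyntheticSpec,
    build_threshold_grid,
    export_heatmap,
    extract_frontier,
    generate_parameter_set,
    run_threshold_sweep,
)

profile = CohortProfile(start_age=65, sex="female", comorbidity="cvd")
bundle = generate_parameter_set(SyntheticSpec(seed=0), profile)
cost = CostScenario("leasing", 4000.0)
grid = build_threshold_grid(strata=[profile], cost_scenarios=[cost])
print(f"running {grid.n_scenarios} scenarios x 200 draws ...")

results = run_threshold_sweep({profile.label: bundle}, grid, PSASpec(n_draws=200, seed=1))
frontier = extract_frontier(results)
print("\nfrontier (per HR, the lowest cost-effective utility-ratio):")
print(frontier[["hr", "ur", "icer"]].round({"icer": 0}).to_string(index=False))

heatmap = export_heatmap(results, profile.label, cost)
print("\nP(cost-effective), HR rows x UR columns (every 4th UR):")
print(heatmap.iloc[:, ::4].round(2).to_string())
print("\nreading: cells left of the frontier are red (never cost-effective),")
print("right of it green; a UR below ~1.25 cannot be rescued by any HR.")
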