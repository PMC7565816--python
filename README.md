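# exocea

Early cost-effectiveness and value-of-information analysis of a
fall-preventing exoskeleton for patients with a prior hip fracture.

## The problem

A second hip fracture (SHF) is more lethal and more expensive than the first,
and patients with dementia or cardiovascular disease (CVD) are at especially
high risk of the falls that cause it. A robotic exoskeleton in development is
expected to reduce falls leading to SHF and to improve quality of life — but
at an early stage there is no trial evidence, only elicited expectations. The
questions a developer and a payer need answered are: *under which assumptions
would the device be cost-effective, what are the minimum requirements it must
meet, and how much uncertainty around those requirements is tolerable before
further research stops being worth paying for?*

`exocea` is a library for answering those questions. It implements:

- a **lifetime Markov cohort model** of hip-fracture natural history — seven
  states crossing clinical status (post-primary, SHF year, major non-hip
  fracture year) with setting (own home / care home, one-way) plus death;
  annual cycles, half-cycle correction, 3.5 %/yr discounting of costs
  (GBP, NHS + personal social services perspective) and QALYs;
- **probabilistic sensitivity analysis** (PSA): beta-distributed
  probabilities and utilities, gamma costs, lognormal ratios, 1000 draws;
- **decision economics**: ICER with full dominance-quadrant handling, net
  monetary benefit at λ = £20,000/QALY, nonparametric percentile CIs;
- **value of information**: per-person EVPI
  `E[max_arm NMB] − max_arm E[NMB]` scaled to the 10-year incident
  population;
- the **two-stage scenario machinery**: a deterministic 6 × 17 grid of the
  exoskeleton's hazard ratio of falling (HR 0.5–1.125) × quality-of-life
  utility-ratio (UR 0.90–1.70) crossed with 12 strata (age 65/75/85 × sex ×
  CVD/dementia) and 8 device cost scenarios (9792 scenarios); extraction of
  the **cost-effectiveness frontier** (per HR, the lowest UR with ICER ≤ λ);
  then an 8 × 10 grid of standard errors around each frontier scenario with
  95 % CIs and population EVPI, summarised by **quantile regressions** of CI
  bounds against population EVPI;
- a **synthetic parameter generator**: the original risk and cost equations
  were fitted to confidential UK administrative data, so the generator
  produces internally consistent stand-ins (age/sex-graded event and
  mortality probabilities, state costs, incidence projections) around the
  published constants (utilities 0.66 / 0.44, comorbidity decrements 4 % /
  26 %, SHF odds ratios 1.89 / 1.32, CCI 2.2, device cost menu). Outputs are
  labelled synthetic and are not reproductions of the original cohort
  estimates.

The exoskeleton's elicited effects enter as lognormals: HR median 0.75 with
log-scale SD = 0.4·|ln 0.75| (95 % interval 0.60–0.94) and UR median 1.70.

## Worked example

```python
from exocea import (CohortProfile, PSASpec, SyntheticSpec,
                    generate_parameter_set, run_psa)

profile = CohortProfile(start_age=65, sex="female", comorbidity="cvd")
bundle = generate_parameter_set(SyntheticSpec(seed=0), profile)
summary = run_psa(bundle, PSASpec(n_draws=1000, seed=1))["summary"]
```

prints (see `examples/base_case_psa.py`):

```
stratum: female_cvd_65 (exoskeleton leased at £6,000/yr)
incremental cost:  £50,135 (95% CI £45,838 to £54,271)
incremental QALYs: 3.08 (95% CI 2.42 to 3.64)
ICER: £16,267/QALY  |  P(cost-effective at £20k): 0.97
per-person EVPI: £176
```

Reading: under the synthetic parameters the device costs ~£50k more over a
65-year-old woman's remaining life but yields ~3 extra QALYs, so at
£16,267/QALY it is below the £20,000 willingness-to-pay; the residual chance
the adoption decision is wrong is worth about £176 per future patient.

The other examples run the downstream stages on one stratum:
`examples/cohort_trace.py` (natural-history trace and its valuation),
`examples/threshold_frontier.py` (102-scenario threshold sweep, frontier and
cost-effectiveness heat map) and `examples/uncertainty_voi.py` (SE grid, CIs
and population EVPI, quantile-regression summary).

## Scope

Parameter estimation from patient-level data, EVPPI, and monthly or
continuous-time cycles are out of scope; model inputs come from a YAML
configuration (`exocea.config`) or the synthetic generator. See
`docs/methods.md` for model assumptions, parameter conventions and known
limitations.
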