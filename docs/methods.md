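# Methods

## Model structure

The natural history of a patient discharged after a primary hip fracture is a
seven-state Markov chain with annual cycles: {post-primary, SHF year, major
non-hip-fracture year} × {own home, care home}, plus absorbing death. The
fracture-year states are tunnels: a new second hip fracture (SHF) or major
non-hip fracture (wrist, spine, humerus requiring hospitalisation) routes the
patient through the corresponding state for exactly one cycle, after which
they return to the post-primary state of the same setting unless they die or
are admitted to a care home. Care-home admission is one-way; the six
carehome→home transition entries are structural zeros, asserted at matrix
construction.

Within a cycle, competing events from a post-primary state are resolved as:
SHF (probability `q1`) and major fracture (`q2`) are exclusive; each fracture
carries a 30-day mortality `d30` applied multiplicatively (`q·d30` to death,
`q·(1−d30)` to the tunnel). Patients with no new fracture face background
annual mortality and then (home setting only) possible care-home admission.
Because no sub-annual structure is specified, the 30-day mortality is
embedded within the annual cycle rather than in a 1/12-cycle sub-model, and
it is attached to fracture events only — care-home admission is an
administrative transition, not a physiological insult, so it carries no
30-day excess mortality. If `q1+q2` ever exceeds 0.98 after adjustment the
pair is rescaled proportionally; every constructed row must sum to 1 within
1e-9 or construction fails.

Two effect transforms are isolated in single functions so the alternative
convention is a one-line change:

- comorbidity enters the SHF probability on the **odds scale**,
  `or·p/(1−p+or·p)`, with OR 1.89 (dementia) and 1.32 (CVD); mortality
  adjustment enters only through the Charlson Comorbidity Index (score 2.2
  for both groups) in the 30-day mortality;
- the exoskeleton's effect enters on the **rate scale**,
  `1−(1−p)^hr`, since hazard ratios act on rates, not probabilities.

The horizon is lifetime: cycles run to age 100, or stop early once living
occupancy falls below 1e-6. Cohorts start in the post-primary home state at
age 65, 75 or 85.

## Valuation

Costs and QALYs are half-cycle-corrected (trapezoidal: the average of
adjacent cycle occupancies — the standard reading of a half-cycle
correction) and discounted at 3.5 %/yr from cycle 0, for both costs and
QALYs. Utilities: 0.66 in post-primary years, 0.44 in any fracture year
(shared by SHF and major non-hip fracture), multiplied by the comorbidity
decrement (0.96 CVD, 0.74 dementia) and, on the intervention arm, by the
exoskeleton utility-ratio. Since 0.66 × 0.96 × 1.70 > 1, adjusted utilities
are capped at 1 (full health) and the capping is logged; capping preserves
the QALY definition at the price of compressing the intervention effect for
mildly-decremented states.

Fracture hospitalisation costs are folded into the effective annual cost of
the tunnel states (state cost + event cost) and valued like all other state
costs on the half-cycle-corrected occupancy. Tunnel occupancy at a cycle
start equals event incidence among 30-day survivors, so this charges each
surviving event once; the hospitalisation costs of patients who die within
30 days are not separately charged — a deliberate simplification that keeps
one valuation code path (noted as a limitation below).

Device costs, intervention arm only:

- **leasing** (£3000/£4000/£5000/£6000 per year): accrued per life-year
  lived, half-cycle corrected — a dead member's device is returned;
- **purchase** (£12,500/£15,000/£17,500/£20,000): irreversible; the full
  price is charged at cycles 0, 5, 10, … (5-year device lifespan) weighted
  by the probability of being alive at the purchase epoch, plus £2500/yr
  maintenance per life-year. This is the only costing that uses all three
  facts defining the purchase scheme (irreversibility, lifespan,
  maintenance).

ICERs are computed from mean incremental cost over mean incremental QALYs.
The dominance logic is exhaustive and exclusive: `zero_effect` (identical
outcomes), `dominant` (no more costly and more effective, or cheaper and no
less effective), `dominated` (the mirror image), else a finite ICER.
Cost-effectiveness at λ = £20,000/QALY: dominant → yes; dominated /
zero-effect → no; ICER with QALY gain → ICER ≤ λ (a tie at exactly λ counts
as cost-effective); ICER in the rarely-reached southwest quadrant (cheaper,
worse) → savings per QALY forgone ≥ λ.

## Probabilistic sensitivity analysis

Distribution families follow standard health-technology-assessment practice:
beta for probabilities and utilities (method of moments from mean and SE),
gamma for costs, lognormal for ratio parameters. Parameters are drawn
independently (no correlation structure is specified). Age gradients and
mortality multipliers are treated as structural constants, not sampled.

The exoskeleton effects are lognormal parameterised by median:

- **hazard ratio**: median 0.75, log-scale SD = 0.40·|ln 0.75| ≈ 0.11507,
  giving a 95 % interval of (0.60, 0.94);
- **utility-ratio**: median 1.70. The "SE inflated by 40 %" description of
  its uncertainty does not pin down a unique scale, and 0.4·ln 1.70 is
  inconsistent with the reported interval (1.46, 1.93). The log-SD is
  therefore exposed as configuration, defaulting to the value that matches
  that interval's width on the log scale,
  (ln 1.93 − ln 1.46)/(2·1.96) ≈ 0.0712. With the median kept at 1.70 the
  implied interval is (1.48, 1.95): the width is honoured, the centre is the
  elicited median.

The base case uses 1000 draws; a convergence check on the running means of
cost and QALYs (stable within 0.5 % relative of the final mean, with
stabilisation required before the last half of the draws) supports that
choice on the synthetic parameters.

Every scenario derives its own seed from a SHA-256 hash of
(master seed, analysis stage, stratum, cost scenario, grid coordinates), so
results are bit-reproducible, independent of execution order, and unchanged
by adding or removing other scenarios. Seeds are 31-bit non-negative
integers.

## Value of information

Per-person EVPI is `E[max_arm NMB] − max_arm E[NMB]` over PSA draws
(non-negative by Jensen's inequality; negative floating-point residue is
clamped). Population EVPI multiplies it by the cumulative 10-year incident
population of the stratum, undiscounted by default — the headline quantities
are plain products of per-person EVPI and cumulative counts — with an
optional discount rate for future cohorts. EVPPI is out of scope.

## Threshold and uncertainty analyses

Threshold stage: HR ∈ {0.5, 0.625, …, 1.125} × UR ∈ {0.90, 0.95, …, 1.70}
are frozen (deterministic) while all other parameters remain probabilistic;
each of the 6·17·12·8 = 9792 combinations of grid point, stratum and cost
scenario is run and its ICER recorded. The frontier keeps, per (stratum,
cost, HR), the lowest UR whose scenario is cost-effective; Monte-Carlo noise
can make the flag non-monotone along UR, in which case the lowest flagged UR
is still taken and the row marked (`monotone_ce=False`). The heat-map export
reports per cell the probability of positive incremental net benefit at λ,
matching a probability colour scale rather than a binary ICER flag.

Uncertainty stage: around each frontier scenario, an 8 × 10 grid of standard
errors re-introduces lognormal uncertainty on HR and UR. The grids' "SE"
values have no stated scale; two conventions are adopted and isolated in one
conversion function each:

- HR grid values 1.05–1.40 are **multiplicative** SEs: `log_sd = ln(se)`
  (values below 1 are rejected; 1.0 means no uncertainty);
- UR grid values 0.25–2.50 are **natural-scale** SEs converted through the
  lognormal moment relation `log_sd = sqrt(ln(1+(se/median)²))`.

These are interpretations, not established facts; changing either is a
one-line edit. Each of the 80 combinations per frontier scenario records the
nonparametric 95 % CIs of the drawn HR and UR and the population EVPI of the
resulting decision. Quantile regressions (pinball loss, via statsmodels
`QuantReg`) then describe each CI bound as a function of population EVPI;
the regressor defaults to GBP millions to keep the fits well conditioned. A
zero-variance regressor leaves the slope undefined and flags the fit.

Nonparametric CIs use linear interpolation between order statistics
(`numpy.percentile`, method "linear").

## Synthetic parameters

The original transition, cost and utility equations were fitted to
confidential UK administrative extracts and are not available. The generator
therefore emulates their *structure*, not their values:

- annual event probabilities anchored at plausible age-65 female values
  (e.g. SHF 0.025/yr at home, care-home admission 0.012/yr rising to
  0.12/yr in a fracture year), multiplied by 1.9 per decade of age for
  events and 2.3 per decade for background mortality (Gompertz-like),
  clamped at 0.95/0.99; men get lower fracture-related probabilities
  (female/male ratio 1.3) and higher mortality (×1.35);
- 30-day post-fracture mortality as a logistic in the CCI score
  (≈ 0.066 at the score of 2.2);
- annual state costs around £1500 (post-primary home) to ~£30–32k (care
  home, residence included), SHF hospitalisation £13k, major fracture £7k,
  all multiplied by a global `cost_scale`;
- published constants embedded verbatim (utilities, decrements, ORs, CCI,
  discount rate, λ, device cost menu);
- all baselines jittered multiplicatively (lognormal, sd 0.05) with a seed
  derived from (seed, age, sex) — comorbidity strata share baselines so the
  comorbidity effect flows only through the OR, the utility decrement and
  the CCI;
- 10-year incidence projections with a 3:1 female:male ratio (men are about
  a quarter of incident hip fractures), 1 %/yr growth;
- standard errors default to 10 % of the mean for probabilities and costs
  and 0.03 absolute for utilities.

`calibrate_soft` bisects `cost_scale` (the one scalar that moves health-care
costs without touching effects or device costs) until the deterministic
base-case ICER of the 65-year-old female CVD stratum lies in a soft band of
£15,000–£30,000 — the order of magnitude a UK early evaluation of this kind
reports — and makes no attempt to hit any specific published number. Under
the default spec the ICER already falls in the band and calibration is a
no-op.

What passing tests on synthetic data do **not** show: that the original
cohort's lifetime costs, QALYs or population EVPI values are reproduced.
Those depend on the unavailable fitted equations; configuration files
written from synthetic bundles carry a provenance note for this reason.

## Problem sizes

The test suite and examples run one stratum and one cost scenario with 200
draws per scenario (102 threshold scenarios plus 80 uncertainty scenarios
per frontier point), which completes in well under a minute and exercises
every stage end-to-end; the full 9792-scenario design at 1000 draws is the
same code path scaled up (about 0.1 s per scenario on one core). The
vectorised engine batches all draws per cycle, so runtime is linear in
scenarios × cycles and nearly flat in draws up to a few thousand.

## Design choices

- Library-first: the public surface is the importable API plus the
  `examples/` scripts; there is no shell CLI, as the pipeline is driven from
  Python and configuration files.
- Tunnel semantics take precedence over matrix-level identities: with all
  event probabilities zero the dynamics are the identity on every reachable
  distribution, but tunnel rows still drain to post-primary (they are
  unreachable in that regime).
- `statsmodels` and `numpy` stand behind the quantile-regression and
  percentile operations; the model, economics, EVPI and scenario machinery
  are implemented here.

## Known limitations

- Hospitalisation costs of patients dying within 30 days of a fracture are
  not charged (tunnel occupancy counts survivors only).
- No parameter correlation; utilities, probabilities and costs are drawn
  independently.
- The utility cap at 1 compresses the intervention's effect precisely in the
  scenarios with high UR and mild decrements, making reported ICERs there
  conservative with respect to QALY gains.
- Care-home admission probabilities use the same per-decade gradient as
  fracture events; real admission risk likely accelerates faster at high
  ages.
- The SE-grid scale conventions (multiplicative for HR, natural for UR) are
  interpretations of an underspecified design.
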