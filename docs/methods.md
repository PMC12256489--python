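# Methods

## The decision problem

Children with epilepsy starting perampanel (PER) either receive therapeutic
drug monitoring (TDM) — monthly plasma-concentration measurement with
protocolized dose adjustment against a 100–1000 ng/mL therapeutic range — or
usual titration by symptoms alone. TDM improves seizure control but adds
testing and, in the source cohort, more intensive service use. The package
asks whether the extra cost buys enough quality-adjusted life years (QALYs)
to be worthwhile from a Chinese health-system perspective, using the
GDP-per-capita thresholds: an ICER below $12,814/QALY is *highly*
cost-effective, below $38,442 *intermediately*, otherwise not; strategies
that cost less and deliver more are *dominant*.

## Clinical outcome model

Outcomes are defined against the baseline 28-day seizure frequency:
seizure freedom is a 100% reduction, response a reduction of at least 50%,
everything else uncontrolled. The 50% boundary is evaluated with the exact
comparison `2·followup ≤ baseline`, so a reduction of exactly half never
falls on the wrong side of a floating-point rounding. Patients who stop PER
before a visit are excluded from that visit's rates (they are modelled as a
separate health state, not imputed as failures).

The arm effect on the ordered outcome (uncontrolled < response < seizure
free) is a proportional-odds cumulative-logit model with the arm indicator
as sole covariate, fitted by maximum likelihood via statsmodels'
`OrderedModel` and then polished with an analytic-gradient BFGS step because
statsmodels differentiates numerically and its MLE is only accurate to about
1e-8 — too coarse for exact likelihood identities such as arm-swap
inversion of the OR, which the polished fit satisfies to ~1e-12. Confidence
intervals and p-values are Wald, from the observed information.

**Known discrepancy.** The published OR is 0.461 (95% CI 0.22–0.965,
p = 0.040). No unadjusted fit to the published 12-month outcome table
reproduces it: the cumulative-logit MLE is 0.293 with the counts as printed,
0.250 with the non-TDM uncontrolled count reconciled (see below), and
adjacent-categories, continuation-ratio, four-category and binary variants
give 0.21–0.42. The published value is internally Wald-consistent
(log 0.461 / SE 0.377 → p = 0.040), so it is evidently the output of a
covariate-adjusted model on patient-level data that is not deposited. The
package reports the fit it can actually perform; the 0.461 enters the
cost-effectiveness model only as the published clinical input parameter it
is.

**Count reconciliation.** The published non-TDM outcome column (8, 10, 4)
sums to 22, contradicting the published completer count (24) and all four
published rates (16.7% = 4/24, 58.3% = 14/24). Uncontrolled = 10 is the
unique value consistent with those; `STUDY_OUTCOME_COUNTS_12M` ships the
reconciled counts with the printed variant alongside.

## Markov cohort model

Four states in fixed order: no response, response, seizure freedom,
discontinuation of PER. Everyone enters in no response. Seizure freedom and
discontinuation are absorbing, as in the source rows ("seizure freedom to
seizure freedom 100%"); discontinued patients keep accruing the costs of
alternative anti-seizure medication. Cycle length is six months; the base
horizon 15 years (30 cycles). A first-cycle transition row governs cycle 1
and a subsequent-phase matrix every later cycle.

### Arm derivation from the odds ratio

The source prints a single set of transition rows plus the arm-contrast OR,
without saying which arm the rows describe or how the OR was applied. All
options are implemented as configuration and resolved by calibration (below):

- `or_mode`: printed rows belong to the TDM arm, the non-TDM arm, or the
  pooled cohort (each arm then shifted half the log-odds, ±√OR).
- `or_includes_discontinue`: the cumulative-logit shift acts on all four
  destinations ordered discontinue < no response < response < seizure free
  (a favourable OR also reduces discontinuation), or only on the three
  on-PER destinations conditional on staying on PER, holding the
  discontinuation probability fixed.
- `or_scope`: the derivation applies to the first-cycle row only, or to
  every non-absorbing row.

The shift itself multiplies every cumulative odds `P(dest > j)/P(dest ≤ j)`
by the OR, which preserves ordering, maps point masses to themselves, and is
exactly inverted by the reciprocal OR.

### Reward accounting

The published totals are not consistent with textbook half-cycle accounting,
and the package reproduces the source's convention deliberately. Two pieces
of internal evidence fix it: (i) between the published 5/10/15-year rows,
both the cost and the QALY increments shrink by a factor of 1.05¹⁰ per ten
cycles, so both were discounted at the annual 5% rate compounded **once per
six-month cycle**; (ii) the published QALY magnitudes (8.66/9.09 over 15
years with utilities ≤ 0.65, and 1.48 over the 1-year horizon) are only
attainable if utility accrues once per cycle **unscaled by cycle length**,
with a reward point at entry. `ModelConfig` therefore carries three flags —
`discount_per_cycle`, `utility_full_cycle`, `include_initial_occupancy` —
defaulting to this source convention; setting all three to their textbook
alternatives (plus the available half-cycle correction) gives conventional
accounting. Cycle 1 (and the entry point) is undiscounted in either mode.
A consequence worth stating: under the source convention the reported
"QALYs" are utility-per-cycle sums, roughly double calendar
quality-adjusted years; the ICER is nevertheless the quantity the source
reports, and increments are consistent within the convention.

### Costs, utilities and adverse events

Per-state per-cycle costs enter as the published totals (non-TDM: 807.08 /
641.99 / 488.70 / 787.31; TDM: 988.95 / 872.10 / 609.16 / 787.31 USD-2022).
The TDM totals exceed their printed components by 18.10 USD = 121.8 RMB at
the study exchange rate of 6.73 — exactly one TDM test per cycle — in every
state, so 18.10 is the per-cycle testing component; the printed "number of
TDM 1.74 × unit price" does not reconcile with the totals and enters only as
a multiplicative perturbation scale in sensitivity analyses. The
hospitalization component identity (probability × number × days × daily
cost = total) holds within 1–2% for five of the six published columns but
fails by 76% for TDM/response; validation reports the identity per column
and the totals govern.

Utilities are SF-6D values shared across arms (0.500 / 0.597 / 0.650 /
0.500). Four mild adverse events (dizziness, somnolence, irritability,
ataxia) apply per cycle while on PER — states no response, response and
seizure freedom, but not discontinuation, whose adverse-event burden is
unmodelled — each contributing probability × $318.70 to cost and
probability × 0.0047 to QALY loss (the disutility is applied at its cited
per-event magnitude, not scaled by cycle length).

### Calibration

The unstated conventions above form a 24-candidate grid (3 `or_mode` ×
2 `or_scope` × 2 `or_includes_discontinue` × source-vs-textbook accounting).
Each candidate is scored against the published base-case and 1/5/10-year
rows: mean relative error over the sixteen per-arm cost/QALY totals plus
mean relative ICER error, equally weighted. The winner — pooled rows,
first-cycle-only derivation, four-category shift, source accounting — is
shipped as `ModelConfig`'s defaults and reproduces the published ICERs to
−4.0% (base), −9.4% (1 y), +0.2% (5 y) and −3.2% (10 y);
`calibration_report()` recomputes the whole table so the selection is
auditable, and no candidate is hidden.

## Sensitivity analyses

### One-way (tornado)

The registry enumerates one factor per (parameter, arm) for every uncertain
input entering each arm's computation: 26 transition cells (13 printed cells
at each arm's derived base values), 78 drug-combination probabilities, 8
adverse-event probabilities, 8 + 8 per-arm copies of the shared
adverse-event costs and disutilities, 8 utilities, 8 state cost totals, 24
hospitalization components, 8 outpatient visit counts, 8 consultation costs
(the discontinuation state mirrors no-response outpatient usage), 2 + 2
test/examination costs, 8 outpatient cost totals, 6 PER state costs, 8
other-ASM costs, 26 combination-drug prices, the PER unit price, the TDM
count and test price, and the OR — 240 factors, matching the source's count.
Ranges are the printed ones where present, else mean ± 1.96 × (20% of mean),
clipped to [0, 1] for probabilities. Each factor is rerun at its low and
high with everything else at base; entries are sorted by ICER spread and a
failed extreme is flagged, never dropped.

Perturbations flow through one assembly path. A perturbed cost *component*
moves its state total by the change in its printed formula (hospitalization
probability × number × days × daily cost; visits × unit costs; drug-mix
share × unit price with shares weighted by probability × price, an
equal-daily-dose approximation forced by the unpublished doses; TDM tests ×
price), anchored so that all printed totals hold exactly at base — which is
also why a degenerate low = high = base range reproduces the base ICER to
1e-8 for every one of the 240 factors. A perturbed transition cell is set
and the rest of its row renormalized proportionally (an absorbing
certainty's remainder is spread evenly, the only coherent option).

### Probabilistic (PSA)

Distribution families follow parameter role: gamma for costs and counts,
beta for probabilities, normal for utilities and outpatient visit counts,
lognormal for the OR (log-scale σ from the CI), gamma on magnitude for the
disutility; all parameterized by method of moments from the base value and
SE (from the 95% range when printed, else 20% of the mean; zero-SE
parameters are point masses, and a beta whose variance exceeds the feasible
bound is shrunk to 99% of it). Each of the 10,000 draws samples the pooled
transition rows cell-wise (rows renormalized to sum to one) and the OR, from
which both arms' rows are re-derived, plus every value parameter; both arms
are rerun and (ΔC, ΔE) recorded. The CEAC is the fraction of draws with
positive net monetary benefit over a willingness-to-pay grid; results are
bit-reproducible for a fixed seed, and invalid draws are resampled with a
counter (none occur on the shipped tables).

Quantities printed once for both arms (utilities, adverse-event costs and
disutilities, drug prices, test/exam costs) receive **one draw applied to
both arms** (`psa_arm_correlation="shared"`, the default): a state's utility
or a drug's price is a property of the state or drug, not of the strategy,
and giving the two arms different values of the same quantity within one
draw would make the incremental QALY reflect parameter incoherence rather
than decision uncertainty. The fully independent per-arm-copy reading is
available as `psa_arm_correlation="independent"`; it inflates ΔE noise
(utility draws then dominate) and lowers the probability of high
cost-effectiveness by roughly 17 percentage points on the shipped tables.
The source does not state its sampling correlation or seed, so its published
79.11% is reproducible only within parameterization uncertainty; the shipped
default gives 83.7–84.7% across seeds at 10,000 draws.

### Scenarios

`time_horizon` changes only the horizon. `one_year_tdm` keeps TDM-guided
care for cycles 1–2, then switches the TDM arm to the non-TDM transition
matrix and adverse-event profile and drops the per-cycle testing cost from
its on-PER states, retaining the state occupancy already reached — the
residual benefit of the first year's TDM persists only through occupancy.
`override` accepts fully user-specified `ArmParameters` per arm and is the
vehicle for the newly-diagnosed and refractory subgroup scenarios, whose
inputs the source does not print; they are therefore supported structurally
but not reproduced.

## Synthetic cohorts

The generator emulates the study's data structure: per patient, a log-normal
baseline frequency (median 8 seizures/28 days, log-σ 1 — a moderately
refractory pediatric cohort), a multinomial draw through the first-cycle row
(discontinuation as a competing destination), a second draw through the
subsequent row while on PER, and follow-up frequencies constructed to be
exactly consistent with the drawn category (seizure freedom 0; response a
uniform reduction in [50%, 100%); no response in [0%, 50%)), so
classification round-trips with probability 1 — the anchor property for the
estimator tests. Per-period costs are gamma with the state's mean total
(CV 0.4) split over categories in fixed shares; TDM counts are gamma with
mean 1.74, rounded. Default enrolment is the study's 78/42. What it does
*not* emulate: covariate-driven confounding (arm assignment is independent
of severity), dropout before six months other than via the transition row,
dose-concentration pharmacokinetics, and correlated costs across periods —
so passing recovery tests shows estimator correctness under the model's own
assumptions, not robustness to real-world selection effects.

## Numerical choices and test scale

Transition rows are validated to sum to 1 within 1e-9 (1e-6 for the printed
fixture, which is rounded to three decimals); traces conserve mass to 1e-9;
the engine agrees with an explicit matrix-product oracle to 1e-12. The
ordinal-fit oracle is a five-round nested grid search over (β, c₁, c₂)
agreeing with the MLE to 1e-6 in log-likelihood. Monetary outputs render
negatives in parentheses, matching the source's table style. Property tests
use 1,000 random stochastic matrices for conservation, 100 replicates at
2,000 patients/arm for transition-row recovery (95% chi-square acceptance
region per arm-replicate, ≥93% required) and 100 replicates at 500/arm for
OR-CI coverage (≥90%), sizes chosen so the full suite stays around a minute.

## Limitations

No mortality or background-death state (the source model has none), no
patient-level microsimulation, no parameter correlation beyond the
shared-draw rule, no EVPI. The reward accounting reproduces the source's
convention rather than textbook discounting — both are available, but only
the former matches the published numbers. Subgroup scenarios require
user-supplied inputs. The published OR and two source-table identities are
irreproducible or violated as documented above; all such discrepancies are
surfaced by validation or failing tests rather than absorbed silently.
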