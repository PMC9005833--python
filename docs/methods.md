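# Methods

## The model

The package evaluates a companion-diagnostic test-and-treat strategy —
*ALK*-rearrangement testing (IHC screen, FISH confirmation) to direct
crizotinib versus no testing and universal docetaxel in advanced
non-small-cell lung cancer — under three health-system capacity
constraints, and quantifies what each constraint costs society per year
using value-of-implementation calculus.

### Markov treatment component

Each treatment arm is a three-state cohort Markov model
(progression-free → progressive disease → dead; dead absorbing) with
exponential survival parameterized by median PFS and OS
(hazard = ln 2 / median). The death hazard out of both alive states is
the OS hazard and the progression hazard is the PFS-event hazard minus
the OS hazard (floored at zero), so time-to-first-event is exponential
with the PFS median and all-cause survival is exponential with the OS
median. Per-cycle transition probabilities are the closed-form matrix
exponential of the hazard generator, so the discrete cohort coincides
with the continuous-time process at the cycle grid — survival at the OS
median is exactly one half, at any cycle length.

Defaults: 30-day cycles, 15-year horizon (183 cycles; the final
half-cycle's accrual is weighted by its in-horizon fraction), 3.5%
annual discounting of both costs and QALYs compounded per cycle with a
365-day year, no half-cycle correction (a start-of-cycle convention,
configurable via `DiscountSpec(half_cycle_correction=True)`). QALYs
accrue as occupancy × utility × cycle-length-in-years × discount factor;
costs analogously from per-cycle state costs plus a one-off entry cost.

### Decision-tree testing component

Among tested patients: a fraction β is tested in localized (in-house)
laboratories at an IHC price 17% above the centralized £25 (£29.25),
the rest centrally; IHC-positives (true positives at the assumed
sensitivity plus false positives at 1 − specificity) receive
confirmatory FISH, treated as perfect; confirmed positives receive
crizotinib, everyone else docetaxel. Incremental outcomes per tested
patient are therefore the test costs plus the treated fraction
(prevalence × sensitivity) times the crizotinib–docetaxel arm contrast.

Constraints:

- **α (commissioning awareness)** — only a proportion α of eligible
  patients is tested at all; the rest receive docetaxel under both
  strategies and contribute zero incremental NMB. α scales population
  totals and leaves per-patient outcomes untouched (access-limiting).
- **β (localization)** — shifts test volume to the dearer localized
  price; with fully staffed laboratories (γ = 1) that price delta is its
  only effect, so incremental cost rises by exactly β × £4.25.
- **γ (pathology capacity)** — γ = 1 (fully staffed) switches all
  quality/turnaround effects off. γ = 0: centrally tested patients who
  proceed to crizotinib incur a £101 delay cost (an extra oncologist
  appointment) and a QALY loss of 0.03 × 9/365 (anxiety disutility over
  a nine-day wait); locally tested crizotinib recipients use a degraded
  arm whose PFS/OS medians are multiplied by 0.822/0.775 (the
  localized-to-centralized median ratios observed when trial testing
  was rolled out from central to local laboratories).

Two deliberately open choices, both configurable:

- *Delay recipients.* The delay penalties default to centrally tested
  patients who proceed to treatment (`delay_applies_to="treated"`). The
  broader reading — every centrally tested patient —
  (`"all_tested"`) produces population losses out of keeping with the
  published scenario aggregates, so it is not the default.
- *Degradation scale.* The 0.822/0.775 ratios are applied as median
  multipliers (equivalently dividing the exponential hazards), the
  natural scale for an exact-embedding engine. We use 0.822 as
  published even though 6.9/8.4 = 0.8214.

Note one substantive asymmetry: survival degradation lowers QALYs *and*
time-on-treatment costs, so under full localization the incremental
cost can fall while the ICER and NMB still strictly worsen; the delay
penalties, by contrast, are non-negative on both axes.

### Economics and value of perfect implementation

At willingness-to-pay λ = £50,000/QALY: ICER = ΔC/ΔQ, per-patient
NMB = λΔQ − ΔC, annual total NMB = α·n·NMB for an annual eligible
population n. The value of perfect implementation is

    VoPI = n · NMB* − α · n · NMB_constrained

where NMB* is the per-patient NMB at full access, full staffing and the
*better* of the two pure localization policies (resolved by evaluating
both endpoints each run, not hard-coded; on the calibrated fixture
centralization wins). QALY shortfalls are VoPI/λ by definition.
Constraints are classified as access-limiting (ICER unchanged, NMB
down), quality-limiting (ICER moved), or mixed.

## The synthetic baseline fixture

The underlying appraisal model (manufacturer submission) is not public;
the fixture emulates it so the pipeline reproduces the published
aggregates. Printed quantities pin the economics down exactly:

1. localizing a test changes only its price, so the localization NMB
   shortfall = n × 0.11 × £4.25 gives **n = 16,626.74 tested
   patients/year**;
2. NMB per patient = £6,373,887 / n = £383.35;
3. ΔQ = NMB/(λ − ICER) = 383.35/10,802 = 0.035489 QALYs,
   ΔC = ICER × ΔQ = £1,391.10.

Calibration then tunes two free parameters — a multiplicative scale on
the crizotinib state utilities and the crizotinib progression-free
cycle cost — so the full pipeline's unconstrained baseline matches
(ΔC, ΔQ). Both targets are exactly linear in their parameter (and ΔQ
is independent of the cycle cost), so two sequential two-point solves
are exact to machine precision; residuals are verified
(|ΔC| < £0.01, |ΔQ| < 10⁻⁶) with a bracketing root-finder fallback.
The calibrated values (utility scale ≈ 1.002, cycle cost ≈ £2,787 over
30 days) are clinically plausible for an oral targeted agent.

Everything else in the fixture is a flagged synthetic assumption:
docetaxel medians 3.0/8.0 months, base utilities 0.75/0.55, *ALK*
prevalence 0.04, IHC sensitivity/specificity 0.95/0.98, FISH £150,
progressive-disease cycle costs £400. The serialized fixture
(`capacity-cea calibrate`) tags every entry `published`, `derived` or
`fixture-assumption`.

**What the fixture does and does not show.** Because the calibration
targets only baseline aggregates and n, the awareness-scenario cells
(NMB £1,465,994; shortfall £4,907,893, 77%; QALY shortfall 98.16; gain
29.32) and the localization ICER (£39,211) are genuine out-of-sample
reproductions of the published table. The localization NMB cells are
calibration-circular (they define n). The pathology and combined
scenario cells, the full-localization figures and the PSA percentages
depend on unpublished internals of the source model and are *not*
reproduction targets here; for those the suite checks structure
instead: constraint-off equals baseline bit-exactly, awareness leaves
the ICER bit-identical, quality constraints strictly worsen ICER and
total NMB, the combined shortfall exceeds each part without being their
sum, and constrained PSA cost-effectiveness probability never exceeds
the baseline's. Passing these says the mechanisms are wired correctly,
not that the synthetic arm set equals the real one.

One published-table inconsistency is deliberately not replicated: the
baseline "annual societal QALY gain" is printed as 124.48 but equals
total NMB/λ = 127.48 in every other row's convention; we print 127.48.

## Probabilistic sensitivity analysis

Per iteration, constraint parameters are redrawn — awareness
~ Beta(498, 1660) (mean 0.2308), localized proportion ~ Beta(19, 158)
(mean 0.1073), PFS ratio ~ U(0.697, 1), OS ratio ~ U(0.633, 1)
(independently), delay disutility ~ Triangular(0, mode 0.03, 0.1),
localized IHC cost = 25 × (1 + U(0.10, 0.25)) (mean uplift 17.5%,
implemented as published with the deterministic base case pinned at
£29.25), delay cost fixed at £101 — and the pipeline re-evaluated. A
draw replaces a parameter only where the scenario activates that
constraint, so the unconstrained baseline cloud collapses to its
deterministic point. Iteration *i* uses an RNG keyed on (seed, *i*):
bit-reproducible, order-invariant, and common random numbers across
scenarios for a comparable cost-effectiveness plane. Default 1000
iterations (a few seconds per scenario). Baseline-level parameter
uncertainty is not published and ships switched off, so the absolute
probability of cost-effectiveness is conservative (1.0 at λ = £50,000
for every preset under the shipped distributions); only its ordering
across scenarios is meaningful.

## Numerical conventions and limitations

- 365-day year throughout; monetary values in 2014 GBP.
- Reported tables round money to the nearest pound and QALY totals to
  two decimals; shortfall percentages to integers except sub-1% values
  (one decimal). CSVs carry plain numbers; the console view adds
  thousands separators.
- Fractional n is allowed (a cohort expectation, not a headcount).
- Degenerate inputs raise typed errors: non-positive medians, PFS
  median above OS median, malformed transition matrices, zero
  incremental QALYs in an ICER, ratios outside (0, 1].
- Not modelled: time-varying hazards or fitted survival curves,
  patient-level simulation, turnaround-time queues, EVPI/EVPPI, the
  "hospital absorbs the loss" reading of the commissioning constraint.
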