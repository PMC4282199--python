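# Methods

## Model structure

The model is a cohort expectation over a finite decision tree — a
two-cycle simplification of a Markov treatment pathway. States and
transitions, per couple:

1. **Fresh cycle** (always): cost components medication €1,570, hospital
   care €325, oocyte pick-up €586, laboratory €1,314, embryo transfer
   €310, hospital admission/other €909 — €5,014 per couple. For the
   diagnostic strategy a fixed test price (base €400) is charged to the
   tested fraction (0.91: couples with a single viable embryo, ~9%, are
   not tested, since ranking one embryo is pointless). The test price is
   per couple, not per embryo.
2. **Fresh transfer** → ongoing pregnancy with probability
   `p_ongoing_fresh` (eSET 0.214, DET 0.403, DxSET 0.334 — the assumed
   effect of the diagnostic on a single transfer), else failure.
3. **Frozen cycle** (horizon 2 only): a failing couple proceeds with
   probability `p_frozen_available`, pays the all-in frozen-cycle cost,
   and achieves an ongoing pregnancy with `p_ongoing_frozen`. Frozen
   transfers are single-embryo in every strategy (no frozen double
   transfer is costed anywhere in the source tables), so DET's frozen
   branch uses the single-transfer twin rate; the diagnostic confers no
   benefit in frozen cycles, so DxSET's frozen success equals eSET's.
4. **Ongoing pregnancy** → twin (`p_twin_given_ongoing`, branch-specific
   on frozen transfers) vs singleton, → complicated vs uncomplicated
   antenatal-cost stratum (twin/singleton-specific pregnancy costs), →
   live delivery with `p_live_given_ongoing` (delivery cost: singleton
   €12,438, twin €41,844, to six weeks post delivery) or pregnancy loss.
   Loss-management costs are not modelled separately; they are absorbed
   into the calibrated conversion parameters.

No discounting is applied: the horizon is under a year. Currency is
euros at 2013 prices; `currency_year` is metadata only (no CPI
machinery). `count_twins_as` selects whether a live twin delivery counts
one delivery event or two children; the calibration (below) selects
**children** — under delivery-event counting the eSET target of 0.314
live births is unreachable, since the cumulative ongoing-pregnancy rate
0.214 + 0.786·p_avail·p_frozen tops out at ~0.31 only with implausible
frozen rates and `p_live ≤ 1` binds.

Two equivalent engines implement the tree: a closed-form expectation
(`cohort.run_cohort`) and an exhaustive path enumeration
(`cohort.pathway_enumerate`), kept as a brute-force oracle; tests require
agreement to 1e-12 relative on random strategies.

## Economics conventions

ICERs are Δcost/Δeffect (comparator − reference), computed at full
precision and rounded half-up to whole euros for reporting; published
figures were themselves computed from rounded inputs, so comparisons
against them allow ±1 €. A comparator with positive Δeffect and
non-negative Δcost gets an ICER; cheaper-and-more-effective is
`comparator_dominant`; any comparator with negative Δeffect is reported
`comparator_dominated` with the ICER suppressed (including the
cost-saving-but-less-effective trade-off, which would otherwise print a
misleading positive ratio — this mirrors the "dominated" convention of
published tornado tables). Zero live births yields an infinite cost per
live birth, flagged rather than raised. The frontier sorts by effect,
flags strictly dominated strategies (pairwise brute force) and chains
sequential ICERs over the survivors.

## Calibration

Free parameters are exactly the pathway quantities absent from the
published inputs: the frozen-cycle cost, frozen availability, the frozen
ongoing-pregnancy rate, twin rates (single-transfer and DET-fresh),
live-delivery and complication probabilities. The targets are the six
published per-strategy aggregates (eSET €14,896 / 0.314; DxSET €16,687 /
0.43; DET €18,952 / 0.473). The objective is the unweighted sum of
squared **relative** errors, since costs (~10⁴ €) and rates (~10⁻¹) are
on different scales.

Live-delivery and complication probabilities are freed per strategy
class (SET-type vs DET) rather than shared. This is forced by the
targets: the live-birth targets pin `p_live·(1+p_twin)` per strategy, and
with a shared `p_live` the expected cost of a DET fresh pregnancy cannot
reach the level the DET cost target requires (the difference between
DET's and SET's per-pregnancy cost is then bounded above by ~€1.4k while
the targets need ~+€4.5k). The resulting representative solution has a
lower live-delivery conversion and much higher twin and complication
rates for DET — consistent with twin-heavy double-transfer pregnancies,
though the fitted values are conventions, not estimates (see
identifiability).

The optimiser is bounded trust-region least squares
(`scipy.optimize.least_squares`) multi-started from a seeded
Latin-hypercube design over the bounded box (default 64 starts; the
incoming config's own values are always one start), run under both
twin-counting conventions when `convention_search` is on; the best
objective wins. Residual evaluation uses a compiled plain-dict snapshot
(validation-free `model_construct`) for speed; the returned fit is
re-evaluated through the fully validated config path, so the shortcut
cannot diverge silently. Every run is deterministic given the seed.
Bounds: probabilities [0, 1]; frozen-cycle cost [0, 10000] € (the product
availability × cost ≈ €5.4k is what the targets fix; the upper bound
merely has to admit it).

**Identifiability.** With nine free parameters and six targets the
solution set is a manifold: frozen availability, frozen success rate and
frozen-cycle cost enter only through products, and `p_live` trades off
against twin rates within each strategy class. `identifiability_report`
refits from many starts and reports the spread of each parameter across
near-optimal solutions (objective within 1e-6 of the best); spread above
5% of the bound width flags the parameter as not pinned down. On the
shipped problem *all* free parameters are flagged — the published
aggregates are reproduced exactly, but the individual pathway values are
representative, not identified. The shipped base-case file records one
interpretable solution (full frozen availability, frozen-cycle cost
€5,419, frozen success 0.0998) with every calibrated field marked in the
config metadata; `examples/recalibrate.py` re-derives it.

## Sensitivity machinery

One-way analysis multiplies a single parameter by 0.8 and 1.2
(probabilities clipped to [0, 1]), reruns the full two-cycle model and
reports the ICER or dominance status per strategy pair plus the absolute
spread. Structural consequence worth knowing: any cost incurred once per
couple by *every* strategy (all fresh-cycle components) shifts all
expected costs equally and leaves every ICER exactly invariant, so those
tornado rows are exact zeros; the diagnostic-test price moves only the
tested strategy, leaving the DET-vs-eSET ICER invariant (difference €0).

Threshold search scans a 65-point grid over the requested range, brackets
every sign change of the cost-per-live-birth difference and bisects each
to tolerance (defaults €1 for prices, 0.001 for probabilities, matching
the granularity at which crossovers are usually reported); the smallest
crossing is reported and all are returned. An identically zero difference
is reported as degenerate. Threshold (and figure-style) analyses run at
one fresh cycle, where the diagnostic's benefit lives; the tornado table
runs at two cycles. With the calibrated configuration the single-cycle
DxSET-vs-DET price crossover falls at ≈ €1,078 and the pregnancy-rate
crossover at ≈ 0.299; the single-fresh-cycle aggregates behind the
published figures are not printed, so only the qualitative shape
(cheapest at low prices, crossing above DET as price rises; overtaking
DET as the success rate rises through the low 0.3s) is checked, not those
published break-even values (€460, 0.335).

## Microsimulation

The generator draws each couple independently through the identical tree:
Bernoulli branches at test uptake, fresh outcome, frozen availability,
frozen outcome, plurality, complication stratum and delivery, with the
same unit costs accumulated along the realised path. It emulates a
homogeneous cohort by design — no age, prognosis or clinic heterogeneity,
no correlation between branches beyond the tree structure — so agreement
with the cohort engine validates the arithmetic of this model, not the
model's fidelity to any real patient population. Randomness comes from a
counter-based Philox generator with a fixed seven-uniform block per
couple, so trajectory *i* is invariant to cohort size and chunking, and
runs are bit-reproducible given the seed. Summaries report sample means
with standard errors (sd/√n); trajectories stream to CSV in blocks to
keep memory flat.

## Problem sizes and numerical choices

The tests run the microsimulation oracle at 10⁵–2·10⁵ couples (sampling
error ~0.3% of the mean cost, comfortably resolving any engine
discrepancy) and calibration at 64 multi-starts; the acceptance script
uses the same sizes and completes in seconds. Probabilities proposed by
the optimiser stay feasible via box bounds rather than penalties.
Half-up euro rounding is used for reported currency; ties at exact .5
round away from zero. Degenerate inputs are first-class: zero-probability
branches are pruned from enumerations, zero live births yield flagged
infinite ratios, and fully deterministic strategies produce single-path
enumerations and zero-variance simulations.

## Known limitations

- The pathway is the minimal structure consistent with the published
  inputs; real treatment adds cancelled cycles, multiple frozen
  transfers, pregnancy-loss management costs and per-embryo laboratory
  work, none of which are separately costed here.
- Calibrated parameters are not identified individually (see above);
  downstream uses that need, say, the true twin rate should source it
  externally rather than read it off the fitted config.
- The published sensitivity table contains cells that are mutually
  inconsistent with the base-case table (and with any
  one-fresh-cycle-per-strategy tree, for the shared unit-cost rows);
  this package reproduces the machinery and the structurally forced
  values, not those cells. Its printed ±20% inputs also differ in the
  fourth decimal from exact ±20% arithmetic (0.1712 vs 0.1714 for base
  0.214); the implementation follows the stated procedure exactly.
- No QALY valuation, willingness-to-pay analysis, probabilistic
  sensitivity analysis or budget impact; the horizon excludes long-term
  costs of multiple-birth children.
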