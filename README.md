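# ivfcea

Decision-analytic cost-effectiveness model for IVF embryo-transfer
strategies, written for health economists and HTA analysts evaluating
embryo-selection technology from a payer's perspective.

## The problem and the model

In vitro fertilisation clinics choose between transferring one embryo
(elective single embryo transfer, **eSET**) — fewer costly twin
pregnancies, lower success per cycle — and two (**DET**) — higher birth
rate, much higher twin risk. A non-invasive embryo-viability diagnostic
(**DxSET**: test the cohort of embryos, transfer the best single one) is
assumed to raise the ongoing-pregnancy rate of a single transfer at a
fixed per-couple test price, and the question is whether that price buys
its keep.

The model is a cohort decision tree over **one fresh plus at most one
frozen cycle**. Every couple incurs the fresh-cycle cost
`C_fresh = Σ (medication, hospital care, OPU, laboratory, transfer,
admission)` plus, for the tested fraction *f* of couples, the test price
*c*<sub>test</sub>. The fresh transfer yields an ongoing pregnancy with
probability *p*<sub>fresh</sub>; failures proceed to a single frozen
transfer with probability *p*<sub>frozen-avail</sub> (cost
*C*<sub>frozen</sub>, success *p*<sub>frozen</sub>, no diagnostic
benefit). Each ongoing pregnancy branches twin/singleton, then
complicated/uncomplicated (pregnancy-stratum cost), then live delivery
(delivery cost, counted into live births) or loss. For a strategy *s*,

```
E[cost]   = C_fresh + f·c_test + (1−p_fresh)·p_avail·C_frozen
            + Σ_arm P(ongoing via arm) · E[pregnancy + delivery cost | arm]
E[births] = Σ_arm P(ongoing via arm) · p_live · (1 + p_twin(arm))
```

and the decision metrics are **cost per live birth** `E[cost]/E[births]`
and the **ICER** `ΔC/ΔE` between ordered strategy pairs, with standard
dominance handling (a costlier, less effective comparator is dominated
and no ratio is reported).

The published aggregates this model targets leave several pathway
parameters unprinted (frozen-cycle cost and availability, twin,
complication and live-delivery rates); a bounded multi-start
least-squares **calibration** recovers them from the six printed
per-strategy aggregates, and an identifiability report says which of the
fitted values are actually pinned down. A seeded patient-level
**microsimulation** of the identical tree serves as a stochastic oracle
for the closed-form engine.

## Worked example

```
$ python examples/base_case_table.py
strategy  expected_cost  expected_cost_rounded  incremental_cost  live_births  cost_per_live_birth  cost_per_live_birth_rounded
    eSET   14896.101862                  14896               NaN     0.314002         47439.571945                        47440
   DxSET   16687.012675                  16687       1790.910813     0.430002         38806.796140                        38807
     DET   18952.126292                  18952       2265.113616     0.473003         40067.643581                        40068

reference comparator  delta_cost  delta_effect  icer_rounded status
     eSET      DxSET 1790.910813      0.116001         15439   icer
     eSET        DET 4056.024430      0.159002         25509   icer
    DxSET        DET 2265.113616      0.043001         52676   icer
```
(ICER columns per strategy omitted above for width.)

Per couple starting treatment, the tested single-transfer strategy costs
€16,687 and yields 0.43 expected live births over the two cycles — the
lowest cost per live birth (€38,807) of the three strategies. Moving
from eSET to DxSET costs €15,439 per extra live birth; the extra births
DET buys over DxSET cost ~€52,700 each. Other examples cover the ±20%
tornado table (`tornado_one_way.py`), test-price and pregnancy-rate
crossovers (`threshold_crossover.py`), re-running the calibration with
its identifiability report (`recalibrate.py`), and the microsimulation
cross-check (`microsim_oracle.py`). The same capabilities are exposed as
a thin CLI: `ivfcea run|sensitivity|threshold|calibrate|microsim --help`.

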