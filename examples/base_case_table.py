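"""Base case: cost, live births, cost per live birth and ICERs per strategy.

Evaluates the shipped two-cycle configuration for the three transfer
strategies and prints the headline cost-effectiveness table. Costs are
euros per couple starting treatment (2013 prices); live births are
cumulative expected children per couple over one fresh plus one frozen
cycle; each ICER is the extra cost per additional live birth of the more
effective strategy in the pair.
"""

from ivfcea import frontier, load_base_case, run_cohort
from ivfcea.report import comparisons_table, outcomes_table

config = load_base_case()
outcomes = [run_cohort(s, config.costs, cycles=2) for s in config.strategies]

print(outcomes_table(outcomes).to_string(index=False))
print()
print(comparisons_table(frontier(outcomes).pairwise)[
    ["reference", "comparator", "delta_cost", "delta_effect", "icer_rounded", "status"]
].to_string(index=False))
print(
    "\nReading: the diagnostic-assisted single transfer (DxSET) has the lowest"
    "\ncost per live birth; double transfer (DET) buys the highest birth rate"
    "\nbut each extra birth over DxSET costs ~€52,700."
)
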