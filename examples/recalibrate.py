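"""Re-run the calibration that produced the shipped base-case parameters.

Starts from neutral values for every calibrated field, fits the free
parameters to the six published per-strategy aggregates (three costs,
three live-birth rates), and reports the fit plus an identifiability
summary: parameters that wander across equally good solutions are not
pinned down by the targets (they enter the model only through products).
"""

from ivfcea import load_base_case, load_calibration_spec, set_parameter
from ivfcea.calibration import calibrate, identifiability_report

NEUTRAL = {
    "costs.frozen_cycle": 2000.0,
    "strategies.*.p_frozen_available": 0.5,
    "strategies.*.p_ongoing_frozen": 0.2,
    "strategies.*.p_twin_given_ongoing": 0.2,
    "strategies.DET.p_twin_frozen": 0.2,
    "strategies.*.p_live_given_ongoing": 0.7,
    "strategies.*.p_complication": 0.3,
}

start = load_base_case()
for path, value in NEUTRAL.items():
    start = set_parameter(start, path, value)

spec = load_calibration_spec()
result = calibrate(spec, start, seed=20140482, n_starts=64)
print(f"converged: {result.converged}   twin counting: {result.convention.value}")
print(f"objective (sum sq. relative error): {result.objective:.3e}")
print(f"worst target error: {result.max_relative_error:.2%}\n")
for name, value in result.fitted.items():
    print(f"  {name:22s} = {value:.4f}")

report = identifiability_report(spec, start, n_starts=32, seed=20140482)
print(f"\nnear-optimal solutions: {report.n_near_optimal}")
print("non-identifiable parameters (spread > "
      f"{report.threshold:.0%} of bounds): {', '.join(report.non_identifiable) or 'none'}")
print(
    "\nReading: the fit reproduces all six published aggregates; flagged"
    "\nparameters trade off against each other (e.g. frozen-cycle cost times"
    "\navailability is fixed, the factors are not), so individual fitted"
    "\nvalues there are one representative solution, not estimates."
)
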