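"""Calibration: parameter recovery, determinism, identifiability."""

import pytest

from ivfcea import (
    CalibrationSpec,
    CalibrationTarget,
    FreeParameter,
    calibrate,
    identifiability_report,
    run_cohort,
    set_parameter,
)


def targets_from(config, strategies=("eSET", "DET"), cycles=2):
    """Generate self-consistent targets by running the model."""
    targets = []
    for name in strategies:
        out = run_cohort(config.strategy(name), config.costs, cycles)
        targets.append(CalibrationTarget(strategy=name, quantity="expected_cost", value=out.expected_cost))
        targets.append(CalibrationTarget(strategy=name, quantity="live_births", value=out.live_births))
    return targets


RECOVERY_FREE = [
    FreeParameter(name="frozen_cycle_cost", paths=["costs.frozen_cycle"], lower=0, upper=10000),
    FreeParameter(name="p_twin_det", paths=["strategies.DET.p_twin_given_ongoing"], lower=0, upper=1),
    FreeParameter(name="p_live_det", paths=["strategies.DET.p_live_given_ongoing"], lower=0, upper=1),
]


class TestParameterRecovery:
    def test_recovers_known_parameters(self, base_config):
        """Targets simulated at known values; calibration from a displaced
        config must recover the values and drive the objective to ~0."""
        truth = {
            "costs.frozen_cycle": 1800.0,
            "strategies.DET.p_twin_given_ongoing": 0.35,
            "strategies.DET.p_live_given_ongoing": 0.75,
        }
        cfg_true = base_config
        for path, v in truth.items():
            cfg_true = set_parameter(cfg_true, path, v)
        spec = CalibrationSpec(
            free_parameters=RECOVERY_FREE,
            targets=targets_from(cfg_true),
            convention_search=False,
        )
        displaced = base_config
        for path, v in {
            "costs.frozen_cycle": 6000.0,
            "strategies.DET.p_twin_given_ongoing": 0.1,
            "strategies.DET.p_live_given_ongoing": 0.4,
        }.items():
            displaced = set_parameter(displaced, path, v)

        res = calibrate(spec, displaced, seed=11, n_starts=16)
        assert res.converged
        assert res.objective < 1e-16
        assert res.fitted["frozen_cycle_cost"] == pytest.approx(1800.0, abs=1e-4 * 1800)
        assert res.fitted["p_twin_det"] == pytest.approx(0.35, abs=1e-4)
        assert res.fitted["p_live_det"] == pytest.approx(0.75, abs=1e-4)

    def test_already_satisfying_parameter_unchanged(self, base_config):
        spec = CalibrationSpec(
            free_parameters=[RECOVERY_FREE[0]],
            targets=targets_from(base_config, strategies=("eSET",)),
            convention_search=False,
        )
        res = calibrate(spec, base_config, seed=3, n_starts=4)
        assert res.fitted["frozen_cycle_cost"] == pytest.approx(
            base_config.costs.frozen_cycle, rel=1e-6
        )
        assert res.max_relative_error < 1e-8

    def test_fitted_config_not_the_input(self, base_config):
        spec = CalibrationSpec(
            free_parameters=[RECOVERY_FREE[0]],
            targets=targets_from(base_config, strategies=("eSET",)),
            convention_search=False,
        )
        res = calibrate(spec, base_config, seed=3, n_starts=2)
        assert res.config is not base_config
        assert res.config.costs is not base_config.costs


class TestSpecValidation:
    def test_no_free_parameters_rejected(self, base_config):
        spec = CalibrationSpec(free_parameters=[], targets=targets_from(base_config))
        with pytest.raises(ValueError, match="free parameters"):
            calibrate(spec, base_config)

    def test_unknown_path_rejected(self, base_config):
        spec = CalibrationSpec(
            free_parameters=[FreeParameter(name="x", paths=["costs.bogus"], lower=0, upper=1)],
            targets=targets_from(base_config),
        )
        with pytest.raises(KeyError):
            calibrate(spec, base_config)

    def test_bad_bounds_rejected(self, base_config):
        spec = CalibrationSpec(
            free_parameters=[FreeParameter(name="x", paths=["costs.frozen_cycle"], lower=5, upper=1)],
            targets=targets_from(base_config),
        )
        with pytest.raises(ValueError, match="bounds"):
            calibrate(spec, base_config)


def test_determinism_same_seed(base_config):
    spec = CalibrationSpec(
        free_parameters=RECOVERY_FREE,
        targets=targets_from(base_config),
        convention_search=False,
    )
    a = calibrate(spec, base_config, seed=5, n_starts=6)
    b = calibrate(spec, base_config, seed=5, n_starts=6)
    assert a.fitted == b.fitted
    assert a.objective == b.objective


class TestIdentifiability:
    def test_uniquely_determined_parameter_has_zero_spread(self, base_config):
        spec = CalibrationSpec(
            free_parameters=[RECOVERY_FREE[0]],
            targets=[
                CalibrationTarget(
                    strategy="eSET",
                    quantity="expected_cost",
                    value=run_cohort(base_config.strategy("eSET"), base_config.costs, 2).expected_cost,
                )
            ],
            convention_search=False,
        )
        rep = identifiability_report(spec, base_config, n_starts=8, seed=2)
        assert rep.non_identifiable == []
        assert rep.normalized_spread["frozen_cycle_cost"] < 1e-6

    def test_confounded_product_flagged(self, base_config):
        """Frozen availability and frozen success enter live births only
        through their product, so a single birth target cannot separate
        them: both must be flagged."""
        spec = CalibrationSpec(
            free_parameters=[
                FreeParameter(name="p_frozen_available",
                              paths=["strategies.eSET.p_frozen_available"], lower=0.3, upper=1),
                FreeParameter(name="p_ongoing_frozen",
                              paths=["strategies.eSET.p_ongoing_frozen"], lower=0.02, upper=1),
            ],
            targets=[
                CalibrationTarget(
                    strategy="eSET",
                    quantity="live_births",
                    value=run_cohort(base_config.strategy("eSET"), base_config.costs, 2).live_births,
                )
            ],
            convention_search=False,
        )
        rep = identifiability_report(spec, base_config, n_starts=16, seed=2)
        assert set(rep.non_identifiable) == {"p_frozen_available", "p_ongoing_frozen"}
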