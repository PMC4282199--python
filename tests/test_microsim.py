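"""Monte-Carlo microsimulation: reproducibility, convergence, round trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ivfcea import TwinCounting, run_cohort, simulate_cohort, write_trajectories
from ivfcea.microsim import iter_trajectories

from conftest import make_strategy


class TestReproducibility:
    def test_same_seed_identical(self, base_config):
        s = base_config.strategy("eSET")
        a = simulate_cohort(s, base_config.costs, 5000, seed=123)
        b = simulate_cohort(s, base_config.costs, 5000, seed=123)
        assert a == b

    def test_trajectory_invariant_to_cohort_size(self, base_config):
        """Couple i draws from a fixed counter block, so the first rows of a
        large run equal a small run exactly."""
        s = base_config.strategy("DET")
        _, small = simulate_cohort(s, base_config.costs, 50, seed=9, return_trajectories=True)
        _, large = simulate_cohort(s, base_config.costs, 400, seed=9, return_trajectories=True)
        pd.testing.assert_frame_equal(small, large.iloc[:50])

    def test_chunking_does_not_change_results(self, base_config):
        s = base_config.strategy("eSET")
        whole = pd.concat(iter_trajectories(s, base_config.costs, 1000, seed=4, chunk=1000),
                          ignore_index=True)
        chunked = pd.concat(iter_trajectories(s, base_config.costs, 1000, seed=4, chunk=137),
                            ignore_index=True)
        pd.testing.assert_frame_equal(whole, chunked)


class TestDegenerate:
    def test_all_degenerate_probabilities_zero_standard_error(self, costs):
        s = make_strategy(
            p_ongoing_fresh=1.0, p_twin_given_ongoing=0.0,
            p_complication=1.0, p_live_given_ongoing=1.0,
        )
        summary, df = simulate_cohort(s, costs, 500, seed=1, return_trajectories=True)
        assert summary.se_cost == 0.0 and summary.se_births == 0.0
        assert df["total_cost"].nunique() == 1
        assert summary.mean_cost == run_cohort(s, costs, 2).expected_cost

    def test_zero_couples_rejected(self, base_config):
        with pytest.raises(ValueError):
            simulate_cohort(base_config.strategy("eSET"), base_config.costs, 0, seed=1)


class TestConvergence:
    def test_means_agree_with_cohort_within_three_se(self, base_config):
        """Law-of-large-numbers oracle: sample means vs analytic expectation."""
        for s in base_config.strategies:
            analytic = run_cohort(s, base_config.costs, 2)
            sim = simulate_cohort(s, base_config.costs, 100_000, seed=7)
            assert abs(sim.mean_cost - analytic.expected_cost) < 3 * sim.se_cost
            assert abs(sim.mean_births - analytic.live_births) < 3 * sim.se_births

    def test_branch_frequencies_match_configured_probabilities(self, base_config):
        """Chi-square goodness of fit on each Bernoulli node, alpha = 0.01."""
        s = base_config.strategy("DET")
        n = 100_000
        _, df = simulate_cohort(s, base_config.costs, n, seed=13, return_trajectories=True)
        checks = [
            (df["fresh_ongoing"].sum(), n, s.p_ongoing_fresh),
            (df["frozen_attempt"].sum(), n - df["fresh_ongoing"].sum(), s.p_frozen_available),
            (df["frozen_ongoing"].sum(), df["frozen_attempt"].sum(), s.p_ongoing_frozen),
            (
                df.loc[df["fresh_ongoing"] == 1, "twin"].sum(),
                df["fresh_ongoing"].sum(),
                s.p_twin_given_ongoing,
            ),
            (
                df.loc[df["fresh_ongoing"] + df["frozen_ongoing"] > 0, "live_delivery"].sum(),
                int((df["fresh_ongoing"] + df["frozen_ongoing"] > 0).sum()),
                s.p_live_given_ongoing,
            ),
        ]
        for successes, trials, p in checks:
            if p in (0.0, 1.0):  # degenerate node: frequency must be exact
                assert successes == trials * p
                continue
            observed = [successes, trials - successes]
            expected = [trials * p, trials * (1 - p)]
            assert stats.chisquare(observed, expected).pvalue > 0.01

    def test_delivery_event_counting_observed(self, costs):
        s = make_strategy(
            p_ongoing_fresh=1.0, p_twin_given_ongoing=1.0, p_live_given_ongoing=1.0,
            count_twins_as=TwinCounting.DELIVERY_EVENT,
        )
        summary = simulate_cohort(s, costs, 100, seed=5)
        assert summary.mean_births == 1.0


class TestTrajectoryFile:
    def test_empty_stream_header_only(self, tmp_path):
        path = tmp_path / "t.csv"
        assert write_trajectories(iter([]), path) == 0
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("couple,")

    def test_row_count(self, base_config, tmp_path):
        s = base_config.strategy("eSET")
        path = tmp_path / "t.csv"
        n = write_trajectories(
            iter_trajectories(s, base_config.costs, 10, seed=2), path
        )
        assert n == 10
        assert len(pd.read_csv(path)) == 10

    def test_round_trip_cost_recomputation(self, base_config, tmp_path):
        """Re-derive each row's cost from its outcome flags; must equal the
        stored total."""
        s = base_config.strategy("DxSET")
        c = base_config.costs
        path = tmp_path / "t.csv"
        write_trajectories(iter_trajectories(s, c, 2000, seed=21), path)
        df = pd.read_csv(path)
        ongoing = (df.fresh_ongoing | df.frozen_ongoing).astype(bool)
        preg = np.select(
            [
                ongoing & df.twin.astype(bool) & df.complicated.astype(bool),
                ongoing & df.twin.astype(bool),
                ongoing & df.complicated.astype(bool),
                ongoing,
            ],
            [
                c.pregnancy_twin_complicated,
                c.pregnancy_twin_uncomplicated,
                c.pregnancy_singleton_complicated,
                c.pregnancy_singleton_uncomplicated,
            ],
            default=0.0,
        )
        delivery = np.where(
            df.live_delivery.astype(bool),
            np.where(df.twin.astype(bool), c.delivery_twin, c.delivery_singleton),
            0.0,
        )
        recomputed = (
            c.fresh_cycle_total
            + df.tested * c.diagnostic_test
            + df.frozen_attempt * c.frozen_cycle
            + preg
            + delivery
        )
        np.testing.assert_allclose(recomputed, df.total_cost)
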