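"""Closed-loop simulation, rotation metrics, and the analytic oracles."""

import numpy as np
import pytest

from minav.simulate import (
    RotationMetrics,
    UserModel,
    compare_strategies,
    expected_imaginations,
    monte_carlo_rotations,
    run_closed_loop,
)

ROUTE = [("walk", 3), ("turn", "left"), ("walk", 2), ("turn", "right")]


class TestPerfectDecoderLoop:
    @pytest.mark.parametrize("mode", ["low", "middle"])
    def test_ne_ideal_times_and_counts(self, mode):
        result = run_closed_loop(UserModel(route=ROUTE, p=1.0, q=1.0),
                                 strategy="ne", mode=mode, seed=0)
        m = result.metrics
        assert m.no_imagination == 1.0
        assert m.no_error == 0.0 and m.no_navigation_error == 0.0
        # ideal command issue times: one epoch each
        assert result.walk_command_times == [6.0, 6.0]
        assert result.rotation_issue_times == [2.0, 2.0]
        assert result.completed

    def test_dc_needs_exactly_two_imaginings(self):
        result = run_closed_loop(UserModel(route=ROUTE, p=1.0, q=1.0),
                                 strategy="dc", mode="low", seed=0)
        assert result.metrics.no_imagination == 2.0
        assert result.rotation_issue_times == [4.0, 4.0]

    def test_ec_needs_one_imagining_plus_correction_window(self):
        result = run_closed_loop(UserModel(route=ROUTE, p=1.0, q=1.0),
                                 strategy="ec", mode="low", seed=0)
        assert result.metrics.no_imagination == 1.0
        assert result.rotation_issue_times == [4.0, 4.0]  # 2 s epoch + 2 s window

    def test_route_is_followed(self):
        result = run_closed_loop(UserModel(route=ROUTE), strategy="ne",
                                 mode="middle", seed=0)
        assert result.trajectory[0] == (0, 0)
        assert result.trajectory[-1] == (3, 2)

    def test_imperfect_decoder_takes_strictly_longer(self):
        fast = run_closed_loop(UserModel(route=ROUTE, p=1.0), strategy="ne", seed=0)
        slow = run_closed_loop(UserModel(route=ROUTE, p=0.7), strategy="ne", seed=1)
        assert slow.total_time_s >= fast.total_time_s
        assert slow.metrics.no_imagination > 1.0

    def test_infeasible_route_rejected(self):
        from minav.navigation import straight_path

        world = straight_path(2)
        with pytest.raises(ValueError, match="infeasible"):
            run_closed_loop(UserModel(route=[("walk", 5)]), world=world)


class TestClosedForms:
    @pytest.mark.parametrize(
        "strategy, p, expected",
        [("ne", 1.0, 1.0), ("dc", 1.0, 2.0), ("ne", 0.75, 2.0), ("dc", 0.75, 4.0),
         ("ec", 0.6, 1.0)],
    )
    def test_expected_imaginations(self, strategy, p, expected):
        assert expected_imaginations(strategy, p) == pytest.approx(expected)

    @pytest.mark.parametrize("strategy", ["ne", "dc"])
    def test_divergence_signalled_below_half(self, strategy):
        with pytest.raises(ValueError, match="0.5|1/2"):
            expected_imaginations(strategy, 0.5)

    def test_monte_carlo_matches_closed_form_at_large_n(self):
        for strategy, p in (("ne", 0.75), ("dc", 0.75), ("ec", 0.7)):
            mc = monte_carlo_rotations(strategy, p, 100_000, seed=9)
            cf = expected_imaginations(strategy, p)
            assert mc["no_imagination"] == pytest.approx(cf, rel=0.02)

    def test_monte_carlo_converges_with_sample_size(self):
        """Mean absolute error shrinks roughly like 1/sqrt(N)."""
        cf = expected_imaginations("ne", 0.75)
        err = {
            n: np.mean(
                [abs(monte_carlo_rotations("ne", 0.75, n, seed=s)["no_imagination"]
                     - cf) for s in range(10)]
            )
            for n in (1_000, 100_000)
        }
        assert err[100_000] < err[1_000]
        # consistent with the 1/sqrt(N) rate (factor 10 expected; allow 3x slack)
        assert err[100_000] < err[1_000] / 3

    def test_ec_flips_every_error_with_reliable_blinks(self):
        mc = monte_carlo_rotations("ec", 0.8, 10_000, seed=4, q=1.0)
        assert mc["no_navigation_error"] == 0.0
        assert mc["no_imagination"] == 1.0
        assert mc["no_error"] == pytest.approx(0.2, rel=0.1)


class TestStructuralIdentities:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("p", [0.6, 0.8])
    def test_ne_classification_errors_equal_navigation_errors(self, seed, p):
        """Under NE every decoder output rotates, so the error counts
        coincide in every run."""
        route = [("walk", 1)] + [("turn", "left"), ("turn", "right")] * 3
        result = run_closed_loop(UserModel(route=route, p=p), strategy="ne",
                                 seed=seed)
        for record in result.per_rotation:
            assert record["errors"] == record["wrong_rotations"]

    @pytest.mark.parametrize("strategy", ["dc", "ec"])
    def test_navigation_errors_bounded_by_classification_errors(self, strategy):
        mc = monte_carlo_rotations(strategy, 0.7, 5_000, seed=6)
        assert mc["no_navigation_error"] <= mc["no_error"]

    def test_dc_perfect_stream_uses_exactly_two_per_rotation(self):
        mc = monte_carlo_rotations("dc", 1.0, 1_000, seed=0)
        assert mc["no_imagination"] == 2.0


class TestCompareStrategies:
    def test_imagination_ordering_across_grid(self):
        table = compare_strategies([0.6, 0.7, 0.8, 0.9], n_rotations=20_000, seed=1)
        for p, group in table.groupby("p"):
            by = group.set_index("strategy")["no_imagination"]
            assert by["ec"] <= by["ne"] <= by["dc"]

    def test_error_control_reduces_navigation_errors(self):
        table = compare_strategies([0.7], n_rotations=20_000, seed=2)
        by = table.set_index("strategy")["no_navigation_error"]
        assert by["dc"] < by["ne"] and by["ec"] < by["ne"]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            compare_strategies([])


class TestWorldInvariance:
    def test_metrics_independent_of_geometry(self):
        """For a fixed turn sequence and seed, rescaling the map does not
        change any rotation metric."""
        from minav.simulate import _default_world_for

        route = [("walk", 2), ("turn", "left"), ("walk", 1)]
        base = _default_world_for(route, "low")
        stretched = _default_world_for(route, "low")
        for node in stretched.graph.nodes:
            x, y = stretched.graph.nodes[node]["pos"]
            stretched.graph.nodes[node]["pos"] = (2.5 * x, 2.5 * y)
        r1 = run_closed_loop(UserModel(route=route, p=0.7), world=base, seed=5)
        r2 = run_closed_loop(UserModel(route=route, p=0.7), world=stretched, seed=5)
        assert r1.metrics == r2.metrics


class TestFullPipelineUser:
    def test_trained_decoder_drives_the_loop(self, small_pipeline):
        """Full mode: synthetic EEG through the fitted decoder, end to end."""
        from minav.synthetic import SyntheticConfig

        user = UserModel(
            route=[("walk", 1), ("turn", "left")],
            pipeline=small_pipeline,
            synth=SyntheticConfig(trial_counts=1, erd_depth=0.8, rng_seed=21),
        )
        result = run_closed_loop(user, strategy="ec", mode="low", seed=3,
                                 max_imaginations_per_rotation=50)
        assert result.metrics.n_rotations == 1
        assert result.metrics.no_imagination >= 1.0
        assert result.total_time_s > 0
        kinds = {e["event"] for e in result.events}
        assert "classified_flexion" in kinds and "blink" in kinds

    def test_events_frame_logs_commands(self):
        result = run_closed_loop(UserModel(route=ROUTE), strategy="dc", seed=0)
        frame = result.events_frame()
        assert {"time", "event", "command", "state"} <= set(frame.columns)
        assert (frame["command"] == "forward").sum() == 5


class TestMetricValidation:
    def test_negative_metrics_rejected(self):
        with pytest.raises(ValueError):
            RotationMetrics(no_error=-1, no_navigation_error=0, no_imagination=0,
                            n_rotations=0, task_time_s=0)
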