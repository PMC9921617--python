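"""The control automaton, rotation strategies, and the street graph."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from minav.navigation import (
    CORRECTION_WINDOW_S,
    EVENT_KINDS,
    STATES,
    ControlEvent,
    NavState,
    Pose,
    StreetGraph,
    grid_city,
    handle_event,
    junction_oracle,
    museum_path,
    rotation_strategy_step,
    straight_path,
)


def ev(kind, t=0.0):
    return ControlEvent(kind=kind, timestamp=t)


@pytest.fixture()
def world():
    return straight_path(6, junctions=(4,))


class TestTransitions:
    def test_flexion_starts_switch(self, world):
        state, cmd = handle_event(NavState(), ev("classified_flexion"), world)
        assert state.state == "switch" and cmd == "start"

    def test_blink_in_switch_enters_rotation(self, world):
        state = NavState(state="switch", state_entered=0.0)
        state, cmd = handle_event(state, ev("blink", 1.0), world)
        assert state.state == "rotation" and cmd == "enter_rotation"

    def test_silent_switch_falls_through_to_walk(self, world):
        state = NavState(state="switch", state_entered=0.0)
        state, cmd = handle_event(state, ev("tick", 1.0), world)
        assert state.state == "switch" and cmd is None  # only 1 s elapsed
        state, cmd = handle_event(state, ev("tick", 2.0), world)
        assert state.state == "walk" and cmd == "start_walk"

    def test_walk_emits_forward_every_second(self, world):
        state = NavState(state="walk", state_entered=0.0, last_forward=0.0)
        state, cmd = handle_event(state, ev("tick", 0.5), world)
        assert cmd is None
        state, cmd = handle_event(state, ev("tick", 1.0), world)
        assert cmd == "forward" and world.agent.node == 1

    def test_low_level_blink_stops_walk(self, world):
        state = NavState(state="walk", mode="low")
        state, cmd = handle_event(state, ev("blink", 1.0), world)
        assert state.state == "idle" and cmd == "stop"

    def test_middle_level_stops_in_front_of_junction(self):
        world = straight_path(6, junctions=(3,))
        world.agent = Pose(1, 0)
        state = NavState(state="walk", mode="middle", last_forward=0.0)
        state, cmd = handle_event(state, ev("tick", 1.0), world)
        assert cmd == "forward" and world.agent.node == 2
        # node 3 ahead is the junction: stop before entering it
        state, cmd = handle_event(state, ev("tick", 2.0), world)
        assert cmd == "stop_at_junction" and state.state == "idle"
        assert world.agent.node == 2

    def test_middle_level_ignores_blink_during_walk(self, world):
        state = NavState(state="walk", mode="middle")
        state, cmd = handle_event(state, ev("blink", 1.0), world)
        assert state.state == "walk" and cmd is None

    def test_blink_exits_rotation(self, world):
        state = NavState(state="rotation")
        state, cmd = handle_event(state, ev("blink", 1.0), world)
        assert state.state == "idle" and cmd == "exit_rotation"

    def test_time_reversal_rejected(self, world):
        state = NavState(clock=5.0)
        with pytest.raises(ValueError, match="nondecreasing"):
            handle_event(state, ev("tick", 1.0), world)

    def test_malformed_event_kind_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            ControlEvent(kind="teleport", timestamp=0.0)

    @given(
        state_name=st.sampled_from([s for s in STATES if s != "correction"]),
        kind=st.sampled_from(EVENT_KINDS),
        mode=st.sampled_from(["low", "middle"]),
        strategy=st.sampled_from(["ne", "dc", "ec"]),
    )
    def test_automaton_is_total(self, state_name, kind, mode, strategy):
        """Every (state, event) pair has a defined transition."""
        world = straight_path(4)
        state = NavState(state=state_name, mode=mode, strategy=strategy,
                         pending_direction="left" if state_name == "correction" else None)
        new_state, _ = handle_event(state, ev(kind, 10.0), world)
        assert new_state.state in STATES

    def test_correction_state_is_total_under_ec(self):
        world = straight_path(4)
        for kind in EVENT_KINDS:
            state = NavState(state="correction", strategy="ec",
                             pending_direction="left", state_entered=0.0)
            new_state, _ = handle_event(state, ev(kind, 10.0), world)
            assert new_state.state in STATES


class TestRotationStrategies:
    def test_ne_executes_every_classification(self, world):
        state = NavState(state="rotation", strategy="ne")
        executed = []
        for direction in ("left", "right", "left", "left"):
            state, done = rotation_strategy_step(state, direction, world=world)
            executed.append(done)
        assert executed == ["left", "right", "left", "left"]

    def test_dc_double_confirmation(self, world):
        state = NavState(state="rotation", strategy="dc")
        state, done = rotation_strategy_step(state, "left", world=world)
        assert done is None and state.pending_direction == "left"
        state, done = rotation_strategy_step(state, "left", world=world)
        assert done == "left" and state.pending_direction is None

    def test_dc_mismatch_resets_without_execution(self, world):
        state = NavState(state="rotation", strategy="dc")
        state, _ = rotation_strategy_step(state, "left", world=world)
        state, done = rotation_strategy_step(state, "right", world=world)
        assert done is None and state.pending_direction is None

    def test_ec_blink_executes_opposite(self, world):
        state = NavState(state="rotation", strategy="ec")
        state, done = rotation_strategy_step(state, "left", world=world)
        assert done is None and state.state == "correction"
        state, done = rotation_strategy_step(state, None, blink=True, world=world)
        assert done == "right" and state.state == "rotation"

    def test_ec_silence_confirms_displayed_direction(self, world):
        state = NavState(state="rotation", strategy="ec")
        state, _ = rotation_strategy_step(state, "left", world=world)
        state, done = rotation_strategy_step(state, None, blink=False, world=world)
        assert done == "left"

    def test_ec_with_reliable_blink_never_rotates_unintended(self, rng):
        """For any error rate, a vetoed arrow flips to the intended side."""
        world = straight_path(3)
        for _ in range(200):
            intended = rng.choice(["left", "right"])
            classified = intended if rng.random() < 0.5 else (
                "right" if intended == "left" else "left")
            state = NavState(state="rotation", strategy="ec")
            state, _ = rotation_strategy_step(state, classified, world=world)
            blink = state.pending_direction != intended
            _, done = rotation_strategy_step(state, None, blink=blink, world=world)
            assert done == intended

    def test_rotation_updates_heading(self):
        world = straight_path(3)
        state = NavState(state="rotation", strategy="ne")
        rotation_strategy_step(state, "left", world=world)
        assert world.agent.heading == 1
        rotation_strategy_step(state, "right", world=world)
        rotation_strategy_step(state, "right", world=world)
        assert world.agent.heading == 3

    def test_step_outside_rotation_rejected(self):
        with pytest.raises(ValueError, match="illegal"):
            rotation_strategy_step(NavState(state="walk"), "left")


class TestStreetGraph:
    def test_junction_oracle_looks_one_edge_ahead(self):
        world = straight_path(5, junctions=(3,))
        assert not junction_oracle(world, Pose(1, 0))
        assert junction_oracle(world, Pose(2, 0))

    def test_degree_rule_flags_crossings(self):
        world = grid_city(3, 3)
        # centre node of a 3x3 grid has four neighbors
        assert world.is_junction((1, 1))
        assert not world.is_junction((0, 0))

    def test_isolated_node_is_not_a_junction(self):
        world = StreetGraph()
        world.add_node("x", (0, 0))
        world.agent = Pose("x", 0)
        assert not junction_oracle(world, world.agent)

    def test_dangling_edge_rejected(self):
        world = StreetGraph()
        world.add_node("a", (0, 0))
        with pytest.raises(ValueError, match="dangling"):
            world.add_street("a", "ghost")

    def test_museum_path_is_connected_corridor(self):
        world = museum_path()
        assert world.neighbor_ahead(0, 0) == 1

    def test_yaml_json_roundtrip(self, tmp_path):
        world = straight_path(5, junctions=(3,))
        for name in ("world.yaml", "world.json"):
            path = tmp_path / name
            world.save(path)
            loaded = StreetGraph.from_file(path)
            assert set(loaded.graph.nodes) == set(world.graph.nodes)
            assert set(loaded.graph.edges) == set(world.graph.edges)
            assert loaded.is_junction(3) and not loaded.is_junction(2)

    def test_correction_state_requires_ec(self):
        with pytest.raises(ValueError, match="only under EC"):
            NavState(state="correction", strategy="dc")
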