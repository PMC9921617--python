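"""Shared-control navigation automaton over a simulated street graph.

The control loop has five states.  From *idle*, a decoded two-hand
flexion enters a 2 s *switch* state: a blink there selects *rotation*,
doing nothing falls through to *walk*.  Walking emits a forward move
every second; low-level mode stops on a blink, middle-level mode stops
automatically in front of the next junction.  In the rotation state a
decoded left/right clench drives one of three error-control strategies:

* **NE** (no error control): every classification executes immediately.
* **DC** (double confirmation): an arrow shows the first classification;
  a second identical classification executes it, a mismatch resets.
* **EC** (error correction): the arrow enters a *correction* state; a
  blink within the correction window vetoes the arrow and executes the
  opposite direction, silence executes the displayed one.

Headings are quantized to the four compass directions and a rotation
command is one discrete 90-degree increment, mirroring street-view arrow
semantics; the world is a directed graph with 2-D node positions and
junction flags, standing in for a street-map service.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import networkx as nx
import yaml

__all__ = [
    "StreetGraph",
    "Pose",
    "NavState",
    "ControlEvent",
    "handle_event",
    "rotation_strategy_step",
    "junction_oracle",
    "straight_path",
    "grid_city",
    "museum_path",
    "SWITCH_DURATION_S",
    "CORRECTION_WINDOW_S",
    "WALK_STEP_S",
]

STATES = ("idle", "switch", "walk", "rotation", "correction")
MODES = ("low", "middle")
STRATEGIES = ("ne", "dc", "ec")
EVENT_KINDS = (
    "classified_left",
    "classified_right",
    "classified_flexion",
    "blink",
    "tick",
    "junction_reached",
)

SWITCH_DURATION_S = 2.0     # transition state between flexion and walking
CORRECTION_WINDOW_S = 2.0   # EC blink-veto dwell (one blink-detection epoch)
WALK_STEP_S = 1.0           # one forward move per second while walking

#: Compass directions, counter-clockwise: E, N, W, S.
HEADINGS = ((1, 0), (0, 1), (-1, 0), (0, -1))


@dataclass
class Pose:
    node: object
    heading: int  # index into HEADINGS

    def __post_init__(self):
        self.heading %= 4


class StreetGraph:
    """Directed street graph with node positions, junction flags and the
    agent's pose."""

    def __init__(self, graph: nx.DiGraph | None = None, agent: Pose | None = None):
        self.graph = graph if graph is not None else nx.DiGraph()
        self.agent = agent

    # ------------------------------------------------------------ topology

    def add_node(self, name, pos, junction: bool = False):
        self.graph.add_node(name, pos=tuple(pos), junction=bool(junction))

    def add_street(self, a, b):
        """Two-way street segment between existing nodes."""
        for node in (a, b):
            if node not in self.graph:
                raise ValueError(f"dangling edge endpoint {node!r}")
        self.graph.add_edge(a, b)
        self.graph.add_edge(b, a)

    def auto_flag_junctions(self, min_degree: int = 3):
        """Flag every node with at least ``min_degree`` distinct neighbors."""
        for node in self.graph.nodes:
            if len(set(self.graph.successors(node))) >= min_degree:
                self.graph.nodes[node]["junction"] = True

    def is_junction(self, node) -> bool:
        return bool(self.graph.nodes[node].get("junction", False))

    def _edge_heading(self, a, b) -> int:
        xa, ya = self.graph.nodes[a]["pos"]
        xb, yb = self.graph.nodes[b]["pos"]
        angle = math.atan2(yb - ya, xb - xa)
        return int(round(angle / (math.pi / 2))) % 4

    def neighbor_ahead(self, node, heading: int):
        """Successor reachable along the given compass heading, or None."""
        if node not in self.graph:
            raise ValueError(f"node {node!r} not in graph")
        for nb in self.graph.successors(node):
            if nb not in self.graph.nodes or "pos" not in self.graph.nodes[nb]:
                raise ValueError(f"dangling edge {node!r} -> {nb!r}")
            if self._edge_heading(node, nb) == heading:
                return nb
        return None

    # ------------------------------------------------------------------ i/o

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {
                    "name": n,
                    "pos": list(self.graph.nodes[n]["pos"]),
                    "junction": bool(self.graph.nodes[n].get("junction", False)),
                }
                for n in self.graph.nodes
            ],
            "edges": [[a, b] for a, b in self.graph.edges],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "StreetGraph":
        world = cls()
        for node in payload["nodes"]:
            world.add_node(node["name"], node["pos"], node.get("junction", False))
        for a, b in payload["edges"]:
            for endpoint in (a, b):
                if endpoint not in world.graph:
                    raise ValueError(f"edge references unknown node {endpoint!r}")
            world.graph.add_edge(a, b)
        return world

    @classmethod
    def from_file(cls, path) -> "StreetGraph":
        text = open(path).read()
        payload = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(payload)

    def save(self, path):
        payload = self.to_dict()
        with open(path, "w") as fh:
            if str(path).endswith(".json"):
                json.dump(payload, fh, indent=2)
            else:
                yaml.safe_dump(payload, fh)


def junction_oracle(world: StreetGraph, pose: Pose) -> bool:
    """True iff the node ahead along the agent's heading is a junction."""
    ahead = world.neighbor_ahead(pose.node, pose.heading)
    return ahead is not None and world.is_junction(ahead)


# ----------------------------------------------------------------- automaton


@dataclass(frozen=True)
class NavState:
    """Immutable snapshot of the control automaton."""

    state: str = "idle"
    mode: str = "low"
    strategy: str = "ne"
    pending_direction: str | None = None
    clock: float = 0.0
    state_entered: float = 0.0
    last_forward: float = 0.0

    def __post_init__(self):
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.state == "correction" and self.strategy != "ec":
            raise ValueError("correction state is reachable only under EC")


@dataclass(frozen=True)
class ControlEvent:
    kind: str
    timestamp: float

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"malformed event kind {self.kind!r}")


def _opposite(direction: str) -> str:
    return "right" if direction == "left" else "left"


def _rotate(world: StreetGraph | None, direction: str):
    if world is not None and world.agent is not None:
        delta = 1 if direction == "left" else -1
        world.agent = Pose(world.agent.node, world.agent.heading + delta)


def rotation_strategy_step(
    state: NavState,
    classification: str | None,
    blink: bool = False,
    world: StreetGraph | None = None,
):
    """One strategy step in the rotation/correction states.

    Returns ``(new_state, executed_direction_or_None)``.  ``classification``
    is ``"left"``/``"right"`` (or None when the step is a pure blink/timeout
    in the EC correction state).  Executed rotations are applied to the
    world's agent pose when a world is given.
    """
    if state.state not in ("rotation", "correction"):
        raise ValueError(f"strategy step illegal in state {state.state!r}")
    if classification is not None and classification not in ("left", "right"):
        raise ValueError(f"bad classification {classification!r}")

    if state.strategy == "ne":
        if classification is None:
            return state, None
        _rotate(world, classification)
        return state, classification

    if state.strategy == "dc":
        if classification is None:
            return state, None
        if state.pending_direction is None:
            return replace(state, pending_direction=classification), None
        if state.pending_direction == classification:
            _rotate(world, classification)
            return replace(state, pending_direction=None), classification
        # mismatch: reset, nothing executed
        return replace(state, pending_direction=None), None

    # EC
    if state.state == "rotation":
        if classification is None:
            return state, None
        return (
            replace(state, state="correction", pending_direction=classification,
                    state_entered=state.clock),
            None,
        )
    # correction state: blink vetoes, silence (timeout) confirms
    pending = state.pending_direction
    executed = _opposite(pending) if blink else pending
    _rotate(world, executed)
    return replace(state, state="rotation", pending_direction=None), executed


def handle_event(state: NavState, event: ControlEvent, world: StreetGraph):
    """Deterministic transition of the automaton.

    Returns ``(new_state, command_or_None)``.  Commands are short strings
    (``"start"``, ``"start_walk"``, ``"forward"``, ``"stop"``,
    ``"stop_at_junction"``, ``"enter_rotation"``, ``"exit_rotation"``,
    ``"show_arrow_left"``/``"show_arrow_right"``, ``"rotate_left"``/
    ``"rotate_right"``).  Irrelevant events are no-ops; unknown event
    kinds or time reversals are rejected with the state unchanged.
    """
    if event.timestamp < state.clock:
        raise ValueError("event timestamps must be nondecreasing")
    t = event.timestamp
    state = replace(state, clock=t)
    kind = event.kind

    if state.state == "idle":
        if kind == "classified_flexion":
            return replace(state, state="switch", state_entered=t), "start"
        return state, None

    if state.state == "switch":
        if kind == "blink":
            return replace(state, state="rotation", state_entered=t), "enter_rotation"
        if kind == "tick" and t - state.state_entered >= SWITCH_DURATION_S:
            return (
                replace(state, state="walk", state_entered=t, last_forward=t),
                "start_walk",
            )
        return state, None

    if state.state == "walk":
        if kind == "blink" and state.mode == "low":
            return replace(state, state="idle", state_entered=t), "stop"
        if kind == "junction_reached" and state.mode == "middle":
            return replace(state, state="idle", state_entered=t), "stop_at_junction"
        if kind == "tick" and t - state.last_forward >= WALK_STEP_S:
            # middle-level look-ahead: stop in front of a junction
            if (
                state.mode == "middle"
                and world.agent is not None
                and junction_oracle(world, world.agent)
            ):
                return replace(state, state="idle", state_entered=t), "stop_at_junction"
            if world.agent is not None:
                ahead = world.neighbor_ahead(world.agent.node, world.agent.heading)
                if ahead is not None:
                    world.agent = Pose(ahead, world.agent.heading)
                    return replace(state, last_forward=t), "forward"
            return replace(state, last_forward=t), None
        return state, None

    if state.state == "rotation":
        if kind in ("classified_left", "classified_right"):
            direction = kind.removeprefix("classified_")
            new_state, executed = rotation_strategy_step(state, direction, world=world)
            if executed is not None:
                return new_state, f"rotate_{executed}"
            if new_state.state == "correction" or new_state.pending_direction:
                shown = new_state.pending_direction
                return new_state, f"show_arrow_{shown}"
            return new_state, None
        if kind == "blink":
            return replace(state, state="idle", state_entered=t), "exit_rotation"
        return state, None

    # correction (EC only)
    if kind == "blink":
        new_state, executed = rotation_strategy_step(state, None, blink=True, world=world)
        return new_state, f"rotate_{executed}"
    if kind == "tick" and t - state.state_entered >= CORRECTION_WINDOW_S:
        new_state, executed = rotation_strategy_step(state, None, blink=False, world=world)
        return new_state, f"rotate_{executed}"
    return state, None


# ------------------------------------------------------------------ fixtures


def straight_path(n_nodes: int, junctions=(), spacing: float = 1.0) -> StreetGraph:
    """A straight east-west street of ``n_nodes`` nodes; selected node
    indices are flagged as junctions."""
    world = StreetGraph()
    for i in range(n_nodes):
        world.add_node(i, (i * spacing, 0.0), junction=i in set(junctions))
    for i in range(n_nodes - 1):
        world.add_street(i, i + 1)
    world.agent = Pose(0, 0)
    return world


def grid_city(rows: int = 4, cols: int = 4, spacing: float = 1.0) -> StreetGraph:
    """A rectangular street grid; interior crossings become junctions
    (degree rule).  Mimics an unknown-city route map."""
    world = StreetGraph()
    for r in range(rows):
        for c in range(cols):
            world.add_node((r, c), (c * spacing, r * spacing))
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                world.add_street((r, c), (r, c + 1))
            if r + 1 < rows:
                world.add_street((r, c), (r + 1, c))
    world.auto_flag_junctions()
    world.agent = Pose((0, 0), 0)
    return world


def museum_path() -> StreetGraph:
    """A hand-drawn gallery corridor with two turns — a low-level-control
    scenario where the user stops at exhibits by blinking (synthetic
    layout, not geo-accurate)."""
    world = StreetGraph()
    coords = [
        (0, 0), (1, 0), (2, 0), (3, 0),          # entrance corridor, eastbound
        (3, 1), (3, 2),                          # north wing
        (2, 2), (1, 2), (0, 2),                  # west gallery
    ]
    for i, pos in enumerate(coords):
        world.add_node(i, pos)
    for i in range(len(coords) - 1):
        world.add_street(i, i + 1)
    world.agent = Pose(0, 0)
    return world
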