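"""Closed-loop simulation, rotation metrics, and analytic oracles.

A :class:`UserModel` follows an intended route — legs of forward walking
interleaved with single left/right turns — through the navigation
automaton.  In *abstract* mode each imagination is classified correctly
with probability ``p`` and each blink is detected with probability ``q``;
in *full* mode the user's imaginations are rendered as synthetic EEG and
pushed through a trained decoder pipeline, so the whole stack is
exercised end to end behind one interface.

Per intended rotation the simulator counts, following the field's
convention:

* ``No_error`` — misclassified imagination trials,
* ``No_navigation_error`` — wrong rotations actually executed,
* ``No_imagination`` — imagination trials until the intended rotation
  is in effect,

plus a simulated-time account built from the epoch lengths (6 s flexion,
2 s left/right), the 2 s switch state, the 0.5 s blink-detection quantum,
the EC correction window, and 1 s per forward move.

Closed forms for the expected number of imaginations per net intended
rotation: the controller keeps issuing intents toward the target, so the
net rotation offset performs a +-1 random walk absorbed at +1.  Under NE
each imagination steps the walk (success probability ``p``), giving
``1/(2p - 1)``; under DC only agreeing pairs execute (``p^2`` vs
``(1-p)^2``), giving ``2/(2p - 1)``; under EC with reliable blink
detection every error is vetoed and flipped, giving exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decoder import FLEXION_REST, LEFT_RIGHT, DecoderPipeline
from .navigation import (
    CORRECTION_WINDOW_S,
    SWITCH_DURATION_S,
    WALK_STEP_S,
    ControlEvent,
    NavState,
    Pose,
    StreetGraph,
    handle_event,
)
from .signals import detect_blink
from .synthetic import SyntheticConfig, generate_trial, inject_blink

__all__ = [
    "UserModel",
    "RotationMetrics",
    "SimResult",
    "run_closed_loop",
    "expected_imaginations",
    "monte_carlo_rotations",
    "compare_strategies",
]

BLINK_QUANTUM_S = 0.5  # online update interval: one blink-detection attempt
FLEXION_EPOCH_S = 6.0
LR_EPOCH_S = 2.0


@dataclass
class UserModel:
    """Route-following user driving the control loop.

    ``route`` is a list of legs: ``("walk", n_nodes)`` or
    ``("turn", "left"|"right")``.  With ``pipeline`` set the user runs in
    *full* mode: imaginations become synthetic EEG epochs decoded by the
    trained pipeline, and blinks become injected transients passed to the
    blink detector.  Otherwise classifications are abstract Bernoulli
    draws with accuracy ``p`` and blink reliability ``q``.
    """

    route: list
    p: float = 1.0
    q: float = 1.0
    pipeline: DecoderPipeline | None = None
    synth: SyntheticConfig | None = None

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.q <= 1.0):
            raise ValueError("p and q must lie in [0, 1]")
        if self.pipeline is not None and self.synth is None:
            self.synth = SyntheticConfig()

    # Each hook returns the *decoded* outcome of one attempt.

    def attempt_flexion(self, rng) -> bool:
        if self.pipeline is None:
            return True
        trial = generate_trial(self.synth, "flexion", rng)
        decision = self.pipeline.classify_epoch(trial.epoch, FLEXION_REST)
        return decision.kind == "label" and decision.label == "flexion"

    def attempt_clench(self, intent: str, rng) -> str | None:
        """Decoded direction of one left/right imagination (None when the
        artifact gate refuses the epoch)."""
        if self.pipeline is None:
            correct = rng.random() < self.p
            return intent if correct else ("right" if intent == "left" else "left")
        trial = generate_trial(self.synth, intent, rng)
        decision = self.pipeline.classify_epoch(trial.epoch, LEFT_RIGHT)
        return decision.label if decision.kind == "label" else None

    def attempt_blink(self, rng) -> bool:
        if self.pipeline is None:
            return rng.random() < self.q
        synth = self.synth
        trial = generate_trial(synth, "rest", rng)
        epoch = inject_blink(trial.epoch, 0.5, synth)
        return detect_blink(epoch, self.pipeline.config.thresholds)


@dataclass(frozen=True)
class RotationMetrics:
    """Per-intended-rotation averages over one simulated task."""

    no_error: float
    no_navigation_error: float
    no_imagination: float
    n_rotations: int
    task_time_s: float

    def __post_init__(self):
        if min(self.no_error, self.no_navigation_error, self.no_imagination) < 0:
            raise ValueError("rotation metrics must be nonnegative")


@dataclass
class SimResult:
    events: list
    metrics: RotationMetrics
    per_rotation: list
    trajectory: list
    walk_command_times: list
    rotation_issue_times: list
    completed: bool
    total_time_s: float

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events)


def _intent_toward(offset_to_target: int) -> str:
    # positive offset = counter-clockwise (left) remaining
    return "left" if offset_to_target > 0 else "right"


class _Loop:
    """Internal clock + event plumbing for one simulated task."""

    def __init__(self, user: UserModel, strategy: str, mode: str,
                 world: StreetGraph, rng):
        self.user = user
        self.world = world
        self.rng = rng
        self.t = 0.0
        self.state = NavState(mode=mode, strategy=strategy)
        self.events = []
        self.trajectory = [world.agent.node]

    def emit(self, kind: str):
        event = ControlEvent(kind=kind, timestamp=self.t)
        self.state, command = handle_event(self.state, event, self.world)
        self.events.append(
            {"time": self.t, "event": kind, "command": command,
             "state": self.state.state}
        )
        if command == "forward":
            self.trajectory.append(self.world.agent.node)
        return command

    def advance(self, seconds: float):
        self.t += seconds

    def blink_until_detected(self, max_attempts: int = 10_000) -> bool:
        for _ in range(max_attempts):
            self.advance(BLINK_QUANTUM_S)
            if self.user.attempt_blink(self.rng):
                self.emit("blink")
                return True
        return False

    def flexion_until_detected(self, max_attempts: int = 10_000) -> int:
        attempts = 0
        for _ in range(max_attempts):
            self.advance(FLEXION_EPOCH_S)
            attempts += 1
            if self.user.attempt_flexion(self.rng):
                self.emit("classified_flexion")
                return attempts
        return attempts


def run_closed_loop(
    user: UserModel,
    strategy: str = "ne",
    mode: str = "low",
    world: StreetGraph | None = None,
    seed: int = 0,
    max_imaginations_per_rotation: int = 100_000,
) -> SimResult:
    """Simulate one full route and measure the rotation metrics.

    The route must be feasible in the world (each walk leg must have the
    requested number of nodes ahead; turns assume the agent keeps
    correcting until its net heading matches the intent).
    """
    if world is None:
        world = _default_world_for(user.route, mode)
    if world.agent is None:
        raise ValueError("world has no agent pose")
    rng = np.random.default_rng(seed)
    loop = _Loop(user, strategy, mode, world, rng)
    per_rotation = []
    walk_times = []
    rotation_issue_times = []
    completed = True

    for leg in user.route:
        kind = leg[0]
        if kind == "walk":
            target_steps = int(leg[1])
            if _walk_feasible_steps(world) < target_steps:
                raise ValueError("infeasible route: walk leg exceeds the street")
            t0 = loop.t
            attempts = loop.flexion_until_detected()
            walk_times.append(FLEXION_EPOCH_S * attempts)
            # switch state passes in silence
            loop.advance(SWITCH_DURATION_S)
            loop.emit("tick")
            assert loop.state.state == "walk"
            steps = 0
            while loop.state.state == "walk":
                loop.advance(WALK_STEP_S)
                cmd = loop.emit("tick")
                if cmd == "forward":
                    steps += 1
                    if mode == "low" and steps >= target_steps:
                        if not loop.blink_until_detected():
                            completed = False
                            break
                elif cmd == "stop_at_junction":
                    break
                elif cmd is None and loop.state.state == "walk":
                    # dead end: nothing ahead, stop trying
                    loop.emit("blink") if mode == "low" else None
                    break
        elif kind == "turn":
            direction = leg[1]
            # flexion -> switch -> blink selects rotation
            loop.flexion_until_detected()
            if not loop.blink_until_detected():
                completed = False
                continue
            assert loop.state.state == "rotation"
            entry_time = loop.t
            record = _rotate_until_done(
                loop, direction, strategy, max_imaginations_per_rotation
            )
            rotation_issue_times.append(loop.t - entry_time)
            per_rotation.append(record)
            # blink exits the rotation state
            loop.blink_until_detected()
        else:
            raise ValueError(f"unknown route leg {leg!r}")

    n_rot = len(per_rotation)
    metrics = RotationMetrics(
        no_error=float(np.mean([r["errors"] for r in per_rotation])) if n_rot else 0.0,
        no_navigation_error=(
            float(np.mean([r["wrong_rotations"] for r in per_rotation])) if n_rot else 0.0
        ),
        no_imagination=(
            float(np.mean([r["imaginations"] for r in per_rotation])) if n_rot else 0.0
        ),
        n_rotations=n_rot,
        task_time_s=loop.t,
    )
    return SimResult(
        events=loop.events,
        metrics=metrics,
        per_rotation=per_rotation,
        trajectory=loop.trajectory,
        walk_command_times=walk_times,
        rotation_issue_times=rotation_issue_times,
        completed=completed,
        total_time_s=loop.t,
    )


def _rotate_until_done(loop: _Loop, direction: str, strategy: str, cap: int) -> dict:
    """Issue imaginations until the net intended rotation is in effect.

    The controller tracks the *net* heading offset (unbounded), so a
    wrong execution is always corrected by counter-rotating rather than
    by going the long way around.
    """
    target = 1 if direction == "left" else -1
    offset = 0
    imaginations = errors = wrong = 0
    for _ in range(cap):
        if offset == target:
            break
        intent = _intent_toward(target - offset)
        loop.advance(LR_EPOCH_S)
        classified = loop.user.attempt_clench(intent, loop.rng)
        if classified is None:  # artifact-rejected epoch: retry
            continue
        imaginations += 1
        if classified != intent:
            errors += 1
        cmd = loop.emit(f"classified_{classified}")
        if loop.state.state == "correction":
            # EC: dwell in the correction window; blink vetoes a wrong arrow
            loop.advance(CORRECTION_WINDOW_S)
            shown = loop.state.pending_direction
            if shown != intent and loop.user.attempt_blink(loop.rng):
                cmd = loop.emit("blink")
            else:
                cmd = loop.emit("tick")
        if cmd in ("rotate_left", "rotate_right"):
            executed = cmd.removeprefix("rotate_")
            offset += 1 if executed == "left" else -1
            if executed != intent:
                wrong += 1
    return {"imaginations": imaginations, "errors": errors, "wrong_rotations": wrong,
            "direction": direction}


def _walk_feasible_steps(world: StreetGraph) -> int:
    pose = world.agent
    node, steps = pose.node, 0
    seen = set()
    while True:
        ahead = world.neighbor_ahead(node, pose.heading)
        if ahead is None or (node, ahead) in seen:
            return steps
        seen.add((node, ahead))
        node = ahead
        steps += 1


def _default_world_for(route, mode: str) -> StreetGraph:
    """Trace the route into a street polyline.

    Walk legs become streets along the current heading; turns bend the
    polyline.  In middle-level mode a flagged junction node is placed one
    step beyond the end of each walk leg, so the automaton's look-ahead
    stops the agent exactly where the route turns.
    """
    from .navigation import HEADINGS

    world = StreetGraph()
    heading = 0
    pos = (0, 0)
    world.add_node(pos, pos)

    def step(p, h):
        dx, dy = HEADINGS[h]
        return (p[0] + dx, p[1] + dy)

    for leg in route:
        if leg[0] == "walk":
            for _ in range(int(leg[1])):
                nxt = step(pos, heading)
                if nxt not in world.graph:
                    world.add_node(nxt, nxt)
                world.add_street(pos, nxt)
                pos = nxt
            if mode == "middle":
                spur = step(pos, heading)
                if spur not in world.graph:
                    world.add_node(spur, spur, junction=True)
                else:
                    world.graph.nodes[spur]["junction"] = True
                world.add_street(pos, spur)
        elif leg[0] == "turn":
            heading = (heading + (1 if leg[1] == "left" else -1)) % 4
    world.agent = Pose((0, 0), 0)
    return world


# ------------------------------------------------------------------ oracles


def expected_imaginations(strategy: str, p: float, q: float = 1.0) -> float:
    """Expected imaginations per net intended rotation (closed form).

    NE: ``1/(2p - 1)``; DC: ``2/(2p - 1)``; EC: ``1/(2r - 1)`` with
    effective success ``r = p + (1 - p) q`` (exactly 1 when ``q = 1``).
    Diverges (raises) when the success probability is not above 1/2.
    """
    strategy = strategy.lower()
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if strategy == "ne":
        if p <= 0.5:
            raise ValueError("NE walk does not drift toward the goal for p <= 0.5")
        return 1.0 / (2.0 * p - 1.0)
    if strategy == "dc":
        if p <= 0.5:
            raise ValueError("DC walk does not drift toward the goal for p <= 0.5")
        return 2.0 / (2.0 * p - 1.0)
    if strategy == "ec":
        r = p + (1.0 - p) * q
        if r <= 0.5:
            raise ValueError("EC effective accuracy not above 1/2")
        return 1.0 / (2.0 * r - 1.0)
    raise ValueError(f"unknown strategy {strategy!r}")


def monte_carlo_rotations(
    strategy: str,
    p: float,
    n_rotations: int,
    seed: int = 0,
    q: float = 1.0,
    max_rounds: int = 1_000_000,
) -> dict:
    """Brute-force the rotation sub-game for ``n_rotations`` independent
    intended rotations; returns mean ``no_imagination``, ``no_error`` and
    ``no_navigation_error`` per rotation.

    Each rotation is a +-1 walk absorbed at +1, simulated directly from
    Bernoulli draws — the independent check of the closed forms.
    """
    strategy = strategy.lower()
    rng = np.random.default_rng(seed)
    offset = np.zeros(n_rotations, dtype=np.int64)
    imaginations = np.zeros(n_rotations, dtype=np.int64)
    errors = np.zeros(n_rotations, dtype=np.int64)
    wrong = np.zeros(n_rotations, dtype=np.int64)

    for _ in range(max_rounds):
        active = offset != 1
        n_active = int(active.sum())
        if n_active == 0:
            break
        if strategy == "ne":
            correct = rng.random(n_active) < p
            imaginations[active] += 1
            errors[active] += ~correct
            wrong[active] += ~correct
            offset[active] += np.where(correct, 1, -1)
        elif strategy == "dc":
            first = rng.random(n_active) < p
            second = rng.random(n_active) < p
            imaginations[active] += 2
            errors[active] += (~first).astype(np.int64) + (~second).astype(np.int64)
            both_ok = first & second
            both_bad = ~first & ~second
            wrong[active] += both_bad
            offset[active] += np.where(both_ok, 1, np.where(both_bad, -1, 0))
        elif strategy == "ec":
            correct = rng.random(n_active) < p
            veto = rng.random(n_active) < q
            imaginations[active] += 1
            errors[active] += ~correct
            executed_ok = correct | veto
            wrong[active] += ~executed_ok
            offset[active] += np.where(executed_ok, 1, -1)
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
    return {
        "no_imagination": float(imaginations.mean()),
        "no_error": float(errors.mean()),
        "no_navigation_error": float(wrong.mean()),
        "n": int(n_rotations),
    }


def compare_strategies(
    p_grid,
    n_rotations: int = 10_000,
    seed: int = 0,
    q: float = 1.0,
) -> pd.DataFrame:
    """Monte-Carlo rotation metrics for every strategy over an accuracy
    grid, with the analytic expectation alongside — the simulated
    counterpart of a strategy-comparison summary table."""
    p_grid = list(p_grid)
    if not p_grid:
        raise ValueError("empty accuracy grid")
    rows = []
    for i, p in enumerate(p_grid):
        for j, strategy in enumerate(("ne", "dc", "ec")):
            mc = monte_carlo_rotations(strategy, p, n_rotations,
                                       seed=seed + 31 * i + j, q=q)
            try:
                analytic = expected_imaginations(strategy, p, q)
            except ValueError:
                analytic = float("nan")
            rows.append(
                {"p": p, "strategy": strategy, **{k: v for k, v in mc.items() if k != "n"},
                 "expected_imagination": analytic}
            )
    return pd.DataFrame(rows)
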