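"""Discrete-time simulator of myoelectric telecar control paradigms.

The vehicle lives on a plane, moves in 12 cm quanta and turns in 45-degree
quanta at constant speeds (12 cm/s linear, 0.25*pi rad/s angular), so every
motion quantum costs exactly one second.  Classifier outputs (or scripted
intent streams) drive one of three paradigms:

* **Paradigm 2** (fixed moving): one channel; a command is issued only
  when two consecutive 125 ms analysis epochs agree.  Mapping: MF=forward,
  REST=backward, WE=clockwise 45 deg, WF=anti-clockwise 45 deg.
* **Paradigm 3** (channel combination): two channels; a command is issued
  only when both channels predict the same class, otherwise the vehicle
  stops and waits.  Same mapping as Paradigm 2.  Recording is concurrent
  with motion, so recognition adds no time while the vehicle moves.
* **Paradigm 4** (state machine): one channel; REST toggles between
  straight-line mode (WF=forward, WE=backward) and rotation mode
  (WF=anti-clockwise, WE=clockwise), MF stops.  The mode can only toggle
  after at least one motion has been executed in the current mode.

Session metrics are travel time and, where defined, recognition rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

STEP_CM = 12.0
TURN_DEG = 45.0
LINEAR_SPEED = 12.0  # cm/s
ANGULAR_SPEED = 0.25 * np.pi  # rad/s

COMMANDS = ("forward", "backward", "cw", "ccw", "stop")

#: Class -> command for the fixed-moving and channel-combination paradigms.
DIRECT_MAP = {"MF": "forward", "REST": "backward", "WE": "cw", "WF": "ccw"}

#: Class -> command per mode for the state-machine paradigm.
STATE_MAP = {
    "straight": {"WF": "forward", "WE": "backward"},
    "rotation": {"WF": "ccw", "WE": "cw"},
}


@dataclass(frozen=True)
class VehicleState:
    """Pose plus state-machine bookkeeping.

    Heading follows the mathematical convention (degrees counter-clockwise
    from +x, normalized to [0, 360)); ``mode`` and ``motions_in_mode`` are
    only meaningful under Paradigm 4.
    """

    x: float = 0.0
    y: float = 0.0
    heading: float = 90.0
    mode: str = "straight"
    stopped: bool = False
    motions_in_mode: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "heading", self.heading % 360.0)


def step_vehicle(state: VehicleState, command: str) -> VehicleState:
    """Apply one motion quantum: +/-12 cm translation or +/-45 deg rotation."""
    if command not in COMMANDS:
        raise ValueError(f"unknown command {command!r}")
    if command == "stop":
        return replace(state, stopped=True)
    if command in ("forward", "backward"):
        sign = 1.0 if command == "forward" else -1.0
        rad = np.deg2rad(state.heading)
        return replace(
            state,
            x=state.x + sign * STEP_CM * np.cos(rad),
            y=state.y + sign * STEP_CM * np.sin(rad),
            stopped=False,
            motions_in_mode=state.motions_in_mode + 1,
        )
    delta = -TURN_DEG if command == "cw" else TURN_DEG
    return replace(
        state,
        heading=(state.heading + delta) % 360.0,
        stopped=False,
        motions_in_mode=state.motions_in_mode + 1,
    )


@dataclass
class MapConfig:
    """Square-loop course with optional rectangular obstacle cells.

    ``obstacles`` are (x0, y0, x1, y1) axis-aligned rectangles in cm; a
    translation whose destination lies inside one is refused.
    """

    side_cm: float = 40.0
    loops: int = 2
    obstacles: list[tuple[float, float, float, float]] = field(default_factory=list)

    def blocks(self, x: float, y: float) -> bool:
        return any(x0 <= x <= x1 and y0 <= y <= y1 for x0, y0, x1, y1 in self.obstacles)


@dataclass
class ParadigmConfig:
    """Control-paradigm parameters."""

    paradigm: int = 2
    window_ms: float = 125.0
    overlap_frac: float = 0.2
    linear_speed: float = LINEAR_SPEED
    angular_speed: float = ANGULAR_SPEED

    def __post_init__(self) -> None:
        if self.paradigm not in (2, 3, 4):
            raise ValueError("paradigm must be 2, 3 or 4")
        if self.window_ms <= 0 or self.linear_speed <= 0 or self.angular_speed <= 0:
            raise ValueError("window and speeds must be positive")

    def command_time_s(self, command: str) -> float:
        if command in ("forward", "backward"):
            return STEP_CM / self.linear_speed
        if command in ("cw", "ccw"):
            return np.deg2rad(TURN_DEG) / self.angular_speed
        return 0.0


@dataclass
class SessionMetrics:
    """Outcome of one simulated session."""

    travel_time_s: float
    recognition_rate_pct: float | None
    command_log: list[dict]
    n_collisions: int


def _validate_label(label: str) -> None:
    if label not in DIRECT_MAP:
        raise ValueError(f"unknown movement label {label!r}")


def run_paradigm(
    intents,
    config: ParadigmConfig,
    initial_state: VehicleState | None = None,
    map_config: MapConfig | None = None,
    ground_truth=None,
):
    """Drive the vehicle from an intent stream; return metrics and trajectory.

    ``intents`` is a list of labels (Paradigms 2 and 4) or of
    ``(ch1, ch2)`` label pairs (Paradigm 3).  ``ground_truth``, when given
    and the paradigm defines one, yields the recognition rate.  Time
    accounting: every executed motion quantum costs one second; under
    Paradigm 2 each analysis epoch additionally costs its window length
    (recognition precedes motion), while under Paradigms 3 and 4
    recognition is concurrent with motion and only idle decisions (stop,
    disagreement, mode toggles) cost window time.
    """
    state = initial_state or VehicleState()
    window_s = config.window_ms / 1000.0
    t = 0.0
    log: list[dict] = []
    trajectory = [(t, state)]
    collisions = 0

    def execute(command: str, label, now: float):
        nonlocal state, collisions
        new = step_vehicle(state, command)
        blocked = (
            command in ("forward", "backward")
            and map_config is not None
            and map_config.blocks(new.x, new.y)
        )
        if blocked:
            collisions += 1
            new = step_vehicle(state, "stop")
            command = "stop"
        state = new
        log.append(
            {"t": now, "label": label, "command": command, "collision": blocked}
        )
        return command

    if config.paradigm == 2:
        pending = None
        for label in intents:
            _validate_label(label)
            t += window_s
            if label == pending:
                cmd = DIRECT_MAP[label]
                cmd = execute(cmd, label, t)
                t += config.command_time_s(cmd)
                pending = None
            else:
                pending = label
        trajectory.append((t, state))

    elif config.paradigm == 3:
        for ch1, ch2 in intents:
            _validate_label(ch1)
            _validate_label(ch2)
            if ch1 == ch2:
                cmd = execute(DIRECT_MAP[ch1], (ch1, ch2), t)
                dt = config.command_time_s(cmd)
                t += dt if dt > 0 else window_s
            else:
                execute("stop", (ch1, ch2), t)
                t += window_s
            trajectory.append((t, state))

    else:  # paradigm 4
        for label in intents:
            _validate_label(label)
            if label == "REST":
                if state.motions_in_mode >= 1:
                    new_mode = "rotation" if state.mode == "straight" else "straight"
                    state = replace(state, mode=new_mode, motions_in_mode=0)
                    log.append({"t": t, "label": label, "command": "toggle"})
                else:
                    log.append({"t": t, "label": label, "command": "ignored"})
                t += window_s
            elif label == "MF":
                execute("stop", label, t)
                t += window_s
            else:
                cmd = STATE_MAP[state.mode][label]
                cmd = execute(cmd, label, t)
                dt = config.command_time_s(cmd)
                t += dt if dt > 0 else window_s
            trajectory.append((t, state))

    rr = None
    if ground_truth is not None:
        rr = recognition_rate(intents, ground_truth, config.paradigm)
    metrics = SessionMetrics(
        travel_time_s=t,
        recognition_rate_pct=rr,
        command_log=log,
        n_collisions=collisions,
    )
    return metrics, trajectory


def recognition_rate(predictions, intents, paradigm: int) -> float | None:
    """Percentage of recognition periods matching the prompted intent.

    Paradigm 2: fraction of epochs whose prediction equals the intent.
    Paradigm 3: fraction of periods where both channels agree with the
    intent.  Paradigm 4 has no ground-truth intent, so no rate is defined
    and ``None`` is returned.
    """
    if paradigm == 4:
        return None
    if len(predictions) != len(intents):
        raise ValueError("prediction and intent streams differ in length")
    if not predictions:
        raise ValueError("empty streams")
    if paradigm == 2:
        hits = sum(p == g for p, g in zip(predictions, intents))
    elif paradigm == 3:
        hits = sum(c1 == c2 == g for (c1, c2), g in zip(predictions, intents))
    else:
        raise ValueError("paradigm must be 2, 3 or 4")
    return 100.0 * hits / len(predictions)


def ideal_route_time(
    map_config: MapConfig | None = None,
    linear_speed: float = LINEAR_SPEED,
    angular_speed: float = ANGULAR_SPEED,
) -> float:
    """Kinematic lower bound on travel time for the square-loop course.

    Path length = loops * 4 * side; each corner costs a 90-degree turn at
    the angular speed.  Two 40 cm loops at 12 cm/s and 0.25*pi rad/s give
    320/12 + 8 * 2 = 42.67 s.
    """
    map_config = map_config or MapConfig()
    if linear_speed <= 0 or angular_speed <= 0:
        raise ValueError("speeds must be positive")
    length = map_config.loops * 4 * map_config.side_cm
    turns = map_config.loops * 4
    return length / linear_speed + turns * (np.pi / 2) / angular_speed
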