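"""Task controllers driven by classified motor-imagery commands.

Process control: the user nudges the effector in ±10 mm steps along one
axis at a time (left-hand imagery = −10 mm, right-hand imagery = +10 mm,
rest holds; two consecutive rests cycle the active axis y→z→x→y).

Goal selection: one command picks the whole task — right-hand imagery
places the disk on the rightmost target (greater robot-frame Cx), left-hand
imagery on the leftmost, rest holds — and the planner expands the choice
into a reachable pick-and-place waypoint sequence through the IK solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .kinematics import IKSolution, RobotModel, inverse_kinematics
from .vision import TableScene

__all__ = [
    "ProcessControlState",
    "StepOutcome",
    "PickPlacePlan",
    "PlanInfeasibleError",
    "AXIS_CYCLE",
    "process_control_step",
    "replay_process_control",
    "goal_selection_action",
    "plan_pick_and_place",
]

AXIS_CYCLE = {"y": "z", "z": "x", "x": "y"}
_AXIS_IDX = {"x": 0, "y": 1, "z": 2}

HOME_MM = (0.0, 155.5, 284.3)
PC_TARGET_MM = (0.0, 300.0, -49.0)
STEP_MM = 10.0
HOVER_MM = 50.0


class PlanInfeasibleError(ValueError):
    """A pick-and-place waypoint has no reachable IK solution."""


@dataclass(frozen=True)
class ProcessControlState:
    """Effector position, active axis, and the pending-rest latch."""

    effector: tuple[float, float, float] = HOME_MM
    axis: Literal["x", "y", "z"] = "y"
    pending_rest: bool = False
    target: tuple[float, float, float] = PC_TARGET_MM
    move_refused: bool = False

    @property
    def distance_to_target(self) -> float:
        return float(np.linalg.norm(np.subtract(self.effector, self.target)))


@dataclass(frozen=True)
class StepOutcome:
    """Bookkeeping for uncued process-control scoring."""

    state: ProcessControlState
    reduced_distance: bool
    axis_changed: bool
    completed_needed_axis_change: bool

    def as_dict(self) -> dict:
        return {
            "reduced_distance": self.reduced_distance,
            "axis_changed": self.axis_changed,
            "completed_needed_axis_change": self.completed_needed_axis_change,
        }


def _workspace_ok(p: np.ndarray, model: RobotModel) -> bool:
    return inverse_kinematics(p, model).reachable


def process_control_step(state: ProcessControlState, label: str,
                         model: RobotModel | None = None,
                         check_workspace: bool = True) -> ProcessControlState:
    """One stimulus: apply the classified command to the controller state.

    RHIM = +10 mm on the active axis, LHIM = −10 mm, rest holds (two rests
    in a row cycle the axis y→z→x→y and clear the latch).  A rejected
    epoch behaves as rest.  Moves leaving the workspace are refused
    (position unchanged, ``move_refused`` flag set).
    """
    model = model or RobotModel()
    if label == "reject":
        label = "rest"
    if label == "rest":
        if state.pending_rest:
            return replace(state, axis=AXIS_CYCLE[state.axis],
                           pending_rest=False, move_refused=False)
        return replace(state, pending_rest=True, move_refused=False)
    if label not in ("LHIM", "RHIM"):
        raise ValueError(f"unknown command label {label!r}")
    delta = STEP_MM if label == "RHIM" else -STEP_MM
    new = np.array(state.effector, dtype=float)
    new[_AXIS_IDX[state.axis]] += delta
    if check_workspace and not _workspace_ok(new, model):
        return replace(state, pending_rest=False, move_refused=True)
    return replace(state, effector=tuple(new), pending_rest=False, move_refused=False)


def _axis_can_reduce(state: ProcessControlState) -> bool:
    """Can a ±10 mm move on the current axis bring the effector closer?"""
    base = state.distance_to_target
    for delta in (STEP_MM, -STEP_MM):
        p = np.array(state.effector, dtype=float)
        p[_AXIS_IDX[state.axis]] += delta
        if np.linalg.norm(p - np.array(state.target)) < base:
            return True
    return False


def replay_process_control(labels: Sequence[str],
                           state: ProcessControlState | None = None,
                           model: RobotModel | None = None,
                           check_workspace: bool = True) -> list[StepOutcome]:
    """Replay a command sequence, recording the per-stimulus outcomes used
    by the uncued process-control performance metric."""
    state = state or ProcessControlState()
    out = []
    for lab in labels:
        before = state.distance_to_target
        could_reduce = _axis_can_reduce(state)
        nxt = process_control_step(state, lab, model, check_workspace)
        axis_changed = nxt.axis != state.axis
        out.append(StepOutcome(
            state=nxt,
            reduced_distance=nxt.distance_to_target < before - 1e-12,
            axis_changed=axis_changed,
            completed_needed_axis_change=axis_changed and not could_reduce,
        ))
        state = nxt
    return out


# --------------------------------------------------------------------------
# goal selection
# --------------------------------------------------------------------------

def goal_selection_action(scene: TableScene, label: str) -> str:
    """Map a classified command to a pick-and-place action.

    RHIM: place the disk on the target with the greater robot-frame Cx;
    LHIM: the smaller Cx; rest (or reject): hold at home.
    """
    if label in ("rest", "reject"):
        return "hold"
    if label not in ("LHIM", "RHIM"):
        raise ValueError(f"unknown command label {label!r}")
    if scene.disk_robot is None:
        raise ValueError("scene has no disk: cannot pick")
    if len(scene.targets_robot) < 2:
        raise ValueError("scene needs two targets for a left/right choice")
    items = sorted(scene.targets_robot.items(), key=lambda kv: kv[1][0])
    chosen = items[-1] if label == "RHIM" else items[0]
    return f"place_{'right' if label == 'RHIM' else 'left'}:{chosen[0]}"


@dataclass
class PickPlacePlan:
    """Ordered effector waypoints with gripper actions and their IK solutions."""

    target_color: str
    waypoints: list[tuple[str, np.ndarray]]
    gripper: list[str]
    solutions: list[IKSolution] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "target_color": self.target_color,
            "waypoints": [
                {"name": n, "xyz_mm": [float(v) for v in p], "gripper": g}
                for (n, p), g in zip(self.waypoints, self.gripper)
            ],
        }


def plan_pick_and_place(scene: TableScene, action: str,
                        model: RobotModel | None = None,
                        hover_mm: float = HOVER_MM,
                        disk_height_mm: float = 6.0) -> PickPlacePlan:
    """Expand a place_left/place_right action into reachable waypoints.

    The table surface sits at z = −base_height in robot frame; the grasp
    height is the disk top.  Waypoints: hover above disk → grasp → hover →
    hover above target → release at target surface + disk height → home.
    Raises ``PlanInfeasibleError`` naming the first unreachable waypoint.
    """
    if action == "hold":
        raise ValueError("hold requires no plan")
    model = model or RobotModel()
    color = action.split(":", 1)[1] if ":" in action else None
    if scene.disk_robot is None:
        raise ValueError("scene has no disk")
    if color is None or color not in scene.targets_robot:
        raise ValueError(f"unknown target in action {action!r}")
    z_table = -model.base_height
    z_grasp = z_table + disk_height_mm
    dx, dy = scene.disk_robot
    tx, ty = scene.targets_robot[color]
    wps = [
        ("disk approach", np.array([dx, dy, z_grasp + hover_mm])),
        ("disk grasp", np.array([dx, dy, z_grasp])),
        ("disk lift", np.array([dx, dy, z_grasp + hover_mm])),
        ("target approach", np.array([tx, ty, z_grasp + hover_mm])),
        ("target release", np.array([tx, ty, z_grasp])),
        ("home", np.array(model.home, dtype=float)),
    ]
    grip = ["open", "close", "close", "close", "open", "open"]
    sols = []
    for name, p in wps:
        sol = inverse_kinematics(p, model)
        if not sol.reachable:
            raise PlanInfeasibleError(f"plan infeasible: {name} ({sol.reason})")
        sols.append(sol)
    return PickPlacePlan(color, wps, grip, sols)
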