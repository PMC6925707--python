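"""One goal-selection command: localize items, pick the disk, place it.

A single classified right-hand-imagery event makes the robot place the disk
on the rightmost target (greater robot-frame x).  The planner expands the
choice into six waypoints, each verified reachable through the IK solver.
"""

import numpy as np

from neuroarm.control import goal_selection_action, plan_pick_and_place
from neuroarm.kinematics import RobotModel
from neuroarm.synth import gen_scene
from neuroarm.vision import locate_scene

img, _ = gen_scene(disk_table=(200.0, 180.0),
                   targets_table={"green": (120.0, 160.0),
                                  "red": (280.0, 190.0)})
scene = locate_scene(img)
print(f"disk at robot frame  : {np.round(scene.disk_robot, 1)} mm")
for c, p in scene.targets_robot.items():
    print(f"{c:<6s} target        : {np.round(p, 1)} mm")

action = goal_selection_action(scene, "RHIM")
print(f"\nclassified RHIM -> action: {action}")

plan = plan_pick_and_place(scene, action, RobotModel())
print("waypoints (all verified reachable):")
for (name, p), g in zip(plan.waypoints, plan.gripper):
    print(f"  {name:<16s} ({p[0]:7.1f}, {p[1]:7.1f}, {p[2]:7.1f}) mm  gripper {g}")
# The grasp height is the disk top (table plane -49 mm + disk height 6 mm);
# hovers add 50 mm of clearance; the arm returns home afterwards.
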