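"""Solve the arm's inverse kinematics for a tabletop target.

The solver builds the effector plane, intersects spheres around the fixed
shoulder geometry, and reads joint angles off oriented angles between link
lines — all in conformal geometric algebra.  The forward-kinematics check
at the end is an independent trigonometric reconstruction.
"""

import numpy as np

from neuroarm.kinematics import RobotModel, forward_kinematics, inverse_kinematics

model = RobotModel()
target = np.array([120.0, 250.0, -43.0])  # mm, robot frame: on the table plane

sol = inverse_kinematics(target, model)
print(f"target          : {target} mm")
print(f"reachable       : {sol.reachable}")
print(f"auxiliary x_h   : {np.round(sol.x_h, 3)} mm  (|x_h| = La = {model.La})")
print(f"shoulder J2     : {np.round(sol.J2, 3)} mm")
print(f"elbow    J3     : {np.round(sol.J3, 3)} mm")
th = np.degrees([sol.theta0, sol.theta2, sol.theta3])
print(f"joint angles    : theta0={th[0]:.2f}  theta2={th[1]:.2f}  "
      f"theta3={th[2]:.2f} deg")

fk = forward_kinematics(sol.theta0, sol.theta2, sol.theta3, model)
print(f"FK round trip   : {np.round(fk, 6)} mm "
      f"(error {np.linalg.norm(fk - target):.2e} mm)")
# theta0 is the base azimuth; theta2/theta3 are shoulder and elbow flexion
# measured between consecutive link directions in the vertical target plane.
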