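"""Build the procedural body model, pose it, and fix its height.

The model is a SMPL-style statistical body: 10 shape parameters deform a
template mesh, 72 pose parameters (24 joints x 3 axis-angle) articulate it
by linear blend skinning. Height is imposed as a hard constraint by solving
for the global-scale shape component.
"""
import numpy as np

from gaitmesh import make_toy_model, pose_model, apply_height_constraint

model = make_toy_model(n_vertices=1000, seed=1)
print(f"model: {model.n_vertices} vertices, {len(model.faces)} faces, "
      f"canonical height {model.height():.3f} m")

# bend the left knee by 30 degrees and look at the ankle displacement
pose = np.zeros((24, 3))
pose[model.tree.index("left_knee"), 0] = -np.deg2rad(30)
verts, joints = pose_model(model, np.zeros(10), pose)
ankle_shift = joints[model.tree.index("left_ankle")] - \
    model.rest_joints(np.zeros(10))[model.tree.index("left_ankle")]
print(f"30 deg knee flexion moves the ankle by {np.linalg.norm(ankle_shift):.3f} m"
      " (the shank swings about the knee)")

# constrain the model to a 1.32 m child
beta = apply_height_constraint(model, np.zeros(10), 1.32)
print(f"height constraint: beta[0] = {beta[0]:+.3f} gives "
      f"{model.height(beta):.4f} m (target 1.3200)")
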