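"""Ground-plane estimation and person segmentation.

The floor plane is found from the red treadmill marker stripes; foreground
points are those above the plane by a clearance margin inside the treadmill
working volume. Robot points near the body are deliberately retained — the
robust fitter deals with them.
"""
import numpy as np

from gaitmesh import (default_gait_profile, estimate_ground_plane,
                      generate_walk, make_toy_model, segment_person)

model = make_toy_model(1000, seed=1)
rec = generate_walk(model, default_gait_profile(), 1.0, 30,
                    noise_sd=0.002, seed=5, n_points=1200)
frame = rec.frames[0]

plane = estimate_ground_plane(frame.points, frame.colors)
print(f"ground plane normal {np.round(plane.normal, 4)}, "
      f"offset {plane.offset * 1000:.1f} mm")

mask = segment_person(frame.points, plane, return_mask=True)
body = frame.origin == "body"
print(f"foreground: {mask.sum()} of {len(frame.points)} points; "
      f"{100 * mask[body].mean():.2f}% of body points kept, "
      f"{mask[frame.origin == 'floor'].sum()} floor points leaked")
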