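"""Filter a crowded image and subdivide it into annotatable crops.

Spots packed into one corner violate the spacing guideline (no pair
closer than 4% of the displayed width), so the preparation step
recursively crops that region; consensus points found in the crops map
exactly back to the parent frame.
"""

import numpy as np

from crowdspot import Guidelines, SynthConfig, reassemble, recursive_subdivide, simulate_image
from crowdspot.imageprep import to_display_coords
from crowdspot.records import spot_coords

# 150 spots allowed as close as 6 px: too dense to annotate directly
config = SynthConfig(n_spots=150, sigma=1.5, min_nnd=6.0, seed=4)
image, truth = simulate_image(config, 384, 384)

crops = recursive_subdivide(image, truth, Guidelines(), display_width=512)
depths = sorted({spec.depth for spec, _ in crops})
print(f"{len(crops)} crops at depths {depths}")

# route every truth point through its covering crops and back
pts = spot_coords(truth)
per_crop = {}
for spec, _pixels in crops:
    inside = pts[
        (pts[:, 0] >= spec.x0)
        & (pts[:, 0] < spec.x0 + spec.width)
        & (pts[:, 1] >= spec.y0)
        & (pts[:, 1] < spec.y0 + spec.height)
    ]
    if len(inside):
        per_crop[spec.crop_id] = to_display_coords(spec, inside)

recovered = reassemble(per_crop, [spec for spec, _ in crops], dedup_radius=2.0)
d = np.hypot(recovered[:, None, 0] - pts[None, :, 0], recovered[:, None, 1] - pts[None, :, 1])
print(f"round trip: {len(recovered)} points recovered of {len(pts)}")
print(f"worst recovery error {d.min(axis=1).max():.2e} px")
# Overlapping crops duplicate boundary points; reassembly deduplicates
# them, so the count matches and every point returns essentially exactly.
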