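"""Detect transcription-factor hubs in a normalized nuclear volume.

Plants five Gaussian hub blobs in a mean-normalized synthetic nucleus, runs
the morphological detection recipe (median filter, erosion, reconstruction,
residual threshold, marker-controlled watershed), and prints per-hub region
properties next to the planted centers.
"""

import numpy as np

from hubburst import detect_hubs, hub_regionprops
from hubburst.synthetic import planted_blob_volume

VOXEL_ZYX = (0.3, 0.104, 0.104)  # anisotropic grid: z step ~3x lateral pitch

volume, mask, centers = planted_blob_volume(5, seed=42)
labels = detect_hubs(volume, mask, VOXEL_ZYX)
regions = hub_regionprops(labels, volume, VOXEL_ZYX)

print(f"planted 5 hubs, detected {labels.max()}")
print("hub  volume(um^3)  mean-int  centroid error (um)")
for r in regions:
    err = np.min(np.linalg.norm(centers - np.array(r.centroid_um), axis=1))
    print(f"{r.hub_id:3d}  {r.volume_um3:12.4f}  {r.mean_intensity:8.3f}  {err:.3f}")
# Mean intensities are in normalized units (1.0 = nucleoplasmic average), so
# a value near 2 means the hub is roughly twice as concentrated as the
# surrounding nucleoplasm.
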