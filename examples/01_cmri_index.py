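"""Compute the CMRI and its components for a single hand-built scene.

The CMRI is a greenness-minus-wetness difference,
CMRI = (NIR-Red)/(NIR+Red) - (NIR-SWIR)/(NIR+SWIR): dense wet mangrove
canopy scores high on both NDVI and canopy moisture, so its CMRI
exceeds that of dry terrestrial vegetation at similar greenness.
"""

import datetime as dt

import numpy as np

from cmri import SceneStack, compute_cmri, compute_component

# one 2x2 scene: a mangrove-like pixel, a dry-vegetation pixel, water,
# and a cloud-contaminated pixel
scene = SceneStack(
    red=np.array([[0.04, 0.12], [0.60, 0.90]]),
    green=np.array([[0.05, 0.07], [0.06, 0.90]]),
    nir=np.array([[0.45, 0.30], [0.02, 0.90]]),
    swir=np.array([[0.25, 0.28], [0.01, 0.90]]),
    cloud_mask=np.array([[False, False], [False, True]]),
    date=dt.date(2020, 7, 15),
)

ndvi = compute_component(scene, "NDVI")
ndwi = compute_component(scene, "NDWI_swir")
cmri = compute_cmri(scene)

names = ["mangrove", "dry vegetation", "water", "cloud"]
print(f"{'pixel':>16} {'NDVI':>8} {'NDWI':>8} {'CMRI':>8}")
for name, (r, c) in zip(names, [(0, 0), (0, 1), (1, 0), (1, 1)]):
    print(f"{name:>16} {ndvi.values[r, c]:8.3f} {ndwi.values[r, c]:8.3f} "
          f"{cmri.values[r, c]:8.3f}")

print("\nThe mangrove pixel combines high greenness with moderate canopy")
print("wetness, giving the largest CMRI; the cloud pixel is flagged")
print(f"invalid (valid mask: {cmri.valid.tolist()}).")
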