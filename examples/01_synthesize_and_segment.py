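"""Generate a synthetic TEM-like fibril field and segment it.

Builds a 1024x1024 px image (4 nm/px) of ~200 non-touching disks with
normally distributed diameters, runs the adaptive-threshold segmentation
and compares the detected interior fibrils with the generator's ground
truth.
"""

import numpy as np

import fibrilmorph as fm
from fibrilmorph.distributions import MixtureParams

spec = fm.SyntheticImageSpec(
    width_px=1024, height_px=1024, nm_per_px=4.0,
    diameter_mixture=MixtureParams([150.0], [20.0**2], [1.0]),
    min_gap_nm=30.0, target_count=200, seed=1)
image, truth = fm.generate_fibril_image(spec)

labels, cell_area = fm.segment(image, fm.SegmentationParams(), spec.nm_per_px)
records = fm.measure(labels, spec.nm_per_px)
interior = [r for r in records if not r.border]

true_interior = truth.interior_mask_raster(spec.nm_per_px, spec.width_px,
                                           spec.height_px).sum()
mfds = np.array([r.mfd_nm for r in interior])

print(f"placed disks:            {truth.n}")
print(f"ground-truth interior:   {true_interior}")
print(f"detected interior:       {len(interior)}")
print(f"detected border-class:   {len(records) - len(interior)}")
print(f"mean MFD of interior:    {mfds.mean():.1f} nm (generator mean 150 nm)")
print(f"mean circularity:        {np.mean([r.circularity for r in interior]):.3f}")
# Interior counts should match the ground truth exactly on noise-free
# fields; the mean MFD slightly undershoots the generator mean because the
# minimum caliper of a digitised disk sits just inside the true diameter.
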