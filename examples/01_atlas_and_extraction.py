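"""Load the social brain atlas and extract spherical ROI means from images.

Builds a tiny synthetic cohort, paints each participant's region volumes into
3D maps, then recovers them by 5 mm FWHM smoothing + 5 mm-diameter sphere
averaging — the same measurement pipeline a real gray-matter map would go
through.
"""

import numpy as np

from sbhbm import (
    SimulationConfig,
    extract_region_means,
    generate_cohort,
    generate_volume_images,
    load_atlas,
)

atlas = load_atlas("default")
print(f"atlas: {len(atlas)} regions from {atlas.source}")
for net, size in atlas.network_sizes().items():
    names = [r.name for r in atlas.regions_in_network(net)]
    print(f"  {net:20s} ({size:2d}): {', '.join(names)}")

cohort = generate_cohort(SimulationConfig(n=10, seed=42))
images = generate_volume_images(cohort, atlas, voxel_size_mm=2.0, participant_ids=["p000000"])
img = images[0]
truth = cohort.volumes.values.loc["p000000"].to_numpy()

means_plain = extract_region_means(img, atlas, diameter_mm=5.0, smooth_fwhm_mm=None)
means_smooth = extract_region_means(img, atlas, diameter_mm=5.0, smooth_fwhm_mm=5.0)

print("\nround trip for participant p000000:")
print(f"  max |error| without smoothing: {np.max(np.abs(means_plain - truth)):.2e}")
print(f"  max relative error with 5 mm FWHM: {np.max(np.abs(means_smooth - truth) / truth):.4%}")
print("Smoothing barely perturbs sphere means because the painted blobs are")
print("wider than the kernel; on real data it suppresses registration noise.")
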