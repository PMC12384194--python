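"""Voxel-wise complexity maps of a synthetic BOLD phantom.

Builds a small 4-D phantom with a low-irregularity and a
high-irregularity region, runs the full per-subject pipeline (discard 5
volumes, motion regression, 0.008-0.1 Hz band-pass, 10% intensity mask,
three maps) and compares mean entropy between the two regions.
"""

import numpy as np

from boldcomplexity import PhantomSpec, gen_phantom, run_subject

spec = PhantomSpec(seed=7)  # 16x16x8 grid, 250 volumes, two MIX regions
vol, motion, truth = gen_phantom(spec)
result = run_subject(vol, motion)

print(f"Phantom {spec.shape}, {spec.n_volumes} volumes, "
      f"{result.mask.n_voxels} in-mask voxels")
for tag, s in result.summaries.items():
    print(f"  {tag:8s} whole-brain mean {s.mean:.3f} (SD {s.sd:.3f})")

fapen = result.maps["fapen"].data
for name in ("regular", "irregular"):
    region_mean = fapen[truth[name]].mean()
    print(f"  mean fApEn in {name!r} region: {region_mean:.3f}")

print()
print("The MIX(0.9) region carries higher entropy than the MIX(0.1)")
print("region, so the voxel-wise map separates the two tissues.")
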