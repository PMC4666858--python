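#!/usr/bin/env python
"""Simulate the study cohort: two labelled proteins, washed and unwashed.

One protein binds dislocations preferentially (true dislocation/wall
emission ratio 2.0, emulating an endoglucanase whose CBM targets
dislocations) and one does not (ratio 1.2).  Fourteen fibers per
washed/unwashed arm give ~28 fibers per protein after pooling, matching the
scale of a realistic imaging campaign.  Stacks, ground-truth sidecars and
auto-placed ROI sets are written under scratch/cohort/ for the measurement
step; this script is regenerative — outputs are reproduced bit-for-bit from
the seed.

Run from the repository root:  python analysis/01_simulate_cohorts.py
"""

import json
from pathlib import Path

from fiberratio.stack_io import write_rois, write_stack
from fiberratio.synthetic import AcquisitionParams, GroupSpec, generate_cohort

SEED = 20260928
OUT = Path("scratch/cohort")

GROUPS = [
    GroupSpec("withCBM", 14, 2.0, washed=False),
    GroupSpec("withCBM", 14, 2.0, washed=True),
    GroupSpec("noCBM", 14, 1.2, washed=False),
    GroupSpec("noCBM", 14, 1.2, washed=True),
]
# 232 nm pixels: the coarser of the two documented pixel sizes, enough to
# resolve every ROI while keeping the cohort quick to simulate
ACQ = AcquisitionParams(pixel_size_nm=232.0)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(GROUPS, ACQ, SEED)
    manifest = []
    for cube, truth in cohort:
        write_stack(cube.stack, OUT / f"{cube.fiber_id}.tif")
        write_rois(cube.rois, OUT / f"{cube.fiber_id}.rois.txt")
        manifest.append(
            {
                "stack": str(OUT / f"{cube.fiber_id}.tif"),
                "rois": str(OUT / f"{cube.fiber_id}.rois.txt"),
                "fiber_id": cube.fiber_id,
                "enzyme": cube.enzyme,
                "washed": cube.washed,
                "rho_true": truth.rho_true,
            }
        )
    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"simulated {len(cohort)} fibers "
          f"({len(GROUPS)} treatment arms) -> {OUT}")


if __name__ == "__main__":
    main()
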