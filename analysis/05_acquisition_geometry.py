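#!/usr/bin/env python
"""Acquisition-geometry numbers used throughout the analysis.

Computes the confocal resolution (lateral/axial FWHM), pixel size and slice
spacing for the documented setup (633 nm excitation, NA 1.2 water-immersion
objective, 1024-pixel raster over a 119.16 µm field, 15 slices over 30 µm)
and writes them to results/acquisition_geometry.csv.  These values are the
simulator's defaults, so the simulated optics and the documented microscope
stay in sync by construction.

Run from the repository root:  python analysis/05_acquisition_geometry.py
"""

from pathlib import Path

import pandas as pd

from fiberratio.optics import (
    OpticsConfig,
    axial_fwhm,
    lateral_fwhm,
    pixel_size,
    slice_spacing,
)

RESULTS = Path("results")


def main() -> None:
    cfg = OpticsConfig(excitation_wavelength=633.0, numerical_aperture=1.2,
                       immersion_refractive_index=1.33)
    rows = [
        {"quantity": "lateral_fwhm_nm", "value": lateral_fwhm(cfg)},
        {"quantity": "axial_fwhm_nm", "value": axial_fwhm(cfg)},
        {"quantity": "pixel_size_nm", "value": pixel_size(119.16, 1024)},
        {"quantity": "slice_spacing_um", "value": slice_spacing(30.0, 15)},
    ]
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "acquisition_geometry.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    for row in rows:
        print(f"{row['quantity']}: {row['value']:.2f}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
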