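"""Shared fixtures: small synthetic fibers and hand-built stacks."""

from __future__ import annotations

import numpy as np
import pytest

from fiberratio.stack_io import ImageStack, Roi, RoiSet
from fiberratio.synthetic import AcquisitionParams, FiberGeometry


@pytest.fixture(scope="session")
def geometry() -> FiberGeometry:
    return FiberGeometry()


@pytest.fixture(scope="session")
def acq_fast() -> AcquisitionParams:
    """Coarse-pixel acquisition (232 nm) for fast simulation tests."""
    return AcquisitionParams(pixel_size_nm=232.0)


@pytest.fixture(scope="session")
def acq_coarse() -> AcquisitionParams:
    """Very coarse acquisition (464 nm) for replicate-heavy tests."""
    return AcquisitionParams(pixel_size_nm=464.0)


def make_stack(
    intensities: np.ndarray,
    pixel_size_nm: float = 232.0,
    slice_spacing_um: float = 2.0,
) -> ImageStack:
    return ImageStack(
        intensities=np.asarray(intensities, dtype=float),
        pixel_size_nm=pixel_size_nm,
        slice_spacing_um=slice_spacing_um,
    )


def make_roiset(
    wall_val_cols: tuple[int, int, int] = (0, 4, 8),
    disl_cols: tuple[int, int, int] = (12, 16, 20),
    bulk_col: int = 24,
    lumen_col: int | None = 28,
    y0: int = 0,
    size: int = 3,
) -> RoiSet:
    """A compact valid RoiSet of 3x3 rectangles laid out along one row."""
    rois = [Roi(c, y0, size, size, "normal_wall") for c in wall_val_cols]
    rois += [Roi(c, y0, size, size, "dislocation") for c in disl_cols]
    rois += [Roi(bulk_col, y0, size, size, "bulk")]
    if lumen_col is not None:
        rois += [Roi(lumen_col, y0, size, size, "lumen")]
    return RoiSet(rois)


@pytest.fixture()
def flat_stack() -> ImageStack:
    """Constant-intensity stack (value 7), 6 slices of 12x40 pixels."""
    return make_stack(np.full((6, 12, 40), 7.0))
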