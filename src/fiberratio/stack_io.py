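"""Image-stack, ROI and results I/O.

Stacks are stored as multi-page TIFF (one page per optical slice) with a
JSON sidecar (``<stem>.meta.json``) holding the physical calibration and
free-form acquisition metadata.  Calibration lives in the sidecar, not in
TIFF tags, so a stack file is never silently mis-calibrated: a missing
sidecar or missing calibration field is a hard read error.

ROI sets are stored as a small structured text format, one rectangle per
line::

    # fiberratio ROI set v1
    kind	x0	y0	width	height
    normal_wall	10	20	9	9
    ...

Coordinates are 0-based with the origin at the top-left pixel; rectangles
are half-open, covering columns [x0, x0+width) and rows [y0, y0+height).

Per-fiber ratio results and group-comparison tables are written as CSV
(``pandas``) with full float precision (repr round-trip).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "CalibrationError",
    "RoiValidationError",
    "ImageStack",
    "Roi",
    "RoiSet",
    "FiberCube",
    "read_stack",
    "write_stack",
    "read_rois",
    "write_rois",
    "write_results",
    "read_results",
]

ROI_KINDS = ("bulk", "normal_wall", "dislocation", "lumen")

_MIN_ROI_SIDE = 3


class CalibrationError(ValueError):
    """A stack is missing or carries invalid physical calibration."""


class RoiValidationError(ValueError):
    """An ROI set violates the triplicate/geometry contract."""


@dataclass
class ImageStack:
    """A confocal z-stack: nonnegative intensities indexed [slice, row, col].

    Parameters
    ----------
    intensities : ndarray, shape (n_slices, n_rows, n_cols)
        Emission intensities, promoted to float64 internally.
    pixel_size_nm : float
        Lateral pixel size in nm.
    slice_spacing_um : float
        Axial distance between optical slices in µm.
    meta : dict
        Free-form acquisition record (gain, laser %, emission window, ...).
    """

    intensities: np.ndarray
    pixel_size_nm: float
    slice_spacing_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3-D stack, got ndim={arr.ndim}")
        if arr.shape[0] < 2:
            raise ValueError(
                f"a stack needs at least 2 slices, got {arr.shape[0]}"
            )
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite and non-negative")
        if not self.pixel_size_nm > 0:
            raise CalibrationError("pixel_size_nm must be positive")
        if not self.slice_spacing_um > 0:
            raise CalibrationError("slice_spacing_um must be positive")
        self.intensities = arr

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass(frozen=True)
class Roi:
    """Axis-aligned rectangle in the image plane, half-open pixel bounds."""

    x0: int
    y0: int
    width: int
    height: int
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ROI_KINDS:
            raise RoiValidationError(
                f"unknown ROI kind {self.kind!r}; expected one of {ROI_KINDS}"
            )
        if self.x0 < 0 or self.y0 < 0:
            raise RoiValidationError("ROI origin must be non-negative")
        if self.width < _MIN_ROI_SIDE or self.height < _MIN_ROI_SIDE:
            raise RoiValidationError(
                f"ROI sides must be at least {_MIN_ROI_SIDE} pixels, "
                f"got {self.width}x{self.height}"
            )

    def slices(self) -> tuple[slice, slice]:
        """(row, col) slices selecting the rectangle from an image plane."""
        return (
            slice(self.y0, self.y0 + self.height),
            slice(self.x0, self.x0 + self.width),
        )

    def fits(self, n_rows: int, n_cols: int) -> bool:
        return self.y0 + self.height <= n_rows and self.x0 + self.width <= n_cols


@dataclass
class RoiSet:
    """Labelled ROI collection for one fiber cube.

    Exactly 3 ``normal_wall`` and 3 ``dislocation`` rectangles (the
    triplicate design), 0-3 ``bulk`` and 0-1 ``lumen``.
    """

    rois: list[Roi]

    def __post_init__(self) -> None:
        counts = {k: 0 for k in ROI_KINDS}
        for roi in self.rois:
            counts[roi.kind] += 1
        for kind in ("normal_wall", "dislocation"):
            if counts[kind] != 3:
                raise RoiValidationError(
                    f"expected exactly 3 {kind} ROIs, got {counts[kind]}"
                )
        if counts["bulk"] > 3:
            raise RoiValidationError(
                f"expected at most 3 bulk ROIs, got {counts['bulk']}"
            )
        if counts["lumen"] > 1:
            raise RoiValidationError(
                f"expected at most 1 lumen ROI, got {counts['lumen']}"
            )

    def of_kind(self, kind: str) -> list[Roi]:
        return [r for r in self.rois if r.kind == kind]

    @property
    def lumen(self) -> Roi | None:
        found = self.of_kind("lumen")
        return found[0] if found else None

    def validate_against(self, stack: ImageStack) -> None:
        """Check every rectangle lies inside the stack's image plane."""
        _, n_rows, n_cols = stack.shape
        for roi in self.rois:
            if not roi.fits(n_rows, n_cols):
                raise RoiValidationError(
                    f"{roi.kind} ROI at ({roi.x0},{roi.y0}) "
                    f"size {roi.width}x{roi.height} overhangs the "
                    f"{n_rows}x{n_cols} image plane"
                )


@dataclass
class FiberCube:
    """A stack paired with its ROI set and treatment labels."""

    stack: ImageStack
    rois: RoiSet
    fiber_id: str
    enzyme: str = ""
    washed: bool = False

    def __post_init__(self) -> None:
        self.rois.validate_against(self.stack)


# ---------------------------------------------------------------------------
# stack I/O


def _sidecar_path(path: Path) -> Path:
    stem = path.stem if path.suffix in (".tif", ".tiff") else path.name
    return path.with_name(stem + ".meta.json")


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as multi-page TIFF plus a JSON calibration sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path, stack.intensities.astype(np.float32), photometric="minisblack"
    )
    sidecar = {
        "pixel_size_nm": stack.pixel_size_nm,
        "slice_spacing_um": stack.slice_spacing_um,
        "meta": stack.meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def read_stack(path: str | Path) -> ImageStack:
    """Read a multi-page TIFF stack; the calibration sidecar is mandatory."""
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise CalibrationError(
            f"calibration sidecar {sidecar_path.name} not found next to "
            f"{path.name}"
        )
    sidecar = json.loads(sidecar_path.read_text())
    for fieldname in ("pixel_size_nm", "slice_spacing_um"):
        if fieldname not in sidecar:
            raise CalibrationError(
                f"calibration field {fieldname!r} missing from "
                f"{sidecar_path.name}"
            )
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] < 2:
        raise ValueError(
            f"{path.name}: a stack needs at least 2 slices, got {arr.shape[0]}"
        )
    return ImageStack(
        intensities=np.asarray(arr, dtype=np.float64),
        pixel_size_nm=float(sidecar["pixel_size_nm"]),
        slice_spacing_um=float(sidecar["slice_spacing_um"]),
        meta=dict(sidecar.get("meta", {})),
    )


# ---------------------------------------------------------------------------
# ROI I/O

_ROI_HEADER = "# fiberratio ROI set v1"
_ROI_COLUMNS = ("kind", "x0", "y0", "width", "height")


def write_rois(rois: RoiSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [_ROI_HEADER, "\t".join(_ROI_COLUMNS)]
    for roi in rois.rois:
        lines.append(
            "\t".join(
                str(v) for v in (roi.kind, roi.x0, roi.y0, roi.width, roi.height)
            )
        )
    path.write_text("\n".join(lines) + "\n")


def read_rois(path: str | Path) -> RoiSet:
    path = Path(path)
    lines = [
        ln
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines or lines[0].split("\t") != list(_ROI_COLUMNS):
        raise RoiValidationError(
            f"{path.name}: expected header {' '.join(_ROI_COLUMNS)!r}"
        )
    rois = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != 5:
            raise RoiValidationError(f"{path.name}: malformed ROI line {ln!r}")
        kind, x0, y0, w, h = parts
        rois.append(Roi(int(x0), int(y0), int(w), int(h), kind))
    return RoiSet(rois)


# ---------------------------------------------------------------------------
# results I/O

_FIBER_COLUMNS = ["fiber_id", "enzyme", "washed", "n_sois", "per_soi_ratios", "R"]


def write_results(
    ratio_results: Iterable,
    group_tests: Iterable[Mapping],
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write the per-fiber R table and group-comparison table as CSV.

    ``ratio_results`` yields objects with fiber_id, enzyme, washed,
    per_soi_ratios, mean_R attributes (see :mod:`fiberratio.ratiometry`).
    ``group_tests`` yields mappings with the full pooled-test record.
    Returns the two paths (fibers.csv, group_comparison.csv).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    fiber_rows = []
    for res in ratio_results:
        fiber_rows.append(
            {
                "fiber_id": res.fiber_id,
                "enzyme": getattr(res, "enzyme", ""),
                "washed": getattr(res, "washed", ""),
                "n_sois": res.n_sois,
                "per_soi_ratios": ";".join(repr(v) for v in res.per_soi_ratios),
                "R": repr(res.mean_R),
            }
        )
    fibers_path = out_dir / "fibers.csv"
    pd.DataFrame(fiber_rows, columns=_FIBER_COLUMNS).to_csv(
        fibers_path, index=False
    )

    groups_path = out_dir / "group_comparison.csv"
    group_rows = [dict(row) for row in group_tests]
    columns = list(group_rows[0].keys()) if group_rows else [
        "group1", "group2", "mean1", "mean2", "n1", "n2", "s2_pooled",
        "sem", "t_crit", "mean_diff", "ci_low", "ci_high", "significant",
    ]
    pd.DataFrame(group_rows, columns=columns).to_csv(groups_path, index=False)
    return fibers_path, groups_path


def read_results(fibers_path: str | Path) -> pd.DataFrame:
    """Read a per-fiber results table back; R and per-SOI ratios as floats."""
    df = pd.read_csv(fibers_path)
    if len(df):
        df["R"] = df["R"].astype(float)
        df["per_soi_ratios"] = df["per_soi_ratios"].map(
            lambda s: [float(v) for v in str(s).split(";")] if pd.notna(s) else []
        )
    return df
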