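"""Axial intensity profiles and slice-of-interest (SOI) selection.

A per-fiber measurement uses only interior optical slices: slices showing
the fiber surface are excluded (surface-bound enzyme and fines would
confound the dislocation signal), and only slices containing the lumen are
kept (the fiber is at or near its widest there, so lateral ROIs stay within
the S2 wall).  This module automates those rules from the axial intensity
profiles of the wall and lumen ROIs; a manual override path accepts an
explicit slice list, reproducing the original manual workflow.

Rules (all thresholds configurable through :class:`SoiRules`):

a. *surface exclusion* — the mean wall-ROI intensity of the slice must not
   exceed ``surface_factor`` times the interior wall plateau (the median
   wall intensity over the middle third of slices);
b. *lumen presence* — the lumen-ROI mean of the slice must fall below
   ``lumen_factor`` times the wall plateau (a dark lumen interior marks the
   fiber's widest depth range);
c. *fiber presence* — the wall-ROI mean of the slice must reach at least
   ``presence_factor`` times the plateau, so that empty slices above or
   below the fiber (where both wall and lumen ROIs see only dim bulk
   solution, and rules a-b alone would pass) are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stack_io import ImageStack, Roi, RoiSet, RoiValidationError

__all__ = [
    "AxialProfile",
    "SoiRules",
    "SoiSelection",
    "NoUsableSoiError",
    "axial_profile",
    "select_sois",
]


class NoUsableSoiError(RuntimeError):
    """Every slice was rejected by the SOI rules; the fiber is unusable."""


@dataclass
class AxialProfile:
    """Mean ROI intensity per optical slice (raw, not normalized)."""

    slice_index: np.ndarray
    mean_intensity: np.ndarray
    roi_kind: str

    def __post_init__(self) -> None:
        self.slice_index = np.asarray(self.slice_index, dtype=int)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        if self.slice_index.shape != self.mean_intensity.shape:
            raise ValueError("profile index/intensity length mismatch")


@dataclass(frozen=True)
class SoiRules:
    """Thresholds of the automated SOI rules (fractions of the wall plateau)."""

    surface_factor: float = 1.5
    lumen_factor: float = 0.5
    presence_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.surface_factor <= 0 or self.lumen_factor <= 0:
            raise ValueError("rule factors must be positive")
        if not 0 < self.presence_factor <= 1:
            raise ValueError("presence_factor must lie in (0, 1]")


@dataclass
class SoiSelection:
    """Selected slice indices plus a trace of why each rejected slice fell."""

    slice_indices: list[int]
    rule_trace: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.slice_indices = sorted(set(int(i) for i in self.slice_indices))

    @property
    def n_sois(self) -> int:
        return len(self.slice_indices)


def axial_profile(stack: ImageStack, roi: Roi) -> AxialProfile:
    """Per-slice arithmetic mean of the intensities inside one rectangle."""
    _, n_rows, n_cols = stack.shape
    if not roi.fits(n_rows, n_cols):
        raise RoiValidationError(
            f"{roi.kind} ROI at ({roi.x0},{roi.y0}) overhangs the "
            f"{n_rows}x{n_cols} image plane"
        )
    rows, cols = roi.slices()
    means = stack.intensities[:, rows, cols].mean(axis=(1, 2))
    return AxialProfile(
        slice_index=np.arange(stack.n_slices),
        mean_intensity=means,
        roi_kind=roi.kind,
    )


def _wall_plateau(wall_mean: np.ndarray) -> float:
    """Robust interior wall intensity: median over the middle third of slices."""
    n = len(wall_mean)
    lo, hi = n // 3, n - n // 3
    return float(np.median(wall_mean[lo:hi]))


def select_sois(
    stack: ImageStack,
    rois: RoiSet,
    rules: SoiRules = SoiRules(),
    *,
    manual_slices: list[int] | None = None,
) -> SoiSelection:
    """Select slices of interest for one fiber cube.

    With ``manual_slices`` the automated rules are bypassed and the given
    slice list is validated and returned (the manual workflow).  Otherwise a
    slice is selected iff it passes the surface-exclusion, lumen-presence
    and fiber-presence rules documented in the module docstring.  Raises
    :class:`NoUsableSoiError` when nothing survives — such a fiber is
    dropped, mirroring the practice of imaging only suitable fibers.
    """
    if manual_slices is not None:
        bad = [i for i in manual_slices if not 0 <= i < stack.n_slices]
        if bad:
            raise ValueError(f"manual slice indices out of range: {bad}")
        if not manual_slices:
            raise NoUsableSoiError("manual slice list is empty")
        return SoiSelection(slice_indices=list(manual_slices),
                            rule_trace={})

    lumen_roi = rois.lumen
    if lumen_roi is None:
        raise RoiValidationError(
            "SOI selection needs a lumen ROI (or a manual slice list)"
        )
    wall_profiles = [axial_profile(stack, r) for r in rois.of_kind("normal_wall")]
    wall_mean = np.mean([p.mean_intensity for p in wall_profiles], axis=0)
    lumen_mean = axial_profile(stack, lumen_roi).mean_intensity
    plateau = _wall_plateau(wall_mean)

    selected: list[int] = []
    trace: dict[int, str] = {}
    for k in range(stack.n_slices):
        if wall_mean[k] > rules.surface_factor * plateau:
            trace[k] = (
                f"surface: wall mean {wall_mean[k]:.4g} > "
                f"{rules.surface_factor} x plateau {plateau:.4g}"
            )
        elif wall_mean[k] < rules.presence_factor * plateau:
            trace[k] = (
                f"no fiber: wall mean {wall_mean[k]:.4g} < "
                f"{rules.presence_factor} x plateau {plateau:.4g}"
            )
        elif lumen_mean[k] >= rules.lumen_factor * plateau:
            trace[k] = (
                f"no lumen: lumen mean {lumen_mean[k]:.4g} >= "
                f"{rules.lumen_factor} x plateau {plateau:.4g}"
            )
        else:
            selected.append(k)

    if not selected:
        raise NoUsableSoiError(
            "no usable SOI: every slice rejected "
            f"({len(trace)} exclusions; first: "
            f"{trace[min(trace)] if trace else 'n/a'})"
        )
    return SoiSelection(slice_indices=selected, rule_trace=trace)
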