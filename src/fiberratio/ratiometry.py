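"""The per-fiber binding ratio R and its background-shift sensitivity model.

R quantifies the relative binding of a labelled enzyme to dislocations
versus the surrounding normal cell wall.  For each selected slice of
interest (SOI) the ratio

    r_k = mean(three dislocation-ROI means) / mean(three wall-ROI means)

is computed, and R is the unweighted arithmetic mean of the r_k.  Ratioing
per slice *before* averaging is deliberate: it tolerates axial modulation
of the emission (absorption and scattering through the cell wall change
with depth), which the alternative — pooling all emissions over the SOIs
first, then ratioing — silently assumes away.  The alternative order is
available behind an explicit flag for comparison studies only.

Because R is a ratio of two emissions measured in the same slice, global
factors — degree of labelling, slice thickness, detector gain — cancel.
The one systematic that does not cancel is a shift of the background
absolute zero.  With the wall emission normalized to 1, shifting the zero
down by a fraction ``beta`` turns a true ratio R into

    R' = (R - beta) / (1 - beta),

so the relative disparity grows with R: it is identically zero at R = 1 and
reaches about 21 % at R = 2 for a 30 % shift.  Ratios up to ~2 therefore
tolerate sizeable baseline drift without changing their interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .soi import SoiSelection
from .stack_io import ImageStack, RoiSet

__all__ = [
    "DegenerateDenominatorError",
    "RatioResult",
    "SensitivityCurve",
    "per_soi_ratio",
    "fiber_R",
    "shifted_ratio",
    "sensitivity_curve",
]

# wall means below this fraction of the stack maximum are considered degenerate
DENOMINATOR_FLOOR_FRACTION = 1e-9


class DegenerateDenominatorError(ZeroDivisionError):
    """The wall-ROI mean is too close to zero for a meaningful ratio."""


@dataclass
class RatioResult:
    """Per-SOI dislocation/wall ratios and their mean, the statistic R."""

    fiber_id: str
    per_soi_ratios: list[float]
    mean_R: float
    n_sois: int
    enzyme: str = ""
    washed: bool = False

    def __post_init__(self) -> None:
        if self.n_sois < 1 or len(self.per_soi_ratios) != self.n_sois:
            raise ValueError("n_sois must match the per-SOI ratio list")


def _mean_of_roi_means(
    stack: ImageStack, rois: RoiSet, kind: str, slice_index: int
) -> float:
    """Equal-weight mean of the triplicate ROI means at one slice.

    Each ROI contributes its own mean regardless of area (the triplicate
    design weights positions, not pixels).
    """
    plane = stack.intensities[slice_index]
    means = []
    for roi in rois.of_kind(kind):
        rows, cols = roi.slices()
        means.append(float(plane[rows, cols].mean()))
    return float(np.mean(means))


def per_soi_ratio(stack: ImageStack, rois: RoiSet, slice_index: int) -> float:
    """Dislocation/wall emission ratio at one slice of interest."""
    if not 0 <= slice_index < stack.n_slices:
        raise IndexError(f"slice {slice_index} out of range")
    rois.validate_against(stack)
    disl = _mean_of_roi_means(stack, rois, "dislocation", slice_index)
    wall = _mean_of_roi_means(stack, rois, "normal_wall", slice_index)
    floor = DENOMINATOR_FLOOR_FRACTION * float(stack.intensities.max())
    if wall <= floor:
        raise DegenerateDenominatorError(
            f"wall mean {wall:.4g} at slice {slice_index} is at or below the "
            f"degenerate-denominator floor {floor:.4g}"
        )
    return disl / wall


def fiber_R(
    stack: ImageStack,
    rois: RoiSet,
    sois: SoiSelection,
    *,
    fiber_id: str = "",
    enzyme: str = "",
    washed: bool = False,
    pool_across_sois: bool = False,
) -> RatioResult:
    """Per-fiber statistic R over the selected SOIs.

    Default order of operations: ratio per SOI, then average.  With
    ``pool_across_sois=True`` the rejected alternative is computed instead
    (average each compartment's emission over all SOIs, then ratio); it is
    exposed only so that the difference between the two orders can be
    studied, and its per-SOI list still reports the per-slice ratios.
    """
    if sois.n_sois < 1:
        raise ValueError("SOI selection is empty")
    ratios = [per_soi_ratio(stack, rois, k) for k in sois.slice_indices]
    if pool_across_sois:
        disl = np.mean([
            _mean_of_roi_means(stack, rois, "dislocation", k)
            for k in sois.slice_indices
        ])
        wall = np.mean([
            _mean_of_roi_means(stack, rois, "normal_wall", k)
            for k in sois.slice_indices
        ])
        floor = DENOMINATOR_FLOOR_FRACTION * float(stack.intensities.max())
        if wall <= floor:
            raise DegenerateDenominatorError(
                f"pooled wall mean {wall:.4g} is at or below the floor"
            )
        mean_R = float(disl / wall)
    else:
        mean_R = float(np.mean(ratios))
    return RatioResult(
        fiber_id=fiber_id,
        per_soi_ratios=[float(r) for r in ratios],
        mean_R=mean_R,
        n_sois=sois.n_sois,
        enzyme=enzyme,
        washed=washed,
    )


def shifted_ratio(R: float, beta: float) -> float:
    """Ratio measured after a downward background-zero shift.

    ``beta`` is the shift expressed as a fraction of the (normalized) wall
    emission, 0 <= beta < 1.  R' = (R - beta) / (1 - beta); R' = R at
    beta = 0 and for R = 1 exactly.
    """
    if not 0 <= beta < 1:
        raise ValueError(f"beta must lie in [0, 1), got {beta}")
    if R < 1:
        raise ValueError(f"R must be >= 1 for the shift model, got {R}")
    return (R - beta) / (1.0 - beta)


@dataclass
class SensitivityCurve:
    """Shifted ratios and percent disparities over a (beta, R) grid."""

    beta: np.ndarray          # shape (n_beta,)
    R_values: np.ndarray      # shape (n_R,)
    shifted_R: np.ndarray     # shape (n_R, n_beta)
    disparity_percent: np.ndarray  # shape (n_R, n_beta)


def sensitivity_curve(
    beta_grid: np.ndarray | list[float],
    R_grid: np.ndarray | list[float],
) -> SensitivityCurve:
    """Evaluate the background-shift sensitivity over a grid.

    ``disparity_percent[i, j] = 100 * (R'(R_i, beta_j) - R_i) / R_i``;
    it is zero along beta = 0 and along R = 1, strictly increasing in beta
    for fixed R > 1 and in R for fixed beta > 0.
    """
    beta = np.asarray(beta_grid, dtype=float)
    R = np.asarray(R_grid, dtype=float)
    if np.any(beta < 0) or np.any(beta >= 1):
        raise ValueError("beta grid must lie in [0, 1)")
    if np.any(R < 1):
        raise ValueError("R grid must be >= 1")
    shifted = (R[:, None] - beta[None, :]) / (1.0 - beta[None, :])
    disparity = 100.0 * (shifted - R[:, None]) / R[:, None]
    return SensitivityCurve(
        beta=beta, R_values=R, shifted_R=shifted, disparity_percent=disparity
    )
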