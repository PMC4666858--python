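"""Synthetic confocal z-stacks of model fibers with voxel ground truth.

The simulator builds a latewood-like fiber lying horizontally in the image
plane: a cylinder (outer diameter 24 µm, lumen diameter 8 µm by default)
whose axis runs along the image x-direction, sectioned by equally spaced
optical slices.  Fluorophore-labelled enzyme produces an emission-density
field:

* ``background_level`` in the bulk solution outside the fiber,
* ``wall_density`` (1 by construction) in the normal S2 wall,
* ``rho_true x wall_density`` inside dislocation bands,
* ``surface_enrichment_factor x wall_density`` in a thin layer at the outer
  fiber surface (enzyme accumulating on the surface and on fines),
* 0 in the lumen interior.

Dislocation bands are axial slabs perpendicular to the fiber axis covering
at least half of the cross-section.  The density field is blurred with a
separable Gaussian parameterized by the lateral/axial PSF FWHMs, then
Poisson photon noise (scaled by ``photon_scale``) and additive Gaussian read
noise are applied.  Every voxel carries a ground-truth label so that
mask-based intensity averages provide an oracle that is independent of the
ROI/SOI measurement pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .optics import OpticsConfig, axial_fwhm, lateral_fwhm
from .stack_io import FiberCube, ImageStack, Roi, RoiSet

__all__ = [
    "FiberGeometry",
    "AcquisitionParams",
    "GroundTruth",
    "GroupSpec",
    "LABELS",
    "generate_fiber_stack",
    "generate_cohort",
    "place_rois",
]

# ground-truth voxel labels; mutually exclusive, exhaustive
LABELS = {
    "background": 0,
    "bulk_solution": 1,
    "normal_wall": 2,
    "dislocation": 3,
    "lumen": 4,
    "surface_layer": 5,
}

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class FiberGeometry:
    """Geometry of one model fiber (all lengths in µm).

    ``dislocation_bands`` lists (axial position, band width, coverage)
    triples; coverage is the fraction of the cross-section spanned by the
    band, at least 0.5 (large dislocations extend at least across half a
    fiber, often all the way).
    """

    fiber_diameter: float = 24.0
    lumen_diameter: float = 8.0
    fiber_axis_length: float = 40.0
    dislocation_bands: tuple[tuple[float, float, float], ...] = (
        (12.0, 6.0, 1.0),
        (28.0, 6.0, 1.0),
    )

    def __post_init__(self) -> None:
        if not 0 < self.lumen_diameter < self.fiber_diameter:
            raise ValueError("need 0 < lumen_diameter < fiber_diameter")
        if self.fiber_axis_length <= 0:
            raise ValueError("fiber_axis_length must be positive")
        for x, w, cov in self.dislocation_bands:
            if w <= 0:
                raise ValueError("dislocation band width must be positive")
            if not 0.5 <= cov <= 1.0:
                raise ValueError(
                    "dislocation coverage fraction must lie in [0.5, 1.0]"
                )
            if not 0 <= x <= self.fiber_axis_length:
                raise ValueError("band position must lie on the fiber axis")


_DEFAULT_OPTICS = OpticsConfig()


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition and detection parameters of the simulated microscope.

    Defaults follow the documented acquisition: 116 nm pixels, 15 slices at
    2 µm spacing (a 30 µm scan depth), PSF FWHMs from the optics module
    (270 nm lateral, 740 nm axial), and a ~1 µm surface-enriched layer.
    The surface enrichment factor is not quantified by the imaging study
    this emulates; the default of 4 produces the qualitatively dominant
    surface signal seen in such data and is recorded in output metadata.
    """

    pixel_size_nm: float = 116.0
    slice_spacing_um: float = 2.0
    n_slices: int = 15
    psf_fwhm_lateral_nm: float = lateral_fwhm(_DEFAULT_OPTICS)
    psf_fwhm_axial_nm: float = axial_fwhm(_DEFAULT_OPTICS)
    surface_layer_thickness_um: float = 1.0
    surface_enrichment_factor: float = 4.0
    background_level: float = 0.05
    photon_scale: float = 200.0
    read_noise_sd: float = 1.0
    field_height_um: float = 36.0

    def __post_init__(self) -> None:
        for name in (
            "pixel_size_nm",
            "slice_spacing_um",
            "psf_fwhm_lateral_nm",
            "psf_fwhm_axial_nm",
            "surface_layer_thickness_um",
            "photon_scale",
            "field_height_um",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_slices < 2:
            raise ValueError("n_slices must be at least 2")
        if self.surface_enrichment_factor < 1:
            raise ValueError("surface_enrichment_factor must be >= 1")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("background_level and read_noise_sd must be >= 0")

    @property
    def scan_depth_um(self) -> float:
        return self.n_slices * self.slice_spacing_um


@dataclass
class GroundTruth:
    """Voxel labels plus the true dislocation/wall emission ratio."""

    labels: np.ndarray  # int8 array, same shape as the stack
    rho_true: float

    def mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]

    def mask_mean(self, stack: ImageStack, name: str) -> float:
        """Mean stack intensity over one ground-truth mask (oracle path)."""
        m = self.mask(name)
        if not m.any():
            raise ValueError(f"ground-truth mask {name!r} is empty")
        return float(stack.intensities[m].mean())


@dataclass(frozen=True)
class GroupSpec:
    """One treatment group of a simulated cohort."""

    label: str
    n_fibers: int
    rho_true: float
    washed: bool = False

    def __post_init__(self) -> None:
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        if self.rho_true <= 0:
            raise ValueError("rho_true must be positive")


def _emission_density(
    geometry: FiberGeometry, acq: AcquisitionParams, rho_true: float
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free emission density and voxel labels on the acquisition grid.

    Grid axes: z = slice index (depth), y = row, x = column (fiber axis).
    The fiber axis sits at mid-height and mid-depth of the scanned volume;
    slice planes sample depths ``k * slice_spacing``, so with the default
    15 x 2 µm scan (planes at 0..28 µm, equator at 15 µm) the fiber center
    falls between two slice planes and the 8 µm lumen intersects the four
    planes nearest the equator.
    """
    px_um = acq.pixel_size_nm / 1000.0
    n_cols = max(int(round(geometry.fiber_axis_length / px_um)), 1)
    n_rows = max(int(round(acq.field_height_um / px_um)), 1)

    r_fiber = geometry.fiber_diameter / 2.0
    r_lumen = geometry.lumen_diameter / 2.0
    if geometry.fiber_diameter > acq.field_height_um:
        raise ValueError(
            "fiber does not fit in the field of view: diameter "
            f"{geometry.fiber_diameter} µm exceeds field height "
            f"{acq.field_height_um} µm"
        )
    if geometry.fiber_diameter > acq.scan_depth_um:
        raise ValueError(
            "fiber does not fit in the scanned depth: diameter "
            f"{geometry.fiber_diameter} µm exceeds scan depth "
            f"{acq.scan_depth_um} µm"
        )

    z = np.arange(acq.n_slices) * acq.slice_spacing_um
    zc = acq.scan_depth_um / 2.0
    y = (np.arange(n_rows) + 0.5) * px_um
    yc = acq.field_height_um / 2.0
    x = (np.arange(n_cols) + 0.5) * px_um

    dz = (z - zc)[:, None, None]
    dy = (y - yc)[None, :, None]
    r = np.sqrt(dz**2 + dy**2)  # radial distance from the fiber axis

    inside_fiber = r <= r_fiber
    in_lumen = r <= r_lumen
    in_surface = inside_fiber & (r > r_fiber - acq.surface_layer_thickness_um)
    in_wall = inside_fiber & ~in_lumen & ~in_surface

    labels = np.full((acq.n_slices, n_rows, n_cols), LABELS["bulk_solution"],
                     dtype=np.int8)
    labels[np.broadcast_to(in_lumen, labels.shape)] = LABELS["lumen"]
    labels[np.broadcast_to(in_surface, labels.shape)] = LABELS["surface_layer"]
    labels[np.broadcast_to(in_wall, labels.shape)] = LABELS["normal_wall"]

    # dislocation bands: slabs along x; coverage c >= 0.5 keeps wall voxels
    # whose row coordinate lies in the upper c-fraction of the cross-section
    for x_pos, width, cov in geometry.dislocation_bands:
        in_band_x = (x >= x_pos - width / 2.0) & (x < x_pos + width / 2.0)
        covered_rows = (yc - y) >= (1.0 - 2.0 * cov) * r_fiber
        sel = (
            np.broadcast_to(in_wall, labels.shape)
            & in_band_x[None, None, :]
            & covered_rows[None, :, None]
        )
        labels[sel] = LABELS["dislocation"]

    wall_density = 1.0
    density = np.full(labels.shape, acq.background_level, dtype=np.float64)
    density[labels == LABELS["lumen"]] = 0.0
    density[labels == LABELS["normal_wall"]] = wall_density
    density[labels == LABELS["dislocation"]] = rho_true * wall_density
    density[labels == LABELS["surface_layer"]] = (
        acq.surface_enrichment_factor * wall_density
    )
    return density, labels


def generate_fiber_stack(
    geometry: FiberGeometry,
    acq: AcquisitionParams,
    rho_true: float,
    seed: int | np.random.SeedSequence,
    *,
    blur: bool = True,
    noise: bool = True,
) -> tuple[ImageStack, GroundTruth]:
    """Simulate one confocal stack of a model fiber.

    Returns the noisy stack (photon units) and the voxel ground truth.
    Identical arguments reproduce the stack bit-for-bit.  ``blur`` and
    ``noise`` can be disabled to obtain the ideal density field (times
    ``photon_scale``) for oracle tests.
    """
    if rho_true <= 0:
        raise ValueError("rho_true must be positive")
    density, labels = _emission_density(geometry, acq, rho_true)

    if blur:
        px_um = acq.pixel_size_nm / 1000.0
        sigma_lat = acq.psf_fwhm_lateral_nm / 1000.0 * _FWHM_TO_SIGMA / px_um
        sigma_ax = (
            acq.psf_fwhm_axial_nm / 1000.0 * _FWHM_TO_SIGMA
            / acq.slice_spacing_um
        )
        density = ndimage.gaussian_filter(
            density, sigma=(sigma_ax, sigma_lat, sigma_lat), mode="nearest"
        )

    expected = density * acq.photon_scale
    if noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(np.float64)
        counts += rng.normal(0.0, acq.read_noise_sd, size=counts.shape)
        intensities = np.clip(counts, 0.0, None)
    else:
        intensities = expected

    stack = ImageStack(
        intensities=intensities,
        pixel_size_nm=acq.pixel_size_nm,
        slice_spacing_um=acq.slice_spacing_um,
        meta={
            "simulated": True,
            "rho_true": rho_true,
            "surface_enrichment_factor": acq.surface_enrichment_factor,
            "background_level": acq.background_level,
            "photon_scale": acq.photon_scale,
            "read_noise_sd": acq.read_noise_sd,
        },
    )
    return stack, GroundTruth(labels=labels, rho_true=rho_true)


# ---------------------------------------------------------------------------
# ROI placement from ground truth


def _rect_fits(footprint: np.ndarray, y0: int, x0: int, h: int, w: int,
               cumsum: np.ndarray) -> bool:
    """Rectangle entirely inside the footprint, via a 2-D integral image."""
    total = (
        cumsum[y0 + h, x0 + w]
        - cumsum[y0, x0 + w]
        - cumsum[y0 + h, x0]
        + cumsum[y0, x0]
    )
    return total == h * w


def _place_in_footprint(
    footprint: np.ndarray, n: int, size: int, taken: list[Roi], kind: str
) -> list[Roi]:
    """Greedy deterministic placement of n non-overlapping size x size
    rectangles inside a boolean footprint, avoiding already-taken ROIs."""
    cumsum = np.zeros((footprint.shape[0] + 1, footprint.shape[1] + 1))
    np.cumsum(np.cumsum(footprint.astype(np.int64), axis=0), axis=1,
              out=cumsum[1:, 1:])
    placed: list[Roi] = []

    def overlaps(y0: int, x0: int) -> bool:
        for r in placed + taken:
            if (x0 < r.x0 + r.width and r.x0 < x0 + size
                    and y0 < r.y0 + r.height and r.y0 < y0 + size):
                return True
        return False

    for y0 in range(0, footprint.shape[0] - size + 1):
        for x0 in range(0, footprint.shape[1] - size + 1):
            if _rect_fits(footprint, y0, x0, size, size, cumsum) and not \
                    overlaps(y0, x0):
                placed.append(Roi(x0, y0, size, size, kind))
                if len(placed) == n:
                    return placed
    raise ValueError(
        f"cannot place {n} non-overlapping {size}x{size} {kind} ROIs "
        f"inside the available mask footprint"
    )


def place_rois(
    truth: GroundTruth,
    roi_size_px: int = 9,
    *,
    candidate_slices: Sequence[int] | None = None,
    margin_px: int = 0,
) -> RoiSet:
    """Derive a complete ROI set (3 wall, 3 dislocation, 3 bulk, 1 lumen)
    from ground-truth masks.

    A rectangle is accepted for a kind only if its footprint lies inside
    that kind's mask in *every* candidate slice (by default the slices whose
    plane intersects the lumen, i.e. the slices the SOI rules can select),
    so a placed ROI is pure wall / dislocation / bulk at measurement depths.
    ``margin_px`` erodes the wall/dislocation/bulk footprints so rectangles
    stay clear of mask boundaries where the PSF bleeds between compartments
    (the lumen ROI, used only as a darkness indicator, is not eroded).  If
    the eroded footprint cannot host the rectangles, placement falls back
    to the uneroded one.
    """
    labels = truth.labels
    n_slices = labels.shape[0]
    if candidate_slices is None:
        lumen_any = truth.mask("lumen").any(axis=(1, 2))
        candidate_slices = np.flatnonzero(lumen_any)
        if len(candidate_slices) == 0:
            raise ValueError("no slice intersects the lumen; cannot place ROIs")
    sel = list(candidate_slices)
    if not sel or min(sel) < 0 or max(sel) >= n_slices:
        raise ValueError("candidate slice indices out of range")

    def footprint(kind: str) -> np.ndarray:
        return np.logical_and.reduce(
            [labels[k] == LABELS[kind] for k in sel]
        )

    def eroded(fp: np.ndarray) -> np.ndarray:
        if margin_px <= 0:
            return fp
        side = 2 * margin_px + 1
        return ndimage.binary_erosion(fp, structure=np.ones((side, side)))

    def place(fp: np.ndarray, n: int, taken: list[Roi], kind: str) -> list[Roi]:
        try:
            return _place_in_footprint(eroded(fp), n, roi_size_px, taken, kind)
        except ValueError:
            if margin_px <= 0:
                raise
            return _place_in_footprint(fp, n, roi_size_px, taken, kind)

    taken: list[Roi] = []
    wall = place(footprint("normal_wall"), 3, taken, "normal_wall")
    taken += wall
    disl = place(footprint("dislocation"), 3, taken, "dislocation")
    taken += disl
    bulk_fp = np.logical_and.reduce(
        [np.isin(labels[k], (LABELS["bulk_solution"], LABELS["background"]))
         for k in range(n_slices)]
    )
    bulk = place(bulk_fp, 3, taken, "bulk")
    taken += bulk
    lumen = _place_in_footprint(footprint("lumen"), 1, roi_size_px, taken,
                                "lumen")
    return RoiSet(wall + disl + bulk + lumen)


def generate_cohort(
    groups: Sequence[GroupSpec],
    acq: AcquisitionParams,
    seed: int | np.random.SeedSequence,
    *,
    geometry: FiberGeometry = FiberGeometry(),
    roi_size_px: int = 9,
) -> list[tuple[FiberCube, GroundTruth]]:
    """Simulate a cohort of fibers across treatment groups.

    Per-fiber sub-seeds are spawned deterministically from the master seed,
    so the same master seed reproduces the identical cohort and each fiber's
    noise stream is independent.  ROIs are auto-placed from ground truth.
    """
    master = (
        seed if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    total = sum(g.n_fibers for g in groups)
    children = master.spawn(total)
    out: list[tuple[FiberCube, GroundTruth]] = []
    i = 0
    for group in groups:
        for j in range(group.n_fibers):
            stack, truth = generate_fiber_stack(
                geometry, acq, group.rho_true, children[i]
            )
            margin = math.ceil(acq.psf_fwhm_lateral_nm / acq.pixel_size_nm)
            rois = place_rois(truth, roi_size_px=roi_size_px, margin_px=margin)
            cube = FiberCube(
                stack=stack,
                rois=rois,
                fiber_id=f"{group.label}_{'w' if group.washed else 'u'}_{j:03d}",
                enzyme=group.label,
                washed=group.washed,
            )
            out.append((cube, truth))
            i += 1
    return out
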