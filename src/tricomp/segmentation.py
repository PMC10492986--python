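"""Adipose-compartment segmentation from fat-fraction MRI stacks.

Stage order per slice: background removal on the combined fat/water image
(tissue mask), fat-fraction thresholding inside the tissue mask, radial
tracing of the subcutaneous ring's outer and inner boundaries, and polar
assignment of fat pixels to SAT (between the boundaries) or VAT (strictly
inside the inner boundary).  Per-slice areas are summed into compartment
volumes; nonadipose tissue (NAT) is the residual volume.

Automated QC replaces manual contour editing: degenerate slices are
flagged with reason codes rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "FatFractionStack",
    "RadialContour",
    "SliceMasks",
    "SegmentationResult",
    "SegmentationConfig",
    "tissue_mask",
    "fat_mask",
    "trace_subcutaneous_boundaries",
    "split_compartments",
    "volumes",
    "segment_stack",
]


@dataclass(frozen=True)
class FatFractionStack:
    """Two-channel image stack: per-voxel fat fraction plus combined signal.

    Arrays are (slices, rows, cols); ``voxel_dims`` is (dx, dy, dz) in mm.
    """

    fat_fraction: np.ndarray
    combined_signal: np.ndarray
    voxel_dims: tuple[float, float, float]
    slab_convention: str = "neck-to-knees, arms excluded"

    def __post_init__(self) -> None:
        ff = np.asarray(self.fat_fraction)
        cs = np.asarray(self.combined_signal)
        if ff.ndim != 3 or cs.shape != ff.shape:
            raise ValueError("fat_fraction and combined_signal must share a 3-D shape")
        if any(v <= 0 for v in self.voxel_dims):
            raise ValueError("voxel_dims must be positive")
        object.__setattr__(self, "fat_fraction", np.clip(ff, 0.0, 1.0))
        object.__setattr__(self, "combined_signal", cs)

    @property
    def slice_count(self) -> int:
        return self.fat_fraction.shape[0]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_dims
        return dx * dy * dz


@dataclass(frozen=True)
class RadialContour:
    """Closed contour stored as radii sampled on equiangular rays from a center.

    ``radii[i]`` is the contour's distance (pixels) from ``center``
    (row, col) at angle ``angles[i]``.  ``hit[i]`` is False where the radius
    was angularly interpolated because the ray met no fat.
    """

    center: tuple[float, float]
    angles: np.ndarray
    radii: np.ndarray
    hit: np.ndarray

    def radius_at(self, theta: np.ndarray) -> np.ndarray:
        """Linear circular interpolation of the radius at arbitrary angles."""
        theta = np.mod(theta, 2.0 * np.pi)
        ang = np.concatenate([self.angles, [2.0 * np.pi + self.angles[0]]])
        rad = np.concatenate([self.radii, [self.radii[0]]])
        return np.interp(theta, ang, rad)

    def vertices(self) -> np.ndarray:
        """(n, 2) array of (row, col) vertices in pixel coordinates."""
        r0, c0 = self.center
        rows = r0 + self.radii * np.sin(self.angles)
        cols = c0 + self.radii * np.cos(self.angles)
        return np.column_stack([rows, cols])


@dataclass
class SliceMasks:
    tissue_mask: np.ndarray
    fat_mask: np.ndarray
    sat_mask: np.ndarray
    vat_mask: np.ndarray
    outer_boundary: RadialContour | None = None
    inner_boundary: RadialContour | None = None
    flags: list[str] = field(default_factory=list)

    def check_invariants(self) -> None:
        if np.any(self.sat_mask & self.vat_mask):
            raise AssertionError("sat_mask and vat_mask overlap")
        if np.any((self.sat_mask | self.vat_mask) & ~self.fat_mask):
            raise AssertionError("compartment masks exceed the fat mask")
        if np.any(self.fat_mask & ~self.tissue_mask):
            raise AssertionError("fat mask exceeds the tissue mask")


@dataclass
class SegmentationResult:
    slices: list[SliceMasks]
    sat_volume_l: float
    vat_volume_l: float
    nat_volume_l: float
    total_tissue_volume_l: float
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {
            "sat_volume_l": self.sat_volume_l,
            "vat_volume_l": self.vat_volume_l,
            "nat_volume_l": self.nat_volume_l,
            "total_tissue_volume_l": self.total_tissue_volume_l,
        }


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunables the source method leaves open; defaults are explicit choices."""

    signal_threshold: float | None = None  # None -> Otsu per slice
    ff_threshold: float = 0.5
    n_rays: int = 360
    ray_step: float = 0.5  # pixels
    min_hit_fraction: float = 0.5
    max_hole_area: int = 64  # pixels; holes smaller than this are filled
    outer_outlier_fraction: float = 0.55  # hits below this x median radius -> miss
    boundary_smooth_rays: int = 5  # circular median window over per-ray radii
    reject_lateral_components: bool = False


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def _fill_small_holes(mask: np.ndarray, max_area: int) -> np.ndarray:
    """Fill background components not touching the border and smaller than max_area."""
    bg, nlab = ndimage.label(~mask)
    if nlab == 0:
        return mask
    border_labels = np.unique(
        np.concatenate([bg[0], bg[-1], bg[:, 0], bg[:, -1]])
    )
    out = mask.copy()
    sizes = np.bincount(bg.ravel())
    for lab in range(1, nlab + 1):
        if lab in border_labels:
            continue
        if sizes[lab] < max_area:
            out[bg == lab] = True
    return out


def tissue_mask(
    combined_signal: np.ndarray,
    threshold: float | None = None,
    max_hole_area: int = 64,
    keep_largest_only: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Background removal: threshold the combined image, keep the main body.

    Returns (mask, flags).  An all-background image yields an empty mask
    flagged ``empty_tissue_mask`` instead of raising.
    """
    img = np.asarray(combined_signal, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("combined_signal must be finite-valued")
    flags: list[str] = []
    if threshold is None:
        if np.ptp(img) == 0:
            return np.zeros(img.shape, bool), ["empty_tissue_mask"]
        threshold = float(threshold_otsu(img))
    mask = img > threshold
    if not mask.any():
        return mask, ["empty_tissue_mask"]
    labels, nlab = ndimage.label(mask)
    if keep_largest_only and nlab > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        mask = labels == int(np.argmax(sizes))
        flags.append("disconnected_components_removed")
    mask = _fill_small_holes(mask, max_hole_area)
    return mask, flags


def fat_mask(
    fat_fraction: np.ndarray, tissue: np.ndarray, ff_threshold: float = 0.5
) -> np.ndarray:
    """Fat pixels: fat fraction at or above threshold, inside the tissue mask."""
    if not 0.0 <= ff_threshold <= 1.0:
        raise ValueError("ff_threshold must lie in [0, 1]")
    if not np.any(tissue):
        raise ValueError("tissue mask is empty")
    return (np.asarray(fat_fraction) >= ff_threshold) & tissue


# ---------------------------------------------------------------------------
# radial boundary tracing
# ---------------------------------------------------------------------------

def _circular_interpolate(radii: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill invalid ray radii by linear interpolation around the circle."""
    n = radii.size
    if valid.all():
        return radii
    if not valid.any():
        return np.zeros(n)
    idx = np.arange(n)
    good = idx[valid]
    # periodic extension so interpolation wraps across 0/2pi
    xp = np.concatenate([good - n, good, good + n]).astype(float)
    fp = np.tile(radii[valid], 3)
    out = radii.copy()
    out[~valid] = np.interp(idx[~valid].astype(float), xp, fp)
    return out


def trace_subcutaneous_boundaries(
    fat: np.ndarray,
    tissue: np.ndarray | None = None,
    config: SegmentationConfig = SegmentationConfig(),
) -> tuple[RadialContour, RadialContour, list[str]]:
    """Trace the subcutaneous ring's outer and inner boundaries radially.

    Rays run from outside the body toward its centroid.  Per ray, the first
    fat pixel marks the outer boundary; the first subsequent fat-to-non-fat
    transition marks the inner boundary.  Rays that meet no fat (or whose
    first hit is an implausibly deep outlier, e.g. a visceral blob seen
    through a ring gap) are filled by angular interpolation.
    """
    fat = np.asarray(fat, dtype=bool)
    if not fat.any():
        raise ValueError("fat mask is empty")
    ref = tissue if tissue is not None and np.any(tissue) else fat
    r0, c0 = ndimage.center_of_mass(ref)

    nray = config.n_rays
    angles = np.arange(nray) * (2.0 * np.pi / nray)
    nrows, ncols = fat.shape
    r_max = float(np.hypot(nrows, ncols))
    steps = np.arange(r_max, 0.0, -config.ray_step)  # outside-in

    # sample the fat mask on an (n_steps, n_rays) polar grid, outside-in
    ir = np.round(r0 + steps[:, None] * np.sin(angles)[None, :]).astype(int)
    ic = np.round(c0 + steps[:, None] * np.cos(angles)[None, :]).astype(int)
    ok = (ir >= 0) & (ir < nrows) & (ic >= 0) & (ic < ncols)
    vals = np.zeros(ir.shape, bool)
    vals[ok] = fat[ir[ok], ic[ok]]

    any_hit = vals.any(axis=0)
    first = np.argmax(vals, axis=0)  # index of the first fat sample per ray
    pos = np.arange(steps.size)[:, None]
    # within the first fat run, locate the first non-fat sample going inward;
    # samples before the run are masked True so argmax finds the run's end
    masked = vals | (pos < first[None, :])
    run_ended = ~masked.all(axis=0)
    end = np.argmax(~masked, axis=0)  # first non-fat index after the run

    outer = np.where(any_hit, steps[first], np.nan)
    # the last fat sample of the run is the inner boundary (SAT-inclusive);
    # a run reaching the centroid means no visceral cavity on this ray
    inner = np.where(
        any_hit, np.where(run_ended, steps[np.maximum(end - 1, 0)], 0.0), np.nan
    )

    hit = np.isfinite(outer)
    flags: list[str] = []
    if hit.any():
        med = float(np.median(outer[hit]))
        deep = hit & (outer < config.outer_outlier_fraction * med)
        if deep.any():
            hit &= ~deep
            outer[deep] = np.nan
            inner[deep] = np.nan
            flags.append("outlier_rays_interpolated")
    hit_fraction = float(hit.mean())
    if hit_fraction < config.min_hit_fraction:
        flags.append("no_subcutaneous_ring")
    if hit_fraction < 1.0 and "no_subcutaneous_ring" not in flags:
        flags.append("gap_rays_interpolated")

    outer = _circular_interpolate(outer, hit)
    inner = _circular_interpolate(inner, hit)
    if config.boundary_smooth_rays > 1:
        # circular median filter suppresses single-ray jitter from
        # rasterized (stair-stepped) boundaries
        outer = ndimage.median_filter(
            outer, size=config.boundary_smooth_rays, mode="wrap"
        )
        inner = ndimage.median_filter(
            inner, size=config.boundary_smooth_rays, mode="wrap"
        )
    inner = np.minimum(inner, outer)
    if hit.any() and float(np.median(inner[hit])) <= 2.0 * config.ray_step:
        flags.append("no_visceral_cavity")

    center = (float(r0), float(c0))
    return (
        RadialContour(center, angles, outer, hit.copy()),
        RadialContour(center, angles, inner, hit.copy()),
        flags,
    )


def split_compartments(
    fat: np.ndarray,
    outer: RadialContour,
    inner: RadialContour,
    tissue: np.ndarray | None = None,
    ray_step: float = 0.5,
) -> SliceMasks:
    """Assign fat pixels to SAT/VAT by polar position relative to the boundaries.

    Convention: a pixel exactly on the inner boundary is SAT (the inner
    boundary is inclusive for SAT and exclusive for VAT); the outer
    boundary is inclusive with half-a-ray-step tolerance for rasterization.
    """
    fat = np.asarray(fat, dtype=bool)
    if outer.center != inner.center:
        raise ValueError("boundary contours must share a center")
    r0, c0 = outer.center
    rows, cols = np.nonzero(fat)
    dr = rows - r0
    dc = cols - c0
    rad = np.hypot(dr, dc)
    theta = np.arctan2(dr, dc)
    r_out = outer.radius_at(theta)
    r_in = inner.radius_at(theta)
    if np.any(r_in > r_out + 1e-9):
        raise ValueError("inner boundary extends outside the outer boundary")

    # rasterization slack: half-pixel jitter plus ray sampling step; the
    # inner boundary stays SAT-inclusive, VAT strictly inside it
    tol = ray_step + 0.5
    sat_sel = (rad >= r_in - tol) & (rad <= r_out + tol)
    vat_sel = rad < r_in - tol

    sat = np.zeros_like(fat)
    vat = np.zeros_like(fat)
    sat[rows[sat_sel], cols[sat_sel]] = True
    vat[rows[vat_sel], cols[vat_sel]] = True

    masks = SliceMasks(
        tissue_mask=tissue if tissue is not None else fat,
        fat_mask=fat,
        sat_mask=sat,
        vat_mask=vat,
        outer_boundary=outer,
        inner_boundary=inner,
    )
    masks.check_invariants()
    return masks


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def volumes(
    slice_masks: list[SliceMasks], voxel_dims: tuple[float, float, float]
) -> SegmentationResult:
    """Sum per-slice compartment areas into volumes (liters).

    NAT is the residual: total tissue minus SAT minus VAT, so compartment
    additivity holds exactly by construction.
    """
    if not slice_masks:
        raise ValueError("at least one slice required")
    shape = slice_masks[0].tissue_mask.shape
    if any(m.tissue_mask.shape != shape for m in slice_masks):
        raise ValueError("inconsistent slice shapes")
    dx, dy, dz = voxel_dims
    voxvol_l = dx * dy * dz / 1e6
    sat = sum(int(m.sat_mask.sum()) for m in slice_masks) * voxvol_l
    vat = sum(int(m.vat_mask.sum()) for m in slice_masks) * voxvol_l
    tot = sum(int(m.tissue_mask.sum()) for m in slice_masks) * voxvol_l
    flags = sorted({f for m in slice_masks for f in m.flags})
    return SegmentationResult(
        slices=slice_masks,
        sat_volume_l=float(sat),
        vat_volume_l=float(vat),
        nat_volume_l=float(tot - sat - vat),
        total_tissue_volume_l=float(tot),
        flags=flags,
    )


def segment_stack(
    stack: FatFractionStack, config: SegmentationConfig = SegmentationConfig()
) -> SegmentationResult:
    """Run the full per-slice pipeline on a stack and sum volumes."""
    slice_masks: list[SliceMasks] = []
    for k in range(stack.slice_count):
        cs = stack.combined_signal[k]
        ff = stack.fat_fraction[k]
        tmask, tflags = tissue_mask(
            cs, config.signal_threshold, config.max_hole_area
        )
        if not tmask.any():
            empty = np.zeros(tmask.shape, bool)
            sm = SliceMasks(tmask, empty, empty.copy(), empty.copy(), flags=tflags)
            slice_masks.append(sm)
            continue
        fmask = fat_mask(ff, tmask, config.ff_threshold)
        if not fmask.any():
            empty = np.zeros(tmask.shape, bool)
            sm = SliceMasks(
                tmask, fmask, empty, empty.copy(), flags=tflags + ["empty_fat_mask"]
            )
            slice_masks.append(sm)
            continue
        outer, inner, bflags = trace_subcutaneous_boundaries(fmask, tmask, config)
        sm = split_compartments(fmask, outer, inner, tmask, config.ray_step)
        sm.flags = tflags + bflags
        if "no_subcutaneous_ring" in bflags:
            # degenerate slice: without a ring the SAT/VAT split is unreliable
            sm.flags.append(f"slice_{k}_degenerate")
        slice_masks.append(sm)
    return volumes(slice_masks, stack.voxel_dims)
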