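"""Radiograph preprocessing and region-of-interest construction.

The prognostic signal in the patellofemoral joint is read from three
equal-sized rectangular regions (superior / middle / inferior) anchored to
the patella bounding box on a vertically aligned, isotropically resampled
lateral knee radiograph.  The committed order of operations is

    align -> resample -> normalize -> (filter bank) -> discretize

so that every intensity filter sees the z-scored, pre-quantisation image and
every ROI lives on one shared 0.5 mm grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class Radiograph:
    """A 2D grayscale radiograph.  Row 0 is the superior edge.

    ``spacing_mm`` is (row spacing, column spacing) in millimetres;
    ``laterality`` records which knee, which fixes the posterior direction
    (for a left knee in standard lateral orientation the femur lies at
    higher column indices).
    """

    pixels: np.ndarray
    spacing_mm: tuple[float, float]
    laterality: str = "left"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("radiograph pixels must be a 2D grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("radiograph contains non-finite pixel values")
        sr, sc = self.spacing_mm
        if sr <= 0 or sc <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.laterality not in ("left", "right"):
            raise ValueError(f"unknown laterality {self.laterality!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class PatellaMask:
    """Binary patella segmentation on the same grid as its radiograph.

    The largest 4-connected foreground component is kept so the mask is a
    single blob even after interpolation.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("mask must be a 2D grid")
        px = px > 0
        if not px.any():
            raise ValueError("patella mask is empty")
        self.pixels = _largest_component(px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BoundingBox:
    """Half-open pixel box [row_min, row_max) x [col_min, col_max)."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if self.row_max <= self.row_min or self.col_max <= self.col_min:
            raise ValueError("bounding box must have positive extent")

    @property
    def height(self) -> int:
        return self.row_max - self.row_min

    @property
    def width(self) -> int:
        return self.col_max - self.col_min

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_min, self.row_max), slice(self.col_min, self.col_max)

    def as_list(self) -> list[int]:
        return [self.row_min, self.row_max, self.col_min, self.col_max]


@dataclass(frozen=True)
class ROISet:
    """The three analysis rectangles, superior to inferior.

    All three are pairwise equal in height and width, pairwise disjoint and
    vertically ordered.
    """

    roi_sup: BoundingBox
    roi_mid: BoundingBox
    roi_inf: BoundingBox

    def __post_init__(self) -> None:
        boxes = [self.roi_sup, self.roi_mid, self.roi_inf]
        h = {b.height for b in boxes}
        w = {b.width for b in boxes}
        if len(h) != 1 or len(w) != 1:
            raise ValueError("ROIs must be equal-sized")
        if not (self.roi_sup.row_max <= self.roi_mid.row_min
                and self.roi_mid.row_max <= self.roi_inf.row_min):
            raise ValueError("ROIs must be stacked superior -> inferior")

    def items(self):
        return (("roi_sup", self.roi_sup), ("roi_mid", self.roi_mid),
                ("roi_inf", self.roi_inf))

    def to_json_dict(self) -> dict[str, list[int]]:
        return {name: box.as_list() for name, box in self.items()}


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_FOUR_CONN)
    if n <= 1:
        return mask
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == int(np.argmax(sizes))


def mask_bbox(mask: PatellaMask | np.ndarray) -> BoundingBox:
    """Tight half-open bounding box of the mask foreground."""
    px = mask.pixels if isinstance(mask, PatellaMask) else np.asarray(mask) > 0
    rows = np.flatnonzero(px.any(axis=1))
    cols = np.flatnonzero(px.any(axis=0))
    if rows.size == 0:
        raise ValueError("cannot compute bounding box of an empty mask")
    return BoundingBox(int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)


def _rotate_grid(arr: np.ndarray, angle_deg: float, center: tuple[float, float],
                 order: int, cval: float) -> np.ndarray:
    """Rotate grid content by ``angle_deg`` about ``center`` (row, col)."""
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    # output[o] = input[R(-theta) @ (o - center) + center]
    rot_inv = np.array([[c, s], [-s, c]])
    center = np.asarray(center)
    offset = center - rot_inv @ center
    return ndimage.affine_transform(arr, rot_inv, offset=offset, order=order,
                                    cval=cval, mode="constant")


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def default_angle_grid(step: float = 0.5, half_range: float = 30.0) -> np.ndarray:
    n = int(round(half_range / step))
    return np.linspace(-half_range, half_range, 2 * n + 1)


def align_patella(image: Radiograph, mask: PatellaMask,
                  angle_grid: np.ndarray | None = None,
                  ) -> tuple[Radiograph, PatellaMask, float]:
    """Rotate image+mask so the patella is vertically aligned.

    The chosen angle maximises the height/width ratio of the rotated-mask
    bounding box over an exhaustive grid (ties broken by smallest |angle|).
    The search rotates the foreground pixel coordinates analytically; only
    the winning angle is applied to the rasters (mask nearest-neighbour,
    image linear, out-of-bounds filled with the image minimum).
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if angle_grid is None:
        angle_grid = default_angle_grid()
    angle_grid = np.asarray(angle_grid, dtype=float)
    if angle_grid.min() > -30.0 or angle_grid.max() < 30.0:
        raise ValueError("angle grid must cover at least [-30, +30] degrees")

    rr, cc = np.nonzero(mask.pixels)
    if rr.size < 2:
        raise ValueError("degenerate patella mask (fewer than 2 pixels)")
    centroid = (rr.mean(), cc.mean())
    # the rotated bounding box depends only on the convex hull vertices
    pts = np.column_stack([rr, cc]).astype(np.float64)
    if rr.size > 16:
        try:
            from scipy.spatial import ConvexHull
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass
    r0 = pts[:, 0] - centroid[0]
    c0 = pts[:, 1] - centroid[1]

    theta = np.deg2rad(angle_grid)[:, None]
    r_rot = np.cos(theta) * r0 - np.sin(theta) * c0
    c_rot = np.sin(theta) * r0 + np.cos(theta) * c0
    height = r_rot.max(axis=1) - r_rot.min(axis=1) + 1.0
    width = c_rot.max(axis=1) - c_rot.min(axis=1) + 1.0
    ratio = height / width

    best = ratio.max()
    # ties (within float wobble) -> smallest |angle|
    tied = np.flatnonzero(ratio >= best - 1e-12)
    chosen = tied[np.argmin(np.abs(angle_grid[tied]))]
    angle = float(angle_grid[chosen])

    # pixel-quantisation wobble on the bbox extents adds ~1-2 deg of noise
    # to the raw argmax; a quadratic fit to the ratio curve around the peak
    # averages it out.  The refined vertex is snapped back to the grid so
    # the committed tie rule and grid semantics are preserved.
    window = np.flatnonzero(np.abs(angle_grid - angle) <= 10.0)
    if window.size >= 5:
        coef = np.polyfit(angle_grid[window], ratio[window], 2)
        if coef[0] < 0:
            vertex = -coef[1] / (2.0 * coef[0])
            lo, hi = angle_grid[window[0]], angle_grid[window[-1]]
            if lo <= vertex <= hi:
                angle = float(angle_grid[np.argmin(np.abs(angle_grid - vertex))])

    if angle == 0.0:
        return image, mask, 0.0
    fill = float(image.pixels.min())
    rot_img = _rotate_grid(image.pixels, angle, centroid, order=1, cval=fill)
    rot_msk = _rotate_grid(mask.pixels.astype(np.float64), angle, centroid,
                           order=0, cval=0.0) > 0.5
    return (Radiograph(rot_img, image.spacing_mm, image.laterality),
            PatellaMask(rot_msk), angle)


def resample_isotropic(image: Radiograph, mask: PatellaMask,
                       target_mm: float = 0.5) -> tuple[Radiograph, PatellaMask]:
    """Resample image (linear) and mask (nearest) onto an isotropic grid."""
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    factors = (image.spacing_mm[0] / target_mm, image.spacing_mm[1] / target_mm)
    out_shape = (int(round(image.shape[0] * factors[0])),
                 int(round(image.shape[1] * factors[1])))
    if out_shape[0] < 1 or out_shape[1] < 1:
        raise ValueError("resampling collapses the image to zero size")
    img = ndimage.zoom(image.pixels, factors, order=1, mode="nearest",
                       grid_mode=True)
    msk = ndimage.zoom(mask.pixels.astype(np.float64), factors, order=0,
                       mode="nearest", grid_mode=True) > 0.5
    return (Radiograph(img, (target_mm, target_mm), image.laterality),
            PatellaMask(msk))


def normalize_patella(image: Radiograph, bbox: BoundingBox,
                      clip_sd: float = 6.0) -> Radiograph:
    """Z-score the whole image by patella-bbox statistics; clip at +-clip_sd."""
    if (bbox.row_min < 0 or bbox.col_min < 0 or bbox.row_max > image.shape[0]
            or bbox.col_max > image.shape[1]):
        raise ValueError("bounding box exceeds image bounds")
    region = image.pixels[bbox.slices()]
    mu = float(region.mean())
    sd = float(region.std())
    if sd == 0.0:
        raise ValueError("degenerate patella region: zero standard deviation")
    z = np.clip((image.pixels - mu) / sd, -clip_sd, clip_sd)
    return Radiograph(z, image.spacing_mm, image.laterality)


def quantize(values: np.ndarray, n_bins: int = 32) -> np.ndarray:
    """Fixed-bin-number discretization to integer levels 1..n_bins.

    level(x) = min(n_bins, 1 + floor(n_bins * (x - min) / (max - min))),
    with min/max taken over ``values`` themselves.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    values = np.asarray(values, dtype=np.float64)
    lo = values.min()
    hi = values.max()
    if hi <= lo:
        raise ValueError("cannot discretize a constant region")
    levels = 1 + np.floor(n_bins * (values - lo) / (hi - lo)).astype(np.int64)
    return np.minimum(levels, n_bins)


def discretize(image: Radiograph, bbox: BoundingBox, n_bins: int = 32) -> np.ndarray:
    """Discretize the pixels inside ``bbox`` to levels 1..n_bins."""
    return quantize(image.pixels[bbox.slices()], n_bins)


def make_rois(bbox: BoundingBox, laterality: str = "left",
              image_shape: tuple[int, int] | None = None) -> ROISet:
    """Build the three PF-joint ROIs from the patella bounding box.

    The posterior one-third vertical strip of the bbox (the third closest to
    the trochlea) is split into three equal-height parts and each part is
    extended posteriorly by twice the strip width, so every ROI is exactly
    bbox-width wide and floor(bbox-height/3) tall.  Column remainders join
    the posterior extension; row remainders fall off the superior end so the
    stack stays anchored to the inferior bbox edge.  For a left knee the
    posterior direction is toward higher column indices; a right knee
    mirrors it.
    """
    W = bbox.width
    H = bbox.height
    w3 = W // 3
    h3 = H // 3
    if w3 < 1 or h3 < 1:
        raise ValueError("patella bounding box too small to build ROIs")

    if laterality == "left":
        c0 = bbox.col_max - w3        # anterior edge of the posterior strip
        c1 = c0 + W                   # strip + posterior extension (+ remainder)
    elif laterality == "right":
        c1 = bbox.col_min + w3
        c0 = c1 - W
    else:
        raise ValueError(f"unknown laterality {laterality!r}")

    r_bottom = bbox.row_max
    r_top = r_bottom - 3 * h3
    rows = [(r_top, r_top + h3), (r_top + h3, r_top + 2 * h3),
            (r_top + 2 * h3, r_bottom)]

    if image_shape is not None:
        nr, nc = image_shape
        if c0 < 0 or c1 > nc or r_top < 0 or r_bottom > nr:
            raise ValueError(
                "ROI posterior extension exceeds image bounds; pad the image "
                f"(needs rows [{r_top},{r_bottom}) cols [{c0},{c1}) "
                f"inside {image_shape})")

    sup, mid, inf = (BoundingBox(a, b, c0, c1) for a, b in rows)
    return ROISet(sup, mid, inf)
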