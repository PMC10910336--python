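"""Filtered-image bank for advanced radiomic feature extraction.

Ten image types share one pixel grid: the original (normalized) image, the
four sub-bands of a single-level undecimated Coiflet-1 wavelet transform,
a Laplacian-of-Gaussian response at sigma = 1 mm, and four monotone
intensity transforms (square, square root, logarithm, exponential).  The
undecimated transform keeps every filtered image congruent with the input
so the ROI boxes are reusable across the whole stack.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

from .imageprep import Radiograph

IMAGE_TYPES: tuple[str, ...] = (
    "original",
    "wavelet-LL", "wavelet-LH", "wavelet-HL", "wavelet-HH",
    "log-sigma-1mm",
    "square", "squareroot", "logarithm", "exponential",
)

_WAVELET = "coif1"
_PAD = 8  # >= coif1 support; also makes padded dims even for swt2


def _swt_subbands(image: np.ndarray) -> dict[str, np.ndarray]:
    """Single-level stationary wavelet transform with mirror boundaries.

    pywt's SWT only offers periodic extension, so the image is mirror-padded
    by the filter support first and the sub-bands cropped back, which
    realises symmetric boundary handling.
    """
    nr, nc = image.shape
    pad_r = _PAD + ((nr + 2 * _PAD) % 2)
    pad_c = _PAD + ((nc + 2 * _PAD) % 2)
    padded = np.pad(image, ((_PAD, pad_r), (_PAD, pad_c)), mode="symmetric")
    (ll, (lh, hl, hh)), = pywt.swt2(padded, _WAVELET, level=1,
                                    start_level=0, norm=False)
    crop = (slice(_PAD, _PAD + nr), slice(_PAD, _PAD + nc))
    return {"wavelet-LL": ll[crop], "wavelet-LH": lh[crop],
            "wavelet-HL": hl[crop], "wavelet-HH": hh[crop]}


def log_filter(image: np.ndarray, spacing_mm: float, sigma_mm: float = 1.0) -> np.ndarray:
    """Laplacian-of-Gaussian response, sigma given in millimetres."""
    sigma_px = sigma_mm / spacing_mm
    # truncate=8: the default 4-sigma kernel keeps a ~1e-4 DC residual
    # (its weights do not sum exactly to zero), visible on smooth regions
    return ndimage.gaussian_laplace(image, sigma=sigma_px, mode="mirror",
                                    truncate=8.0)


def intensity_transforms(image: np.ndarray) -> dict[str, np.ndarray]:
    """Monotone intensity transforms of the (possibly negative) image.

    The image is first shifted to be non-negative, xh = x - min(x) with
    range R = max(xh).  Scaling constants keep each output on [0, R]:

        square      = (xh / sqrt(R))**2
        squareroot  = sqrt(R) * sqrt(xh)
        logarithm   = R * log1p(xh) / log1p(R)
        exponential = expm1(xh * log1p(R) / R)   (range [0, R] exactly)

    A constant input (R = 0) passes through unchanged.
    """
    xh = image - image.min()
    R = float(xh.max())
    if R == 0.0:
        return {k: image.copy() for k in
                ("square", "squareroot", "logarithm", "exponential")}
    return {
        "square": (xh / np.sqrt(R)) ** 2,
        "squareroot": np.sqrt(R) * np.sqrt(xh),
        "logarithm": R * np.log1p(xh) / np.log1p(R),
        "exponential": np.expm1(xh * (np.log1p(R) / R)),
    }


def dump_stack(stack: dict[str, np.ndarray], out_dir, spacing_mm: float = 0.5
               ) -> None:
    """Debug dump of each filtered image as 32-bit float NIfTI-1."""
    from pathlib import Path

    import nibabel as nib
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag([spacing_mm, spacing_mm, 1.0, 1.0])
    for name, grid in stack.items():
        nib.save(nib.Nifti1Image(grid.astype(np.float32).T, affine),
                 str(out / f"{name}.nii.gz"))


def apply_filter_bank(image: Radiograph) -> dict[str, np.ndarray]:
    """Compute the 10-image stack for one radiograph.

    Returns a dict keyed by the labels in ``IMAGE_TYPES`` (insertion order
    matches); all grids share the input shape.
    """
    px = image.pixels
    if not np.all(np.isfinite(px)):
        raise ValueError("input image contains non-finite values")
    stack: dict[str, np.ndarray] = {"original": px.copy()}
    stack.update(_swt_subbands(px))
    stack["log-sigma-1mm"] = log_filter(px, spacing_mm=float(image.spacing_mm[0]))
    stack.update(intensity_transforms(px))
    for name in IMAGE_TYPES:
        if not np.all(np.isfinite(stack[name])):
            raise ValueError(f"filter {name!r} produced non-finite values")
    return {name: stack[name] for name in IMAGE_TYPES}
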