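"""First-order and texture radiomic features (native implementation).

Each image type contributes 93 features: 18 first-order intensity
statistics plus 24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM and 5 NGTDM texture
features, following the standard (IBSI-style) definitions.  Texture
matrices are built on the ROI discretized to 32 gray levels with
fixed-bin-number quantisation computed per ROI, so every ROI uses its full
1..32 range on every image type.  Ten image types x 93 features = 930
features per ROI.

Conventions (documented, deliberate):

* GLCM/GLRLM use distance 1 and the four 2D directions (0/45/90/135 deg);
  features are computed per direction and averaged.
* GLSZM zones and GLDM/NGTDM neighbourhoods use 8-connectivity.
* GLDM dependence size = 1 + number of neighbours whose level differs by
  at most alpha (alpha = 0), so sizes start at 1.
* Entropies use log base 2; 0 log 0 = 0.
* Degenerate single-level regions (only reachable with
  ``allow_constant=True``) use: skewness = kurtosis = 0, GLCM
  correlation = 1, IMC1 = IMC2 = 0, MCC = 1, NGTDM contrast = 0.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import ndimage

from .filterbank import IMAGE_TYPES
from .imageprep import BoundingBox, quantize

N_BINS_DEFAULT = 32

# distance-1 offsets for 0, 45, 90, 135 degrees in (row, col) coordinates
_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

_EIGHT_CONN = np.ones((3, 3), dtype=bool)

FIRST_ORDER_NAMES = (
    "energy", "total_energy", "entropy", "minimum", "percentile10",
    "percentile90", "maximum", "mean", "median", "interquartile_range",
    "range", "mean_absolute_deviation", "robust_mean_absolute_deviation",
    "root_mean_squared", "skewness", "kurtosis", "variance", "uniformity",
)
GLCM_NAMES = (
    "autocorrelation", "joint_average", "cluster_prominence", "cluster_shade",
    "cluster_tendency", "contrast", "correlation", "difference_average",
    "difference_entropy", "difference_variance", "joint_energy",
    "joint_entropy", "imc1", "imc2", "idm", "idmn", "id", "idn",
    "inverse_variance", "maximum_probability", "sum_average", "sum_entropy",
    "sum_squares", "mcc",
)
GLRLM_NAMES = (
    "short_run_emphasis", "long_run_emphasis", "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized", "run_length_nonuniformity",
    "run_length_nonuniformity_normalized", "run_percentage",
    "gray_level_variance", "run_variance", "run_entropy",
    "low_gray_level_run_emphasis", "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis", "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis", "long_run_high_gray_level_emphasis",
)
GLSZM_NAMES = (
    "small_area_emphasis", "large_area_emphasis", "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized", "size_zone_nonuniformity",
    "size_zone_nonuniformity_normalized", "zone_percentage",
    "gray_level_variance", "zone_variance", "zone_entropy",
    "low_gray_level_zone_emphasis", "high_gray_level_zone_emphasis",
    "small_area_low_gray_level_emphasis", "small_area_high_gray_level_emphasis",
    "large_area_low_gray_level_emphasis", "large_area_high_gray_level_emphasis",
)
GLDM_NAMES = (
    "small_dependence_emphasis", "large_dependence_emphasis",
    "gray_level_nonuniformity", "dependence_nonuniformity",
    "dependence_nonuniformity_normalized", "gray_level_variance",
    "dependence_variance", "dependence_entropy", "low_gray_level_emphasis",
    "high_gray_level_emphasis", "small_dependence_low_gray_level_emphasis",
    "small_dependence_high_gray_level_emphasis",
    "large_dependence_low_gray_level_emphasis",
    "large_dependence_high_gray_level_emphasis",
)
NGTDM_NAMES = ("coarseness", "contrast", "busyness", "complexity", "strength")

FAMILIES = (
    ("firstorder", FIRST_ORDER_NAMES),
    ("glcm", GLCM_NAMES),
    ("glrlm", GLRLM_NAMES),
    ("glszm", GLSZM_NAMES),
    ("gldm", GLDM_NAMES),
    ("ngtdm", NGTDM_NAMES),
)

N_FEATURES_PER_IMAGE_TYPE = sum(len(names) for _, names in FAMILIES)  # 93
N_FEATURES_PER_ROI = N_FEATURES_PER_IMAGE_TYPE * len(IMAGE_TYPES)     # 930


def feature_names() -> list[str]:
    """The 930 feature names in extraction order: <imagetype>__<family>__<feature>."""
    return [f"{t}__{fam}__{name}"
            for t in IMAGE_TYPES for fam, names in FAMILIES for name in names]


def feature_dictionary() -> dict[str, dict[str, str]]:
    """name -> {image_type, family, feature} for all 930 features."""
    return {f"{t}__{fam}__{name}":
            {"image_type": t, "family": fam, "feature": name}
            for t in IMAGE_TYPES for fam, names in FAMILIES for name in names}


def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p, dtype=np.float64)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


# --------------------------------------------------------------------------
# first order
# --------------------------------------------------------------------------

def _percentiles_sorted(xs: np.ndarray, qs) -> list[float]:
    """Linear-interpolation percentiles of an already sorted array."""
    n = xs.size
    out = []
    for q in qs:
        h = (n - 1) * (q / 100.0)
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        out.append(float(xs[lo] + (h - lo) * (xs[hi] - xs[lo])))
    return out


def first_order_features(values: np.ndarray, pixel_area_mm2: float = 0.25,
                         n_bins: int = N_BINS_DEFAULT) -> dict[str, float]:
    """The 18 first-order intensity features of a flat value array.

    Entropy and uniformity are computed on the ``n_bins`` fixed-bin-number
    histogram of the values; everything else on the raw values.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 values for first-order features")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in first-order input")
    n = x.size
    mean = x.mean()
    dev = x - mean
    m2 = np.mean(dev ** 2)
    if m2 > 0:
        skew = np.mean(dev ** 3) / m2 ** 1.5
        kurt = np.mean(dev ** 4) / m2 ** 2       # Pearson (non-excess)
    else:
        skew = 0.0
        kurt = 0.0
    xs = np.sort(x)
    p10, p25, p50, p75, p90 = _percentiles_sorted(xs, (10.0, 25.0, 50.0, 75.0, 90.0))
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    if x.max() > x.min():
        hist = np.bincount(quantize(x, n_bins), minlength=n_bins + 1)[1:]
    else:
        hist = np.zeros(n_bins, dtype=np.int64)
        hist[0] = n
    p = hist / n
    energy = float(np.sum(x ** 2))
    return {
        "energy": energy,
        "total_energy": energy * pixel_area_mm2,
        "entropy": float(-_xlog2x(p).sum()),
        "minimum": float(x.min()),
        "percentile10": float(p10),
        "percentile90": float(p90),
        "maximum": float(x.max()),
        "mean": float(mean),
        "median": float(p50),
        "interquartile_range": float(p75 - p25),
        "range": float(x.max() - x.min()),
        "mean_absolute_deviation": float(np.abs(dev).mean()),
        "robust_mean_absolute_deviation": rmad,
        "root_mean_squared": float(np.sqrt(np.mean(x ** 2))),
        "skewness": float(skew),
        "kurtosis": float(kurt),
        "variance": float(m2),
        "uniformity": float(np.sum(p ** 2)),
    }


# --------------------------------------------------------------------------
# GLCM
# --------------------------------------------------------------------------

def _offset_pairs(levels: np.ndarray, dr: int, dc: int):
    nr, nc = levels.shape
    r0, r1 = max(0, -dr), nr - max(0, dr)
    c0, c1 = max(0, -dc), nc - max(0, dc)
    a = levels[r0:r1, c0:c1].ravel()
    b = levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    return a, b


def glcm(levels: np.ndarray, n_levels: int = N_BINS_DEFAULT,
         offsets=_OFFSETS) -> list[np.ndarray]:
    """Symmetric, normalized co-occurrence matrix per direction."""
    mats = []
    for dr, dc in offsets:
        a, b = _offset_pairs(levels, dr, dc)
        counts = np.bincount((a - 1) * n_levels + (b - 1),
                             minlength=n_levels * n_levels
                             ).reshape(n_levels, n_levels).astype(np.float64)
        counts = counts + counts.T
        total = counts.sum()
        if total == 0:
            raise ValueError("no pixel pairs for GLCM direction")
        mats.append(counts / total)
    return mats


@lru_cache(maxsize=4)
def _glcm_grids(Ng: int):
    i = np.arange(1, Ng + 1, dtype=np.float64)
    ii = i[:, None]
    jj = i[None, :]
    dsq = (ii - jj) ** 2
    absd = np.abs(ii - jj)
    # weighted sums evaluated as one matrix product: rows are flat weights
    with np.errstate(divide="ignore"):
        inv_dsq = np.where(dsq > 0, 1.0 / np.where(dsq > 0, dsq, 1.0), 0.0)
    weights = np.stack([
        (ii * jj).ravel(),                  # autocorrelation
        (1.0 / (1.0 + dsq)).ravel(),        # idm
        (1.0 / (1.0 + dsq / Ng ** 2)).ravel(),   # idmn
        (1.0 / (1.0 + absd)).ravel(),       # id
        (1.0 / (1.0 + absd / Ng)).ravel(),  # idn
        inv_dsq.ravel(),                    # inverse variance
    ])
    # aggregation maps onto the sum (k = i+j, 2..2Ng) and difference
    # (k = |i-j|, 0..Ng-1) marginals
    agg_sum = np.zeros((2 * Ng - 1, Ng * Ng))
    agg_diff = np.zeros((Ng, Ng * Ng))
    flat = np.arange(Ng * Ng)
    agg_sum[(ii + jj).astype(np.int64).ravel() - 2, flat] = 1.0
    agg_diff[absd.astype(np.int64).ravel(), flat] = 1.0
    return i, weights, agg_sum, agg_diff


def glcm_features(matrices: list[np.ndarray]) -> dict[str, float]:
    """Per-direction features averaged over directions.

    The four direction matrices are stacked and every formula is evaluated
    batched.  Because each matrix is symmetric, the marginals satisfy
    px = py, the cross entropies collapse to HXY1 = HXY2 = 2*HX, and all
    (i+j)/(i-j) statistics reduce to moments of the sum/difference
    marginals, so only a handful of full-matrix reductions remain.
    """
    P = np.stack(matrices)                    # (A, Ng, Ng)
    A, Ng, _ = P.shape
    i, weights, agg_sum, agg_diff = _glcm_grids(Ng)
    Pf = P.reshape(A, Ng * Ng)
    px = P.sum(axis=2)                        # (A, Ng); == py by symmetry
    mu_x = px @ i                             # (A,)
    sig2_x = (px @ i ** 2) - mu_x ** 2

    wsum = Pf @ weights.T                     # (A, 6)
    autocorr = wsum[:, 0]
    pxy_sum = Pf @ agg_sum.T                  # (A, 2Ng-1), k = 2..2Ng
    pxy_diff = Pf @ agg_diff.T                # (A, Ng),    k = 0..Ng-1
    k_sum = np.arange(2, 2 * Ng + 1, dtype=np.float64)
    k_diff = np.arange(Ng, dtype=np.float64)

    correlation = np.where(sig2_x > 0,
                           (autocorr - mu_x ** 2) / np.where(sig2_x > 0,
                                                             sig2_x, 1.0),
                           1.0)

    HX = -_xlog2x(px).sum(axis=1)
    HXY = -_xlog2x(Pf).sum(axis=1)
    safe_HX = np.where(HX > 0, HX, 1.0)
    imc1 = np.where(HX > 0, (HXY - 2.0 * HX) / safe_HX, 0.0)
    imc2 = np.where(HX > 0,
                    np.sqrt(np.clip(1.0 - np.exp(-2.0 * (2.0 * HX - HXY)),
                                    0.0, None)),
                    0.0)

    # MCC: second-largest eigenvalue of Q(i,j) = sum_k p(i,k)p(j,k)/(px(i)py(k)).
    # Q is similar to the symmetric PSD matrix G G^T with
    # G = D^-1/2 P D^-1/2 (D = diag(px) = diag(py)), so a symmetric solver
    # applies; absent levels contribute only extra zero eigenvalues.
    sqrt_px = np.sqrt(np.where(px > 0, px, 1.0))
    G = P / sqrt_px[:, :, None] / sqrt_px[:, None, :]
    S = G @ np.swapaxes(G, 1, 2)
    eig = np.linalg.eigvalsh(S)               # ascending
    n_present = (px > 0).sum(axis=1)
    mcc = np.where(n_present > 1, np.sqrt(np.clip(eig[:, -2], 0.0, None)), 1.0)

    # central moments of the sum marginal give the cluster statistics
    da = pxy_diff @ k_diff
    dk_sum = k_sum[None, :] - 2.0 * mu_x[:, None]
    vals = {
        "autocorrelation": autocorr,
        "joint_average": mu_x,
        "cluster_prominence": (pxy_sum * dk_sum ** 4).sum(axis=1),
        "cluster_shade": (pxy_sum * dk_sum ** 3).sum(axis=1),
        "cluster_tendency": (pxy_sum * dk_sum ** 2).sum(axis=1),
        "contrast": pxy_diff @ k_diff ** 2,
        "correlation": correlation,
        "difference_average": da,
        "difference_entropy": -_xlog2x(pxy_diff).sum(axis=1),
        "difference_variance": (pxy_diff @ k_diff ** 2) - da ** 2,
        "joint_energy": (Pf ** 2).sum(axis=1),
        "joint_entropy": HXY,
        "imc1": imc1,
        "imc2": imc2,
        "idm": wsum[:, 1],
        "idmn": wsum[:, 2],
        "id": wsum[:, 3],
        "idn": wsum[:, 4],
        "inverse_variance": wsum[:, 5],
        "maximum_probability": Pf.max(axis=1),
        "sum_average": pxy_sum @ k_sum,
        "sum_entropy": -_xlog2x(pxy_sum).sum(axis=1),
        "sum_squares": sig2_x,
        "mcc": mcc,
    }
    stacked = np.stack([np.broadcast_to(vals[name], (A,))
                        for name in GLCM_NAMES]).mean(axis=1)
    return dict(zip(GLCM_NAMES, stacked.tolist()))


# --------------------------------------------------------------------------
# GLRLM
# --------------------------------------------------------------------------

def _direction_lines(levels: np.ndarray, dr: int, dc: int) -> list[np.ndarray]:
    if (dr, dc) == (0, 1):
        return list(levels)
    if (dr, dc) == (-1, 0):
        return list(levels.T)
    nr, nc = levels.shape
    base = np.fliplr(levels) if (dr, dc) == (-1, 1) else levels
    return [np.diagonal(base, k) for k in range(-(nr - 1), nc)]


@lru_cache(maxsize=16)
def _line_gather(shape: tuple[int, int], dr: int, dc: int):
    """Flat gather indices walking every line of a given direction, with -1
    marking the separator slots between lines (cached per ROI shape)."""
    idx = np.arange(shape[0] * shape[1]).reshape(shape)
    parts = []
    for ln in _direction_lines(idx, dr, dc):
        parts.append(np.asarray(ln))
        parts.append(np.array([-1]))
    return np.concatenate(parts)


def _run_encode(arr: np.ndarray):
    """Runs of a 1D array where 0 separates lines; returns (levels, lengths)."""
    brk = np.flatnonzero(np.diff(arr) != 0)
    starts = np.r_[0, brk + 1]
    ends = np.r_[brk, arr.size - 1]
    vals = arr[starts]
    lens = ends - starts + 1
    keep = vals > 0
    return vals[keep], lens[keep]


def glrlm(levels: np.ndarray, n_levels: int = N_BINS_DEFAULT,
          offsets=_OFFSETS) -> list[np.ndarray]:
    """Run-length count matrix (Ng x Rmax) per direction."""
    mats = []
    rmax = max(levels.shape)
    flat = np.r_[levels.ravel(), 0]          # index -1 lands on the separator
    for dr, dc in offsets:
        vals, lens = _run_encode(flat[_line_gather(levels.shape, dr, dc)])
        mat = np.zeros((n_levels, rmax), dtype=np.float64)
        np.add.at(mat, (vals - 1, lens - 1), 1.0)
        mats.append(mat)
    return mats


@lru_cache(maxsize=32)
def _size_grids(Ng: int, Smax: int):
    i = np.arange(1, Ng + 1, dtype=np.float64)
    sz = np.arange(1, Smax + 1, dtype=np.float64)
    return i, sz, i ** 2, 1.0 / i ** 2, sz ** 2, 1.0 / sz ** 2


def _size_family_features(P: np.ndarray, n_pixels: int,
                          names: tuple[str, ...]) -> dict[str, float]:
    """Shared GLRLM/GLSZM feature formulas over (level x size) count
    matrices; both families divide the run/zone count by the pixel count
    for the percentage feature.  ``P`` may be a single matrix or a stack
    of per-direction matrices (batched; features averaged at the end).
    Every product weight factorises as f(level) * g(size), so the sums are
    marginal contractions."""
    if P.ndim == 2:
        P = P[None]
    A, Ng, Smax = P.shape
    i, sz, i2, inv_i2, s2, inv_s2 = _size_grids(Ng, Smax)
    Nz = P.sum(axis=(1, 2))
    if np.any(Nz == 0):
        raise ValueError("empty size matrix")
    g_marg = P.sum(axis=2)                    # (A, Ng)
    s_marg = P.sum(axis=1)                    # (A, Smax)
    t_inv_s = P @ inv_s2                      # (A, Ng): sum_s P / s^2
    t_s = P @ s2                              # (A, Ng): sum_s P s^2
    mu_i = (g_marg @ i) / Nz
    mu_s = (s_marg @ sz) / Nz
    vals = {
        names[0]: t_inv_s.sum(axis=1) / Nz,
        names[1]: t_s.sum(axis=1) / Nz,
        names[2]: (g_marg ** 2).sum(axis=1) / Nz,
        names[3]: (g_marg ** 2).sum(axis=1) / Nz ** 2,
        names[4]: (s_marg ** 2).sum(axis=1) / Nz,
        names[5]: (s_marg ** 2).sum(axis=1) / Nz ** 2,
        names[6]: Nz / n_pixels,
        names[7]: (g_marg @ i2) / Nz - mu_i ** 2,
        names[8]: (s_marg @ s2) / Nz - mu_s ** 2,
        names[9]: -_xlog2x(P.reshape(A, -1) / Nz[:, None]).sum(axis=1),
        names[10]: (g_marg @ inv_i2) / Nz,
        names[11]: (g_marg @ i2) / Nz,
        names[12]: (t_inv_s @ inv_i2) / Nz,
        names[13]: (t_inv_s @ i2) / Nz,
        names[14]: (t_s @ inv_i2) / Nz,
        names[15]: (t_s @ i2) / Nz,
    }
    stacked = np.stack([vals[k] for k in names]).mean(axis=1)
    return dict(zip(names, stacked.tolist()))


def glrlm_features(matrices: list[np.ndarray], n_pixels: int) -> dict[str, float]:
    return _size_family_features(np.stack(matrices), n_pixels, GLRLM_NAMES)


# --------------------------------------------------------------------------
# GLSZM
# --------------------------------------------------------------------------

_SLAB_CONN = np.zeros((3, 3, 3), dtype=bool)
_SLAB_CONN[1] = True                       # 8-connectivity within a slab only


def glszm(levels: np.ndarray, n_levels: int = N_BINS_DEFAULT) -> np.ndarray:
    """Zone-size count matrix (Ng x Smax); zones are 8-connected.

    Zones of every gray level are found with one labelling pass: each level
    occupies its own slab of a boolean volume and the structuring element
    does not connect across slabs.
    """
    vol = levels[None, :, :] == np.arange(1, n_levels + 1)[:, None, None]
    lab, n_zones = ndimage.label(vol, structure=_SLAB_CONN)
    if n_zones == 0:
        raise ValueError("no zones in level grid")
    sizes = np.bincount(lab.ravel())[1:]
    lv_vox = np.nonzero(vol)[0] + 1
    lev_of_zone = np.zeros(n_zones + 1, dtype=np.int64)
    lev_of_zone[lab[vol]] = lv_vox
    mat = np.zeros((n_levels, int(sizes.max())), dtype=np.float64)
    np.add.at(mat, (lev_of_zone[1:] - 1, sizes - 1), 1.0)
    return mat


def glszm_features(matrix: np.ndarray, n_pixels: int) -> dict[str, float]:
    return _size_family_features(matrix, n_pixels, GLSZM_NAMES)


# --------------------------------------------------------------------------
# GLDM
# --------------------------------------------------------------------------

def gldm(levels: np.ndarray, n_levels: int = N_BINS_DEFAULT,
         alpha: int = 0) -> np.ndarray:
    """Dependence count matrix (Ng x 9): size = 1 + #{8-neighbours with
    |level difference| <= alpha}; neighbours outside the ROI do not count."""
    nr, nc = levels.shape
    padded = np.full((nr + 2, nc + 2), -10 ** 6, dtype=np.int64)
    padded[1:-1, 1:-1] = levels
    cnt = np.zeros((nr, nc), dtype=np.int64)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nb = padded[1 + dr:1 + dr + nr, 1 + dc:1 + dc + nc]
            cnt += np.abs(nb - levels) <= alpha
    dep = cnt + 1                       # sizes 1..9
    mat = np.zeros((n_levels, 9), dtype=np.float64)
    np.add.at(mat, (levels.ravel() - 1, dep.ravel() - 1), 1.0)
    return mat


def gldm_features(matrix: np.ndarray) -> dict[str, float]:
    P = matrix
    Ng, Nd = P.shape
    i = np.arange(1, Ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, Nd + 1, dtype=np.float64)[None, :]
    Nz = P.sum()
    g_marg = P.sum(axis=1)
    d_marg = P.sum(axis=0)
    p = P / Nz
    mu_i = (i * p).sum()
    mu_j = (j * p).sum()
    vals = {
        "small_dependence_emphasis": (P / j ** 2).sum() / Nz,
        "large_dependence_emphasis": (P * j ** 2).sum() / Nz,
        "gray_level_nonuniformity": (g_marg ** 2).sum() / Nz,
        "dependence_nonuniformity": (d_marg ** 2).sum() / Nz,
        "dependence_nonuniformity_normalized": (d_marg ** 2).sum() / Nz ** 2,
        "gray_level_variance": ((i - mu_i) ** 2 * p).sum(),
        "dependence_variance": ((j - mu_j) ** 2 * p).sum(),
        "dependence_entropy": -_xlog2x(p).sum(),
        "low_gray_level_emphasis": (P / i ** 2).sum() / Nz,
        "high_gray_level_emphasis": (P * i ** 2).sum() / Nz,
        "small_dependence_low_gray_level_emphasis":
            (P / (i ** 2 * j ** 2)).sum() / Nz,
        "small_dependence_high_gray_level_emphasis":
            (P * i ** 2 / j ** 2).sum() / Nz,
        "large_dependence_low_gray_level_emphasis":
            (P * j ** 2 / i ** 2).sum() / Nz,
        "large_dependence_high_gray_level_emphasis":
            (P * i ** 2 * j ** 2).sum() / Nz,
    }
    return {k: float(v) for k, v in vals.items()}


# --------------------------------------------------------------------------
# NGTDM
# --------------------------------------------------------------------------

def ngtdm(levels: np.ndarray, n_levels: int = N_BINS_DEFAULT
          ) -> tuple[np.ndarray, np.ndarray]:
    """Neighbourhood gray-tone difference table: (n_i counts, s_i sums).

    For every pixel, A is the mean level of its available 8-neighbours;
    s_i accumulates |level - A| over pixels of level i.
    """
    kernel = np.ones((3, 3), dtype=np.float64)
    kernel[1, 1] = 0.0
    nb_sum = ndimage.convolve(levels.astype(np.float64), kernel,
                              mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(np.ones_like(levels, dtype=np.float64), kernel,
                              mode="constant", cval=0.0)
    A = nb_sum / nb_cnt
    diff = np.abs(levels - A)
    n_i = np.bincount(levels.ravel() - 1, minlength=n_levels).astype(np.float64)
    s_i = np.bincount(levels.ravel() - 1, weights=diff.ravel(),
                      minlength=n_levels)
    return n_i, s_i


def ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    Nvp = n_i.sum()
    p_i = n_i / Nvp
    present = p_i > 0
    Ngp = int(present.sum())
    lv = np.arange(1, n_i.size + 1, dtype=np.float64)

    denom_coarse = float((p_i * s_i).sum())
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else 1e6

    if Ngp > 1:
        ip = lv[present]
        pp = p_i[present]
        sp = s_i[present]
        di = ip[:, None] - ip[None, :]
        contrast = (float((pp[:, None] * pp[None, :] * di ** 2).sum())
                    / (Ngp * (Ngp - 1))) * float(s_i.sum()) / Nvp
        busy_den = float(np.abs(ip[:, None] * pp[:, None]
                                - ip[None, :] * pp[None, :]).sum())
        busyness = denom_coarse / busy_den if busy_den > 0 else 0.0
        complexity = float((np.abs(di)
                            * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
                            / (pp[:, None] + pp[None, :])).sum()) / Nvp
        s_total = float(s_i.sum())
        strength = (float(((pp[:, None] + pp[None, :]) * di ** 2).sum())
                    / s_total) if s_total > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "coarseness": float(coarseness),
        "contrast": float(contrast),
        "busyness": float(busyness),
        "complexity": float(complexity),
        "strength": float(strength),
    }


# --------------------------------------------------------------------------
# full extraction
# --------------------------------------------------------------------------

def extract_image_type(values: np.ndarray, pixel_area_mm2: float,
                       n_bins: int = N_BINS_DEFAULT,
                       allow_constant: bool = False) -> dict[str, float]:
    """All 93 features of one image type's ROI (2D value grid)."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise ValueError("ROI values must be 2D")
    n_pixels = values.size
    if values.max() > values.min():
        levels = quantize(values, n_bins)
    elif allow_constant:
        levels = np.ones(values.shape, dtype=np.int64)
    else:
        raise ValueError("constant ROI")
    out: dict[str, float] = {}
    fo = first_order_features(values, pixel_area_mm2, n_bins)
    out.update({f"firstorder__{k}": v for k, v in fo.items()})
    out.update({f"glcm__{k}": v
                for k, v in glcm_features(glcm(levels, n_bins)).items()})
    out.update({f"glrlm__{k}": v
                for k, v in glrlm_features(glrlm(levels, n_bins), n_pixels).items()})
    out.update({f"glszm__{k}": v
                for k, v in glszm_features(glszm(levels, n_bins), n_pixels).items()})
    out.update({f"gldm__{k}": v
                for k, v in gldm_features(gldm(levels, n_bins)).items()})
    out.update({f"ngtdm__{k}": v
                for k, v in ngtdm_features(*ngtdm(levels, n_bins)).items()})
    return out


def extract_all(stack: dict[str, np.ndarray], roi: BoundingBox,
                spacing_mm: float = 0.5, n_bins: int = N_BINS_DEFAULT,
                allow_constant: bool = False) -> dict[str, float]:
    """The 930-entry feature vector of one ROI over the 10-image stack.

    Every pixel inside the rectangular ROI is used (the ROI, not the patella
    mask, is the analysis region); each image type is discretized
    independently on its own ROI min/max.
    """
    pixel_area = spacing_mm * spacing_mm
    sl = roi.slices()
    vec: dict[str, float] = {}
    for name in IMAGE_TYPES:
        grid = stack[name]
        if (roi.row_min < 0 or roi.col_min < 0 or roi.row_max > grid.shape[0]
                or roi.col_max > grid.shape[1]):
            raise ValueError(f"ROI exceeds bounds of image type {name!r}")
        try:
            feats = extract_image_type(grid[sl], pixel_area, n_bins,
                                       allow_constant)
        except ValueError as exc:
            raise ValueError(f"image type {name!r}: {exc}") from exc
        vec.update({f"{name}__{k}": v for k, v in feats.items()})
    if len(vec) != N_FEATURES_PER_ROI:
        raise AssertionError("feature vector has unexpected length")
    return vec
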