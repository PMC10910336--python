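"""Independent literal-formula reference implementation of every feature.

This is a deliberately naive second code path used only by the tests: all
texture matrices are accumulated with explicit Python loops and every
feature is a direct transcription of its defining formula.  It shares no
code with the package implementation (only numpy primitives and the
eigenvalue solver for MCC).  Conventions mirror the documented ones:
distance-1 directions 0/45/90/135, per-direction features averaged,
8-connected zones/neighbourhoods, GLDM dependence size = 1 + count,
log base 2, fixed-bin-number discretization with per-region min/max.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]


def ref_quantize(values, n_bins=32):
    lo = float(np.min(values))
    hi = float(np.max(values))
    out = np.zeros(np.shape(values), dtype=int)
    arr = np.asarray(values, dtype=float)
    for r in range(arr.shape[0]):
        for c in range(arr.shape[1]):
            lvl = 1 + math.floor(n_bins * (arr[r, c] - lo) / (hi - lo))
            out[r, c] = min(n_bins, lvl)
    return out


def _percentile(sorted_vals, q):
    n = len(sorted_vals)
    h = (n - 1) * q / 100.0
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])


def ref_first_order(values, pixel_area_mm2, n_bins=32):
    x = sorted(float(v) for v in np.asarray(values).ravel())
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    skew = m3 / m2 ** 1.5 if m2 > 0 else 0.0
    kurt = m4 / m2 ** 2 if m2 > 0 else 0.0
    p10 = _percentile(x, 10)
    p90 = _percentile(x, 90)
    robust = [v for v in x if p10 <= v <= p90]
    rmean = sum(robust) / len(robust)
    rmad = sum(abs(v - rmean) for v in robust) / len(robust)
    lo, hi = x[0], x[-1]
    counts = [0] * n_bins
    for v in x:
        if hi > lo:
            lvl = min(n_bins, 1 + math.floor(n_bins * (v - lo) / (hi - lo)))
        else:
            lvl = 1
        counts[lvl - 1] += 1
    probs = [c / n for c in counts]
    entropy = -sum(p * math.log2(p) for p in probs if p > 0)
    energy = sum(v * v for v in x)
    return {
        "energy": energy,
        "total_energy": energy * pixel_area_mm2,
        "entropy": entropy,
        "minimum": lo,
        "percentile10": p10,
        "percentile90": p90,
        "maximum": hi,
        "mean": mean,
        "median": _percentile(x, 50),
        "interquartile_range": _percentile(x, 75) - _percentile(x, 25),
        "range": hi - lo,
        "mean_absolute_deviation": sum(abs(v - mean) for v in x) / n,
        "robust_mean_absolute_deviation": rmad,
        "root_mean_squared": math.sqrt(energy / n),
        "skewness": skew,
        "kurtosis": kurt,
        "variance": m2,
        "uniformity": sum(p * p for p in probs),
    }


# --------------------------------------------------------------------------
# GLCM
# --------------------------------------------------------------------------

def ref_glcm_matrix(levels, dr, dc, n_levels=32):
    nr, nc = levels.shape
    P = np.zeros((n_levels, n_levels))
    for r in range(nr):
        for c in range(nc):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nr and 0 <= c2 < nc:
                a, b = levels[r, c] - 1, levels[r2, c2] - 1
                P[a, b] += 1
                P[b, a] += 1          # symmetric accumulation
    return P / P.sum()


def ref_glcm_features_single(P):
    Ng = P.shape[0]
    px = [sum(P[i, j] for j in range(Ng)) for i in range(Ng)]
    py = [sum(P[i, j] for i in range(Ng)) for j in range(Ng)]
    mu_x = sum((i + 1) * px[i] for i in range(Ng))
    mu_y = sum((j + 1) * py[j] for j in range(Ng))
    sig_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(Ng)))
    sig_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(Ng)))

    p_sum = [0.0] * (2 * Ng + 1)      # index k = i+j (2..2Ng)
    p_diff = [0.0] * Ng               # index k = |i-j| (0..Ng-1)
    for i in range(Ng):
        for j in range(Ng):
            p_sum[(i + 1) + (j + 1)] += P[i, j]
            p_diff[abs(i - j)] += P[i, j]

    autoc = sum((i + 1) * (j + 1) * P[i, j]
                for i in range(Ng) for j in range(Ng))
    contrast = sum((i - j) ** 2 * P[i, j]
                   for i in range(Ng) for j in range(Ng))
    if sig_x > 0 and sig_y > 0:
        correlation = (autoc - mu_x * mu_y) / (sig_x * sig_y)
    else:
        correlation = 1.0
    da = sum(k * p_diff[k] for k in range(Ng))
    dvar = sum((k - da) ** 2 * p_diff[k] for k in range(Ng))
    dent = -sum(p * math.log2(p) for p in p_diff if p > 0)
    HX = -sum(p * math.log2(p) for p in px if p > 0)
    HY = -sum(p * math.log2(p) for p in py if p > 0)
    HXY = -sum(P[i, j] * math.log2(P[i, j])
               for i in range(Ng) for j in range(Ng) if P[i, j] > 0)
    HXY1 = -sum(P[i, j] * math.log2(px[i] * py[j])
                for i in range(Ng) for j in range(Ng)
                if P[i, j] > 0 and px[i] * py[j] > 0)
    HXY2 = -sum(px[i] * py[j] * math.log2(px[i] * py[j])
                for i in range(Ng) for j in range(Ng) if px[i] * py[j] > 0)
    hmax = max(HX, HY)
    imc1 = (HXY - HXY1) / hmax if hmax > 0 else 0.0
    imc2 = (math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (HXY2 - HXY))))
            if hmax > 0 else 0.0)

    present = [i for i in range(Ng) if px[i] > 0]
    if len(present) > 1:
        Q = np.zeros((len(present), len(present)))
        for a, i in enumerate(present):
            for b, j in enumerate(present):
                Q[a, b] = sum(P[i, k] * P[j, k] / (px[i] * py[k])
                              for k in present if py[k] > 0)
        eigs = sorted(np.real(np.linalg.eigvals(Q)))
        mcc = math.sqrt(max(0.0, eigs[-2]))
    else:
        mcc = 1.0

    return {
        "autocorrelation": autoc,
        "joint_average": mu_x,
        "cluster_prominence": sum((i + 1 + j + 1 - mu_x - mu_y) ** 4 * P[i, j]
                                  for i in range(Ng) for j in range(Ng)),
        "cluster_shade": sum((i + 1 + j + 1 - mu_x - mu_y) ** 3 * P[i, j]
                             for i in range(Ng) for j in range(Ng)),
        "cluster_tendency": sum((i + 1 + j + 1 - mu_x - mu_y) ** 2 * P[i, j]
                                for i in range(Ng) for j in range(Ng)),
        "contrast": contrast,
        "correlation": correlation,
        "difference_average": da,
        "difference_entropy": dent,
        "difference_variance": dvar,
        "joint_energy": sum(P[i, j] ** 2
                            for i in range(Ng) for j in range(Ng)),
        "joint_entropy": HXY,
        "imc1": imc1,
        "imc2": imc2,
        "idm": sum(P[i, j] / (1 + (i - j) ** 2)
                   for i in range(Ng) for j in range(Ng)),
        "idmn": sum(P[i, j] / (1 + ((i - j) / Ng) ** 2)
                    for i in range(Ng) for j in range(Ng)),
        "id": sum(P[i, j] / (1 + abs(i - j))
                  for i in range(Ng) for j in range(Ng)),
        "idn": sum(P[i, j] / (1 + abs(i - j) / Ng)
                   for i in range(Ng) for j in range(Ng)),
        "inverse_variance": sum(P[i, j] / (i - j) ** 2
                                for i in range(Ng) for j in range(Ng) if i != j),
        "maximum_probability": max(P[i, j]
                                   for i in range(Ng) for j in range(Ng)),
        "sum_average": sum(k * p_sum[k] for k in range(2, 2 * Ng + 1)),
        "sum_entropy": -sum(p_sum[k] * math.log2(p_sum[k])
                            for k in range(2, 2 * Ng + 1) if p_sum[k] > 0),
        "sum_squares": sum((i + 1 - mu_x) ** 2 * P[i, j]
                           for i in range(Ng) for j in range(Ng)),
        "mcc": mcc,
    }


def ref_glcm_features(levels, n_levels=32):
    per = [ref_glcm_features_single(ref_glcm_matrix(levels, dr, dc, n_levels))
           for dr, dc in OFFSETS]
    return {k: sum(d[k] for d in per) / len(per) for k in per[0]}


# --------------------------------------------------------------------------
# GLRLM
# --------------------------------------------------------------------------

def _lines(levels, dr, dc):
    nr, nc = levels.shape
    if (dr, dc) == (0, 1):
        return [list(levels[r, :]) for r in range(nr)]
    if (dr, dc) == (-1, 0):
        return [list(levels[:, c]) for c in range(nc)]
    lines = []
    arr = levels[:, ::-1] if (dr, dc) == (-1, 1) else levels
    for k in range(-(nr - 1), nc):
        lines.append([arr[r, r + k] for r in range(nr)
                      if 0 <= r + k < nc])
    return lines


def ref_glrlm_matrix(levels, dr, dc, n_levels=32):
    rmax = max(levels.shape)
    P = np.zeros((n_levels, rmax))
    for line in _lines(levels, dr, dc):
        run_val, run_len = line[0], 1
        for v in line[1:]:
            if v == run_val:
                run_len += 1
            else:
                P[run_val - 1, run_len - 1] += 1
                run_val, run_len = v, 1
        P[run_val - 1, run_len - 1] += 1
    return P


def _ref_size_features(P, n_pixels, names):
    Ng, Smax = P.shape
    Nz = P.sum()
    g = [sum(P[i, s] for s in range(Smax)) for i in range(Ng)]
    z = [sum(P[i, s] for i in range(Ng)) for s in range(Smax)]
    mu_i = sum((i + 1) * P[i, s] for i in range(Ng) for s in range(Smax)) / Nz
    mu_s = sum((s + 1) * P[i, s] for i in range(Ng) for s in range(Smax)) / Nz
    ent = -sum(P[i, s] / Nz * math.log2(P[i, s] / Nz)
               for i in range(Ng) for s in range(Smax) if P[i, s] > 0)
    f = [
        sum(P[i, s] / (s + 1) ** 2 for i in range(Ng) for s in range(Smax)) / Nz,
        sum(P[i, s] * (s + 1) ** 2 for i in range(Ng) for s in range(Smax)) / Nz,
        sum(v ** 2 for v in g) / Nz,
        sum(v ** 2 for v in g) / Nz ** 2,
        sum(v ** 2 for v in z) / Nz,
        sum(v ** 2 for v in z) / Nz ** 2,
        Nz / n_pixels,
        sum((i + 1 - mu_i) ** 2 * P[i, s] for i in range(Ng)
            for s in range(Smax)) / Nz,
        sum((s + 1 - mu_s) ** 2 * P[i, s] for i in range(Ng)
            for s in range(Smax)) / Nz,
        ent,
        sum(P[i, s] / (i + 1) ** 2 for i in range(Ng) for s in range(Smax)) / Nz,
        sum(P[i, s] * (i + 1) ** 2 for i in range(Ng) for s in range(Smax)) / Nz,
        sum(P[i, s] / ((i + 1) ** 2 * (s + 1) ** 2)
            for i in range(Ng) for s in range(Smax)) / Nz,
        sum(P[i, s] * (i + 1) ** 2 / (s + 1) ** 2
            for i in range(Ng) for s in range(Smax)) / Nz,
        sum(P[i, s] * (s + 1) ** 2 / (i + 1) ** 2
            for i in range(Ng) for s in range(Smax)) / Nz,
        sum(P[i, s] * (i + 1) ** 2 * (s + 1) ** 2
            for i in range(Ng) for s in range(Smax)) / Nz,
    ]
    return dict(zip(names, f))


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


def ref_glrlm_features(levels, n_levels=32):
    per = [_ref_size_features(ref_glrlm_matrix(levels, dr, dc, n_levels),
                              levels.size, GLRLM_NAMES)
           for dr, dc in OFFSETS]
    return {k: sum(d[k] for d in per) / len(per) for k in per[0]}


# --------------------------------------------------------------------------
# GLSZM (zones via breadth-first flood fill, 8-connected)
# --------------------------------------------------------------------------

def ref_glszm_matrix(levels, n_levels=32):
    nr, nc = levels.shape
    seen = np.zeros((nr, nc), dtype=bool)
    zones = []
    for r0 in range(nr):
        for c0 in range(nc):
            if seen[r0, c0]:
                continue
            lv = levels[r0, c0]
            stack = [(r0, c0)]
            seen[r0, c0] = True
            size = 0
            while stack:
                r, c = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        r2, c2 = r + dr, c + dc
                        if (0 <= r2 < nr and 0 <= c2 < nc
                                and not seen[r2, c2]
                                and levels[r2, c2] == lv):
                            seen[r2, c2] = True
                            stack.append((r2, c2))
            zones.append((lv, size))
    smax = max(sz for _, sz in zones)
    P = np.zeros((n_levels, smax))
    for lv, sz in zones:
        P[lv - 1, sz - 1] += 1
    return P


def ref_glszm_features(levels, n_levels=32):
    return _ref_size_features(ref_glszm_matrix(levels, n_levels),
                              levels.size, GLSZM_NAMES)


# --------------------------------------------------------------------------
# GLDM
# --------------------------------------------------------------------------

def ref_gldm_matrix(levels, n_levels=32, alpha=0):
    nr, nc = levels.shape
    P = np.zeros((n_levels, 9))
    for r in range(nr):
        for c in range(nc):
            dep = 0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if (0 <= r2 < nr and 0 <= c2 < nc
                            and abs(int(levels[r2, c2]) - int(levels[r, c])) <= alpha):
                        dep += 1
            P[levels[r, c] - 1, dep] += 1     # size = dep + 1 -> column dep
    return P


def ref_gldm_features(levels, n_levels=32, alpha=0):
    P = ref_gldm_matrix(levels, n_levels, alpha)
    Ng, Nd = P.shape
    Nz = P.sum()
    g = [sum(P[i, j] for j in range(Nd)) for i in range(Ng)]
    d = [sum(P[i, j] for i in range(Ng)) for j in range(Nd)]
    mu_i = sum((i + 1) * P[i, j] for i in range(Ng) for j in range(Nd)) / Nz
    mu_j = sum((j + 1) * P[i, j] for i in range(Ng) for j in range(Nd)) / Nz
    ent = -sum(P[i, j] / Nz * math.log2(P[i, j] / Nz)
               for i in range(Ng) for j in range(Nd) if P[i, j] > 0)
    names = (
        "small_dependence_emphasis", "large_dependence_emphasis",
        "gray_level_nonuniformity", "dependence_nonuniformity",
        "dependence_nonuniformity_normalized", "gray_level_variance",
        "dependence_variance", "dependence_entropy",
        "low_gray_level_emphasis", "high_gray_level_emphasis",
        "small_dependence_low_gray_level_emphasis",
        "small_dependence_high_gray_level_emphasis",
        "large_dependence_low_gray_level_emphasis",
        "large_dependence_high_gray_level_emphasis",
    )
    f = [
        sum(P[i, j] / (j + 1) ** 2 for i in range(Ng) for j in range(Nd)) / Nz,
        sum(P[i, j] * (j + 1) ** 2 for i in range(Ng) for j in range(Nd)) / Nz,
        sum(v ** 2 for v in g) / Nz,
        sum(v ** 2 for v in d) / Nz,
        sum(v ** 2 for v in d) / Nz ** 2,
        sum((i + 1 - mu_i) ** 2 * P[i, j] for i in range(Ng)
            for j in range(Nd)) / Nz,
        sum((j + 1 - mu_j) ** 2 * P[i, j] for i in range(Ng)
            for j in range(Nd)) / Nz,
        ent,
        sum(P[i, j] / (i + 1) ** 2 for i in range(Ng) for j in range(Nd)) / Nz,
        sum(P[i, j] * (i + 1) ** 2 for i in range(Ng) for j in range(Nd)) / Nz,
        sum(P[i, j] / ((i + 1) ** 2 * (j + 1) ** 2)
            for i in range(Ng) for j in range(Nd)) / Nz,
        sum(P[i, j] * (i + 1) ** 2 / (j + 1) ** 2
            for i in range(Ng) for j in range(Nd)) / Nz,
        sum(P[i, j] * (j + 1) ** 2 / (i + 1) ** 2
            for i in range(Ng) for j in range(Nd)) / Nz,
        sum(P[i, j] * (i + 1) ** 2 * (j + 1) ** 2
            for i in range(Ng) for j in range(Nd)) / Nz,
    ]
    return dict(zip(names, f))


# --------------------------------------------------------------------------
# NGTDM
# --------------------------------------------------------------------------

def ref_ngtdm_features(levels, n_levels=32):
    nr, nc = levels.shape
    n_i = [0.0] * n_levels
    s_i = [0.0] * n_levels
    for r in range(nr):
        for c in range(nc):
            nb = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < nr and 0 <= c2 < nc:
                        nb.append(float(levels[r2, c2]))
            A = sum(nb) / len(nb)
            lv = levels[r, c]
            n_i[lv - 1] += 1
            s_i[lv - 1] += abs(lv - A)
    Nvp = sum(n_i)
    p_i = [v / Nvp for v in n_i]
    present = [i for i in range(n_levels) if p_i[i] > 0]
    Ngp = len(present)
    denom = sum(p_i[i] * s_i[i] for i in present)
    coarseness = 1.0 / denom if denom > 0 else 1e6
    if Ngp > 1:
        contrast = (sum(p_i[i] * p_i[j] * (i - j) ** 2
                        for i in present for j in present)
                    / (Ngp * (Ngp - 1))) * sum(s_i) / Nvp
        busy_den = sum(abs((i + 1) * p_i[i] - (j + 1) * p_i[j])
                       for i in present for j in present)
        busyness = denom / busy_den if busy_den > 0 else 0.0
        complexity = sum(abs(i - j) * (p_i[i] * s_i[i] + p_i[j] * s_i[j])
                         / (p_i[i] + p_i[j])
                         for i in present for j in present) / Nvp
        s_total = sum(s_i)
        strength = (sum((p_i[i] + p_i[j]) * (i - j) ** 2
                        for i in present for j in present) / s_total
                    if s_total > 0 else 0.0)
    else:
        contrast = busyness = complexity = strength = 0.0
    return {"coarseness": coarseness, "contrast": contrast,
            "busyness": busyness, "complexity": complexity,
            "strength": strength}


# --------------------------------------------------------------------------
# assembled 93-feature reference
# --------------------------------------------------------------------------

def ref_all_features(values, pixel_area_mm2=0.25, n_bins=32):
    levels = ref_quantize(values, n_bins)
    out = {}
    out.update({f"firstorder__{k}": v
                for k, v in ref_first_order(values, pixel_area_mm2, n_bins).items()})
    out.update({f"glcm__{k}": v
                for k, v in ref_glcm_features(levels, n_bins).items()})
    out.update({f"glrlm__{k}": v
                for k, v in ref_glrlm_features(levels, n_bins).items()})
    out.update({f"glszm__{k}": v
                for k, v in ref_glszm_features(levels, n_bins).items()})
    out.update({f"gldm__{k}": v
                for k, v in ref_gldm_features(levels, n_bins).items()})
    out.update({f"ngtdm__{k}": v
                for k, v in ref_ngtdm_features(levels, n_bins).items()})
    return out
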