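"""Feature selection and RadScore modelling.

Features are ranked by the greedy mRMR (MID) scheme — relevance to the
60-month knee-replacement label minus mean redundancy against the already
selected set, both measured by discrete mutual information — and the top
five enter an easy-ensemble of L2-penalised logistic submodels.  Each
submodel sees every minority-class (KR) subject plus an equal-sized random
majority subsample, so the heavily imbalanced label (~7% events by 60
months) never swamps the fit; the RadScore is the mean predicted
probability over the ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


# --------------------------------------------------------------------------
# mutual information & mRMR
# --------------------------------------------------------------------------

def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Integer codes from equal-frequency binning (duplicate edges merged)."""
    codes = pd.qcut(x, n_bins, labels=False, duplicates="drop")
    return np.asarray(codes, dtype=np.int64)


def _codes(v: np.ndarray, n_bins: int) -> np.ndarray:
    v = np.asarray(v)
    uniq = np.unique(v)
    if uniq.size <= n_bins:
        return np.searchsorted(uniq, v).astype(np.int64)
    if uniq.size == v.size:
        # distinct values: rank-based equal-frequency bins (exact balance)
        ranks = np.empty(v.size, dtype=np.int64)
        ranks[np.argsort(v, kind="stable")] = np.arange(v.size)
        return (ranks * n_bins) // v.size
    return _equal_frequency_bins(v.astype(np.float64), n_bins)


def _mi_from_codes(cx: np.ndarray, cy: np.ndarray) -> float:
    nx = cx.max() + 1
    ny = cy.max() + 1
    joint = np.bincount(cx * ny + cy, minlength=nx * ny).reshape(nx, ny)
    n = joint.sum()
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float((pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])).sum())


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int = 8) -> float:
    """Discrete mutual information (natural log) after equal-frequency
    binning of continuous variables; discrete variables are used as-is.
    Constant ``x`` returns 0."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if np.unique(x).size < 2:
        return 0.0
    return _mi_from_codes(_codes(x, n_bins), _codes(y, n_bins))


@dataclass
class MrmrRanking:
    """Greedy mRMR ranking trace: one (name, relevance, redundancy, score)
    row per selection step."""
    selected: list[str]
    relevance: list[float]
    redundancy: list[float]
    score: list[float]


def mrmr_rank(features: pd.DataFrame, labels: np.ndarray, k: int = 5,
              n_bins: int = 8) -> MrmrRanking:
    """Greedy MID mRMR: step score = I(x;y) - mean_s I(x;x_s).

    Constant features are dropped beforehand; ties break lexicographically
    by feature name.
    """
    labels = np.asarray(labels)
    keep = [c for c in features.columns
            if np.unique(features[c].to_numpy()).size > 1]
    if k > len(keep):
        raise ValueError(f"requested k={k} exceeds {len(keep)} usable features")
    # stable, order-independent candidate ordering for the tie rule
    keep = sorted(keep)
    codes = {c: _codes(features[c].to_numpy(), n_bins) for c in keep}
    ycode = _codes(labels, n_bins)
    rel = {c: _mi_from_codes(codes[c], ycode) for c in keep}

    selected: list[str] = []
    red_sum = {c: 0.0 for c in keep}
    out = MrmrRanking([], [], [], [])
    for _ in range(k):
        best_name, best_score, best_red = None, -np.inf, 0.0
        for c in keep:
            if c in out.selected:
                continue
            red = red_sum[c] / len(out.selected) if out.selected else 0.0
            sc = rel[c] - red
            if sc > best_score + 1e-15:
                best_name, best_score, best_red = c, sc, red
        out.selected.append(best_name)
        out.relevance.append(rel[best_name])
        out.redundancy.append(best_red)
        out.score.append(best_score)
        for c in keep:
            if c not in out.selected:
                red_sum[c] += _mi_from_codes(codes[c], codes[best_name])
    return out


# --------------------------------------------------------------------------
# ridge-logistic easy-ensemble
# --------------------------------------------------------------------------

def _ridge_logistic(X: np.ndarray, y: np.ndarray, lam: float,
                    tol: float = 1e-8, max_iter: int = 100) -> np.ndarray:
    """Newton fit of L2-penalised logistic regression.

    Returns [intercept, coefs...]; the penalty (lam/2)*||beta||^2 excludes
    the intercept.
    """
    n, p = X.shape
    Xd = np.hstack([np.ones((n, 1)), X])
    w = np.zeros(p + 1)
    pen = np.full(p + 1, lam)
    pen[0] = 0.0
    for _ in range(max_iter):
        eta = Xd @ w
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = Xd.T @ (y - mu) - pen * w
        W = mu * (1.0 - mu)
        H = (Xd * W[:, None]).T @ Xd + np.diag(pen)
        step = np.linalg.solve(H, grad)
        w = w + step
        if np.abs(step).max() < tol:
            break
    return w


@dataclass
class RadScoreModel:
    """Fitted easy-ensemble RadScore model for one ROI."""
    selected_features: list[str]
    norm_mean: np.ndarray
    norm_sd: np.ndarray
    lam: float
    seed: int
    coefs: np.ndarray          # (n_sub, n_features + 1); column 0 = intercept

    def to_json_dict(self) -> dict:
        return {
            "selected_features": self.selected_features,
            "norm_mean": self.norm_mean.tolist(),
            "norm_sd": self.norm_sd.tolist(),
            "lambda": self.lam,
            "seed": self.seed,
            "coefs": self.coefs.tolist(),
        }


def fit_radscore(features: pd.DataFrame, event60: np.ndarray,
                 lam: float = 1.0, n_sub: int = 500,
                 seed: int = 0) -> RadScoreModel:
    """Fit the easy-ensemble RadScore on the 60-month KR label.

    Each of the ``n_sub`` submodels trains on all minority-class subjects
    plus an equal-sized majority subsample drawn without replacement (fresh
    seeded draw per submodel).  Features are z-scored by training statistics.
    """
    y = np.asarray(event60, dtype=np.float64)
    X = features.to_numpy(dtype=np.float64)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("event60 must contain both classes")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(features.columns, sd) if s == 0]
        raise ValueError(f"constant selected features: {bad}")
    Z = (X - mean) / sd

    minority = 1.0 if y.sum() <= (1 - y).sum() else 0.0
    idx_min = np.flatnonzero(y == minority)
    idx_maj = np.flatnonzero(y != minority)
    if idx_min.size < 5:
        raise ValueError("minority class has fewer than 5 samples")

    rng = np.random.default_rng(seed)
    coefs = np.empty((n_sub, Z.shape[1] + 1))
    for b in range(n_sub):
        sub = rng.choice(idx_maj, size=idx_min.size, replace=False)
        idx = np.concatenate([idx_min, sub])
        coefs[b] = _ridge_logistic(Z[idx], y[idx], lam)
    return RadScoreModel(list(features.columns), mean, sd, lam, seed, coefs)


def score(model: RadScoreModel, features: pd.DataFrame) -> np.ndarray:
    """RadScore per subject: ensemble-mean predicted probability in [0, 1]."""
    missing = [c for c in model.selected_features if c not in features.columns]
    if missing:
        raise ValueError(f"missing selected features: {missing}")
    X = features[model.selected_features].to_numpy(dtype=np.float64)
    Z = (X - model.norm_mean) / model.norm_sd
    eta = model.coefs[:, 0][None, :] + Z @ model.coefs[:, 1:].T
    return (1.0 / (1.0 + np.exp(-eta))).mean(axis=1)


def binary_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with tie correction (shared with time-dependent ROC)."""
    from .survival import mann_whitney_auc
    labels = np.asarray(labels, dtype=bool)
    return mann_whitney_auc(np.asarray(scores, float)[labels],
                            np.asarray(scores, float)[~labels])


def select_best_roi(per_roi_scores: dict[str, np.ndarray],
                    event60: np.ndarray) -> str:
    """Pick the ROI whose RadScore best separates 60-month KR (training AUC);
    ties go to the inferior-most ROI."""
    if len(per_roi_scores) < 2:
        raise ValueError("need at least 2 candidate ROIs")
    order = {"roi_sup": 0, "roi_mid": 1, "roi_inf": 2}
    best_name, best_auc, best_rank = None, -np.inf, -1
    for name, s in per_roi_scores.items():
        auc = binary_auc(np.asarray(s), np.asarray(event60))
        rank = order.get(name, -1)
        if auc > best_auc + 1e-12 or (abs(auc - best_auc) <= 1e-12
                                      and rank > best_rank):
            best_name, best_auc, best_rank = name, auc, rank
    return best_name
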