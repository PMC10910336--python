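"""KR risk-score fusion and three-class progression-speed stratification.

The RadScore (standardized by training mean/sd) is fused with the
Kellgren-Lawrence grade and any independently significant demographic
covariates in a multivariate Cox model; the linear predictor is the KR risk
score.  Two Youden-index thresholds split the score into low / medium /
high risk groups aimed at the three progression-speed classes:

* non-progressor   — no KR within 84 months (event-free follow-up >= 84 m)
* slow progressor  — KR in (30, 84] months
* fast progressor  — KR at or before 30 months

Subjects censored before 84 months without an event cannot be labelled and
are "indeterminate" for threshold training and confusion matrices (they
still contribute to Cox fits and KM curves).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import CoxFit, cox_fit

NON, SLOW, FAST, INDET = "non", "slow", "fast", "indeterminate"
LOW, MEDIUM, HIGH = "low", "medium", "high"

_CANDIDATE_COVARIATES = ("radscore", "age", "gender", "bmi", "klg", "pfoa")


def progression_labels(time: np.ndarray, event: np.ndarray,
                       fast_horizon: float = 30.0,
                       non_horizon: float = 84.0) -> np.ndarray:
    """Per-subject progression-speed class (object array of labels)."""
    t = np.asarray(time, float)
    e = np.asarray(event, bool)
    out = np.full(t.size, INDET, dtype=object)
    out[e & (t <= fast_horizon)] = FAST
    out[e & (t > fast_horizon) & (t <= non_horizon)] = SLOW
    out[~e & (t >= non_horizon)] = NON
    # events after the non-progressor horizon count as event-free within it
    out[e & (t > non_horizon)] = NON
    return out


@dataclass
class KRRiskModel:
    """Fused Cox risk model: score = linear predictor over retained covariates."""
    fit: CoxFit
    retained: list[str]
    radscore_mean: float
    radscore_sd: float
    dropped: list[str]
    fallback_used: bool
    impute_means: dict[str, float]

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        cols = []
        for name in self.retained:
            v = table[name].to_numpy(dtype=np.float64)
            if name == "radscore":
                v = (v - self.radscore_mean) / self.radscore_sd
            # missing covariate values (e.g. unread PFOA) take the training mean
            v = np.where(np.isnan(v), self.impute_means[name], v)
            cols.append(v)
        X = np.column_stack(cols)
        return X @ self.fit.beta


def fit_risk_score(table: pd.DataFrame, radscore: np.ndarray,
                   p_threshold: float = 0.05) -> KRRiskModel:
    """Two-stage covariate selection + refit.

    Stage 1: multivariate Cox on {RadScore, age, gender, BMI, KLG, PFOA}
    (subjects with missing PFOA excluded from this stage only).  Stage 2:
    refit on the covariates with Wald p < ``p_threshold``; if none survive,
    fall back to {RadScore, KLG}.  RadScore is standardized by its training
    mean/sd so its hazard ratio is per-SD.
    """
    df = table.copy()
    rs = np.asarray(radscore, dtype=np.float64)
    mu, sd = float(rs.mean()), float(rs.std())
    if sd == 0:
        raise ValueError("constant RadScore")
    df["radscore"] = (rs - mu) / sd
    if "gender" in df and df["gender"].dtype == object:
        df["gender"] = (df["gender"] == "male").astype(float)

    candidates = [c for c in _CANDIDATE_COVARIATES if c in df.columns]
    stage1 = df.dropna(subset=[c for c in candidates])
    usable = [c for c in candidates
              if np.unique(stage1[c].to_numpy(dtype=float)).size > 1]
    X1 = stage1[usable].to_numpy(dtype=np.float64)
    fit1 = cox_fit(X1, stage1["kr_time_months"].to_numpy(float),
                   stage1["kr_event"].to_numpy(float), names=usable)
    retained = [name for name, p in zip(usable, fit1.p_values)
                if p < p_threshold]
    fallback = False
    if not retained:
        retained = [c for c in ("radscore", "klg") if c in df.columns]
        fallback = True
    dropped = [c for c in usable if c not in retained]

    stage2 = df.dropna(subset=retained)
    X2 = stage2[retained].to_numpy(dtype=np.float64)
    fit2 = cox_fit(X2, stage2["kr_time_months"].to_numpy(float),
                   stage2["kr_event"].to_numpy(float), names=retained)
    impute = {name: float(stage2[name].mean()) for name in retained}
    return KRRiskModel(fit2, retained, mu, sd, dropped, fallback, impute)


# --------------------------------------------------------------------------
# threshold optimisation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskStrata:
    """The two stratification cutpoints (t_low < t_high)."""
    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        if not self.t_low < self.t_high:
            raise ValueError("t_low must be below t_high")


def youden_best_cutpoint(scores: np.ndarray, positive: np.ndarray,
                         candidates: np.ndarray) -> tuple[float, float]:
    """Cutpoint maximising J = sensitivity + specificity - 1 for the rule
    'score >= cut -> positive'; ties prefer the lower cutpoint."""
    s = np.asarray(scores, float)
    pos = np.asarray(positive, bool)
    n_pos = pos.sum()
    n_neg = (~pos).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for Youden optimisation")
    best_cut, best_j = None, -np.inf
    for cut in candidates:                      # ascending candidates
        pred = s >= cut
        sens = (pred & pos).sum() / n_pos
        spec = (~pred & ~pos).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_cut, best_j = float(cut), float(j)
    return best_cut, best_j


def optimize_thresholds(scores: np.ndarray, labels: np.ndarray) -> RiskStrata:
    """Fit the two Youden cutpoints on labelled training subjects.

    t_low targets any progression by 84 months ((slow or fast) vs non);
    t_high targets fast progression by 30 months (fast vs rest).
    Indeterminate subjects are ignored.  If the upper cut does not exceed
    the lower one it is raised to the next candidate above t_low.
    """
    s = np.asarray(scores, float)
    lab = np.asarray(labels, dtype=object)
    known = lab != INDET
    s, lab = s[known], lab[known]
    for cls in (NON, SLOW, FAST):
        if not (lab == cls).any():
            raise ValueError(f"progression class {cls!r} absent")
    uniq = np.sort(np.unique(s))
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    if candidates.size == 0:
        raise ValueError("all scores identical; no candidate cutpoints")
    t_low, _ = youden_best_cutpoint(s, (lab == SLOW) | (lab == FAST), candidates)
    t_high, _ = youden_best_cutpoint(s, lab == FAST, candidates)
    if t_high <= t_low:
        above = candidates[candidates > t_low]
        if above.size == 0:
            raise ValueError("cannot place upper threshold above lower")
        t_high = float(above[0])
    return RiskStrata(t_low, t_high)


def classify(scores: np.ndarray, strata: RiskStrata) -> np.ndarray:
    """low / medium / high risk class per subject.

    Boundary scores go upward: exactly t_low -> medium, exactly t_high -> high.
    """
    s = np.asarray(scores, float)
    out = np.full(s.size, LOW, dtype=object)
    out[s >= strata.t_low] = MEDIUM
    out[s >= strata.t_high] = HIGH
    return out


def confusion_and_ppv(pred_classes: np.ndarray,
                      labels: np.ndarray) -> dict:
    """3x3 confusion matrix (rows: predicted low/medium/high, columns:
    observed non/slow/fast) plus the positive predictive values of the
    high-risk class; indeterminate subjects are excluded and counted."""
    pred = np.asarray(pred_classes, dtype=object)
    lab = np.asarray(labels, dtype=object)
    known = lab != INDET
    pred_k, lab_k = pred[known], lab[known]
    rows = (LOW, MEDIUM, HIGH)
    cols = (NON, SLOW, FAST)
    mat = np.zeros((3, 3), dtype=int)
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            mat[i, j] = int(((pred_k == r) & (lab_k == c)).sum())
    n_high = int((pred_k == HIGH).sum())
    if n_high > 0:
        ppv_any = float(((pred_k == HIGH)
                         & ((lab_k == SLOW) | (lab_k == FAST))).sum() / n_high)
        ppv_fast = float(((pred_k == HIGH) & (lab_k == FAST)).sum() / n_high)
    else:
        ppv_any = None
        ppv_fast = None
    return {
        "matrix": mat,
        "row_labels": rows,
        "col_labels": cols,
        "ppv_high_any_progression": ppv_any,
        "ppv_high_fast_progression": ppv_fast,
        "n_indeterminate_excluded": int((~known).sum()),
    }
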