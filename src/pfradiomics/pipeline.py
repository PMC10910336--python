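"""End-to-end orchestration: cohort -> features -> RadScore -> risk score
-> stratification -> report.

The driver mirrors the prognosis workflow: preprocess each radiograph
(align, resample to 0.5 mm, patella-bbox z-score normalisation), build the
three PF-joint ROIs, extract 930 features per ROI over the 10-image filter
bank, split the cohort 2:1, rank features per ROI by mRMR and fit one
easy-ensemble RadScore per ROI, keep the ROI with the best training
60-month AUC, fuse the standardized RadScore with KLG (and any demographic
covariate that stays independently significant) in a Cox model, and
stratify the Cox linear predictor with two Youden thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features as feat
from . import selection, stratify, survival
from .filterbank import apply_filter_bank
from .imageprep import (PatellaMask, Radiograph, align_patella, mask_bbox,
                        make_rois, normalize_patella, resample_isotropic)
from .synthdata import SimulationConfig, generate_cohort, records_to_frame

ROI_NAMES = ("roi_sup", "roi_mid", "roi_inf")


@dataclass
class PipelineConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    target_spacing_mm: float = 0.5
    n_bins: int = 32
    mrmr_k: int = 5
    ridge_lambda: float = 1.0
    n_submodels: int = 500
    horizons: tuple[float, ...] = (30.0, 60.0, 84.0)
    radscore_horizon: float = 60.0
    n_boot: int = 0            # bootstrap C-index CI iterations (0 = skip)
    n_perm: int = 0            # permutation comparison iterations (0 = skip)
    train_fraction: float = 2.0 / 3.0
    stratify_split: bool = True
    seed: int = 0


def preprocess_subject(image: Radiograph, mask: PatellaMask,
                       target_spacing_mm: float = 0.5):
    """Align, resample and normalize one subject; returns the processed
    image plus the ROI set on the processed grid."""
    img, msk, angle = align_patella(image, mask)
    img, msk = resample_isotropic(img, msk, target_spacing_mm)
    bbox = mask_bbox(msk)
    img = normalize_patella(img, bbox)
    rois = make_rois(bbox, img.laterality, image_shape=img.shape)
    return img, msk, rois, angle


def extract_subject_features(image: Radiograph, mask: PatellaMask,
                             target_spacing_mm: float = 0.5,
                             n_bins: int = 32) -> dict[str, float]:
    """The 3 x 930 ROI-prefixed feature vector of one subject."""
    img, _msk, rois, _angle = preprocess_subject(image, mask, target_spacing_mm)
    stack = apply_filter_bank(img)
    out: dict[str, float] = {}
    for roi_name, box in rois.items():
        vec = feat.extract_all(stack, box, spacing_mm=target_spacing_mm,
                               n_bins=n_bins)
        out.update({f"{roi_name}__{k}": v for k, v in vec.items()})
    return out


def extract_cohort_features(images, masks, subject_ids,
                            target_spacing_mm: float = 0.5,
                            n_bins: int = 32) -> pd.DataFrame:
    rows = []
    for sid, img, msk in zip(subject_ids, images, masks):
        try:
            rows.append(extract_subject_features(img, msk, target_spacing_mm,
                                                 n_bins))
        except Exception as exc:
            raise RuntimeError(f"feature extraction failed for subject "
                               f"{sid}: {exc}") from exc
    return pd.DataFrame(rows, index=list(subject_ids))


def train_test_split(table: pd.DataFrame, train_fraction: float,
                     stratify_by_event: bool, seed: int) -> np.ndarray:
    """Boolean mask: True = training cohort (2:1 by default)."""
    rng = np.random.default_rng(seed)
    n = len(table)
    is_train = np.zeros(n, dtype=bool)
    if stratify_by_event:
        for val in (0, 1):
            idx = np.flatnonzero(table["kr_event"].to_numpy() == val)
            k = int(round(train_fraction * idx.size))
            chosen = rng.choice(idx, size=k, replace=False)
            is_train[chosen] = True
    else:
        k = int(round(train_fraction * n))
        is_train[rng.choice(n, size=k, replace=False)] = True
    return is_train


def event_by_horizon(table: pd.DataFrame, horizon: float):
    """(label, usable) at a horizon: censored-before-horizon non-events are
    unusable for binary fitting."""
    t = table["kr_time_months"].to_numpy(float)
    e = table["kr_event"].to_numpy(int).astype(bool)
    label = e & (t <= horizon)
    usable = label | (t > horizon)
    return label.astype(int), usable


@dataclass
class PipelineResult:
    report: dict
    table: pd.DataFrame
    features: pd.DataFrame
    is_train: np.ndarray
    radscore: np.ndarray
    risk_score: np.ndarray
    risk_classes: np.ndarray
    progression: np.ndarray
    strata: stratify.RiskStrata
    risk_model: stratify.KRRiskModel
    radscore_models: dict
    best_roi: str


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis on one synthetic cohort."""
    records, images, masks = generate_cohort(config.sim)
    table = records_to_frame(records)
    feats = extract_cohort_features(images, masks, table["subject_id"],
                                    config.target_spacing_mm, config.n_bins)

    is_train = train_test_split(table, config.train_fraction,
                                config.stratify_split, config.seed + 101)
    label60, usable60 = event_by_horizon(table, config.radscore_horizon)
    fit_rows = is_train & usable60

    # drop zero-variance columns on the training cohort before ranking
    train_feats = feats[fit_rows]
    variable = train_feats.columns[train_feats.std(axis=0) > 0]

    roi_models: dict[str, dict] = {}
    train_scores: dict[str, np.ndarray] = {}
    for k_roi, roi in enumerate(ROI_NAMES):
        cols = [c for c in variable if c.startswith(roi + "__")]
        ranking = selection.mrmr_rank(train_feats[cols], label60[fit_rows],
                                      k=config.mrmr_k)
        model = selection.fit_radscore(train_feats[ranking.selected],
                                       label60[fit_rows],
                                       lam=config.ridge_lambda,
                                       n_sub=config.n_submodels,
                                       seed=config.seed + 1000 + k_roi)
        roi_models[roi] = {"ranking": ranking, "model": model}
        train_scores[roi] = selection.score(model, train_feats)
    best_roi = selection.select_best_roi(train_scores, label60[fit_rows])
    final_model = roi_models[best_roi]["model"]
    radscore = selection.score(final_model, feats)

    # --- Cox fusion on the training cohort ---
    train_table = table[is_train].reset_index(drop=True)
    risk_model = stratify.fit_risk_score(train_table, radscore[is_train])

    df_all = table.copy()
    df_all["radscore"] = radscore
    if df_all["gender"].dtype == object:
        df_all["gender"] = (df_all["gender"] == "male").astype(float)
    df_all["radscore"] = radscore          # linear_predictor re-standardizes
    risk_score = risk_model.linear_predictor(df_all)

    # --- comparator models (fit on training) ---
    t = table["kr_time_months"].to_numpy(float)
    e = table["kr_event"].to_numpy(int)
    scores = {"klg": table["klg"].to_numpy(float),
              "radscore": radscore,
              "combined": risk_score}
    # PFOA + KLG clinical comparator; missing PFOA imputed at training mean
    pfoa = table["pfoa"].to_numpy(float)
    pfoa_mean = np.nanmean(pfoa[is_train])
    pfoa_filled = np.where(np.isnan(pfoa), pfoa_mean, pfoa)
    X_pk = np.column_stack([pfoa_filled, table["klg"].to_numpy(float)])
    fit_pk = survival.cox_fit(X_pk[is_train], t[is_train], e[is_train],
                              names=["pfoa", "klg"])
    scores["pfoa_klg"] = X_pk @ fit_pk.beta

    metrics: dict[str, dict] = {}
    for name, sc in scores.items():
        entry: dict = {}
        for split, sel in (("train", is_train), ("test", ~is_train)):
            m: dict = {"c_index": survival.concordance_index(
                sc[sel], t[sel], e[sel])}
            if config.n_boot > 0:
                m["c_index_ci"] = survival.c_index_ci(
                    sc[sel], t[sel], e[sel], n_boot=config.n_boot,
                    seed=config.seed + 71)
            if config.n_perm > 0 and name != "combined":
                m["c_index_p_vs_combined"] = survival.compare_models_permutation(
                    scores["combined"][sel], sc[sel], t[sel], e[sel],
                    n_perm=config.n_perm, seed=config.seed + 72)
            for h in config.horizons:
                try:
                    m[f"auc_{int(h)}m"] = survival.td_auc(sc[sel], t[sel],
                                                          e[sel], h)
                except ValueError:
                    m[f"auc_{int(h)}m"] = None
            entry[split] = m
        metrics[name] = entry

    # --- stratification (skipped, not fatal, if a progression class is
    # absent from the training cohort -- possible in small null cohorts) ---
    progression = stratify.progression_labels(t, e)
    try:
        strata = stratify.optimize_thresholds(risk_score[is_train],
                                              progression[is_train])
    except ValueError as exc:
        strata = None
        strat_reason = str(exc)
    if strata is not None:
        risk_classes = stratify.classify(risk_score, strata)
        confusion = stratify.confusion_and_ppv(risk_classes, progression)
        km = survival.km_estimate(t, e, risk_classes)
        km_84 = {str(g): curve.at(84.0) for g, curve in km.items()}

    ranking_audit = {
        roi: {"selected": d["ranking"].selected,
              "score": d["ranking"].score}
        for roi, d in roi_models.items()
    }
    n_excl_60 = int((is_train & ~usable60).sum())
    report = {
        "config": {
            "n_subjects": config.sim.n_subjects,
            "seed": config.seed,
            "sim_seed": config.sim.seed,
            "n_submodels": config.n_submodels,
            "ridge_lambda": config.ridge_lambda,
            "mrmr_k": config.mrmr_k,
            "horizons": list(config.horizons),
            "target_spacing_mm": config.target_spacing_mm,
            "n_bins": config.n_bins,
        },
        "cohort": {
            "n_train": int(is_train.sum()),
            "n_test": int((~is_train).sum()),
            "n_events": int(e.sum()),
            "event_rate_84m": float(np.mean((e == 1) & (t <= 84.0))),
            "n_train_excluded_censored_before_60m": n_excl_60,
        },
        "radscore": {
            "best_roi": best_roi,
            "selected_features": final_model.selected_features,
            "mrmr": ranking_audit,
            "train_auc_60m": selection.binary_auc(
                selection.score(final_model, train_feats), label60[fit_rows]),
        },
        "risk_model": {
            "retained_covariates": risk_model.retained,
            "dropped_covariates": risk_model.dropped,
            "fallback_used": risk_model.fallback_used,
            "cox": risk_model.fit.summary_dict(),
        },
        "metrics": metrics,
        "stratification": ({
            "available": True,
            "t_low": strata.t_low,
            "t_high": strata.t_high,
            "class_counts": {c: int((risk_classes == c).sum())
                             for c in ("low", "medium", "high")},
            "confusion_matrix": confusion["matrix"].tolist(),
            "ppv_high_any_progression": confusion["ppv_high_any_progression"],
            "ppv_high_fast_progression": confusion["ppv_high_fast_progression"],
            "n_indeterminate": confusion["n_indeterminate_excluded"],
            "km_survival_84m_by_class": km_84,
        } if strata is not None else {
            "available": False, "reason": strat_reason,
        }),
    }
    if strata is None:
        risk_classes = np.full(len(table), "unstratified", dtype=object)
    return PipelineResult(report, table, feats, is_train, radscore,
                          risk_score, risk_classes, progression, strata,
                          risk_model, roi_models, best_roi)
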