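"""Fuse RadScore and KLG into the KR risk score; compare prognostic models.

Works from results/cohort + results/radscore.csv: runs the two-stage
multivariate Cox selection on the training cohort, computes the risk score
for everyone, and evaluates KLG-alone, RadScore-alone, PFOA+KLG and the
combined risk score by C-index (with bootstrap CI) and time-dependent AUC
at 30/60/84 months, with one-sided permutation comparisons against the
combined model.  Writes results/risk_scores.csv and results/metrics.json.

Usage: python analysis/04_fit_risk_model.py [n_boot] [n_perm]
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from pfradiomics import stratify, survival, synthdata

N_BOOT = int(sys.argv[1]) if len(sys.argv) > 1 else 1000
N_PERM = int(sys.argv[2]) if len(sys.argv) > 2 else 1000
RES = Path("results")


def main() -> None:
    records, _, _ = synthdata.read_cohort(RES / "cohort/manifest.json")
    table = synthdata.records_to_frame(records)
    rad = pd.read_csv(RES / "radscore.csv")
    assert list(rad.subject_id) == list(table.subject_id)
    is_train = rad.is_train.to_numpy(bool)
    radscore = rad.radscore.to_numpy()

    model = stratify.fit_risk_score(table[is_train].reset_index(drop=True),
                                    radscore[is_train])
    print("retained covariates:", model.retained,
          "(fallback)" if model.fallback_used else "")
    for name, row in model.fit.summary_dict().items():
        print(f"  {name}: HR {row['hr']:.2f} "
              f"({row['ci_low']:.2f}-{row['ci_high']:.2f}), p={row['p']:.2g}")

    df = table.copy()
    df["radscore"] = radscore
    if df["gender"].dtype == object:
        df["gender"] = (df["gender"] == "male").astype(float)
    risk = model.linear_predictor(df)

    t = table.kr_time_months.to_numpy()
    e = table.kr_event.to_numpy()
    pfoa = table.pfoa.to_numpy(float)
    pfoa = np.where(np.isnan(pfoa), np.nanmean(pfoa[is_train]), pfoa)
    X_pk = np.column_stack([pfoa, table.klg.to_numpy(float)])
    fit_pk = survival.cox_fit(X_pk[is_train], t[is_train], e[is_train],
                              names=["pfoa", "klg"])
    scores = {"klg": table.klg.to_numpy(float), "radscore": radscore,
              "pfoa_klg": X_pk @ fit_pk.beta, "combined": risk}

    metrics = {}
    for name, sc in scores.items():
        metrics[name] = {}
        for split, sel in (("train", is_train), ("test", ~is_train)):
            m = {"c_index": survival.concordance_index(sc[sel], t[sel], e[sel])}
            m["c_index_ci"] = survival.c_index_ci(sc[sel], t[sel], e[sel],
                                                  n_boot=N_BOOT, seed=71)
            if name != "combined":
                m["p_vs_combined"] = survival.compare_models_permutation(
                    scores["combined"][sel], sc[sel], t[sel], e[sel],
                    n_perm=N_PERM, seed=72)
            for h in (30.0, 60.0, 84.0):
                try:
                    m[f"auc_{int(h)}m"] = survival.td_auc(sc[sel], t[sel],
                                                          e[sel], h)
                except ValueError:        # no cases/controls at this horizon
                    m[f"auc_{int(h)}m"] = None
            metrics[name][split] = m
            auc60 = m["auc_60m"]
            print(f"{name:9s} {split:5s} C={m['c_index']:.3f} "
                  f"({m['c_index_ci'][0]:.3f}-{m['c_index_ci'][1]:.3f}) "
                  f"AUC60={'n/a' if auc60 is None else format(auc60, '.3f')}"
                  + (f" p_vs_combined={m['p_vs_combined']:.3f}"
                     if name != "combined" else ""))

    out = rad.copy()
    out["risk_score"] = risk
    out.to_csv(RES / "risk_scores.csv", index=False)
    (RES / "metrics.json").write_text(json.dumps({
        "risk_model": {"retained": model.retained,
                       "cox": model.fit.summary_dict()},
        "metrics": metrics}, indent=1))
    print(f"wrote {RES/'risk_scores.csv'}, {RES/'metrics.json'}")


if __name__ == "__main__":
    main()
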