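"""Rank features per ROI, fit the easy-ensemble RadScore, pick the best ROI.

Works from results/cohort + results/features.csv: splits the cohort 2:1
(event-stratified), builds the 60-month KR label, runs mRMR (top 5) and the
500-submodel ridge-logistic easy-ensemble per ROI on the training cohort,
and keeps the ROI with the highest training 60-month AUC.  Writes
results/radscore.csv (per-subject scores + split), results/radscore_model.json
and results/mrmr_ranking.csv.

Usage: python analysis/03_train_radscore.py [seed] [n_submodels]
"""

import json
import sys
from pathlib import Path

import pandas as pd

from pfradiomics import pipeline, selection, synthdata

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7
N_SUB = int(sys.argv[2]) if len(sys.argv) > 2 else 500
RES = Path("results")


def main() -> None:
    records, _, _ = synthdata.read_cohort(RES / "cohort/manifest.json")
    table = synthdata.records_to_frame(records)
    feats = pd.read_csv(RES / "features.csv", index_col=0)

    is_train = pipeline.train_test_split(table, 2 / 3, True, seed=SEED + 101)
    label60, usable60 = pipeline.event_by_horizon(table, 60.0)
    fit_rows = is_train & usable60
    print(f"train {is_train.sum()} / test {(~is_train).sum()}; "
          f"{(is_train & ~usable60).sum()} training subjects censored "
          "before 60 m excluded from RadScore fitting")

    train_feats = feats[fit_rows]
    variable = train_feats.columns[train_feats.std(axis=0) > 0]
    rows, scores = [], {}
    models = {}
    for k, roi in enumerate(pipeline.ROI_NAMES):
        cols = [c for c in variable if c.startswith(roi + "__")]
        ranking = selection.mrmr_rank(train_feats[cols], label60[fit_rows], k=5)
        model = selection.fit_radscore(train_feats[ranking.selected],
                                       label60[fit_rows], n_sub=N_SUB,
                                       seed=SEED + 1000 + k)
        models[roi] = model
        scores[roi] = selection.score(model, train_feats)
        auc = selection.binary_auc(scores[roi], label60[fit_rows])
        print(f"{roi}: train AUC(60m) = {auc:.3f}; top feature "
              f"{ranking.selected[0]}")
        for step, (name, rel, red, sc) in enumerate(zip(
                ranking.selected, ranking.relevance, ranking.redundancy,
                ranking.score)):
            rows.append({"roi": roi, "step": step, "feature": name,
                         "relevance": rel, "redundancy": red, "score": sc})

    best = selection.select_best_roi(scores, label60[fit_rows])
    print(f"selected ROI: {best}")
    final = models[best]

    out = table[["subject_id"]].copy()
    out["is_train"] = is_train
    out["event60"] = label60
    out["radscore"] = selection.score(final, feats)
    out.to_csv(RES / "radscore.csv", index=False)
    pd.DataFrame(rows).to_csv(RES / "mrmr_ranking.csv", index=False)
    (RES / "radscore_model.json").write_text(
        json.dumps({"best_roi": best, **final.to_json_dict()}, indent=1))
    print(f"wrote {RES/'radscore.csv'}, {RES/'mrmr_ranking.csv'}, "
          f"{RES/'radscore_model.json'}")


if __name__ == "__main__":
    main()
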