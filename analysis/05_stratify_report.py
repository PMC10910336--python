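"""Three-class risk stratification, confusion matrices and KM curves.

Works from results/cohort + results/risk_scores.csv: optimises the two
Youden thresholds on the training cohort's progression-speed labels
(non / slow / fast), classifies every subject into low / medium / high
risk, and writes the confusion matrix with PPVs plus the per-stratum
Kaplan-Meier curve points.  Outputs results/stratification.json and
results/km_curves.csv.

Usage: python analysis/05_stratify_report.py
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from pfradiomics import stratify, survival, synthdata

RES = Path("results")


def main() -> None:
    records, _, _ = synthdata.read_cohort(RES / "cohort/manifest.json")
    table = synthdata.records_to_frame(records)
    rs = pd.read_csv(RES / "risk_scores.csv")
    risk = rs.risk_score.to_numpy()
    is_train = rs.is_train.to_numpy(bool)
    t = table.kr_time_months.to_numpy()
    e = table.kr_event.to_numpy()

    labels = stratify.progression_labels(t, e)
    strata = stratify.optimize_thresholds(risk[is_train], labels[is_train])
    classes = stratify.classify(risk, strata)
    conf = stratify.confusion_and_ppv(classes, labels)
    print(f"thresholds: {strata.t_low:.3f} / {strata.t_high:.3f}")
    print("class counts:", {c: int((classes == c).sum())
                            for c in ("low", "medium", "high")})
    print("confusion (rows low/med/high, cols non/slow/fast):")
    print(conf["matrix"])
    ppv_any = conf["ppv_high_any_progression"]
    ppv_fast = conf["ppv_high_fast_progression"]
    print(f"PPV(high -> any KR by 84 m): "
          f"{'n/a' if ppv_any is None else f'{100 * ppv_any:.1f}%'}")
    print(f"PPV(high -> KR by 30 m):     "
          f"{'n/a' if ppv_fast is None else f'{100 * ppv_fast:.1f}%'}")

    km = survival.km_estimate(t, e, classes)
    rows = []
    for group, curve in km.items():
        print(f"KM S(84 m) {group}: {curve.at(84.0):.3f}")
        for tt, ss, nn in zip(curve.times, curve.survival, curve.at_risk):
            rows.append({"group": group, "time_months": tt,
                         "survival": ss, "at_risk": nn})
    pd.DataFrame(rows).to_csv(RES / "km_curves.csv", index=False)
    (RES / "stratification.json").write_text(json.dumps({
        "t_low": strata.t_low, "t_high": strata.t_high,
        "class_counts": {c: int((classes == c).sum())
                         for c in ("low", "medium", "high")},
        "confusion_matrix": conf["matrix"].tolist(),
        "ppv_high_any_progression": ppv_any,
        "ppv_high_fast_progression": ppv_fast,
        "n_indeterminate": conf["n_indeterminate_excluded"],
        "km_survival_84m": {str(g): c.at(84.0) for g, c in km.items()},
    }, indent=1))
    print(f"wrote {RES/'stratification.json'}, {RES/'km_curves.csv'}")


if __name__ == "__main__":
    main()
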