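#!/usr/bin/env python
"""Transfer the archetype classifier to the cancer-like populations.

Scores every cell of the two blended populations (plus the held-out
archetype test cells) with the four transferred scores, applies the 5.6-SD
outlier rule to the SVM scores, and reports score histograms, ROC/AUC on
the test cells, score-score correlations, blend-tracking validity, and the
representative cells at the score order statistics. Writes tables and
figures under results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from emscore import classify, evaluate


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--features", type=Path, default=Path("results/features.csv"))
    parser.add_argument("--model", type=Path, default=Path("results/em_model.json"))
    parser.add_argument("--test-cells", type=Path, default=Path("results/test_cells.csv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    model = classify.EMModel.from_json(args.model)
    table = pd.read_csv(args.features)
    test = pd.read_csv(args.test_cells)
    cancer = table[~table["line"].isin(["GIE", "HGF"])]

    test_scores = classify.transfer_score(model, test)
    transfer_scores = classify.transfer_score(model, cancer)
    test_scores.to_csv(args.out / "test_scores.csv", index=False)
    transfer_scores.to_csv(args.out / "transfer_scores.csv", index=False)

    for line, sub in transfer_scores.groupby("line"):
        frac_e = (sub["predicted_class"] == "E").mean()
        print(f"{line}: {len(sub)} cells, {100 * frac_e:.1f}% classified "
              f"epithelial, median SVM score {sub.svm_score.median():+.2f}")

    rho = stats.spearmanr(transfer_scores["blend_m"],
                          transfer_scores["svm_score"]).statistic
    print(f"Spearman(blend fraction, SVM score) = {rho:.3f} "
          f"over {len(transfer_scores)} blended cells")

    report = evaluate.evaluate_scores(test_scores, transfer_scores)
    print(f"test-set accuracy by score: "
          f"{ {k: round(v, 4) for k, v in report.accuracy.items()} }")
    print(f"test-set AUC: { {k: round(v, 4) for k, v in report.auc.items()} }")
    print(f"SVM-score outliers excluded (>5.6 SD): {report.excluded_outliers}")

    reps = report.representatives
    for line in ("MCF7", "MDA"):
        if line in reps:
            picks = reps[line][["statistic", "score"]].round(2)
            print(f"{line} representative cells: "
                  + ", ".join(f"{r.statistic}={r.score:+.2f}"
                              for r in picks.itertuples()))
    evaluate_dir = args.out / "report"
    evaluate_dir.mkdir(exist_ok=True)
    from emscore.pipeline import _render_figures

    _render_figures(report, test_scores, transfer_scores, evaluate_dir)
    print(f"figures written under {evaluate_dir}")


if __name__ == "__main__":
    main()
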