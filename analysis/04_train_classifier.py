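#!/usr/bin/env python
"""Train the binary epithelial/mesenchymal archetype classifier.

Partitions the two archetype lines 4:1 (80 held out per line), selects the
number of principal components by repeated-measures ANOVA over repeated
fivefold cross-validation (optional), trains the linear SVM plus the
Platt, AdaBoost and bagged-trees models, and reports training CV accuracy
and held-out test accuracy. Writes the model bundle to
results/em_model.json and the CV table to results/training_report.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from emscore import classify


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--features", type=Path, default=Path("results/features.csv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--select-k", action="store_true",
                        help="run the ANOVA-based component-count selection")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = pd.read_csv(args.features)
    arch = table[table["line"].isin(["GIE", "HGF"])]
    train, test = classify.partition_data(arch, test_n=80, seed=args.seed)
    print(f"training cells: {len(train)} "
          f"(GIE {(train.line == 'GIE').sum()}, HGF {(train.line == 'HGF').sum()}); "
          f"test cells: {len(test)}")

    report = {}
    k = 6
    if args.select_k:
        y = classify.labels_from_lines(train)
        k, sel = classify.select_pc_count(train, y, seed=args.seed)
        print(f"ANOVA across 1..17 components: F = {sel.f_stat:.1f}, "
              f"p = {sel.p_value:.2g}; selected k* = {k}")
        report["pc_selection"] = {
            "k_star": k, "F": sel.f_stat, "p": sel.p_value,
            "mean_accuracy_by_k": dict(zip(
                map(str, sel.candidates), sel.acc_table.mean(axis=0).round(4).tolist())),
        }

    model = classify.train_em_model(train, k=k, seed=args.seed)
    model.to_json(args.out / "em_model.json")
    train.to_csv(args.out / "train_cells.csv", index=False)
    test.to_csv(args.out / "test_cells.csv", index=False)

    y = classify.labels_from_lines(train)
    x = classify.pca_transform(model.pca, train)
    cv = classify.crossvalidate(classify.svm_trainer(), x, y, seed=args.seed)
    scores = classify.transfer_score(model, test)
    acc = float((scores["predicted_class"] == scores["true_class"]).mean())
    print(f"linear SVM, {k} PCs: CV accuracy {100 * cv.mean:.1f}% ± "
          f"{100 * cv.sd:.1f}%; held-out test accuracy {100 * acc:.1f}%")

    report.update({"k_pcs": k, "cv_accuracy_mean": cv.mean, "cv_accuracy_sd": cv.sd,
                   "cv_accuracies": cv.accuracies.tolist(), "test_accuracy": acc})
    (args.out / "training_report.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
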