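#!/usr/bin/env python
"""Step 4: train the Bayesian compound covariate predictor and transfer it.

Fits the predictor on the standardized training cohort with the clustered
labels, estimates the LOOCV misclassification rate, then predicts the
(platform-shifted) validation cohort and scores the predictions against the
simulated ground truth.
"""

import argparse
import json
from pathlib import Path

from sklearn.metrics import balanced_accuracy_score

from fatsig import io as fio
from fatsig.bccp import fit_bccp, loocv_error, predict_bccp, standardize

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    parser.add_argument("--results", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    sig = fio.read_signature(args.results / "signature.json")
    labels = fio.read_labels(args.results / "labels.tsv")

    train_expr = fio.read_expression(args.data / "training_expression.tsv")
    std_train, _ = standardize(train_expr[labels.index])
    model = fit_bccp(std_train, labels, sig)
    loocv = loocv_error(std_train, labels, sig)
    fio.write_model(model, args.results / "model.json")

    val_expr = fio.read_expression(args.data / "validation_1_expression.tsv")
    std_val, _ = standardize(val_expr)
    pred = predict_bccp(model, std_val)
    pred.to_csv(args.results / "validation_predictions.tsv", sep="\t")
    fio.write_labels(pred["label"], args.results / "labels_validation_1.tsv")

    truth = fio.read_labels(args.data / "validation_1_truth_labels.tsv")
    acc = balanced_accuracy_score(truth, pred["label"].loc[truth.index])
    metrics = {"loocv_misclassification": round(loocv, 4),
               "validation_balanced_accuracy": round(float(acc), 4),
               "n_signature_genes": len(model.gene_ids)}
    (args.results / "bccp_metrics.json").write_text(
        json.dumps(metrics, indent=2) + "\n")
    print(json.dumps(metrics, indent=2))


if __name__ == "__main__":
    main()
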