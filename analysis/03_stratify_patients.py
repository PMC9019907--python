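#!/usr/bin/env python
"""Step 3: stratify the training cohort into LR/HR subgroups.

Clusters samples on the signature genes (centered-correlation distance,
complete linkage), cuts the dendrogram into two groups and labels them by
mutation rate. Writes the labels and a subgroup composition summary.
"""

import argparse
from pathlib import Path

import pandas as pd

from fatsig import io as fio
from fatsig.simulate import ANCHOR_GENE
from fatsig.stratify import assign_risk_labels, cluster_samples, cut_two

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    parser.add_argument("--results", type=Path, default=ROOT / "results")
    parser.add_argument("--anchor", default=ANCHOR_GENE)
    args = parser.parse_args()

    expr = fio.read_expression(args.data / "training_expression.tsv")
    clin = fio.read_clinical(args.data / "training_clinical.tsv")
    mut = fio.read_mutations(args.data / "training_mutation.tsv")
    expr, clin, mut, _ = fio.align_cohort(expr, clin, mut)
    sig = fio.read_signature(args.results / "signature.json")

    genes = [g for g in sig.gene_ids if g in expr.index]
    dend = cluster_samples(expr.loc[genes])
    risk = assign_risk_labels(cut_two(dend), mut, expr, args.anchor)
    fio.write_labels(risk.labels, args.results / "labels.tsv")

    rows = []
    for label in ("LR", "HR"):
        idx = risk.labels[risk.labels == label].index
        rows.append({
            "label": label,
            "n": len(idx),
            "pct": round(100.0 * len(idx) / len(risk.labels), 2),
            "mutation_rate": round(float(mut.loc[idx].mean()), 4),
            "anchor_mean": round(float(expr.loc[args.anchor, idx].mean()), 3),
        })
    summary = pd.DataFrame(rows).set_index("label")
    summary.to_csv(args.results / "subgroup_summary.tsv", sep="\t")
    print(f"labeling basis: {risk.labeling_basis}")
    print(summary)


if __name__ == "__main__":
    main()
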