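#!/usr/bin/env python
"""Step 2: derive the anchor-gene signature on the training cohort.

Applies the four selection criteria (fold change, pooled-t p, anchor
correlation, correlation p) to every gene and writes the selected signature
plus the full per-gene statistics table.
"""

import argparse
from pathlib import Path

from fatsig import io as fio
from fatsig.signature import (SelectionThresholds, anchor_correlation,
                              gene_group_stats, select_signature)
from fatsig.simulate import ANCHOR_GENE

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    parser.add_argument("--anchor", default=ANCHOR_GENE)
    args = parser.parse_args()

    expr = fio.read_expression(args.data / "training_expression.tsv")
    clin = fio.read_clinical(args.data / "training_clinical.tsv")
    mut = fio.read_mutations(args.data / "training_mutation.tsv")
    expr, clin, mut, _ = fio.align_cohort(expr, clin, mut)

    sig = select_signature(expr, mut, args.anchor, SelectionThresholds())
    args.out.mkdir(parents=True, exist_ok=True)
    fio.write_signature(sig, args.out / "signature.json")

    stats = gene_group_stats(expr, mut).join(
        anchor_correlation(expr, args.anchor), rsuffix="_anchor")
    stats.to_csv(args.out / "gene_stats.tsv", sep="\t")

    print(f"selected {len(sig)} signature genes "
          f"(of {expr.shape[0]} tested) -> {args.out / 'signature.json'}")


if __name__ == "__main__":
    main()
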