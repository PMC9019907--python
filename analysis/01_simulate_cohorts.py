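#!/usr/bin/env python
"""Step 1: simulate a training + validation cohort pair.

Writes expression, clinical, mutation and ground-truth tables for each cohort
under results/data/. Later steps only ever read the expression/clinical/
mutation files; the truth tables exist so step 4 can score the pipeline.
"""

import argparse
from pathlib import Path

from fatsig import SimulationConfig, simulate_multi_cohort
from fatsig import io as fio

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-cohorts", type=int, default=2)
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "data")
    args = parser.parse_args()

    cfg = SimulationConfig(seed=args.seed, n_cohorts=args.n_cohorts)
    cohorts = simulate_multi_cohort(cfg)

    args.out.mkdir(parents=True, exist_ok=True)
    cfg.to_file(args.out / "simulation.cfg")
    for c in cohorts:
        fio.write_expression(c.expression,
                             args.out / f"{c.name}_expression.tsv")
        fio.write_clinical(c.clinical, args.out / f"{c.name}_clinical.tsv")
        fio.write_mutations(c.mutation, args.out / f"{c.name}_mutation.tsv")
        fio.write_labels(c.truth_labels,
                         args.out / f"{c.name}_truth_labels.tsv")
        print(f"{c.name}: {c.expression.shape[1]} samples, "
              f"{c.expression.shape[0]} genes, "
              f"mutation rate {c.mutation.mean():.3f}")
    (args.out / "truth_genes.txt").write_text(
        "\n".join(cohorts[0].truth_genes) + "\n")
    print(f"wrote {args.n_cohorts} cohorts to {args.out}")


if __name__ == "__main__":
    main()
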