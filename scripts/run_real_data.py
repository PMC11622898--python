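#!/usr/bin/env python
"""Run the full classification benchmark on a real repertoire export.

This is a convenience runner for a TCRdb-style beta-chain export (a
delimited table with `sequence` and `label` columns, ~50k rows, five
cancer-type labels). It is NOT exercised by the test suite: the heaviest
single configuration (support-vector machine on the one-hot encoding)
takes on the order of days of CPU time at full repertoire size.

Usage:
    python scripts/run_real_data.py --input dataset.tsv --out reports/ \
        [--methods tcellr2vec,spike2vec] [--with-tcellr2vec] [--repeats 5]
"""

from __future__ import annotations

import argparse
from pathlib import Path

from tcrembed import EvalConfig, evaluate, read_table
from tcrembed.pipeline import EMBEDDING_METHODS, compute_embedding


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--input", type=Path, required=True)
    parser.add_argument("--out", type=Path, required=True)
    parser.add_argument("--delimiter", default="\t")
    parser.add_argument("--methods", default=",".join(EMBEDDING_METHODS))
    parser.add_argument("--with-tcellr2vec", action="store_true")
    parser.add_argument("--repeats", type=int, default=5)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument(
        "--classifiers", default="SVM,NB,MLP,KNN,RF,LR,DT",
        help="Comma-separated subset; drop SVM for tractable runtimes on OHE.",
    )
    args = parser.parse_args()

    seqs = read_table(args.input, delimiter=args.delimiter)
    args.out.mkdir(parents=True, exist_ok=True)
    cfg = EvalConfig(
        repeats=args.repeats,
        seed=args.seed,
        classifiers=tuple(args.classifiers.split(",")),
    )
    for method in args.methods.split(","):
        emb = compute_embedding(method, seqs, with_features=args.with_tcellr2vec)
        result = evaluate(emb, seqs, cfg)
        name = f"tcellr2vec+{method}" if args.with_tcellr2vec else method
        report = result.summary.copy()
        report.insert(0, "embedding", name)
        path = args.out / f"{name.replace('+', '_')}.csv"
        report.to_csv(path, index=False)
        print(f"{name}: wrote {path}")


if __name__ == "__main__":
    main()
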