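#!/usr/bin/env python
"""Build the 0-or-1 pair indicator matrix and apply the validity filter.

Every unordered pair of DE immune-related lncRNAs becomes a binary feature
per tumor sample (1 iff the first gene's expression exceeds the second's);
pairs whose indicator prevalence falls outside [0.2, 0.8] are near-constant
and removed.  Writes results/pairs.tsv.
"""

import argparse
from pathlib import Path

import irlpair as ir
from irlpair.pairs import write_pairs


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    expr = ir.read_expression(args.cohort / "expression.tsv")
    de_ids = ir.read_gene_list(args.results / "de_irlnc.txt")

    pm = ir.build_pair_matrix(expr, de_ids)
    valid = ir.filter_valid_pairs(pm)
    k = len(de_ids)
    print(f"{k} DE irlncRNAs -> {k * (k - 1) // 2} candidate pairs "
          f"-> {valid.indicators.shape[0]} valid (prevalence in [0.2, 0.8])")
    write_pairs(valid, args.results / "pairs.tsv")
    print(f"written: {args.results}/pairs.tsv")


if __name__ == "__main__":
    main()
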