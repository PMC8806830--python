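#!/usr/bin/env python
"""Screen immune-related lncRNAs and filter to differentially expressed ones.

Reads the cohort fixture, classifies genes by biotype, keeps lncRNAs whose
FPKM correlates with at least one immune gene (|r| > 0.4, p < 0.001 across
tumor samples), and retains those differentially expressed between tumor
and normal (Wilcoxon rank-sum, FDR < 0.01, |log2FC| > 2).  Writes the DE
table and the screened ID list under results/.
"""

import argparse
from pathlib import Path

import irlpair as ir
from irlpair.io import read_annotation


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    expr = ir.read_expression(args.cohort / "expression.tsv")
    ann = read_annotation(args.cohort / "annotation.tsv")
    immune = ir.read_gene_list(args.cohort / "immune_genes.txt")
    lnc_ids, _ = ir.classify_genes(expr, ann)

    de_ids, irlnc_ids, de_table = ir.screen_irlncs(expr, immune, lnc_ids)
    print(f"{len(lnc_ids)} lncRNAs -> {len(irlnc_ids)} immune-related "
          f"-> {len(de_ids)} differentially expressed (DE irlncRNAs)")
    up = (de_table.loc[de_ids, "direction"] == "up").sum()
    print(f"DE direction: {up} up / {len(de_ids) - up} down in tumors")

    args.out.mkdir(parents=True, exist_ok=True)
    de_table.to_csv(args.out / "de_table.tsv", sep="\t")
    (args.out / "de_irlnc.txt").write_text("\n".join(de_ids) + "\n")
    (args.out / "irlnc.txt").write_text("\n".join(irlnc_ids) + "\n")
    print(f"written: {args.out}/de_table.tsv, de_irlnc.txt, irlnc.txt")


if __name__ == "__main__":
    main()
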