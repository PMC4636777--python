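#!/usr/bin/env python
"""Call differentially expressed tags between matched status groups.

Filters low-expression tags (>= 10 reads in enough samples of some group),
TMM-normalizes, estimates a common NB dispersion, runs the two-group exact
test for each pregnant-vs-cyclic contrast within a day and for day contrasts
within a status, applies BH correction, and reports the significant tags
(|log2FC| >= 1, FDR < 0.05) plus Venn relations between contrasts.
"""

import argparse
from pathlib import Path

import pandas as pd

from mirvar.expression_stats import (
    DEParams,
    FilterParams,
    estimate_common_dispersion,
    expression_filter,
    nb_exact_test,
    tmm_normalize,
    venn_sets,
)
from mirvar.reference_io import CountTable, read_sample_sheet

CONTRASTS = [("CD16", "PD16"), ("CD20", "PD20"), ("PD16", "PD20"), ("CD16", "CD20")]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--workdir", type=Path, default=Path("scratch/sim"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--min-reads", type=int, default=10)
    ap.add_argument("--min-samples", type=int, default=2)
    ap.add_argument("--min-lfc", type=float, default=1.0)
    ap.add_argument("--max-fdr", type=float, default=0.05)
    args = ap.parse_args()

    sheet = read_sample_sheet(args.workdir / "sample_sheet.tsv")
    counts = pd.read_csv(args.out_dir / "tag_counts.tsv", sep="\t", index_col=0)
    table = CountTable(counts=counts, groups=sheet.groups)

    filtered = expression_filter(
        table, FilterParams(min_reads=args.min_reads, min_samples=args.min_samples)
    )
    print(f"expression filter: {len(counts)} -> {len(filtered.counts)} tags")
    factors, cpm = tmm_normalize(filtered.counts)
    cpm.to_csv(args.out_dir / "normalized_cpm.tsv", sep="\t")
    phi = estimate_common_dispersion(cpm, filtered.groups)
    print(f"common dispersion estimate: {phi:.4f}")

    de_params = DEParams(min_abs_log2fc=args.min_lfc, max_fdr=args.max_fdr)
    all_res, de_sets = [], {}
    for a, b in CONTRASTS:
        res = nb_exact_test(filtered, a, b, phi, factors=factors, params=de_params)
        res.insert(0, "contrast", f"{b}_vs_{a}")
        all_res.append(res)
        de_sets[f"{b}_vs_{a}"] = set(res.index[res.significant])
        print(f"{b} vs {a}: {int(res.significant.sum())} DE tags "
              f"(log2FC range {res.log2fc.min():.2f}..{res.log2fc.max():.2f})")
    pd.concat(all_res).to_csv(args.out_dir / "differential_expression.tsv", sep="\t")

    venn = venn_sets({k: de_sets[k] for k in list(de_sets)[:3]})
    with open(args.out_dir / "de_venn.tsv", "w") as fh:
        fh.write("region\tcount\n")
        for region, count in sorted(venn.items()):
            fh.write(f"{'&'.join(region)}\t{count}\n")


if __name__ == "__main__":
    main()
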