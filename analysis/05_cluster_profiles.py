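#!/usr/bin/env python
"""Cluster expression profiles across the study groups.

Builds mean-centered log2(CPM+1) group-mean profiles for the tags kept by
the expression filter, runs Pearson-distance average-linkage hierarchical
clustering (merge list written as TSV) and SOTA partitioning into a fixed
number of expression-pattern clusters.
"""

import argparse
from pathlib import Path

import pandas as pd

from mirvar.clustering import SotaParams, group_mean_profiles, hcl, pearson_distance, sota
from mirvar.reference_io import read_sample_sheet


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--workdir", type=Path, default=Path("scratch/sim"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--k", type=int, default=7)
    ap.add_argument("--seed", type=int, default=17)
    args = ap.parse_args()

    sheet = read_sample_sheet(args.workdir / "sample_sheet.tsv")
    cpm = pd.read_csv(args.out_dir / "normalized_cpm.tsv", sep="\t", index_col=0)
    profiles = group_mean_profiles(cpm, sheet.groups)
    profiles = profiles[profiles.std(axis=1) > 0]
    print(f"clustering {len(profiles)} non-constant profiles over {list(profiles.columns)}")

    d = pearson_distance(profiles)
    merges = hcl(d)
    merges.to_csv(args.out_dir / "hcl_merges.tsv", sep="\t", index=False)

    k = min(args.k, len(profiles))
    res = sota(profiles, SotaParams(max_clusters=k, rng_seed=args.seed))
    out = res.labels.rename("cluster").to_frame()
    out.index.name = "tag_id"
    out.to_csv(args.out_dir / "sota_clusters.tsv", sep="\t")
    print("SOTA cluster sizes:")
    print(res.labels.value_counts().sort_index().to_string())


if __name__ == "__main__":
    main()
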