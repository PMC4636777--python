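"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates an adapter-ligated small-RNA library: mature miRNAs
embedded in random hairpins, reads drawn as template length variants (5'/3'
ADD/DEL into or out of the flanking hairpin sequence) with the 3' sequencing
adapter appended and per-base Phred qualities, plus group-structured
negative-binomial count matrices with planted fold changes.  Every emitted
insert is an exact substring of its parent hairpin, and every read carries a
recoverable truth label (parent, end modifications, category).

Default modification proportions are informed by observed isomiR populations
in small RNA-seq data: ~70% of modified variants touch only the 3' end,
deletions outnumber additions at both ends, single-base changes dominate,
and 5' changes are never longer than 2 nt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference_io import CountTable, MatureLocus, MiRNAReference

CATEGORY_KEYS = ("none", "3p_only", "5p_only", "both")

#: standard Illumina small-RNA 3' adapter, a documented placeholder default;
#: real runs must supply the kit's own adapter sequence.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class SimConfig:
    rng_seed: int = 0
    n_mirnas: int = 50
    hairpin_len: int = 80
    mature_len: int = 22
    # proportions of read modification categories
    mod_distribution: dict[str, float] = field(
        default_factory=lambda: {"none": 0.30, "3p_only": 0.48, "5p_only": 0.07, "both": 0.15}
    )
    # probability that a modified end is a deletion (rest: addition)
    del_vs_add: dict[str, float] = field(default_factory=lambda: {"3p": 0.66, "5p": 0.71})
    # modification-size distributions per end (5' changes observed <= 2 nt)
    size_distribution_3p: dict[int, float] = field(
        default_factory=lambda: {1: 0.44, 2: 0.25, 3: 0.15, 4: 0.08, 5: 0.05, 6: 0.03}
    )
    size_distribution_5p: dict[int, float] = field(default_factory=lambda: {1: 0.80, 2: 0.20})
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 40
    # per-base quality model: truncated Gaussian
    quality_mean: float = 36.0
    quality_sd: float = 3.0
    quality_min: int = 2
    # fraction of reads given one deliberately low-quality base (exercises
    # the strict per-base quality gate)
    low_quality_read_rate: float = 0.01
    # count-matrix model
    nb_mean_range: tuple[float, float] = (20.0, 1000.0)
    dispersion: float = 0.05
    de_fraction: float = 0.10
    planted_abs_lfc: float = 2.0

    def __post_init__(self) -> None:
        for dist in (self.mod_distribution, self.size_distribution_3p, self.size_distribution_5p):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError("probability map must sum to 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.mature_len >= self.hairpin_len:
            raise ValueError("mature_len must be smaller than hairpin_len")


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def make_reference(config: SimConfig, rng: np.random.Generator | None = None) -> MiRNAReference:
    """Random hairpins, each with one embedded mature at a recorded locus.

    Matures have pairwise distinct seeds (positions 2-8); each mature occurs
    exactly once across all hairpins, with at least 6 nt of flank on both
    sides so that template additions up to 6 nt always exist.
    """
    rng = rng or np.random.default_rng(config.rng_seed)
    flank = 6
    max_start = config.hairpin_len - config.mature_len - flank
    if max_start < flank:
        raise ValueError("hairpin too short for the mature plus flanks")
    ref = MiRNAReference()
    seeds: set[str] = set()
    for i in range(config.n_mirnas):
        for _ in range(1000):
            mature = _random_seq(rng, config.mature_len)
            if mature[1:8] not in seeds:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not draw a mature with a fresh seed")
        seeds.add(mature[1:8])
        name = f"sim-miR-{i + 1}"
        hname = f"sim-mir-{i + 1}"
        for _ in range(1000):
            start = int(rng.integers(flank, max_start + 1))
            hairpin = (
                _random_seq(rng, start)
                + mature
                + _random_seq(rng, config.hairpin_len - start - config.mature_len)
            )
            # the mature must occur once here and nowhere in earlier hairpins
            if hairpin.count(mature) == 1 and all(
                mature not in h for h in ref.hairpins.values()
            ) and all(m not in hairpin for m in ref.matures.values()):
                break
        else:  # pragma: no cover
            raise RuntimeError("could not place mature uniquely")
        ref.matures[name] = mature
        ref.mature_species[name] = "sim"
        ref.hairpins[hname] = hairpin
        ref.hairpin_species[hname] = "sim"
        ref.mature_loci[name] = [MatureLocus(hname, start, start + config.mature_len)]
    return ref


def _draw_from(rng: np.random.Generator, dist: dict) -> object:
    keys = list(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=probs))]


def _draw_end(rng: np.random.Generator, end: str, config: SimConfig) -> tuple[str, int]:
    kind = "DEL" if rng.random() < config.del_vs_add[end] else "ADD"
    sizes = config.size_distribution_3p if end == "3p" else config.size_distribution_5p
    return kind, int(_draw_from(rng, sizes))


def simulate_reads(
    reference: MiRNAReference,
    config: SimConfig,
    n_reads: int,
    rng: np.random.Generator | None = None,
    read_prefix: str = "r",
) -> tuple[list[tuple[str, str, list[int]]], pd.DataFrame]:
    """Draw adapter-ligated reads with per-read truth labels.

    Returns (records, truth): records are (read_id, sequence, quality)
    triples; truth has one row per read with the parent mature, end
    modification kinds/sizes and the category.  Requested modifications that
    would leave the hairpin are resampled (bounded retries).
    """
    rng = rng or np.random.default_rng(config.rng_seed)
    names = list(reference.matures)
    records, truth_rows = [], []
    for ridx in range(n_reads):
        name = names[int(rng.integers(len(names)))]
        locus = reference.mature_loci[name][0]
        hairpin = reference.hairpins[locus.hairpin]
        category = str(_draw_from(rng, config.mod_distribution))
        for _ in range(100):
            e5 = ("none", 0)
            e3 = ("none", 0)
            if category in ("5p_only", "both"):
                e5 = _draw_end(rng, "5p", config)
            if category in ("3p_only", "both"):
                e3 = _draw_end(rng, "3p", config)
            start = locus.start + (e5[1] if e5[0] == "DEL" else -e5[1])
            end = locus.end + (e3[1] if e3[0] == "ADD" else -e3[1])
            if 0 <= start < end <= len(hairpin):
                break
        insert = hairpin[start:end]
        read = (insert + config.adapter)[: config.read_length]
        quals = np.clip(
            np.rint(rng.normal(config.quality_mean, config.quality_sd, len(read))),
            config.quality_min,
            41,
        ).astype(int)
        low_quality = rng.random() < config.low_quality_read_rate
        if low_quality:
            quals[int(rng.integers(len(read)))] = int(rng.integers(config.quality_min, 21))
        records.append((f"{read_prefix}{ridx + 1}", read, list(quals)))
        truth_rows.append(
            {
                "read_id": f"{read_prefix}{ridx + 1}",
                "insert": insert,
                "parent": name,
                "category": category,
                "end5_kind": e5[0],
                "end5_n": e5[1],
                "end3_kind": e3[0],
                "end3_n": e3[1],
                "low_quality": low_quality,
            }
        )
    return records, pd.DataFrame(truth_rows)


def write_fastq(records: list[tuple[str, str, list[int]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, quals in records:
            qline = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{rid}\n{seq}\n+\n{qline}\n")


def truth_by_sequence(truth: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-read truth to per-insert-sequence truth.

    Insert sequences generated with conflicting labels (possible only via
    coincidental sequence collisions) are dropped.
    """
    cols = ["parent", "category", "end5_kind", "end5_n", "end3_kind", "end3_n"]
    per_seq = truth.groupby("insert")[cols].nunique()
    consistent = per_seq.index[(per_seq == 1).all(axis=1)]
    out = truth.drop_duplicates("insert").set_index("insert")[cols]
    return out.loc[consistent]


def simulate_counts(
    config: SimConfig,
    group_sizes: dict[str, int],
    n_tags: int,
    de_group: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CountTable, pd.DataFrame]:
    """Group-structured NB counts with planted fold changes.

    Baseline means are log-uniform over ``nb_mean_range``; a ``de_fraction``
    of tags receives a +/- ``planted_abs_lfc`` log2 fold change in
    ``de_group`` (default: the last group).  ``dispersion`` = 0 gives Poisson
    counts.  Returns the count table and per-tag truth (baseline mean and
    planted lfc).
    """
    if len(group_sizes) < 2:
        raise ValueError("need >= 2 groups")
    rng = rng or np.random.default_rng(config.rng_seed)
    groups_order = list(group_sizes)
    de_group = de_group or groups_order[-1]
    lo, hi = config.nb_mean_range
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), n_tags))
    lfc = np.zeros(n_tags)
    n_de = int(round(config.de_fraction * n_tags))
    de_idx = rng.choice(n_tags, size=n_de, replace=False)
    lfc[de_idx] = config.planted_abs_lfc * rng.choice([-1.0, 1.0], size=n_de)

    cols, data, groups = [], [], {}
    for g in groups_order:
        mu = base_mean * (2.0 ** lfc if g == de_group else 1.0)
        for i in range(group_sizes[g]):
            sid = f"{g}_s{i + 1}"
            if config.dispersion <= 0:
                col = rng.poisson(mu)
            else:
                r = 1.0 / config.dispersion
                col = rng.negative_binomial(r, r / (r + mu))
            cols.append(sid)
            data.append(col)
            groups[sid] = g
    counts = pd.DataFrame(
        np.column_stack(data),
        index=[f"tag{i + 1}" for i in range(n_tags)],
        columns=cols,
    )
    truth = pd.DataFrame(
        {"baseline_mean": base_mean, "planted_lfc": lfc}, index=counts.index
    )
    return CountTable(counts=counts, groups=groups), truth
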