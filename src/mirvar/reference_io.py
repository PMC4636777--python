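"""Readers/writers for the formats the pipeline touches and the indexed miRNA reference.

Everything is stored internally in the DNA alphabet (U -> T); RNA letters
are rendered only in human-facing display names.  Coordinates are 0-based,
half-open throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

_DNA = set("ACGT")


class FastqParseError(ValueError):
    """Raised for a malformed FASTQ record; message names the record index."""


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA to the internal DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Render an internal DNA-alphabet sequence as RNA (T -> U)."""
    return seq.upper().replace("T", "U")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, list[int]]]:
    """Stream (read_id, sequence, quality) from a Phred+33 FASTQ file.

    Yields records in file order; quality scores are integers.  A malformed
    record (missing header, sequence/quality length mismatch) raises
    :class:`FastqParseError` naming the 0-based record index.
    """
    with open(path) as handle:
        idx = -1
        try:
            for idx, rec in enumerate(SeqIO.parse(handle, "fastq")):
                quals = rec.letter_annotations["phred_quality"]
                yield rec.id, str(rec.seq).upper(), list(quals)
        except ValueError as exc:
            # the failure happened while fetching the record after the last
            # yielded one; report its 1-based index
            raise FastqParseError(f"malformed FASTQ record at index {idx + 2}: {exc}") from exc


@dataclass(frozen=True)
class MatureLocus:
    """Placement of a mature miRNA inside a hairpin (0-based, half-open)."""

    hairpin: str
    start: int
    end: int


@dataclass
class MiRNAReference:
    """Mature and hairpin sequences with mature-in-hairpin coordinates.

    The annotation universe: exact-identity matching of collapsed tags is
    performed against these sequences.  ``mature_loci`` maps a mature name to
    every exact occurrence of that mature inside a same-species hairpin; a
    mature absent from all hairpins has an empty locus list and is usable for
    canonical matching only.
    """

    matures: dict[str, str] = field(default_factory=dict)
    mature_species: dict[str, str] = field(default_factory=dict)
    hairpins: dict[str, str] = field(default_factory=dict)
    hairpin_species: dict[str, str] = field(default_factory=dict)
    mature_loci: dict[str, list[MatureLocus]] = field(default_factory=dict)

    def matures_of_species(self, species: str) -> dict[str, str]:
        return {n: s for n, s in self.matures.items() if self.mature_species[n] == species}

    def validate(self) -> None:
        for name, loci in self.mature_loci.items():
            seq = self.matures[name]
            for loc in loci:
                if self.hairpins[loc.hairpin][loc.start : loc.end] != seq:
                    raise ValueError(f"locus of {name} does not reproduce its sequence")


def _species_of(name: str) -> str:
    return name.split("-", 1)[0] if "-" in name else ""


def _parse_fasta_named(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id  # first whitespace-delimited header token
        if name in out:
            raise ValueError(f"duplicate FASTA name: {name}")
        seq = normalize_seq(str(rec.seq))
        bad = set(seq) - _DNA
        if bad:
            raise ValueError(f"{name}: non-ACGU/T characters {sorted(bad)}")
        out[name] = seq
    return out


def find_occurrences(needle: str, haystack: str) -> list[int]:
    """All start positions of exact occurrences of ``needle`` in ``haystack``."""
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def load_reference(
    mature_fasta: str | Path,
    hairpin_fasta: str | Path,
    species_prefixes: list[str] | None = None,
) -> MiRNAReference:
    """Build the indexed reference from miRBase-style mature/hairpin FASTA.

    Mature loci are computed by exact substring search of each mature in
    hairpins of the same species prefix (the token before the first ``-``
    in the name, e.g. ``ssc``).  Every exact occurrence is retained.
    """
    matures = _parse_fasta_named(mature_fasta)
    hairpins = _parse_fasta_named(hairpin_fasta)
    ref = MiRNAReference(
        matures=matures,
        mature_species={n: _species_of(n) for n in matures},
        hairpins=hairpins,
        hairpin_species={n: _species_of(n) for n in hairpins},
    )
    if species_prefixes is not None:
        known = set(ref.mature_species.values()) | set(ref.hairpin_species.values())
        missing = set(species_prefixes) - known
        if missing:
            warnings.warn(f"species prefixes absent from reference: {sorted(missing)}")
    by_species: dict[str, list[str]] = {}
    for hname, sp in ref.hairpin_species.items():
        by_species.setdefault(sp, []).append(hname)
    for mname, mseq in matures.items():
        loci = []
        for hname in by_species.get(ref.mature_species[mname], []):
            for start in find_occurrences(mseq, hairpins[hname]):
                loci.append(MatureLocus(hname, start, start + len(mseq)))
        if not loci:
            logger.warning("mature %s not found in any same-species hairpin (locus-less)", mname)
        ref.mature_loci[mname] = loci
    return ref


def write_reference(ref: MiRNAReference, mature_fasta: str | Path, hairpin_fasta: str | Path) -> None:
    with open(mature_fasta, "w") as fh:
        for name, seq in ref.matures.items():
            fh.write(f">{name}\n{seq}\n")
    with open(hairpin_fasta, "w") as fh:
        for name, seq in ref.hairpins.items():
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# collapsed unique tags


def write_collapsed_fasta(tags: Iterable, path: str | Path) -> None:
    """Write unique tags as FASTA with headers ``>{tag_id}_x{total_count}``."""
    with open(path, "w") as fh:
        for tag in tags:
            fh.write(f">{tag.tag_id}_x{tag.total}\n{tag.sequence}\n")


def read_collapsed_fasta(path: str | Path) -> list[tuple[str, int, str]]:
    """Read back (tag_id, total_count, sequence) triples."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tag_id, _, count = rec.id.rpartition("_x")
        out.append((tag_id, int(count), str(rec.seq).upper()))
    return out


# ---------------------------------------------------------------------------
# count tables and sample sheets


@dataclass
class CountTable:
    """Tags x samples integer counts with per-sample group labels."""

    counts: pd.DataFrame  # index: tag ids, columns: sample ids
    groups: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def tag_ids(self) -> list[str]:
        return list(self.counts.index)

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]


def write_count_table(table: CountTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.index.name = "tag_id"
    df.to_csv(path, sep="\t")


def read_count_table(path: str | Path, groups: dict[str, str]) -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountTable(counts=df, groups=groups)


@dataclass
class SampleSheet:
    """Library -> group mapping (group encodes reproductive status x day, e.g. CD12/PD16)."""

    samples: list[tuple[str, str, str]]  # (sample_id, fastq_path, group)

    def __post_init__(self) -> None:
        ids = [s[0] for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample ids in sample sheet")

    @property
    def groups(self) -> dict[str, str]:
        return {sid: grp for sid, _, grp in self.samples}

    @property
    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for _, _, grp in self.samples:
            sizes[grp] = sizes.get(grp, 0) + 1
        return sizes


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a sample sheet from TSV (sample_id/fastq_path/group columns) or YAML."""
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        with open(path) as fh:
            data = yaml.safe_load(fh)
        rows = [(d["sample_id"], d.get("fastq_path", ""), d["group"]) for d in data["samples"]]
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        rows = [
            (r["sample_id"], r.get("fastq_path", "") or "", r["group"])
            for _, r in df.iterrows()
        ]
    return SampleSheet(samples=rows)
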