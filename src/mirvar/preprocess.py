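"""Read cleaning for small RNA libraries.

The chain is: per-base Phred quality gate, 3' adapter detection and
trimming, length/ambiguity filter, then collapsing of identical inserts
into unique tags with per-sample counts.  The quality gate is strict
(every base must exceed ``min_phred``); reads in which no adapter can be
located are discarded, since an insert boundary cannot be established.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

_DNA = set("ACGT")


@dataclass
class PreprocessParams:
    adapter: str
    min_phred: int = 20
    min_adapter_overlap: int = 8
    max_adapter_mismatch_rate: float = 0.1
    min_len: int = 17

    def __post_init__(self) -> None:
        if not self.adapter:
            raise ValueError("adapter sequence must be non-empty")
        if self.min_phred < 0:
            raise ValueError("min_phred must be >= 0")
        if not (0 <= self.max_adapter_mismatch_rate < 0.5):
            raise ValueError("mismatch rate must be in [0, 0.5)")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        self.adapter = self.adapter.upper().replace("U", "T")


@dataclass
class UniqueTag:
    """A collapsed insert sequence with per-sample read counts."""

    tag_id: str
    sequence: str
    per_sample_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.per_sample_counts.values())


def quality_filter(quality: list[int], min_phred: int = 20) -> bool:
    """Keep a read iff every base quality strictly exceeds ``min_phred``.

    Empty reads are discarded.
    """
    return len(quality) > 0 and min(quality) > min_phred


def find_and_trim_adapter(sequence: str, params: PreprocessParams) -> str | None:
    """Locate the leftmost qualifying 3' adapter match and return the insert.

    A qualifying match aligns an adapter prefix of at least
    ``min_adapter_overlap`` bases (the prefix may be shortened where it runs
    off the 3' end of the read) with a mismatch rate at most
    ``max_adapter_mismatch_rate``.  Returns the sequence upstream of the
    match, or ``None`` when no position qualifies.
    """
    seq = sequence.upper()
    adapter = params.adapter
    n, k = len(seq), len(adapter)
    for start in range(0, n - params.min_adapter_overlap + 1):
        aligned = min(k, n - start)
        mism = sum(1 for a, b in zip(seq[start : start + aligned], adapter) if a != b)
        if mism <= params.max_adapter_mismatch_rate * aligned:
            return seq[:start]
    return None


def length_ambiguity_filter(sequence: str, min_len: int = 17) -> bool:
    """Keep iff the trimmed insert is >= min_len and contains only A/C/G/T."""
    return len(sequence) >= min_len and set(sequence) <= _DNA


def collapse(valid_reads_per_sample: Mapping[str, Iterable[str]]) -> list[UniqueTag]:
    """Collapse identical insert sequences across samples into unique tags.

    One tag per distinct sequence; per-sample counts are conserved.  Tags are
    ordered by descending total count, then lexicographic sequence, and named
    ``tag1``, ``tag2``, ...
    """
    counts: dict[str, dict[str, int]] = {}
    for sample, reads in valid_reads_per_sample.items():
        for seq in reads:
            per = counts.setdefault(seq, {})
            per[sample] = per.get(sample, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-sum(kv[1].values()), kv[0]))
    return [
        UniqueTag(tag_id=f"tag{i + 1}", sequence=seq, per_sample_counts=per)
        for i, (seq, per) in enumerate(ordered)
    ]


def preprocess_reads(
    records: Iterable[tuple[str, str, list[int]]], params: PreprocessParams
) -> tuple[list[str], dict[str, int]]:
    """Run the filter chain on one library; return valid inserts and tallies.

    Tally keys mirror the chain: raw >= pass_quality >= adapter_found >= valid.
    """
    tally = {"raw": 0, "pass_quality": 0, "adapter_found": 0, "valid": 0}
    inserts: list[str] = []
    for _rid, seq, quals in records:
        tally["raw"] += 1
        if not quality_filter(quals, params.min_phred):
            continue
        tally["pass_quality"] += 1
        insert = find_and_trim_adapter(seq, params)
        if insert is None:
            continue
        tally["adapter_found"] += 1
        if not length_ambiguity_filter(insert, params.min_len):
            continue
        tally["valid"] += 1
        inserts.append(insert)
    return inserts, tally


def run_preprocess(
    records_per_sample: Mapping[str, Iterable[tuple[str, str, list[int]]]],
    params: PreprocessParams,
    groups: Mapping[str, str] | None = None,
) -> tuple[list[UniqueTag], pd.DataFrame]:
    """Preprocess every library and collapse; return tags and the report.

    The report has one row per sample with the chain tallies plus the number
    of unique tags observed in that sample; when ``groups`` is given, pooled
    per-group rows are appended (the same chain tallies summed over the
    group's libraries, with unique tags counted over the pooled group).
    """
    valid: dict[str, list[str]] = {}
    rows: dict[str, dict[str, int]] = {}
    for sample, records in records_per_sample.items():
        inserts, tally = preprocess_reads(records, params)
        valid[sample] = inserts
        rows[sample] = tally
    tags = collapse(valid)
    for sample in rows:
        rows[sample]["unique_tags"] = sum(
            1 for t in tags if t.per_sample_counts.get(sample, 0) > 0
        )
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.index.name = "sample"
    if groups:
        grp_rows = {}
        for grp in dict.fromkeys(groups.values()):
            members = [s for s in rows if groups.get(s) == grp]
            agg = {
                k: sum(rows[s][k] for s in members)
                for k in ("raw", "pass_quality", "adapter_found", "valid")
            }
            agg["unique_tags"] = sum(
                1 for t in tags if any(t.per_sample_counts.get(s, 0) > 0 for s in members)
            )
            grp_rows[f"group:{grp}"] = agg
        report = pd.concat([report, pd.DataFrame.from_dict(grp_rows, orient="index")])
    return tags, report


def tags_to_count_frame(tags: list[UniqueTag], sample_ids: list[str]) -> pd.DataFrame:
    """Tag x sample integer count matrix (zeros where a tag was unseen)."""
    data = {
        t.tag_id: [t.per_sample_counts.get(s, 0) for s in sample_ids] for t in tags
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=sample_ids).astype(int)
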