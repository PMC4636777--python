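"""Seed-match target-site scanning on 3'UTRs.

Canonical site types, in increasing efficacy: 6mer (Watson-Crick match to
miRNA positions 2-7), 7mer-A1 (6mer plus an A opposite miRNA position 1),
7mer-m8 (6mer plus a match to position 8) and 8mer (both).  Each 6mer core
occurrence on a UTR is reported once, at its highest-ranked type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .isomir_annotate import extract_seed  # re-exported convenience
from .reference_io import normalize_seq

__all__ = [
    "SeedSite", "SITE_RANK", "revcomp", "scan_sites", "target_set",
    "compare_canonical_vs_isomir", "extract_seed",
]

SITE_RANK = {"6mer": 0, "7mer-A1": 1, "7mer-m8": 2, "8mer": 3}

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SeedSite:
    utr_id: str
    position: int  # 0-based start of the full matched site on the UTR
    site_type: str
    seed_used: str  # the miRNA's 7-nt seed (positions 2-8)


def scan_sites(utr_sequence: str, mirna_sequence: str, utr_id: str = "utr") -> list[SeedSite]:
    """All seed-match sites of a miRNA on one UTR, each at its highest type.

    The UTR is scanned for the reverse complement of miRNA positions 2-7
    (the 6mer core); a match to the complement of position 8 immediately 5'
    of the core upgrades to 7mer-m8, an A immediately 3' (opposite position
    1) upgrades to 7mer-A1, and both give an 8mer.  Ambiguous bases never
    match.
    """
    utr = normalize_seq(utr_sequence)
    mir = normalize_seq(mirna_sequence)
    if len(mir) < 8:
        raise ValueError("miRNA must be >= 8 nt")
    core6 = revcomp(mir[1:7])
    m8 = mir[7].translate(_COMP)
    seed = extract_seed(mir)
    sites = []
    i = utr.find(core6)
    while i != -1:
        has_m8 = i >= 1 and utr[i - 1] == m8
        has_a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        if has_m8 and has_a1:
            stype, pos = "8mer", i - 1
        elif has_m8:
            stype, pos = "7mer-m8", i - 1
        elif has_a1:
            stype, pos = "7mer-A1", i
        else:
            stype, pos = "6mer", i
        sites.append(SeedSite(utr_id, pos, stype, seed))
        i = utr.find(core6, i + 1)
    return sites


def target_set(
    utrs: Mapping[str, str], mirna_sequence: str, min_site_type: str = "7mer-A1"
) -> set[str]:
    """UTR ids with at least one site at or above the given type rank."""
    if min_site_type not in SITE_RANK:
        raise ValueError(f"unknown site type {min_site_type!r}")
    threshold = SITE_RANK[min_site_type]
    hits = set()
    for uid, seq in utrs.items():
        if any(SITE_RANK[s.site_type] >= threshold for s in scan_sites(seq, mirna_sequence, uid)):
            hits.add(uid)
    return hits


def compare_canonical_vs_isomir(
    utrs: Mapping[str, str],
    canonical_seq: str,
    shift5: int = 1,
    min_site_type: str = "7mer-A1",
) -> dict[str, int]:
    """Venn comparison of target sets of a miRNA and its 5'-shifted isomiR.

    The isomiR is formed by deleting ``shift5`` leading bases, which shifts
    the seed window and hence the recognized site repertoire.  Returns counts
    for only_canonical / common / only_isomir.
    """
    canonical_seq = normalize_seq(canonical_seq)
    if shift5 < 1:
        raise ValueError("shift5 must be >= 1")
    if shift5 >= len(canonical_seq) - 7:
        raise ValueError("5' shift leaves no complete seed")
    isomir_seq = canonical_seq[shift5:]
    t_can = target_set(utrs, canonical_seq, min_site_type)
    t_iso = target_set(utrs, isomir_seq, min_site_type)
    return {
        "only_canonical": len(t_can - t_iso),
        "common": len(t_can & t_iso),
        "only_isomir": len(t_iso - t_can),
    }
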