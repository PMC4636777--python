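"""Exact-match annotation of unique tags and template isomiR classification.

A tag is annotated by a cascade of 100%-identity checks: (1) equality with a
primary-species mature sequence -> canonical; (2) full-length exact substring
of a primary-species hairpin whose interval overlaps a mature locus ->
template isomiR of that mature, with 5'/3' ADD/DEL calls derived from the
offsets between the tag interval and the mature locus; (3) equality with a
mature of another species -> mammalian canonical; otherwise unannotated.
Tags whose hairpin placements overlap loci of more than one distinct mature
name are ambiguous and excluded from isomiR statistics.

Only template variants are modelled: every isomiR here is an exact substring
of its parent hairpin.  Non-template 3' tailing is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .reference_io import MiRNAReference, find_occurrences, to_rna

logger = logging.getLogger(__name__)

CATEGORIES = (
    "canonical",
    "isomir_3p_only",
    "isomir_5p_only",
    "isomir_both",
    "mammalian_canonical",
    "ambiguous",
    "unannotated",
)

#: modification sizes above this are still classified but flagged
MAX_REPORTED_MOD_SIZE = 6


@dataclass(frozen=True)
class EndMod:
    """Template modification at one end: ADD/DEL of ``n`` bases (or none)."""

    kind: str = "none"  # ADD | DEL | none
    n: int = 0
    bases: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("ADD", "DEL", "none"):
            raise ValueError(f"bad end-modification kind {self.kind!r}")
        if (self.kind == "none") != (self.n == 0):
            raise ValueError("n must be >= 1 exactly when kind != none")


NO_MOD = EndMod()


@dataclass
class IsomiRAnnotation:
    tag_id: str
    sequence: str
    parent_mature: str | None
    category: str
    end5: EndMod = NO_MOD
    end3: EndMod = NO_MOD
    template: bool = False
    seed: str | None = None
    display_name: str | None = None
    oversize: bool = False  # any end modification larger than MAX_REPORTED_MOD_SIZE


def extract_seed(sequence: str) -> str:
    """The 7-nt seed: positions 2-8 (1-based, inclusive) of the sequence."""
    if len(sequence) < 8:
        raise ValueError(f"sequence shorter than 8 nt has no seed: {sequence!r}")
    return sequence[1:8]


def classify_offsets(
    tag_interval: tuple[int, int],
    mature_interval: tuple[int, int],
    hairpin_seq: str,
) -> tuple[EndMod, EndMod, str]:
    """Derive 5'/3' ADD/DEL calls from tag-vs-mature intervals on one hairpin.

    With 0-based half-open intervals: a tag starting downstream of the mature
    start lost 5' bases (5' DEL); starting upstream gained hairpin bases
    (5' ADD); the 3' end is symmetric with signs flipped.  The modified bases
    are read off the hairpin.  Non-overlapping intervals are refused.
    """
    ts, te = tag_interval
    ms, me = mature_interval
    if te <= ms or me <= ts:
        raise ValueError("tag and mature intervals do not overlap")
    d5 = ts - ms
    if d5 > 0:
        end5 = EndMod("DEL", d5, hairpin_seq[ms:ts])
    elif d5 < 0:
        end5 = EndMod("ADD", -d5, hairpin_seq[ts:ms])
    else:
        end5 = NO_MOD
    d3 = te - me
    if d3 > 0:
        end3 = EndMod("ADD", d3, hairpin_seq[me:te])
    elif d3 < 0:
        end3 = EndMod("DEL", -d3, hairpin_seq[te:me])
    else:
        end3 = NO_MOD
    if end5.kind == "none" and end3.kind == "none":
        category = "canonical"
    elif end5.kind == "none":
        category = "isomir_3p_only"
    elif end3.kind == "none":
        category = "isomir_5p_only"
    else:
        category = "isomir_both"
    return end5, end3, category


def name_isomir(parent: str, end5: EndMod, end3: EndMod) -> str:
    """Display name in the ``miR-x DEL G`` / ``miR-x 5' DEL U`` style.

    Bases are rendered in the RNA alphabet; for modifications at both ends
    the 5' clause comes first.
    """
    clauses = []
    if end5.kind != "none":
        clauses.append(f"5' {end5.kind} {to_rna(end5.bases)}")
    if end3.kind != "none":
        clauses.append(f"{end3.kind} {to_rna(end3.bases)}")
    if not clauses:
        return parent
    return f"{parent} " + " ".join(clauses)


def annotate_tag(
    tag_id: str,
    sequence: str,
    reference: MiRNAReference,
    primary_species: str,
) -> IsomiRAnnotation:
    """Annotate one collapsed tag through the exact-identity cascade."""
    seq = sequence.upper().replace("U", "T")
    seed = extract_seed(seq) if len(seq) >= 8 else None

    primary = reference.matures_of_species(primary_species)
    canonical_hits = sorted(n for n, s in primary.items() if s == seq)
    if canonical_hits:
        parent = canonical_hits[0]
        return IsomiRAnnotation(
            tag_id, seq, parent, "canonical",
            template=True, seed=seed, display_name=parent,
        )

    # hairpin-context template isomiR search
    placements: list[tuple[str, tuple[int, int], tuple[int, int], str]] = []
    for hname, hseq in reference.hairpins.items():
        if reference.hairpin_species[hname] != primary_species:
            continue
        for start in find_occurrences(seq, hseq):
            tag_iv = (start, start + len(seq))
            for mname, loci in reference.mature_loci.items():
                for loc in loci:
                    if loc.hairpin == hname and loc.start < tag_iv[1] and tag_iv[0] < loc.end:
                        placements.append((mname, tag_iv, (loc.start, loc.end), hname))
    if placements:
        names = {p[0] for p in placements}
        if len(names) > 1:
            return IsomiRAnnotation(tag_id, seq, None, "ambiguous", seed=seed)
        # same mature may occur at several loci (multi-copy miRNA): pick the
        # most parsimonious placement, ties broken by smallest coordinates
        def parsimony(p):
            (_, (ts, te), (ms, me), h) = p
            return (abs(ts - ms) + abs(te - me), h, ts)

        mname, tag_iv, mat_iv, hname = min(placements, key=parsimony)
        end5, end3, category = classify_offsets(tag_iv, mat_iv, reference.hairpins[hname])
        oversize = max(end5.n, end3.n) > MAX_REPORTED_MOD_SIZE
        if oversize:
            logger.warning("tag %s: modification larger than %d nt", tag_id, MAX_REPORTED_MOD_SIZE)
        return IsomiRAnnotation(
            tag_id, seq, mname, category, end5, end3,
            template=True, seed=seed,
            display_name=name_isomir(mname, end5, end3), oversize=oversize,
        )

    other_hits = sorted(
        n for n, s in reference.matures.items()
        if reference.mature_species[n] != primary_species and s == seq
    )
    if other_hits:
        parent = other_hits[0]
        return IsomiRAnnotation(
            tag_id, seq, parent, "mammalian_canonical",
            template=True, seed=seed, display_name=parent,
        )
    return IsomiRAnnotation(tag_id, seq, None, "unannotated", seed=seed)


def annotate_tags(
    tags: Iterable, reference: MiRNAReference, primary_species: str
) -> list[IsomiRAnnotation]:
    return [annotate_tag(t.tag_id, t.sequence, reference, primary_species) for t in tags]


def annotations_to_frame(annotations: Iterable[IsomiRAnnotation]) -> pd.DataFrame:
    rows = [
        {
            "tag_id": a.tag_id,
            "parent": a.parent_mature,
            "category": a.category,
            "end5_kind": a.end5.kind,
            "end5_n": a.end5.n,
            "end5_bases": a.end5.bases,
            "end3_kind": a.end3.kind,
            "end3_n": a.end3.n,
            "end3_bases": a.end3.bases,
            "seed": a.seed,
            "display_name": a.display_name,
        }
        for a in annotations
    ]
    return pd.DataFrame(rows)


_ISOMIR_CATS = ("isomir_3p_only", "isomir_5p_only", "isomir_both")


def summarize_modifications(annotations: Iterable[IsomiRAnnotation]) -> pd.DataFrame:
    """Tidy summary of the isomiR population: site, kind and size breakdowns.

    Percentages by site (3'-only / 5'-only / both) are computed over all
    isomiRs; ADD-vs-DEL percentages per end are computed over isomiRs
    modified at that end (both-end variants count toward both ends); size
    percentages are per end and kind.  Canonical, ambiguous and unannotated
    tags are excluded.  Returns a DataFrame with columns
    (dimension, level, count, percent); empty input yields an empty frame.
    """
    isomirs = [a for a in annotations if a.category in _ISOMIR_CATS]
    cols = ["dimension", "level", "count", "percent"]
    if not isomirs:
        return pd.DataFrame(columns=cols)
    rows = []
    total = len(isomirs)
    for cat, label in (
        ("isomir_3p_only", "3p_only"),
        ("isomir_5p_only", "5p_only"),
        ("isomir_both", "both"),
    ):
        n = sum(1 for a in isomirs if a.category == cat)
        rows.append(("site", label, n, 100.0 * n / total))
    for end_label, getter in (("3p", lambda a: a.end3), ("5p", lambda a: a.end5)):
        mods = [getter(a) for a in isomirs if getter(a).kind != "none"]
        for kind in ("ADD", "DEL"):
            of_kind = [m for m in mods if m.kind == kind]
            pct = 100.0 * len(of_kind) / len(mods) if mods else 0.0
            rows.append((f"kind_{end_label}", kind, len(of_kind), pct))
            for size in range(1, MAX_REPORTED_MOD_SIZE + 1):
                k = sum(1 for m in of_kind if m.n == size)
                pct_k = 100.0 * k / len(of_kind) if of_kind else 0.0
                rows.append((f"size_{end_label}_{kind}", str(size), k, pct_k))
    return pd.DataFrame(rows, columns=cols)


@dataclass
class SeedFamily:
    """Tags sharing an identical 7-nt seed, quantified by summed normalized counts."""

    seed: str
    members: list[str]
    per_sample_normalized_sum: dict[str, float]


def build_seed_families(
    annotations: Iterable[IsomiRAnnotation],
    normalized_counts: pd.DataFrame,
) -> list[SeedFamily]:
    """Group annotated tags by extracted seed and sum normalized counts.

    ``normalized_counts`` is tags x samples (e.g. TMM-adjusted CPM); every
    member tag must be present.  Ambiguous and unannotated tags are excluded.
    Families are ordered by descending total normalized sum.
    """
    by_seed: dict[str, list[str]] = {}
    for a in annotations:
        if a.category in ("ambiguous", "unannotated") or a.seed is None:
            continue
        by_seed.setdefault(a.seed, []).append(a.tag_id)
    families = []
    for seed, members in by_seed.items():
        missing = [m for m in members if m not in normalized_counts.index]
        if missing:
            raise KeyError(f"normalized counts missing for tags {missing}")
        sums = normalized_counts.loc[members].sum(axis=0)
        families.append(SeedFamily(seed, members, sums.to_dict()))
    families.sort(key=lambda f: -sum(f.per_sample_normalized_sum.values()))
    return families


def seed_families_to_frame(families: list[SeedFamily]) -> pd.DataFrame:
    rows = []
    for f in families:
        row: dict = {"seed": f.seed, "n_members": len(f.members), "members": ",".join(f.members)}
        row.update(f.per_sample_normalized_sum)
        rows.append(row)
    return pd.DataFrame(rows)


def rescue_with_newer_reference(
    annotations: list[IsomiRAnnotation],
    tags_by_id: Mapping[str, str],
    newer_reference: MiRNAReference,
    primary_species: str,
) -> list[IsomiRAnnotation]:
    """Second annotation pass for unannotated tags against a newer mature set.

    Mirrors the rescue of canonical-less isomiRs via an updated reference
    release: tags left unannotated by the first pass are re-annotated; any
    improvement replaces the original annotation.
    """
    out = []
    for a in annotations:
        if a.category == "unannotated":
            redo = annotate_tag(a.tag_id, tags_by_id[a.tag_id], newer_reference, primary_species)
            out.append(redo if redo.category != "unannotated" else a)
        else:
            out.append(a)
    return out
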