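import numpy as np
import pandas as pd
import pytest

from mirvar.isomir_annotate import (
    EndMod,
    IsomiRAnnotation,
    annotate_tag,
    build_seed_families,
    classify_offsets,
    extract_seed,
    name_isomir,
    summarize_modifications,
)
from mirvar.reference_io import MatureLocus, MiRNAReference


def _ref_single(hairpin="GGCCAACGTACGTCCGGTTA", mature_iv=(4, 13)):
    """One mature embedded once in one hairpin."""
    s, e = mature_iv
    ref = MiRNAReference(
        matures={"sim-miR-1": hairpin[s:e]},
        mature_species={"sim-miR-1": "sim"},
        hairpins={"sim-mir-1": hairpin},
        hairpin_species={"sim-mir-1": "sim"},
        mature_loci={"sim-miR-1": [MatureLocus("sim-mir-1", s, e)]},
    )
    return ref


class TestExtractSeed:
    def test_canonical_seed_positions_2_to_8(self):
        assert extract_seed("TACCACAGGGT") == "ACCACAG"

    def test_five_prime_shift_moves_the_seed_window(self):
        assert extract_seed("ACCACAGGGT") == "CCACAGG"

    def test_homopolymer(self):
        assert extract_seed("AAAAAAAA") == "AAAAAAA"

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            extract_seed("ACGTACG")


class TestClassifyOffsets:
    HP = "GGTACGTACGTCAGG"  # mature at [2, 12) = TACGTACGTC

    def test_3p_deletion_of_one_base(self):
        end5, end3, cat = classify_offsets((2, 11), (2, 12), self.HP)
        assert (end5.kind, end3.kind, end3.n, end3.bases) == ("none", "DEL", 1, "C")
        assert cat == "isomir_3p_only"

    def test_3p_addition_reads_next_hairpin_base(self):
        end5, end3, cat = classify_offsets((2, 13), (2, 12), self.HP)
        assert (end3.kind, end3.bases) == ("ADD", "A")
        assert cat == "isomir_3p_only"

    def test_5p_deletion_of_leading_base(self):
        end5, end3, cat = classify_offsets((3, 12), (2, 12), self.HP)
        assert (end5.kind, end5.n, end5.bases) == ("DEL", 1, "T")
        assert cat == "isomir_5p_only"

    def test_both_ends(self):
        end5, end3, cat = classify_offsets((1, 13), (2, 12), self.HP)
        assert end5.kind == "ADD" and end3.kind == "ADD"
        assert cat == "isomir_both"

    def test_zero_offsets_are_canonical(self):
        *_, cat = classify_offsets((2, 12), (2, 12), self.HP)
        assert cat == "canonical"

    def test_non_overlap_refused(self):
        with pytest.raises(ValueError, match="overlap"):
            classify_offsets((12, 15), (2, 12), self.HP)


class TestAnnotateTag:
    def test_equal_to_mature_is_canonical(self):
        ref = _ref_single()
        a = annotate_tag("t", ref.matures["sim-miR-1"], ref, "sim")
        assert a.category == "canonical" and a.end5.kind == "none" and a.end3.kind == "none"
        assert a.display_name == "sim-miR-1"

    def test_3p_shift_is_template_isomir(self):
        hp = "GGCCAACGTACGTCCGGTTA"
        ref = _ref_single(hp, (4, 13))
        tag = hp[4:12]  # 3' end shifted by -1
        a = annotate_tag("t", tag, ref, "sim")
        assert a.category == "isomir_3p_only"
        assert (a.end3.kind, a.end3.n) == ("DEL", 1)
        # template property: hairpin substring reproduces the tag
        assert hp[4:12] == a.sequence

    def test_overlap_of_two_matures_is_ambiguous(self):
        hp = "GGTACGTACGTCAGGAT"
        ref = MiRNAReference(
            matures={"sim-miR-a": hp[2:10], "sim-miR-b": hp[5:13]},
            mature_species={"sim-miR-a": "sim", "sim-miR-b": "sim"},
            hairpins={"sim-mir-1": hp},
            hairpin_species={"sim-mir-1": "sim"},
            mature_loci={
                "sim-miR-a": [MatureLocus("sim-mir-1", 2, 10)],
                "sim-miR-b": [MatureLocus("sim-mir-1", 5, 13)],
            },
        )
        a = annotate_tag("t", hp[4:12], ref, "sim")
        assert a.category == "ambiguous" and a.parent_mature is None

    def test_other_species_mature_is_mammalian_canonical(self, tiny_reference):
        a = annotate_tag("t", "GGGGCCCC", tiny_reference, "sim")
        assert a.category == "mammalian_canonical" and a.parent_mature == "hsa-miR-9"

    def test_unmatched_tag_is_unannotated(self, tiny_reference):
        a = annotate_tag("t", "ACACACACACAC", tiny_reference, "sim")
        assert a.category == "unannotated"

    def test_multi_locus_same_mature_is_not_ambiguous(self):
        # the same mature twice in one hairpin (multi-copy miRNA)
        mat = "TACGTACGTC"
        hp = "GG" + mat + "AAAA" + mat + "GG"
        ref = MiRNAReference(
            matures={"sim-miR-1": mat},
            mature_species={"sim-miR-1": "sim"},
            hairpins={"sim-mir-1": hp},
            hairpin_species={"sim-mir-1": "sim"},
            mature_loci={
                "sim-miR-1": [MatureLocus("sim-mir-1", 2, 12), MatureLocus("sim-mir-1", 16, 26)],
            },
        )
        a = annotate_tag("t", mat[:9], ref, "sim")
        assert a.category == "isomir_3p_only" and a.parent_mature == "sim-miR-1"


class TestNaming:
    def test_3p_deletion_name(self):
        assert name_isomir("miR-191-5p", EndMod(), EndMod("DEL", 1, "G")) == "miR-191-5p DEL G"

    def test_5p_deletion_name(self):
        assert name_isomir("miR-140-3p", EndMod("DEL", 1, "T"), EndMod()) == "miR-140-3p 5' DEL U"

    def test_canonical_name_unchanged(self):
        assert name_isomir("miR-21", EndMod(), EndMod()) == "miR-21"

    def test_both_ends_5p_clause_first(self):
        name = name_isomir("miR-1", EndMod("DEL", 1, "T"), EndMod("ADD", 1, "C"))
        assert name == "miR-1 5' DEL U ADD C"


def _fake_ann(i, category, end5=EndMod(), end3=EndMod()):
    return IsomiRAnnotation(f"t{i}", "A" * 20, "m", category, end5, end3, True, "A" * 7)


class TestSummarizeModifications:
    def test_site_percentages_match_independent_tally(self, rng):
        anns = []
        cats = ["isomir_3p_only", "isomir_5p_only", "isomir_both", "canonical"]
        draw = rng.choice(cats, 500, p=[0.5, 0.1, 0.2, 0.2])
        for i, c in enumerate(draw):
            e5 = EndMod("DEL", 1, "A") if c in ("isomir_5p_only", "isomir_both") else EndMod()
            e3 = EndMod("ADD", 2, "CC") if c in ("isomir_3p_only", "isomir_both") else EndMod()
            anns.append(_fake_ann(i, c, e5, e3))
        table = summarize_modifications(anns)
        iso = [a for a in anns if a.category.startswith("isomir")]
        for label, cat in [("3p_only", "isomir_3p_only"), ("5p_only", "isomir_5p_only"), ("both", "isomir_both")]:
            row = table[(table.dimension == "site") & (table.level == label)].iloc[0]
            want = sum(1 for a in iso if a.category == cat)
            assert row["count"] == want
            assert row["percent"] == pytest.approx(100 * want / len(iso))

    def test_all_canonical_gives_empty_summary(self):
        anns = [_fake_ann(i, "canonical") for i in range(5)]
        assert summarize_modifications(anns).empty

    def test_kind_percentages_count_both_end_variants_at_each_end(self):
        anns = [
            _fake_ann(0, "isomir_3p_only", end3=EndMod("DEL", 1, "A")),
            _fake_ann(1, "isomir_3p_only", end3=EndMod("ADD", 1, "C")),
            _fake_ann(2, "isomir_both", EndMod("DEL", 1, "T"), EndMod("DEL", 2, "GG")),
        ]
        table = summarize_modifications(anns)
        del3 = table[(table.dimension == "kind_3p") & (table.level == "DEL")].iloc[0]
        assert del3["count"] == 2 and del3["percent"] == pytest.approx(100 * 2 / 3)
        del5 = table[(table.dimension == "kind_5p") & (table.level == "DEL")].iloc[0]
        assert del5["count"] == 1 and del5["percent"] == 100.0


class TestSeedFamilies:
    def test_shared_seed_sums_member_counts(self):
        # canonical + two 3' isomiRs share the seed; a 5'-shifted isomiR does not
        seq = "TACCACAGGGTAGAACCACGG"
        anns = [
            IsomiRAnnotation("t1", seq, "m", "canonical", seed=extract_seed(seq)),
            IsomiRAnnotation("t2", seq[:-1], "m", "isomir_3p_only", seed=extract_seed(seq[:-1])),
            IsomiRAnnotation("t3", seq[:-2], "m", "isomir_3p_only", seed=extract_seed(seq[:-2])),
            IsomiRAnnotation("t4", seq[1:], "m", "isomir_5p_only", seed=extract_seed(seq[1:])),
        ]
        norm = pd.DataFrame(
            {"s1": [10.0, 5.0, 1.0, 30.0], "s2": [20.0, 2.0, 2.0, 40.0]},
            index=["t1", "t2", "t3", "t4"],
        )
        fams = build_seed_families(anns, norm)
        by_seed = {f.seed: f for f in fams}
        assert set(by_seed) == {"ACCACAG", "CCACAGG"}
        assert sorted(by_seed["ACCACAG"].members) == ["t1", "t2", "t3"]
        assert by_seed["ACCACAG"].per_sample_normalized_sum == {"s1": 16.0, "s2": 24.0}
        assert by_seed["CCACAGG"].per_sample_normalized_sum == {"s1": 30.0, "s2": 40.0}

    def test_disjoint_seeds_give_singleton_families(self, rng):
        anns, data = [], {}
        for i in range(6):
            seq = "".join(rng.choice(list("ACGT"), 20))
            anns.append(IsomiRAnnotation(f"t{i}", seq, "m", "canonical", seed=f"SEED{i:03d}"))
            data[f"t{i}"] = [float(i)]
        norm = pd.DataFrame.from_dict(data, orient="index", columns=["s1"])
        fams = build_seed_families(anns, norm)
        assert len(fams) == 6
        assert all(f.per_sample_normalized_sum["s1"] == float(f.members[0][1:]) for f in fams)

    def test_mass_conservation(self, rng):
        anns = []
        for i in range(40):
            seed = rng.choice(["AAAAAAA", "CCCCCCC", "GGGGGGG"])
            anns.append(IsomiRAnnotation(f"t{i}", "N", "m", "canonical", seed=str(seed)))
        norm = pd.DataFrame(
            rng.uniform(0, 100, (40, 3)),
            index=[f"t{i}" for i in range(40)],
            columns=["s1", "s2", "s3"],
        )
        fams = build_seed_families(anns, norm)
        total_family = sum(sum(f.per_sample_normalized_sum.values()) for f in fams)
        assert total_family == pytest.approx(norm.values.sum())
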