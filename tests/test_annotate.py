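"""Variant consequence classification on toy gene models, translation
against an independent codon-table oracle, and haplotype grouping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from redleaf.annotate import (
    GeneModel,
    annotate_variant,
    group_haplotypes,
    protein_change,
)
from redleaf.toygenes import build_cds, multi_exon_gene, single_exon_gene

#: independent standard-code oracle (distinct from the implementation path)
CODON = {}
_bases = "TCAG"
_aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _aa in enumerate(_aas):
    CODON[_bases[_i // 16] + _bases[(_i // 4) % 4] + _bases[_i % 4]] = _aa


def oracle_translate(cds: str) -> str:
    return "".join(CODON[cds[i : i + 3]] for i in range(0, len(cds) - len(cds) % 3, 3))


class TestCausalVariantReconstructions:
    """The four causal lesions of the colour loci, rebuilt on toy models."""

    def test_exonic_5bp_deletion_is_frameshift(self):
        model, (_, e2s, _) = multi_exon_gene(build_cds(60))
        pos = e2s + 5
        ref = model.seq[pos - 1 : pos + 5]  # anchor + 5 deleted bases
        cons = annotate_variant(model, pos, ref, ref[0])
        assert cons.category == "frameshift"
        assert cons.protein_changes and cons.protein_changes[0].endswith("fs")

    def test_missense_C42Y_and_W52S(self):
        cds = build_cds(special={42: "TGC", 52: "TGG"})
        model = single_exon_gene(cds)
        # codon 42 TGC(Cys) -> TAC(Tyr): G>A at the second codon position
        pos42 = model.cds_start + 41 * 3 + 1
        cons = annotate_variant(model, pos42, "G", "A")
        assert cons.category == "missense"
        assert cons.protein_changes == ("C42Y",)
        # codon 52 TGG(Trp) -> TCG(Ser): G>C
        pos52 = model.cds_start + 51 * 3 + 1
        cons = annotate_variant(model, pos52, "G", "C")
        assert cons.category == "missense"
        assert cons.protein_changes == ("W52S",)

    def test_missense_V134D(self):
        cds = build_cds(special={134: "GTT"})
        model = single_exon_gene(cds)
        pos = model.cds_start + 133 * 3 + 1  # GTT -> GAT
        cons = annotate_variant(model, pos, "T", "A")
        assert cons.category == "missense"
        assert cons.protein_changes == ("V134D",)

    def test_promoter_TA_insertion_at_minus_411(self):
        model = single_exon_gene(build_cds())
        atg = model.cds_start
        pos = atg - 412  # inserted bases land at offset -411
        ref = model.seq[pos - 1]
        cons = annotate_variant(model, pos, ref, ref + "TA")
        assert cons.category == "promoter_indel"
        assert cons.promoter_offset == -411


class TestOtherCategories:
    def test_inframe_deletion(self):
        model = single_exon_gene(build_cds())
        pos = model.cds_start + 9  # codon-aligned 3-bp deletion
        ref = model.seq[pos - 1 : pos + 3]
        cons = annotate_variant(model, pos, ref, ref[0])
        assert cons.category == "inframe_indel"

    def test_synonymous(self):
        cds = build_cds(special={10: "CTC"})
        model = single_exon_gene(cds)
        pos = model.cds_start + 9 * 3 + 2  # CTC -> CTT, both Leu
        cons = annotate_variant(model, pos, "C", "T")
        assert cons.category == "synonymous"

    def test_intron_and_splice_adjacent(self):
        model, (_, e2s, _) = multi_exon_gene(build_cds(60))
        mid_intron = e2s - 20
        assert annotate_variant(model, mid_intron, model.seq[mid_intron - 1], "A" if model.seq[mid_intron-1] != "A" else "G").category == "intronic"
        near = e2s - 1  # one base before the exon start
        base = model.seq[near - 1]
        alt = "A" if base != "A" else "G"
        assert annotate_variant(model, near, base, alt).category == "splice_adjacent"

    def test_intergenic_and_upstream_snv(self):
        model = single_exon_gene(build_cds())
        assert annotate_variant(model, 10, model.seq[9], "A").category == "intergenic"

    def test_ref_mismatch_reports_observed(self):
        model = single_exon_gene(build_cds())
        with pytest.raises(ValueError, match="reference has"):
            annotate_variant(model, model.cds_start, "C", "T")

    def test_indel_left_alignment(self):
        # a deletion in a homopolymer is shifted to its leftmost placement
        cds = build_cds(special={20: "AAA", 21: "AAA"})
        model = single_exon_gene(cds)
        run_start = model.cds_start + 19 * 3  # anchor before the A-run
        late = run_start + 3
        ref = model.seq[late - 1 : late + 1]
        a = annotate_variant(model, late, ref, ref[0])
        b = annotate_variant(model, run_start, model.seq[run_start - 1 : run_start + 1],
                             model.seq[run_start - 1])
        assert a == b


def test_minus_strand_equals_mirrored_plus():
    """Annotating a variant on a minus-strand gene matches annotating its
    reverse complement on the mirrored plus-strand model."""
    comp = str.maketrans("ACGT", "TGCA")
    cds = build_cds(special={42: "TGC"})
    plus = single_exon_gene(cds)
    L = len(plus.seq)
    rc = plus.seq.translate(comp)[::-1]
    minus = GeneModel(
        gene_id="toy-", strand="-",
        exons=((L + 1 - plus.exons[0][1], L + 1 - plus.exons[0][0]),),
        cds_start=L + 1 - plus.cds_end, cds_end=L + 1 - plus.cds_start, seq=rc,
    )
    assert minus.spliced_cds() == plus.spliced_cds()
    pos = plus.cds_start + 41 * 3 + 1
    cons_plus = annotate_variant(plus, pos, "G", "A")
    cons_minus = annotate_variant(minus, L + 1 - pos, "C", "T")
    assert cons_plus.category == cons_minus.category == "missense"
    assert cons_plus.protein_changes == cons_minus.protein_changes == ("C42Y",)


class TestProteinChange:
    def test_identity_and_validation(self):
        cds = build_cds(20)
        assert protein_change(cds, cds) == []
        with pytest.raises(ValueError, match="non-nucleotide"):
            protein_change("ATGXA", "ATGCA")

    def test_random_substitutions_match_oracle(self, rng):
        bases = "ACGT"
        for _ in range(200):
            n = int(rng.integers(5, 60))
            cods = [bases[i] + bases[j] + bases[k] for i, j, k in rng.integers(0, 4, (n, 3))]
            cods = [c if CODON[c] != "*" else "GGA" for c in cods]
            cds = "ATG" + "".join(cods) + "TAA"
            k = int(rng.integers(1, n + 1))  # codon index to mutate (after ATG)
            old = cds[3 * k : 3 * k + 3]
            new = bases[rng.integers(0, 4)] + old[1:]
            if CODON[new] == "*" or new == old:
                continue
            alt = cds[: 3 * k] + new + cds[3 * k + 3 :]
            expected = (
                [] if CODON[new] == CODON[old]
                else [f"{CODON[old]}{k + 1}{CODON[new]}"]
            )
            assert protein_change(cds, alt) == expected

    def test_frameshift_descriptor(self):
        cds = build_cds(30, special={10: "TGG"})
        alt = cds[:27] + cds[32:]  # 5-bp deletion within codons 10-11
        changes = protein_change(cds, alt)
        assert len(changes) == 1 and changes[0].endswith("fs")
        assert changes[0].startswith("W10")


@settings(deadline=None, max_examples=60, derandomize=True)
@given(length=st.integers(1, 9), offset=st.integers(0, 20))
def test_frameshift_predicate_property(length, offset):
    """A CDS-overlapping deletion is a frameshift exactly when its length
    is not a multiple of three."""
    model = single_exon_gene(build_cds(60))
    pos = model.cds_start + 30 + offset
    ref = model.seq[pos - 1 : pos + length]
    cons = annotate_variant(model, pos, ref, ref[0])
    if length % 3:
        assert cons.category == "frameshift"
    else:
        assert cons.category == "inframe_indel"


class TestHaplotypeGrouping:
    def test_identity_and_single_difference(self):
        g = group_haplotypes({"a": "ACGTACGT", "b": "acgtacgt", "c": "ACGTACGT"})
        assert g.n_groups == 1 and set(g.groups[0]) == {"a", "b", "c"}
        g = group_haplotypes({"a": "ACGTACGT", "b": "ACGAACGT"})
        assert g.n_groups == 2
        g = group_haplotypes({"a": "ACGT", "b": "ACGGT"})  # indel also separates
        assert g.n_groups == 2

    def test_ambiguity_flags_multi_homolog(self):
        g = group_haplotypes({"het": "ACRTACGT", "hom": "ACGTACGT"})
        assert g.multi_homolog == frozenset({"het"})
        with pytest.raises(ValueError):
            group_haplotypes({"bad": "ACX!"})
        with pytest.raises(ValueError):
            group_haplotypes({})

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.sampled_from(["ACGT", "ACGA", "ACG", "TCGT"]), min_size=1, max_size=12))
    def test_grouping_is_an_order_invariant_partition(self, seqs):
        named = {f"s{i}": s for i, s in enumerate(seqs)}
        g = group_haplotypes(named)
        members = [x for grp in g.groups for x in grp]
        assert sorted(members) == sorted(named)  # disjoint cover
        reversed_named = dict(reversed(list(named.items())))
        assert group_haplotypes(reversed_named).n_groups == g.n_groups
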