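"""Consequence annotation of candidate-gene variants and amplicon
haplotype grouping.

Classifies SNVs and indels against a single-transcript gene model
(synonymous / missense / frameshift / in-frame indel / promoter indel /
splice-adjacent / intronic / intergenic), reports protein changes in
``C42Y``-style notation, and groups amplicon sequences into exact-identity
haplotype classes, flagging direct-Sanger heterozygotes by their IUPAC
ambiguity codes.

Coordinates are 1-based; indels use the VCF convention (anchored at the
base before the event) and are left-aligned before classification.
Promoter offsets are measured from the A of the start codon: the base
immediately 5' of the ATG is position -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "Consequence",
    "HaplotypeGroups",
    "annotate_variant",
    "protein_change",
    "group_haplotypes",
]

_IUPAC = set("ACGTURYSWKMBDHVN-")
_AMBIGUOUS = set("RYSWKMBDHVN")
_SPLICE_BP = 2


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene model on a reference sequence.

    ``exons`` are sorted, non-overlapping 1-based inclusive genomic
    intervals; ``cds_start``/``cds_end`` bound the coding region in genomic
    coordinates (``cds_start < cds_end`` regardless of strand).  ``seq`` is
    the genomic reference sequence the coordinates refer to.  The spliced
    CDS must be a whole number of codons starting with ATG and ending with
    a stop.
    """

    gene_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        ex = tuple(tuple(map(int, e)) for e in self.exons)
        if any(s > e for s, e in ex):
            raise ValueError("exon start > end")
        if any(ex[i][1] >= ex[i + 1][0] for i in range(len(ex) - 1)):
            raise ValueError("exons must be sorted and non-overlapping")
        object.__setattr__(self, "exons", ex)
        object.__setattr__(self, "seq", self.seq.upper())
        if not (ex[0][0] <= self.cds_start <= self.cds_end <= ex[-1][1]):
            raise ValueError("CDS must lie within the exon span")
        cds = self.spliced_cds()
        if len(cds) % 3 != 0:
            raise ValueError("spliced CDS length is not a multiple of 3")
        if not cds.startswith("ATG"):
            raise ValueError("CDS does not start with ATG")
        if str(Seq(cds[-3:]).translate()) != "*":
            raise ValueError("CDS does not end with a stop codon")

    def coding_positions(self) -> np.ndarray:
        """Genomic positions (ascending) that are part of the CDS."""
        parts = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                parts.append(np.arange(lo, hi + 1))
        return np.concatenate(parts)

    def spliced_cds(self, seq: str | None = None) -> str:
        """CDS on the coding strand, spliced from ``seq`` (default: the
        model's reference sequence)."""
        seq = (seq or self.seq).upper()
        cds = "".join(seq[p - 1] for p in self.coding_positions())
        return str(Seq(cds).reverse_complement()) if self.strand == "-" else cds

    @property
    def atg_position(self) -> int:
        """Genomic position of the A of the start codon."""
        return self.cds_start if self.strand == "+" else self.cds_end

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class Consequence:
    """Structured effect of one variant on one gene model."""

    category: str
    protein_changes: tuple[str, ...] = ()
    promoter_offset: int | None = None
    detail: str = ""


@dataclass(frozen=True)
class HaplotypeGroups:
    """Exact-identity grouping of amplicon sequences.

    ``groups`` lists, per distinct sequence, the ids carrying it (groups
    ordered by size, largest first, then by first appearance); sequences
    containing IUPAC ambiguity codes flag their genotype as carrying
    multiple homologs (direct Sanger reads of a heterozygous template show
    double peaks)."""

    groups: tuple[tuple[str, ...], ...]
    sequences: tuple[str, ...]
    multi_homolog: frozenset[str]

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def _normalize_variant(seq: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Check REF against the reference, trim shared context and left-align
    indels (VCF style: anchored at the base before the event)."""
    ref, alt = ref.upper(), alt.upper()
    observed = seq[pos - 1 : pos - 1 + len(ref)]
    if observed != ref:
        raise ValueError(
            f"REF mismatch at {pos}: variant says {ref!r}, reference has {observed!r}"
        )
    # trim identical trailing bases, then leading bases (keeping an anchor)
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if len(ref) != len(alt):
        if len(ref) > 1 and len(alt) > 1:
            return pos, ref, alt  # complex indel; leave as is
        # pure indel: shift left through repeats
        if len(ref) > len(alt):  # deletion, alt is the anchor base
            allele = ref[1:]
            while pos > 1 and seq[pos - 2] == allele[-1]:
                allele = seq[pos - 2] + allele[:-1]
                pos -= 1
            ref, alt = seq[pos - 1] + allele, seq[pos - 1]
        else:  # insertion
            allele = alt[1:]
            while pos > 1 and seq[pos - 2] == allele[-1]:
                allele = seq[pos - 2] + allele[:-1]
                pos -= 1
            ref, alt = seq[pos - 1], seq[pos - 1] + allele
    return pos, ref, alt


def _alt_coding_sequence(model: GeneModel, pos: int, ref: str, alt: str) -> str | None:
    """Spliced CDS after applying the variant, or None when the edit cannot
    be projected (e.g. a deletion running past the modelled sequence)."""
    seq = model.seq
    new = seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]
    # rebuild exon coordinates on the edited sequence: only positions at or
    # after the edit shift, by the length difference
    shift = len(alt) - len(ref)
    edit_after = pos + len(ref) - 1  # genomic positions > this move by `shift`

    def moved(p: int) -> int:
        return p + shift if p > edit_after else p

    try:
        parts = []
        for s, e in model.exons:
            lo, hi = max(s, model.cds_start), min(e, model.cds_end)
            if lo > hi:
                continue
            lo2 = lo if lo <= pos else moved(lo)
            hi2 = moved(hi)
            parts.append(new[lo2 - 1 : hi2])
        cds = "".join(parts)
    except IndexError:
        return None
    return str(Seq(cds).reverse_complement()) if model.strand == "-" else cds


def protein_change(ref_cds: str, alt_cds: str) -> list[str]:
    """Residue-level description of the difference between two CDSs.

    Substitutions come back as ``<refAA><position><altAA>`` (one entry per
    changed residue); a length change that is not a multiple of three comes
    back as a single ``<refAA><position>fs`` frameshift descriptor anchored
    at the first affected residue.  Identical sequences give ``[]``.
    """
    for name, s in (("ref", ref_cds), ("alt", alt_cds)):
        bad = set(s.upper()) - set("ACGTU")
        if bad:
            raise ValueError(f"non-nucleotide characters in {name} CDS: {sorted(bad)}")
    ref_cds, alt_cds = ref_cds.upper(), alt_cds.upper()
    if len(ref_cds) % 3 != 0:
        raise ValueError("reference CDS length is not a multiple of 3")
    ref_aa = str(Seq(ref_cds).translate())
    if (len(ref_cds) - len(alt_cds)) % 3 != 0:
        alt_aa = str(Seq(alt_cds[: len(alt_cds) - len(alt_cds) % 3]).translate())
        k = next(
            (i for i, (a, b) in enumerate(zip(ref_aa, alt_aa)) if a != b),
            min(len(ref_aa), len(alt_aa)),
        )
        k = min(k, len(ref_aa) - 1)
        return [f"{ref_aa[k]}{k + 1}fs"]
    alt_aa = str(Seq(alt_cds).translate())
    changes = [
        f"{a}{i + 1}{b}" for i, (a, b) in enumerate(zip(ref_aa, alt_aa)) if a != b
    ]
    if len(ref_aa) != len(alt_aa) and not changes:
        changes = [f"{ref_aa[min(len(ref_aa), len(alt_aa)) - 1]}{min(len(ref_aa), len(alt_aa))}del"]
    return changes


def _promoter_offset(model: GeneModel, pos: int, ref: str, alt: str) -> int | None:
    """Offset of the first altered base relative to the A of ATG (-1 is the
    adjacent 5' base); None when the variant is not 5' of the start codon."""
    atg = model.atg_position
    insertion = len(alt) > len(ref)
    if model.strand == "+":
        first = pos + 1 if insertion else pos + (1 if len(ref) > len(alt) else 0)
        if len(ref) == len(alt):
            first = pos
        if first >= atg:
            return None
        return first - atg
    # minus strand: upstream means genomic positions > atg; the 5'-most
    # altered base is the highest genomic coordinate touched
    if len(ref) == len(alt):
        first = pos + len(ref) - 1
    elif insertion:
        first = pos + 1  # inserted bases sit between pos and pos+1
    else:
        first = pos + len(ref) - 1
    if first <= atg:
        return None
    return atg - first


def annotate_variant(
    model: GeneModel,
    pos: int,
    ref: str,
    alt: str,
    promoter_window: int = 2000,
) -> Consequence:
    """Classify one variant against a gene model.

    The variant is checked against the reference, left-normalized, and
    classified by where it falls: CDS SNVs are translated and reported as
    residue-numbered substitutions (or synonymous), CDS indels by length
    modulo 3 (frameshift vs in-frame), indels within ``promoter_window``
    bases 5' of the start codon as promoter indels with a negative offset,
    and the rest as splice-adjacent, intronic or intergenic.
    """
    if promoter_window < 0:
        raise ValueError("promoter_window must be >= 0")
    pos, ref, alt = _normalize_variant(model.seq, pos, ref, alt)
    is_indel = len(ref) != len(alt)
    coding = model.coding_positions()
    coding_set = set(int(p) for p in coding)
    if is_indel:
        if len(ref) > len(alt):  # deletion: bases pos+1 .. pos+len(ref)-1 removed
            affected = set(range(pos + 1, pos + len(ref)))
            touches_cds = bool(affected & coding_set)
        else:  # insertion between pos and pos+1
            touches_cds = pos in coding_set and (pos + 1) in coding_set
        if touches_cds:
            shift = abs(len(ref) - len(alt)) % 3
            category = "frameshift" if shift else "inframe_indel"
            alt_cds = _alt_coding_sequence(model, pos, ref, alt)
            changes: tuple[str, ...] = ()
            if alt_cds is not None:
                try:
                    changes = tuple(protein_change(model.spliced_cds(), alt_cds))
                except ValueError:
                    changes = ()
            return Consequence(category, protein_changes=changes)
        offset = _promoter_offset(model, pos, ref, alt)
        if offset is not None and -offset <= promoter_window:
            return Consequence("promoter_indel", promoter_offset=offset)
    else:
        if pos in coding_set:
            alt_cds = _alt_coding_sequence(model, pos, ref, alt)
            changes = tuple(protein_change(model.spliced_cds(), alt_cds))
            if not changes:
                return Consequence("synonymous")
            return Consequence("missense", protein_changes=changes)
    # non-coding: intron / splice / intergenic
    span = model.span
    first, last = pos, pos + max(len(ref) - 1, 0)
    if span[0] <= first and last <= span[1]:
        in_exon = any(s <= first and last <= e for s, e in model.exons)
        if not in_exon:
            near_boundary = any(
                0 < first - e <= _SPLICE_BP or 0 < s - last <= _SPLICE_BP
                for s, e in model.exons
            )
            return Consequence("splice_adjacent" if near_boundary else "intronic")
    return Consequence("intergenic")


def group_haplotypes(sequences: dict[str, str]) -> HaplotypeGroups:
    """Group amplicon sequences by exact identity (after uppercasing).

    Two groups differ by at least one substitution or indel by
    construction; genotypes whose sequence contains IUPAC ambiguity codes
    are flagged as carrying two or more homologs.
    """
    if not sequences:
        raise ValueError("no sequences to group")
    cleaned: dict[str, str] = {}
    multi = set()
    for gid, seq in sequences.items():
        s = seq.upper().replace("U", "T")
        bad = set(s) - _IUPAC
        if bad:
            raise ValueError(f"sequence {gid!r} has non-IUPAC characters: {sorted(bad)}")
        if set(s) & _AMBIGUOUS:
            multi.add(gid)
        cleaned[gid] = s
    order: dict[str, list[str]] = {}
    for gid, s in cleaned.items():
        order.setdefault(s, []).append(gid)
    ranked = sorted(order.items(), key=lambda kv: (-len(kv[1]), list(cleaned).index(kv[1][0])))
    return HaplotypeGroups(
        groups=tuple(tuple(ids) for _, ids in ranked),
        sequences=tuple(s for s, _ in ranked),
        multi_homolog=frozenset(multi),
    )
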