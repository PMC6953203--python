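"""Synthetic toy gene models for reconstructing the causal lesions.

The study's four causal variants are point lesions whose classification
depends only on local gene structure, so they can be replayed on small
synthetic models: a generic CDS with selected codons overridden, hosted
either in a single exon or split over three exons with two introns.
These are synthetic stand-ins, not the real gene sequences.
"""

from __future__ import annotations

from .annotate import GeneModel

__all__ = ["build_cds", "single_exon_gene", "multi_exon_gene", "causal_variant_set"]


def build_cds(n_codons: int = 140, special: dict[int, str] | None = None) -> str:
    """ATG + alanine filler + stop, with 1-based codon overrides."""
    codons = ["GCT"] * n_codons
    codons[0] = "ATG"
    codons[-1] = "TAA"
    for pos, cod in (special or {}).items():
        codons[pos - 1] = cod
    return "".join(codons)


def single_exon_gene(cds: str, upstream: int = 500, downstream: int = 100) -> GeneModel:
    seq = "T" * upstream + cds + "G" * downstream
    return GeneModel(
        gene_id="toy1",
        strand="+",
        exons=((upstream + 1, upstream + len(cds)),),
        cds_start=upstream + 1,
        cds_end=upstream + len(cds),
        seq=seq,
    )


def multi_exon_gene(cds: str, upstream: int = 450) -> tuple[GeneModel, tuple[int, int, int]]:
    """CDS split over three exons (33 / 60 / rest nt) with two introns;
    returns the model and the genomic start of each exon."""
    p1, p2, p3 = cds[:33], cds[33:93], cds[93:]
    intron1 = "GTAAGT" + "C" * 38 + "TTTTAG"
    intron2 = "GTAAGT" + "A" * 28 + "TTTTAG"
    seq = "T" * upstream + p1 + intron1 + p2 + intron2 + p3 + "G" * 60
    e1 = (upstream + 1, upstream + 33)
    e2s = e1[1] + len(intron1) + 1
    e2 = (e2s, e2s + 59)
    e3s = e2[1] + len(intron2) + 1
    e3 = (e3s, e3s + len(p3) - 1)
    model = GeneModel(
        gene_id="toy3x",
        strand="+",
        exons=(e1, e2, e3),
        cds_start=e1[0],
        cds_end=e3[1],
        seq=seq,
    )
    return model, (e1[0], e2[0], e3[0])


def causal_variant_set() -> list[dict]:
    """The four causal lesions rebuilt on toy models: gene label, model,
    VCF-style variant and the expected consequence."""
    fs_model, (_, e2s, _) = multi_exon_gene(build_cds(60))
    pos = e2s + 2
    ref = fs_model.seq[pos - 1 : pos + 5]
    out = [
        {
            "label": "bHLH activator: 5-bp deletion in an internal exon",
            "model": fs_model, "pos": pos, "ref": ref, "alt": ref[0],
            "expect": "frameshift",
        }
    ]
    mis_model = single_exon_gene(build_cds(special={42: "TGC", 52: "TGG", 134: "GTT"}))
    for pos_off, ref, alt, change in (
        (41 * 3 + 1, "G", "A", "C42Y"),  # TGC (Cys) -> TAC (Tyr)
        (51 * 3 + 1, "G", "C", "W52S"),  # TGG (Trp) -> TCG (Ser)
        (133 * 3 + 1, "T", "A", "V134D"),  # GTT (Val) -> GAT (Asp)
    ):
        out.append(
            {
                "label": f"missense {change}",
                "model": mis_model, "pos": mis_model.cds_start + pos_off,
                "ref": ref, "alt": alt, "expect": f"missense {change}",
            }
        )
    pos = mis_model.cds_start - 412
    anchor = mis_model.seq[pos - 1]
    out.append(
        {
            "label": "MYB activator: TA insertion in the promoter (-411)",
            "model": mis_model, "pos": pos, "ref": anchor, "alt": anchor + "TA",
            "expect": "promoter_indel -411",
        }
    )
    return out
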