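"""Readers and writers for the formats the pipeline touches.

* allele-count tables: a TSV dialect (``CHROM POS REF ALT HIGH_REF HIGH_ALT
  LOW_REF LOW_ALT``, 1-based positions) and minimal biallelic VCF with
  per-sample allele depths (two pooled samples, AD format);
* candidate regions as BED (0-based half-open, converted from the internal
  1-based inclusive convention);
* populations as TSV with phased ``a|b`` genotype columns per marker;
* gene models from GFF3 + FASTA (gene/mRNA/exon/CDS subset);
* run configuration from a TOML file merged over package defaults.
"""

from __future__ import annotations

import logging
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import GeneModel
from .simulate import POOL_COUNT_COLUMNS, MarkerMap, Population
from .trait import GeneticArchitecture

logger = logging.getLogger("redleaf")

__all__ = [
    "read_allele_counts",
    "write_allele_counts",
    "write_regions_bed",
    "read_regions_bed",
    "write_population_tsv",
    "read_population_tsv",
    "gene_model_from_gff",
    "load_config",
    "DEFAULT_CONFIG",
]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulation": {
        "n_f2": 218,
        "pool_high": 50,
        "pool_low": 50,
        "mean_depth": 50.0,
        "dispersion": None,
        "error_rate": 0.001,
        "markers_per_chromosome": 200,
        "family_size": 600,
    },
    "scan": {
        "min_depth": 10,
        "window_bp": 2_000_000,
        "step_bp": 500_000,
        "min_snps": 5,
        "min_consecutive": 3,
        "levels": [0.05, 0.01],
        "n_reps": 10_000,
    },
}


def _validate_counts(df: pd.DataFrame, path: str) -> pd.DataFrame:
    for col in ("HIGH_REF", "HIGH_ALT", "LOW_REF", "LOW_ALT"):
        bad = df.index[df[col] < 0]
        if len(bad):
            raise ValueError(f"{path}: negative count in {col} at line {bad[0] + 2}")
    if (df["POS"] < 1).any():
        line = int(df.index[df["POS"] < 1][0]) + 2
        raise ValueError(f"{path}: non-positive POS at line {line}")
    return df


def read_allele_counts(path, fmt: str | None = None) -> pd.DataFrame:
    """Load a pooled allele-count table from TSV or VCF (auto-detected from
    the extension unless ``fmt`` is given)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#")
        missing = set(POOL_COUNT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for col in ("POS", "HIGH_REF", "HIGH_ALT", "LOW_REF", "LOW_ALT"):
            if not np.issubdtype(df[col].dtype, np.number):
                bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
                raise ValueError(f"{path}: malformed {col} at line {int(bad[0]) + 2}")
        return _validate_counts(df[list(POOL_COUNT_COLUMNS)], str(path))
    if fmt == "vcf":
        return _read_vcf_counts(path)
    raise ValueError(f"unknown format {fmt!r}")


def _read_vcf_counts(path: Path) -> pd.DataFrame:
    import pysam

    rows = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 2:
            raise ValueError(
                f"{path}: expected exactly two pooled samples (high, low), got {samples}"
            )
        for rec in vcf.fetch() if vcf.index else vcf:
            if rec.alts is None or len(rec.alts) != 1 or len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                skipped += 1
                continue
            ads = [rec.samples[s].get("AD") for s in samples]
            if any(ad is None for ad in ads):
                skipped += 1
                continue
            rows.append(
                (
                    rec.chrom,
                    rec.pos,
                    rec.ref,
                    rec.alts[0],
                    ads[0][0],
                    ads[0][1],
                    ads[1][0],
                    ads[1][1],
                )
            )
    if skipped:
        logger.warning("%s: skipped %d non-biallelic-SNP or AD-less records", path, skipped)
    df = pd.DataFrame(rows, columns=list(POOL_COUNT_COLUMNS))
    try:
        df["CHROM"] = df["CHROM"].astype(int)
    except (ValueError, TypeError):
        pass
    return _validate_counts(df, str(path))


def write_allele_counts(counts: pd.DataFrame, path, fmt: str | None = None) -> None:
    """Write an allele-count table as TSV, or as a minimal biallelic VCF
    with two pooled samples carrying AD fields."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if fmt == "tsv":
        counts.to_csv(path, sep="\t", index=False)
        return
    if fmt != "vcf":
        raise ValueError(f"unknown format {fmt!r}")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        for chrom in pd.unique(counts["CHROM"]):
            end = int(counts.loc[counts["CHROM"] == chrom, "POS"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={end}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\thigh_pool\tlow_pool\n")
        for row in counts.itertuples(index=False):
            fh.write(
                f"{row.CHROM}\t{row.POS}\t.\t{row.REF}\t{row.ALT}\t.\tPASS\t.\tAD\t"
                f"{row.HIGH_REF},{row.HIGH_ALT}\t{row.LOW_REF},{row.LOW_ALT}\n"
            )


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    """Write candidate regions as BED: 0-based half-open intervals
    (``start - 1``, ``end``), name = exceedance level, score = 1000 * peak
    |delta| clipped to [0, 1000]."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write('track name=redleaf_regions description="delta-index candidate regions"\n')
        for row in regions.itertuples(index=False):
            score = int(np.clip(round(1000 * abs(row.peak_delta)), 0, 1000))
            fh.write(
                f"{row.chrom}\t{row.start - 1}\t{row.end}\tP{row.level}\t{score}\t.\n"
            )


def read_regions_bed(path) -> pd.DataFrame:
    """Read a regions BED back into the internal 1-based inclusive form."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "browser", "#")) or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            rows.append(
                (
                    int(f[0]) if f[0].isdigit() else f[0],
                    int(f[1]) + 1,
                    int(f[2]),
                    float(f[3].lstrip("P")) if len(f) > 3 and f[3].startswith("P") else np.nan,
                    int(f[4]) / 1000.0 if len(f) > 4 else np.nan,
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "level", "peak_delta"])


def write_population_tsv(pop: Population, path) -> None:
    """One row per individual; phased ``a|b`` red-allele indicators per
    marker, plus the phenotype columns."""
    path = Path(path)
    m = pop.marker_map.markers
    with open(path, "w") as fh:
        fh.write(f"#generation={pop.generation}\n")
        if pop.family:
            fh.write(f"#family={pop.family}\n")
        fh.write("id\tlatent\tcolour\t" + "\t".join(m["id"]) + "\n")
        latent = pop.latent if pop.latent is not None else np.full(pop.n, np.nan)
        colour = pop.colour if pop.colour is not None else np.full(pop.n, "", dtype=object)
        for i in range(pop.n):
            genos = "\t".join(
                f"{a}|{b}" for a, b in zip(pop.haplotypes[i, 0], pop.haplotypes[i, 1])
            )
            fh.write(f"ind{i:05d}\t{latent[i]:.4g}\t{colour[i]}\t{genos}\n")


def read_population_tsv(path, marker_map: MarkerMap, arch: GeneticArchitecture) -> Population:
    path = Path(path)
    generation, family = "F2", None
    with open(path) as fh:
        text = fh.read().splitlines()
    body_start = 0
    for line in text:
        if line.startswith("#generation="):
            generation = line.split("=", 1)[1]
        elif line.startswith("#family="):
            family = line.split("=", 1)[1]
        elif not line.startswith("#"):
            break
        body_start += 1
    header = text[body_start].split("\t")
    marker_ids = header[3:]
    if marker_ids != list(marker_map.markers["id"]):
        raise ValueError(f"{path}: marker columns do not match the marker map")
    n = len(text) - body_start - 1
    haps = np.zeros((n, 2, len(marker_map)), dtype=np.uint8)
    latent = np.empty(n)
    colour = np.empty(n, dtype=object)
    for i, line in enumerate(text[body_start + 1 :]):
        f = line.split("\t")
        latent[i] = float(f[1])
        colour[i] = f[2]
        for j, g in enumerate(f[3:]):
            haps[i, 0, j] = g[0] == "1"
            haps[i, 1, j] = g[2] == "1"
    pop = Population(generation, marker_map, arch, haps, family=family)
    pop.latent, pop.colour = latent, colour
    return pop


def gene_model_from_gff(gff_path, fasta_path, gene_id: str) -> GeneModel:
    """Build a :class:`GeneModel` for one gene from a GFF3 file (gene /
    mRNA / exon / CDS features) and its reference FASTA."""
    import gffutils
    from Bio import SeqIO

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    gene = db[gene_id]
    exons = sorted(
        (f.start, f.end) for f in db.children(gene, featuretype="exon")
    )
    cds = sorted((f.start, f.end) for f in db.children(gene, featuretype="CDS"))
    if not exons or not cds:
        raise ValueError(f"gene {gene_id!r} needs exon and CDS features")
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if gene.seqid not in seqs:
        raise ValueError(f"sequence {gene.seqid!r} not in {fasta_path}")
    return GeneModel(
        gene_id=gene_id,
        strand=gene.strand,
        exons=tuple(exons),
        cds_start=cds[0][0],
        cds_end=cds[-1][1],
        seq=seqs[gene.seqid],
    )


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> dict:
    """TOML run configuration merged over the package defaults, with basic
    range validation."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path, "rb") as fh:
            cfg = _merge(DEFAULT_CONFIG, tomllib.load(fh))
    sim, scan = cfg["simulation"], cfg["scan"]
    if sim["n_f2"] < 0 or sim["pool_high"] < 1 or sim["pool_low"] < 1:
        raise ValueError("simulation sizes out of range")
    if not 0 <= sim["error_rate"] < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    if scan["min_depth"] < 1 or not scan["window_bp"] >= scan["step_bp"] > 0:
        raise ValueError("scan window configuration out of range")
    return cfg
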