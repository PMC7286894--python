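"""Variant and interval I/O plus the central genotype container.

The in-memory model is a :class:`GenotypeTable`: an ordered set of biallelic
variant records, a ``(n_variants, n_samples, 2)`` allele-index array (``-1``
for missing), a phased flag per call, and per-sample metadata (group, sex,
size class).  External formats keep their native conventions (VCF 1-based,
BED 0-based half-open); internally everything is 1-based with inclusive
endpoints, and segment lengths are plain coordinate differences ``|b - a|``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_LABELS = ("CnSouth", "CnNorth", "Europe", "wild", "admixed")
SIZE_CLASSES = ("small", "large", "NA")

VARIANT_COLUMNS = ["contig", "pos", "ref", "alt", "vclass"]

SV_LENGTH_THRESHOLD = 45  # bp; larger indels are structural variants


class VcfParseError(ValueError):
    """Malformed VCF content; carries the offending record's position."""


class PhaseError(ValueError):
    """An operation required phased haplotypes but found unphased calls."""


def classify_alleles(ref: str, alt: str) -> str:
    """Classify a biallelic record as SNP, indel or SV by allele lengths."""
    if not ref or not alt:
        raise ValueError("alleles must be non-empty")
    if alt.startswith("<"):
        return "SV"
    if len(ref) == 1 and len(alt) == 1:
        return "SNP"
    if abs(len(ref) - len(alt)) > SV_LENGTH_THRESHOLD:
        return "SV"
    return "indel"


@dataclass
class VariantRecord:
    contig: str
    pos: int          # 1-based
    ref: str
    alt: str
    vclass: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.vclass:
            self.vclass = classify_alleles(self.ref, self.alt)


@dataclass
class GenotypeTable:
    """Ordered variants x samples genotype matrix with sample metadata.

    Attributes
    ----------
    variants : pandas.DataFrame
        Columns ``contig, pos, ref, alt, vclass``; ordered by (contig, pos).
    genotypes : numpy.ndarray
        ``(n_variants, n_samples, 2)`` int8 allele indices; ``-1`` missing.
    phased : numpy.ndarray
        ``(n_variants, n_samples)`` bool.
    samples : list of str
    metadata : pandas.DataFrame
        Indexed by sample; columns ``group, sex, size_class``.
    """

    variants: pd.DataFrame
    genotypes: np.ndarray
    phased: np.ndarray
    samples: list
    metadata: pd.DataFrame
    contig_lengths: dict = field(default_factory=dict)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phased = np.asarray(self.phased, dtype=bool)
        n_var, n_samp = len(self.variants), len(self.samples)
        if self.genotypes.shape != (n_var, n_samp, 2):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} inconsistent "
                f"with {n_var} variants x {n_samp} samples"
            )
        if self.phased.shape != (n_var, n_samp):
            raise ValueError("phased array shape inconsistent")
        if not self.metadata.index.equals(pd.Index(self.samples)):
            self.metadata = self.metadata.reindex(self.samples)

    # -- basic accessors -------------------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, name: str) -> int:
        return self.samples.index(name)

    def group_of(self, sample: str) -> str:
        return self.metadata.loc[sample, "group"]

    def samples_in_group(self, group: str) -> list:
        return [s for s in self.samples if self.metadata.loc[s, "group"] == group]

    def dosage(self) -> np.ndarray:
        """Alt-allele dosage ``(n_variants, n_samples)`` float; NaN missing."""
        g = self.genotypes
        complete = (g >= 0).all(axis=2)
        return np.where(complete, g.sum(axis=2), np.nan)

    def haplotypes(self, variant_mask=None) -> np.ndarray:
        """Phased haplotype matrix ``(n_variants, 2*n_samples)``; -1 missing.

        Columns ``2*i`` and ``2*i + 1`` are sample ``i``'s two haplotypes.
        Raises :class:`PhaseError` on an unphased heterozygote.
        """
        idx = np.arange(self.n_variants) if variant_mask is None else np.where(variant_mask)[0]
        g = self.genotypes[idx]
        het = g[..., 0] != g[..., 1]
        nonmissing = (g >= 0).all(axis=2)
        bad = het & nonmissing & ~self.phased[idx]
        if bad.any():
            v, s = np.argwhere(bad)[0]
            raise PhaseError(
                f"phase required: unphased heterozygote at "
                f"{self.variants.iloc[idx[v]]['contig']}:{self.variants.iloc[idx[v]]['pos']} "
                f"sample {self.samples[s]}"
            )
        return g.reshape(len(idx), -1)

    def allele_freq(self, sample_names=None, variant_mask=None) -> np.ndarray:
        """Alt-allele frequency per variant over non-missing alleles."""
        cols = (
            slice(None)
            if sample_names is None
            else [self.sample_index(s) for s in sample_names]
        )
        g = self.genotypes[:, cols, :]
        if variant_mask is not None:
            g = g[variant_mask]
        valid = g >= 0
        n_alleles = valid.sum(axis=(1, 2))
        n_alt = np.where(valid, g, 0).sum(axis=(1, 2))
        return np.where(n_alleles > 0, n_alt / np.maximum(n_alleles, 1), np.nan)

    def region_mask(self, contig: str, start: int, end: int) -> np.ndarray:
        pos = self.variants["pos"].to_numpy()
        return (
            (self.variants["contig"].to_numpy() == contig)
            & (pos >= start)
            & (pos <= end)
        )

    def subset_variants(self, mask) -> "GenotypeTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.where(mask)[0]
        else:
            idx = mask
        return GenotypeTable(
            self.variants.iloc[idx].reset_index(drop=True),
            self.genotypes[idx],
            self.phased[idx],
            list(self.samples),
            self.metadata.copy(),
            dict(self.contig_lengths),
        )

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(
            self.variants.copy(),
            self.genotypes.copy(),
            self.phased.copy(),
            list(self.samples),
            self.metadata.copy(),
            dict(self.contig_lengths),
        )


# ---------------------------------------------------------------------------
# coordinate / proportion arithmetic
# ---------------------------------------------------------------------------

def _round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("1." + "0" * ndigits), rounding=ROUND_HALF_UP))


def segment_length(a: int, b: int):
    """Length of the segment between coordinates ``a`` and ``b``.

    Returns ``(bp, Mb)`` where bp is the plain coordinate difference
    ``|b - a|`` and Mb is bp/1e6 rounded half-away-from-zero to 2 decimals.
    """
    if a < 1 or b < 1:
        raise ValueError("coordinates must be >= 1")
    bp = abs(int(b) - int(a))
    return bp, _round_half_up(bp / 1e6, 2)


def percent(k: int, n: int) -> float:
    """``100*k/n`` rounded half-away-from-zero to 2 decimals."""
    if n == 0:
        raise ZeroDivisionError("undefined denominator: n = 0")
    if not (0 <= k <= n):
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    return _round_half_up(100.0 * k / n, 2)


@dataclass(frozen=True)
class GenomicInterval:
    """1-based, inclusive-endpoint interval; endpoints normalized start<=end."""

    contig: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self):
        a, b = self.start, self.end
        if a > b:
            object.__setattr__(self, "start", b)
            object.__setattr__(self, "end", a)
        if self.start < 1:
            raise ValueError("start must be >= 1")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and min(self.end, other.end) - max(self.start, other.start) + 1 >= 1
        )


def make_interval(contig, a, b, name="") -> GenomicInterval:
    a, b = int(a), int(b)
    return GenomicInterval(contig, min(a, b), max(a, b), name)


def read_intervals(path) -> list:
    """Read intervals from BED (0-based half-open) or TSV (1-based printed).

    BED coordinates are converted to the internal 1-based inclusive form.
    """
    path = str(path)
    out = []
    is_bed = path.endswith(".bed")
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            contig, a, b = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            if is_bed:
                a = a + 1
            out.append(make_interval(contig, a, b, name))
    return out


def overlap(intervals_a, intervals_b) -> list:
    """All pairs (a, b) with >= 1 bp intersection on inclusive intervals."""
    return [
        (a, b) for a in intervals_a for b in intervals_b if a.overlaps(b)
    ]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, metadata=None, split_multiallelic: bool = True) -> GenotypeTable:
    """Load a VCF v4.x into a :class:`GenotypeTable` via cyvcf2.

    Multi-allelic records are split into biallelic records (calls carrying a
    different alt become missing) and counted in an INFO-level log line.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows, gts, ph = [], [], []
    n_split = 0
    try:
        contig_lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    except Exception:
        contig_lengths = {}
    for var in vcf:
        alts = var.ALT or []
        if len(alts) > 1:
            n_split += 1
        for ai, alt in enumerate(alts, start=1):
            g = np.array(var.genotypes, dtype=int)  # (n_samples, 3)
            alleles = g[:, :2].copy()
            phased_row = g[:, 2].astype(bool)
            # remap: this alt -> 1, other alts -> missing
            out = np.full_like(alleles, -1)
            out[alleles == 0] = 0
            out[alleles == ai] = 1
            other = (alleles > 0) & (alleles != ai)
            out[other] = -1
            rows.append((var.CHROM, var.POS, var.REF, alt, classify_alleles(var.REF, alt)))
            gts.append(out)
            ph.append(phased_row)
    if n_split:
        logger.info("split %d multi-allelic records into biallelic", n_split)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    genotypes = (
        np.array(gts, dtype=np.int8)
        if gts
        else np.empty((0, len(samples), 2), dtype=np.int8)
    )
    phased = (
        np.array(ph, dtype=bool) if ph else np.empty((0, len(samples)), dtype=bool)
    )
    if metadata is None:
        metadata = pd.DataFrame(
            {"group": "NA", "sex": "NA", "size_class": "NA"}, index=samples
        )
    logger.info("read %d variant records, %d samples from %s", len(variants), len(samples), path)
    return GenotypeTable(variants, genotypes, phased, samples, metadata, contig_lengths)


def write_vcf(table: GenotypeTable, path) -> None:
    """Write a deterministic, spec-compliant VCF v4.2 (GT only)."""
    order = {c: i for i, c in enumerate(dict.fromkeys(table.variants["contig"]))}
    if table.contig_lengths:
        order = {c: i for i, c in enumerate(table.contig_lengths)}
    unknowns = set(table.variants["contig"]) - set(order)
    if unknowns:
        raise ValueError(f"contigs without declared order: {sorted(unknowns)}")
    idx = sorted(
        range(table.n_variants),
        key=lambda i: (
            order[table.variants.iloc[i]["contig"]],
            int(table.variants.iloc[i]["pos"]),
        ),
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pigpopgen\n")
        for c in order:
            length = table.contig_lengths.get(c)
            if length:
                fh.write(f"##contig=<ID={c},length={length}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=VT,Number=1,Type=String,Description="Variant class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for i in idx:
            v = table.variants.iloc[i]
            fields = [
                str(v["contig"]), str(int(v["pos"])), ".", v["ref"], v["alt"],
                ".", "PASS", f"VT={v['vclass']}", "GT",
            ]
            for s in range(table.n_samples):
                a, b = table.genotypes[i, s]
                sep = "|" if table.phased[i, s] else "/"
                sa = "." if a < 0 else str(int(a))
                sb = "." if b < 0 else str(int(b))
                fields.append(f"{sa}{sep}{sb}")
            fh.write("\t".join(fields) + "\n")
    logger.info("wrote %d records to %s", table.n_variants, path)


# ---------------------------------------------------------------------------
# metadata / FASTA / GFF
# ---------------------------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV with columns sample, group, sex, size_class."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "group", "sex", "size_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing column(s): {sorted(missing)}")
    return df.set_index("sample")


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.rename_axis("sample").reset_index().to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict:
    """Contig name -> sequence string."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path, width: int = 70) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


GFF_COLUMNS = [
    "contig", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def read_gff(path) -> pd.DataFrame:
    """GFF3 features as a DataFrame; gene_id extracted from attributes."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=GFF_COLUMNS,
        dtype={"start": int, "end": int},
    )
    def _gene_id(attrs):
        for part in str(attrs).split(";"):
            if part.startswith(("ID=", "Parent=")):
                return part.split("=", 1)[1].split(".")[0]
        return ""
    df["gene_id"] = df["attributes"].map(_gene_id)
    return df


def write_gff(features: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        cols = GFF_COLUMNS
        for _, row in features.iterrows():
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def write_bed(intervals, path, extra_cols=None) -> None:
    """Write intervals as BED (converting to 0-based half-open)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fields = [iv.contig, str(iv.start - 1), str(iv.end)]
            if iv.name:
                fields.append(iv.name)
            if extra_cols is not None:
                fields.extend(str(x) for x in extra_cols[i])
            fh.write("\t".join(fields) + "\n")
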