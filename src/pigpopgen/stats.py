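"""Windowed diversity and differentiation statistics plus coding effects.

Estimators
----------
theta_pi   mean pairwise difference per site, unbiased frequency form
           ``sum_sites 2 p (1 - p) n / (n - 1)``, reported per Kb.
theta_w    Watterson's estimator ``S / a_n`` with ``a_n = sum_{i<n} 1/i``,
           per Kb; with missing data each segregating site contributes
           ``1 / a_{n_site}``.
hudson_fst ratio-of-averages Hudson estimator ``1 - pi_within/pi_between``
           summed over window sites, with the unbiased within-group pi.

Sites with missing haplotypes contribute with reduced n (pairwise-complete).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeTable, GenomicInterval

logger = logging.getLogger(__name__)

EFFECT_LABELS = (
    "synonymous", "nonsynonymous", "stop_gain", "frameshift", "nonframeshift",
    "intergenic", "updownstream_5kb", "intronic",
)

# most-severe-first ordering for variants hitting several transcripts
EFFECT_SEVERITY = {
    "stop_gain": 0, "frameshift": 1, "nonsynonymous": 2, "nonframeshift": 3,
    "synonymous": 4, "intronic": 5, "updownstream_5kb": 6, "intergenic": 7,
}


@dataclass
class WindowStat:
    interval: GenomicInterval
    n_sites: int
    n_haplotypes: int
    theta_pi_per_kb: float
    theta_w_per_kb: float
    fst: float | None = None


def _site_freq_and_n(haps: np.ndarray):
    """Per-site alt frequency and haplotype count over non-missing entries."""
    valid = haps >= 0
    n = valid.sum(axis=1)
    alt = np.where(valid, haps, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return p, n


def theta_pi(haps: np.ndarray, window_bp: float) -> float:
    """Nucleotide diversity per Kb for one window of haplotypes (sites x haps)."""
    if haps.ndim != 2 or haps.shape[1] < 2:
        raise ValueError("need >= 2 haplotypes")
    if window_bp < 1:
        raise ValueError("window length must be >= 1 bp")
    p, n = _site_freq_and_n(haps)
    use = n >= 2
    if haps.shape[0] and not use.any() and (n == 0).all():
        raise ValueError("zero usable haplotypes in window")
    contrib = 2.0 * p[use] * (1.0 - p[use]) * n[use] / (n[use] - 1.0)
    return float(contrib.sum() / (window_bp / 1000.0))


def theta_pi_pairs(haps: np.ndarray, window_bp: float) -> float:
    """All-pairs form of theta_pi (oracle-grade; O(n^2) haplotype pairs)."""
    n = haps.shape[1]
    total, npairs = 0.0, 0
    for i in range(n):
        for j in range(i + 1, n):
            both = (haps[:, i] >= 0) & (haps[:, j] >= 0)
            total += float((haps[both, i] != haps[both, j]).sum())
            npairs += 1
    if npairs == 0:
        raise ValueError("need >= 2 haplotypes")
    # frequency form weights each site by its own n; with complete data the
    # two forms agree exactly
    return total / npairs / (window_bp / 1000.0)


def harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n))) if n >= 2 else 0.0


def theta_w(haps: np.ndarray, window_bp: float) -> float:
    """Watterson's theta per Kb for one window of haplotypes."""
    if haps.ndim != 2 or haps.shape[1] < 2:
        raise ValueError("need >= 2 haplotypes")
    if window_bp < 1:
        raise ValueError("window length must be >= 1 bp")
    p, n = _site_freq_and_n(haps)
    seg = (p > 0) & (p < 1) & (n >= 2)
    total = sum(1.0 / harmonic(int(ni)) for ni in n[seg])
    return float(total / (window_bp / 1000.0))


def hudson_fst(haps_a: np.ndarray, haps_b: np.ndarray) -> float:
    """Hudson F_ST (ratio of averages) between two haplotype sets.

    Returns NaN with a warning when between-group diversity is zero over
    the window (F_ST undefined).
    """
    pa, na = _site_freq_and_n(haps_a)
    pb, nb = _site_freq_and_n(haps_b)
    use = (na >= 2) & (nb >= 2)
    pa, pb, na, nb = pa[use], pb[use], na[use], nb[use]
    pi_a = 2.0 * pa * (1.0 - pa) * na / (na - 1.0)
    pi_b = 2.0 * pb * (1.0 - pb) * nb / (nb - 1.0)
    pi_within = 0.5 * (pi_a + pi_b)
    pi_between = pa * (1.0 - pb) + pb * (1.0 - pa)
    denom = pi_between.sum()
    if denom == 0:
        warnings.warn("pi_between is zero over window; F_ST undefined")
        return float("nan")
    return float(1.0 - pi_within.sum() / denom)


def iter_windows(contig_length: int, width: int):
    """Non-overlapping [start, end] windows anchored at position 1."""
    start = 1
    while start <= contig_length:
        yield start, min(start + width - 1, contig_length)
        start += width


def windowed_stats(
    table: GenotypeTable,
    width: int = 100_000,
    groups: tuple | None = None,
) -> pd.DataFrame:
    """Per-window theta_pi/Kb, theta_w/Kb and (optionally) Hudson F_ST.

    ``groups`` is an optional pair of group labels for F_ST; diversity is
    computed over all haplotypes.
    """
    haps = table.haplotypes()
    if groups is not None:
        cols_a = _group_hap_columns(table, groups[0])
        cols_b = _group_hap_columns(table, groups[1])
    rows = []
    contigs = table.variants["contig"].to_numpy()
    positions = table.variants["pos"].to_numpy()
    for contig in dict.fromkeys(contigs):
        clen = table.contig_lengths.get(contig, int(positions[contigs == contig].max()))
        for start, end in iter_windows(clen, width):
            mask = (contigs == contig) & (positions >= start) & (positions <= end)
            wbp = end - start + 1
            h = haps[mask]
            fst = np.nan
            if mask.sum() == 0:
                tp = tw = 0.0
            else:
                tp = theta_pi(h, wbp)
                tw = theta_w(h, wbp)
                if groups is not None:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        fst = hudson_fst(h[:, cols_a], h[:, cols_b])
            rows.append(
                {"contig": contig, "start": start, "end": end,
                 "n_sites": int(mask.sum()), "n_haplotypes": haps.shape[1],
                 "theta_pi_kb": tp, "theta_w_kb": tw,
                 "fst": fst if groups is not None else np.nan}
            )
    return pd.DataFrame(rows)


def _group_hap_columns(table: GenotypeTable, group: str) -> list:
    cols = []
    for s in table.samples_in_group(group):
        i = table.sample_index(s)
        cols.extend([2 * i, 2 * i + 1])
    return cols


def hom_het_ratio(table: GenotypeTable) -> pd.Series:
    """Per-sample homozygous-alt / heterozygous call ratio (missing excluded).

    A sample with zero heterozygous calls gets ``inf`` with a warning.
    """
    g = table.genotypes
    complete = (g >= 0).all(axis=2)
    hom_alt = ((g[..., 0] == 1) & (g[..., 1] == 1) & complete).sum(axis=0)
    het = ((g[..., 0] != g[..., 1]) & complete).sum(axis=0)
    if (het == 0).any():
        warnings.warn("sample(s) with zero heterozygous calls: ratio is inf")
    with np.errstate(divide="ignore"):
        ratio = np.where(het > 0, hom_alt / np.maximum(het, 1), np.inf)
    return pd.Series(ratio, index=table.samples, name="hom_het_ratio")


# ---------------------------------------------------------------------------
# coding-effect classification
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _translate(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


def _gene_models(features: pd.DataFrame):
    """gene_id -> dict(contig, strand, gene interval, ordered CDS exons)."""
    models = {}
    genes = features[features["type"] == "gene"]
    for _, g in genes.iterrows():
        cds = features[(features["type"] == "CDS") & (features["gene_id"] == g["gene_id"])]
        exons = sorted(
            [(int(r["start"]), int(r["end"])) for _, r in cds.iterrows()]
        )
        models[g["gene_id"]] = {
            "contig": g["contig"], "strand": g["strand"],
            "start": int(g["start"]), "end": int(g["end"]), "exons": exons,
        }
    return models


def classify_coding_effect(
    variant, sequences: dict, features: pd.DataFrame, updown_bp: int = 5000
) -> str:
    """Assign one effect label to a variant given a genome and CDS features.

    SNPs in CDS are translated ref-vs-alt with the standard genetic code
    (minus-strand genes via the reverse complement of the spliced CDS);
    indels in CDS are frameshift iff length difference mod 3 != 0.  A
    variant inside a gene but outside its CDS is intronic; within
    ``updown_bp`` of a gene, up/downstream; otherwise intergenic.  With
    several overlapping transcripts the most severe label wins.
    """
    contig = variant["contig"]
    pos = int(variant["pos"])
    ref, alt = variant["ref"], variant["alt"]
    models = _gene_models(features) if not isinstance(features, dict) else features
    labels = []
    near_gene = False
    for gm in models.values():
        if gm["contig"] != contig:
            continue
        if gm["start"] - updown_bp <= pos <= gm["end"] + updown_bp:
            near_gene = True
        if not (gm["start"] <= pos <= gm["end"]):
            continue
        in_exon = any(s <= pos <= e for s, e in gm["exons"])
        if not in_exon:
            labels.append("intronic")
            continue
        if len(ref) == len(alt) == 1:
            labels.append(_snp_cds_effect(pos, ref, alt, gm, sequences[contig]))
        else:
            diff = abs(len(ref) - len(alt))
            labels.append("frameshift" if diff % 3 != 0 else "nonframeshift")
    if labels:
        return min(labels, key=lambda l: EFFECT_SEVERITY[l])
    return "updownstream_5kb" if near_gene else "intergenic"


def _snp_cds_effect(pos, ref, alt, gm, seq) -> str:
    spliced = "".join(seq[s - 1 : e] for s, e in gm["exons"])
    offsets = []
    off = 0
    for s, e in gm["exons"]:
        if s <= pos <= e:
            offsets.append(off + (pos - s))
        off += e - s + 1
    cds_pos = offsets[0]
    if seq[pos - 1] != ref:
        warnings.warn(
            f"reference allele {ref} at {gm['contig'] if 'contig' in gm else ''}:{pos} "
            f"disagrees with sequence base {seq[pos - 1]}"
        )
    alt_spliced = spliced[:cds_pos] + alt + spliced[cds_pos + 1 :]
    if gm["strand"] == "-":
        spliced = spliced.translate(_COMPLEMENT)[::-1]
        alt_spliced = alt_spliced.translate(_COMPLEMENT)[::-1]
        cds_pos = len(spliced) - 1 - cds_pos
    codon_i = cds_pos // 3
    ref_codon = spliced[3 * codon_i : 3 * codon_i + 3]
    alt_codon = alt_spliced[3 * codon_i : 3 * codon_i + 3]
    if len(ref_codon) < 3:
        warnings.warn("variant overlaps CDS boundary; labeling by partial codon")
        return "nonsynonymous"
    aa_ref, aa_alt = _translate(ref_codon), _translate(alt_codon)
    if aa_alt == aa_ref:
        return "synonymous"
    if aa_alt == "*":
        return "stop_gain"
    return "nonsynonymous"


def classify_effects(
    table: GenotypeTable, sequences: dict, features: pd.DataFrame
) -> pd.Series:
    """Effect label per variant in the table."""
    models = _gene_models(features)
    labels = [
        classify_coding_effect(table.variants.iloc[i], sequences, models)
        for i in range(table.n_variants)
    ]
    return pd.Series(labels, name="effect")


def ns_s_ratio(labels) -> float:
    """NS/S ratio (omega): nonsynonymous / synonymous counts.

    Returns NaN with a warning when there are no synonymous variants.
    """
    labels = pd.Series(labels)
    ns = int((labels == "nonsynonymous").sum())
    s = int((labels == "synonymous").sum())
    if s == 0:
        warnings.warn("no synonymous variants; NS/S ratio undefined")
        return float("nan")
    return ns / s
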