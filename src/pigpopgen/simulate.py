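"""Synthetic multi-population genotype data with planted ground truth.

The generator stands in for a non-deposited multi-breed resequencing panel.
Per-site ancestral allele frequencies are drawn uniformly on (0.05, 0.95)
and group frequencies follow the Balding–Nichols model: a Beta distribution
with mean p and a single drift parameter F per group,

    p_g ~ Beta(p (1 - F) / F, (1 - p)(1 - F) / F).

Sites are unlinked except where structure is explicitly planted:
introgression tracts (copied donor genotypes), an X-chromosome
low-recombination block carrying two ancestral backgrounds (N/S) with
recombinant mosaics, and size-class-differentiated coding variants.  A
separate copy-with-mutation haplotype process provides linked data for LD
work.  All randomness flows from one seeded generator; identical configs
produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    GenotypeTable,
    VARIANT_COLUMNS,
    write_fasta,
    write_gff,
    GFF_COLUMNS,
)

NUCLEOTIDES = np.array(list("ACGT"))


class SimConfigError(ValueError):
    """A simulation parameter is invalid; message names the field."""


@dataclass
class SimConfig:
    """Study design for one synthetic dataset.

    ``n_per_group`` maps group label -> diploid sample count.
    ``divergence_F`` maps group label -> Balding–Nichols drift parameter.
    ``introgression_spec`` entries: (donor_group, recipient_sample, contig,
    start, end).  ``x_block_spec``: (contig, start, end, assignments) where
    assignments maps sample -> "N" | "S" | tuple of breakpoint positions.
    ``size_effect_spec`` entries: (site_index, high_size_class, f_high, f_low).
    """

    n_per_group: dict
    n_sites: int
    contig_lengths: dict
    divergence_F: dict
    seed: int
    introgression_spec: list = field(default_factory=list)
    x_block_spec: tuple = ()
    size_effect_spec: list = field(default_factory=list)
    ancestral_freq_range: tuple = (0.05, 0.95)
    freq_spectrum: str = "uniform"  # "uniform" | "neutral" (1/i SFS, needs F=0)

    def validate(self):
        if self.freq_spectrum not in ("uniform", "neutral"):
            raise SimConfigError("freq_spectrum: must be 'uniform' or 'neutral'")
        if self.freq_spectrum == "neutral" and any(
            F != 0 for F in self.divergence_F.values()
        ):
            raise SimConfigError("freq_spectrum: 'neutral' requires divergence_F = 0")
        if len(self.n_per_group) < 2:
            raise SimConfigError("n_per_group: need >= 2 groups")
        for g, n in self.n_per_group.items():
            if n < 1:
                raise SimConfigError(f"n_per_group[{g}]: must be >= 1")
        if self.n_sites < 1:
            raise SimConfigError("n_sites: must be >= 1")
        for g in self.n_per_group:
            F = self.divergence_F.get(g)
            if F is None:
                raise SimConfigError(f"divergence_F[{g}]: missing")
            if not (0 <= F < 1):
                raise SimConfigError(f"divergence_F[{g}]: must be in [0, 1)")
        for c, L in self.contig_lengths.items():
            if L < 1:
                raise SimConfigError(f"contig_lengths[{c}]: must be >= 1")
        for donor, recip, contig, a, b in self.introgression_spec:
            if contig not in self.contig_lengths:
                raise SimConfigError(f"introgression_spec: unknown contig {contig}")
            if not (1 <= a <= b <= self.contig_lengths[contig]):
                raise SimConfigError(
                    f"introgression_spec: tract [{a}, {b}] outside contig {contig}"
                )
        for entry in self.size_effect_spec:
            _, _, fh, fl = entry
            if not (0 <= fh <= 1 and 0 <= fl <= 1):
                raise SimConfigError("size_effect_spec: frequencies must be in [0, 1]")


@dataclass
class SimTruth:
    """Planted ground truth accompanying a simulated dataset."""

    tracts: pd.DataFrame  # sample, contig, start, end, donor_group, donor_sample
    x_labels: dict = field(default_factory=dict)        # sample -> N/S/recombinant
    x_breakpoints: dict = field(default_factory=dict)   # sample -> list of bp
    x_block: tuple = ()                                 # (contig, start, end)
    site_freqs: pd.DataFrame | None = None              # true group frequencies
    effects: pd.DataFrame | None = None                 # site_index, effect label
    size_sites: list = field(default_factory=list)      # planted contrast site indices

    @staticmethod
    def empty() -> "SimTruth":
        return SimTruth(
            tracts=pd.DataFrame(
                columns=["sample", "contig", "start", "end", "donor_group", "donor_sample"]
            )
        )


def _sample_names(n_per_group: dict) -> tuple[list, pd.DataFrame]:
    names, groups, sexes, sizes = [], [], [], []
    for g, n in n_per_group.items():
        for i in range(n):
            names.append(f"{g}_{i + 1:02d}")
            groups.append(g)
            sexes.append("M" if i % 2 == 0 else "F")
            sizes.append("small" if i % 2 == 0 else "large")
    meta = pd.DataFrame(
        {"group": groups, "sex": sexes, "size_class": sizes}, index=names
    )
    return names, meta


def simulate_populations(config: SimConfig) -> tuple[GenotypeTable, SimTruth]:
    """Draw a phased multi-group diploid panel under Balding–Nichols drift."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples, meta = _sample_names(config.n_per_group)

    # distribute sites over contigs proportionally to length
    contigs = list(config.contig_lengths)
    lengths = np.array([config.contig_lengths[c] for c in contigs], dtype=float)
    counts = np.floor(config.n_sites * lengths / lengths.sum()).astype(int)
    counts[0] += config.n_sites - counts.sum()
    rows = []
    for c, k in zip(contigs, counts):
        if k == 0:
            continue
        pos = np.sort(
            rng.choice(np.arange(1, config.contig_lengths[c] + 1), size=k, replace=False)
            if config.contig_lengths[c] >= k
            else rng.integers(1, config.contig_lengths[c] + 1, size=k)
        )
        for p in pos:
            rows.append((c, int(p)))
    variants = pd.DataFrame(rows, columns=["contig", "pos"])
    n_sites = len(variants)

    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_off = rng.integers(1, 4, size=n_sites)
    variants["ref"] = NUCLEOTIDES[ref_idx]
    variants["alt"] = NUCLEOTIDES[(ref_idx + alt_off) % 4]
    variants["vclass"] = "SNP"
    variants = variants[VARIANT_COLUMNS]

    genotypes = np.empty((n_sites, len(samples), 2), dtype=np.int8)
    if config.freq_spectrum == "neutral":
        # allele count i among 2N haplotypes with P(i) proportional to 1/i,
        # assigned to uniformly random haplotypes: the standard neutral SFS,
        # under which theta_pi and theta_w agree in expectation
        n_hap = 2 * len(samples)
        counts_sfs = np.arange(1, n_hap)
        probs = (1.0 / counts_sfs) / np.sum(1.0 / counts_sfs)
        flat = np.zeros((n_sites, n_hap), dtype=np.int8)
        for k in range(n_sites):
            i = rng.choice(counts_sfs, p=probs)
            carriers = rng.choice(n_hap, size=i, replace=False)
            flat[k, carriers] = 1
        genotypes = flat.reshape(n_sites, len(samples), 2)
        group_freq = {
            g: flat.mean(axis=1) for g in config.n_per_group
        }
    else:
        lo, hi = config.ancestral_freq_range
        p_anc = rng.uniform(lo, hi, size=n_sites)
        group_freq = {}
        for g in config.n_per_group:
            F = config.divergence_F[g]
            if F == 0:
                group_freq[g] = p_anc.copy()
            else:
                a = p_anc * (1 - F) / F
                b = (1 - p_anc) * (1 - F) / F
                group_freq[g] = rng.beta(a, b)
        for si, s in enumerate(samples):
            f = group_freq[meta.loc[s, "group"]]
            genotypes[:, si, 0] = rng.random(n_sites) < f
            genotypes[:, si, 1] = rng.random(n_sites) < f
    phased = np.ones((n_sites, len(samples)), dtype=bool)

    table = GenotypeTable(
        variants, genotypes, phased, samples, meta, dict(config.contig_lengths)
    )
    truth = SimTruth.empty()
    truth.site_freqs = pd.DataFrame(group_freq)

    if config.size_effect_spec:
        _plant_size_effects(table, truth, config.size_effect_spec, rng)
    if config.introgression_spec:
        table, truth = plant_introgression_tracts(
            table, truth, config.introgression_spec, rng
        )
    if config.x_block_spec:
        table, truth = simulate_x_mosaic(table, truth, config.x_block_spec, rng)
    return table, truth


def _plant_size_effects(table, truth, spec, rng):
    """Overwrite selected sites with size-class-stratified frequencies."""
    size = table.metadata["size_class"].to_numpy()
    for site, high_class, f_high, f_low in spec:
        f = np.where(size == high_class, f_high, f_low)
        for si in range(table.n_samples):
            table.genotypes[site, si, 0] = rng.random() < f[si]
            table.genotypes[site, si, 1] = rng.random() < f[si]
        truth.size_sites.append(int(site))


def plant_introgression_tracts(
    table: GenotypeTable, truth: SimTruth, spec, rng, haplotypes: str = "genotype"
) -> tuple[GenotypeTable, SimTruth]:
    """Copy donor material into recipient samples over declared tracts.

    Default mode ``"genotype"`` copies both alleles of one randomly chosen
    donor, so recipient-vs-donor sharing is 1.0 at every tract SNP; mode
    ``"one"`` overwrites a single recipient haplotype with one donor
    haplotype.  Overlapping tracts for one recipient are rejected.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    new_rows = []
    for donor_group, recipient, contig, start, end in spec:
        if recipient not in table.samples:
            raise ValueError(f"unknown recipient sample {recipient}")
        donors = [s for s in table.samples_in_group(donor_group) if s != recipient]
        if not donors:
            raise ValueError(f"no donor samples in group {donor_group}")
        prior = [
            t for _, t in truth.tracts[truth.tracts["sample"] == recipient].iterrows()
        ] + [t for t in new_rows if t["sample"] == recipient]
        for t in prior:
            if t["contig"] == contig and not (end < t["start"] or start > t["end"]):
                raise ValueError(
                    f"overlapping tracts for {recipient} on {contig}: "
                    f"[{start}, {end}] vs [{t['start']}, {t['end']}]"
                )
        donor = donors[rng.integers(0, len(donors))]
        mask = table.region_mask(contig, start, end)
        ri = table.sample_index(recipient)
        di = table.sample_index(donor)
        if haplotypes == "genotype":
            table.genotypes[mask, ri, :] = table.genotypes[mask, di, :]
        elif haplotypes == "one":
            hap = int(rng.integers(0, 2))
            table.genotypes[mask, ri, hap] = table.genotypes[mask, di, int(rng.integers(0, 2))]
        else:
            raise ValueError(f"unknown haplotypes mode {haplotypes!r}")
        new_rows.append(
            {"sample": recipient, "contig": contig, "start": start, "end": end,
             "donor_group": donor_group, "donor_sample": donor}
        )
    truth.tracts = pd.concat(
        [truth.tracts, pd.DataFrame(new_rows)], ignore_index=True
    )
    return table, truth


def simulate_x_mosaic(
    table: GenotypeTable,
    truth: SimTruth,
    x_block_spec,
    rng,
    informative_frac: float = 0.9,
    noise: float = 0.0,
) -> tuple[GenotypeTable, SimTruth]:
    """Overwrite an X block with two ancestral backgrounds and mosaics.

    Backgrounds N and S are distinct allele vectors over the block markers
    (S flips N at ``informative_frac`` of markers).  Each listed sample is
    assigned pure N, pure S, or a mosaic starting on the first-listed
    background and switching at the given breakpoints; both haplotypes of a
    sample carry the same background (males are haploid coded as homozygous).
    ``noise`` flips each written allele independently with that probability.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    contig, start, end, assignments = x_block_spec
    mask = table.region_mask(contig, start, end)
    pos = table.variants.loc[mask, "pos"].to_numpy()
    m = mask.sum()
    if m == 0:
        raise ValueError("x block contains no markers")
    hap_n = rng.integers(0, 2, size=m).astype(np.int8)
    informative = rng.random(m) < informative_frac
    hap_s = np.where(informative, 1 - hap_n, hap_n).astype(np.int8)

    for sample, assign in assignments.items():
        si = table.sample_index(sample)
        if assign == "N":
            hap, bps = hap_n, []
        elif assign == "S":
            hap, bps = hap_s, []
        else:
            bps = sorted(int(b) for b in assign)
            for b in bps:
                if not (start <= b <= end):
                    raise ValueError(f"breakpoint {b} outside block [{start}, {end}]")
            # alternate backgrounds starting from N
            seg = np.searchsorted(np.array(bps), pos, side="right")
            hap = np.where(seg % 2 == 0, hap_n, hap_s).astype(np.int8)
        written = hap.copy()
        if noise > 0:
            flips = rng.random(m) < noise
            written = np.where(flips, 1 - written, written).astype(np.int8)
        table.genotypes[mask, si, 0] = written
        table.genotypes[mask, si, 1] = written
        truth.x_labels[sample] = assign if assign in ("N", "S") else "recombinant"
        truth.x_breakpoints[sample] = bps
    truth.x_block = (contig, start, end)
    return table, truth


# ---------------------------------------------------------------------------
# linked haplotypes for LD work
# ---------------------------------------------------------------------------

def simulate_linked_haplotypes(
    n_haplotypes: int,
    n_sites: int,
    contig_length: int,
    switch_prob_per_bp: float,
    seed: int,
    n_founders: int = 4,
):
    """Copy-with-mutation haplotype process producing distance-decaying LD.

    Each haplotype tracks one of ``n_founders`` founder lineages; moving
    along the chromosome it re-draws its lineage with probability
    ``1 - exp(-switch_prob_per_bp * gap)`` per inter-marker gap.  Alleles are
    the founder's (Bernoulli per site), so nearby sites are correlated and
    correlation decays with distance.  Returns (positions, haplotype matrix
    of shape (n_sites, n_haplotypes)).
    """
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, contig_length + 1), size=n_sites, replace=False))
    founder = rng.integers(0, 2, size=(n_sites, n_founders)).astype(np.int8)
    # ensure sites are polymorphic among founders
    mono = founder.min(axis=1) == founder.max(axis=1)
    founder[mono, 0] = 1 - founder[mono, 0]
    lineage = rng.integers(0, n_founders, size=n_haplotypes)
    haps = np.empty((n_sites, n_haplotypes), dtype=np.int8)
    haps[0] = founder[0, lineage]
    for i in range(1, n_sites):
        gap = pos[i] - pos[i - 1]
        p_switch = 1.0 - np.exp(-switch_prob_per_bp * gap)
        switch = rng.random(n_haplotypes) < p_switch
        lineage = np.where(switch, rng.integers(0, n_founders, size=n_haplotypes), lineage)
        haps[i] = founder[i, lineage]
    return pos, haps


# ---------------------------------------------------------------------------
# toy genome annotation
# ---------------------------------------------------------------------------

def emit_genome_annotation(
    config: SimConfig,
    rng=None,
    n_genes_per_contig: int = 3,
    exons_per_gene: int = 2,
    exon_length: int = 30,
    intron_length: int = 20,
):
    """Random reference sequences plus non-overlapping CDS features.

    Returns ``(sequences, features)`` where sequences maps contig -> string
    and features is a GFF-style DataFrame (gene + CDS rows, strand and phase
    set; CDS total length is a codon multiple).  Raises if a gene does not
    fit inside its contig.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    sequences = {
        c: "".join(rng.choice(NUCLEOTIDES, size=L))
        for c, L in config.contig_lengths.items()
    }
    gene_span = exons_per_gene * exon_length + (exons_per_gene - 1) * intron_length
    rows = []
    gid = 0
    for c, L in config.contig_lengths.items():
        if n_genes_per_contig == 0:
            continue
        if gene_span > L:
            raise ValueError(f"CDS span {gene_span} longer than contig {c} ({L} bp)")
        slot = L // max(n_genes_per_contig, 1)
        for k in range(n_genes_per_contig):
            lo = k * slot + 1
            hi = min((k + 1) * slot, L) - gene_span
            if hi < lo:
                continue
            gstart = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            gene_id = f"gene{gid:03d}"
            gend = gstart + gene_span - 1
            rows.append((c, "pigpopgen_sim", "gene", gstart, gend, ".", strand, ".",
                         f"ID={gene_id}"))
            exon_starts = [gstart + e * (exon_length + intron_length) for e in range(exons_per_gene)]
            # CDS phase: bases of the previous codon carried over
            exons = exon_starts if strand == "+" else exon_starts[::-1]
            carried = 0
            for e_start in exons:
                phase = (3 - carried % 3) % 3
                rows.append((c, "pigpopgen_sim", "CDS", e_start, e_start + exon_length - 1,
                             ".", strand, str(phase), f"Parent={gene_id}"))
                carried += exon_length
    features = pd.DataFrame(rows, columns=GFF_COLUMNS)
    features["gene_id"] = features["attributes"].str.extract(r"(?:ID|Parent)=(\w+)")
    return sequences, features


def sync_ref_alleles(table: GenotypeTable, sequences: dict, rng) -> GenotypeTable:
    """Rewrite SNP ref alleles to match a reference sequence (alt differs)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    refs, alts = [], []
    for _, v in table.variants.iterrows():
        base = sequences[v["contig"]][int(v["pos"]) - 1]
        choices = [n for n in "ACGT" if n != base]
        refs.append(base)
        alts.append(choices[int(rng.integers(0, 3))])
    table.variants["ref"] = refs
    table.variants["alt"] = alts
    return table


def write_simulation(table, truth, outdir, sequences=None, features=None):
    """Write VCF, metadata, truth tables (and FASTA/GFF if given) to outdir."""
    import os

    from .io import write_vcf, write_metadata

    os.makedirs(outdir, exist_ok=True)
    write_vcf(table, os.path.join(outdir, "variants.vcf"))
    write_metadata(table.metadata, os.path.join(outdir, "samples.tsv"))
    truth.tracts.to_csv(os.path.join(outdir, "truth_tracts.tsv"), sep="\t", index=False)
    if truth.x_labels:
        pd.DataFrame(
            {
                "sample": list(truth.x_labels),
                "label": [truth.x_labels[s] for s in truth.x_labels],
                "breakpoints": [
                    ",".join(str(b) for b in truth.x_breakpoints.get(s, []))
                    for s in truth.x_labels
                ],
            }
        ).to_csv(os.path.join(outdir, "truth_x_haplotypes.tsv"), sep="\t", index=False)
    if truth.site_freqs is not None:
        truth.site_freqs.round(6).to_csv(
            os.path.join(outdir, "truth_site_freqs.tsv"), sep="\t", index=False
        )
    if sequences is not None:
        write_fasta(sequences, os.path.join(outdir, "genome.fasta"))
    if features is not None:
        write_gff(features[GFF_COLUMNS], os.path.join(outdir, "genes.gff3"))
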