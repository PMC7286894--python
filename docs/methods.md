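# Methods

This note documents the statistical models behind each module, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical decisions made
where the design was genuinely open.

## Coordinates, lengths, percentages

External formats keep their native conventions (VCF is 1-based, BED
0-based half-open); the internal canonical form is 1-based with inclusive
endpoints.  Segment lengths are plain coordinate differences |b − a| —
not inclusive lengths — because that is the convention under which the
panel's printed spans (40.09 Mb, 10.40 Mb, 382 bp, 487 bp) are internally
consistent.  Percentages and Mb values are rounded half-away-from-zero to
two decimals, which reproduces every printed proportion exactly.

## Diversity and differentiation

θπ uses the unbiased frequency form Σ_sites 2p̂(1−p̂)·n/(n−1), which equals
the mean over all C(n,2) haplotype pairs of per-site differences on
complete data (an exact identity the suite verifies).  θw is S/aₙ; with
missing data each segregating site contributes 1/a_{n_site}, i.e. sites
enter with their own haplotype count (pairwise-complete, never dropped
wholesale).  Both are reported per Kb of window length, over
non-overlapping windows anchored at position 1 (width a config knob,
default 100 Kb).  All genotyped sites in a window are used, not only a
pre-filtered SNP set; this is documented because either convention is
defensible and the choice shifts absolute (not relative) values.

F_ST is the Hudson ratio-of-averages estimator 1 − π_within/π_between
with the unbiased within-group π, chosen for its robustness with the
small, unbalanced group sizes typical of these panels (Weir–Cockerham
behaves poorly at n of a few per group).  When π_between is zero over a
window the value is undefined and reported missing with a warning.

The coding-effect classifier translates ref-vs-alt codons of the spliced
CDS (reverse complement on minus-strand genes) with the standard code;
indels are frameshift iff the length difference mod 3 ≠ 0; one label per
variant, resolved most-severe-first (stop_gain > frameshift >
nonsynonymous > nonframeshift > synonymous > intronic > updownstream_5kb >
intergenic) when features overlap.

## Population structure

The p-distance between diploids is the allele-sharing distance
1 − IBS/2 = |a − b|/2 averaged over pairwise-complete sites (a, b are alt
dosages).  The exact diploid distance definition is not fixed by the
field's usage, so the IBS-based form is declared here.  Neighbor joining
is plain Saitou–Nei: join the pair minimizing the Q-criterion, standard
branch-length formulas, negative branch lengths clamped to zero with the
excess moved to the sister branch (preserving path lengths), final
three-node star resolved by the three-point formulas.  NJ's consistency
on additive matrices is exercised against randomly generated trees and
against scikit-bio's implementation as an independent oracle.

PCA codes genotypes 0/1/2, mean-imputes missing entries per site, drops
monomorphic sites, centers and scales by √(p(1−p)), and eigendecomposes
the sample covariance; coordinates are eigenvectors scaled by √λ.

Admixture uses the standard unsupervised binomial mixture
L = Π Binom(g_il; 2, Σ_k q_ik f_kl), fit by EM with simultaneous Q/F
updates from one E-step; the log-likelihood is non-decreasing every
iteration (asserted in tests).  Because the published EM schedule of the
original ancestry tools is not printed anywhere usable, plain EM with 5
seeded random restarts is used and the best likelihood kept; degenerate
(empty) components trigger a re-seeded restart.  Missing genotypes
contribute nothing to the likelihood.  K is swept externally (default
2–5 in the pipeline config); no automatic K selection is attempted.

## Linkage disequilibrium

For a marker pair, D = p_AB − p_A p_B, r² = D²/(p_A(1−p_A)p_B(1−p_B))
(equal to the squared Pearson correlation of haplotype indicators —
verified exactly), and D′ = D/D_max with the sign-appropriate D_max.
The |D′| confidence bounds come from a profile likelihood on the 2×2
haplotype counts: allele frequencies held at their MLEs, |D′| scanned on
a 0.001 grid, the normalized likelihood read off at 2.5%/97.5%.

Gabriel blocks: a pair is "strong LD" when CI_low ≥ 0.70 and
CI_high ≥ 0.98, "strong recombination" when CI_high < 0.90; informative
pairs are those in either class.  A candidate span's outermost pair must
be strong LD and ≥95% of its informative pairs strong; candidates are
accepted greedily, longest in bp first, without marker overlap.  The
output is verified against an exhaustive span enumeration on small
instances.  Marker thinning (default 3 Kb minimum gap) is a greedy scan
and may be applied before block calling; both thinned and unthinned modes
are supported since published usage is ambiguous on this point.

EM phasing enumerates, per individual, all haplotype pairs compatible
with the multi-locus genotype (missing sites unconstrained), splits each
ambiguous genotype across ordered pairs ∝ the product of current
haplotype frequencies, and renormalizes; capacity is capped at 12 markers
per window — beyond that, phase windows and stitch.

LD decay bins all intra-contig pairs within 500 Kb at 5 Kb width; the
half-decay distance interpolates linearly between bin midpoints at half
the maximum bin mean, with an explicit "not reached" sentinel.

## X-chromosome haplotype structure

Block genotypes are recoded relative to the reference genome's alleles
(0 = same, 1 = opposite); each sample contributes its two phased
haplotypes as separate rows, and a male's haploid X is represented as two
identical rows.  Background consensuses are per-marker majorities over
anchor groups (southern samples for S; European plus northern-wild for
N).  A row is called N or S at match fraction ≥ 0.95 over informative
markers (those where the consensuses differ); the purity value is a
package choice — no published tolerance exists — and is configurable.
Otherwise a two-state dynamic program (mismatch cost 1, switch penalty 3
mismatch-equivalents, i.e. up to two isolated genotyping flips never
create a spurious breakpoint) segments the row; a fit with every segment
≥ 0.95 pure is a recombinant, else unclassified.

Each switch is reported as the open interval between the last informative
marker consistent with the left background and the first consistent with
the right.  A candidate bounding marker contradicted by markers between
it and its nearest confirming neighbor is skipped as a likely genotyping
flip; this only widens intervals.  Even so, a flip lying flush against
the true breakpoint with no informative marker in between leaves the data
exactly consistent with an interval that excludes the truth, so at a 2%
flip rate the containment probability is ~96%, not 1 — the test suite
therefore checks the ≥95% containment claim with a one-sided binomial
bound rather than a raw cutoff.  Intervals across samples are clustered
by overlap; each cluster's maximal range is its union, and the conserved
core runs between consecutive clusters' inner bounds.

## Introgression scan

Sharing between two diploids at a SNP is IBS/2 (1, 0.5, 0); the paper of
record for this analysis style never defines the score numerically, so
the genotype-level form is declared here.  For each focal pig and each
non-overlapping 100 Kb window with ≥10 SNPs, when ≥3 pigs per group are
comparable, R = S_own/S_cross is computed and R < 0.8 flags putative
introgression; consecutive flagged windows merge into segments (gap
tolerance 0 by default).  The ≥90% criterion is computed separately: the
maximum over other-group members of the fraction of SNPs with *identical*
genotypes.  Full identity is used because "at least one shared allele"
holds for ~92% of baseline SNP pairs, which would make a 90% rule
meaningless; identity gives a sharp criterion whose null rate is ~0 and
which a planted tract saturates at 1.0 against its donor.  The ancestry
LRT is a documented stand-in for the unprinted original construction:
per-group log-likelihood of the focal pig's alleles under group allele
frequencies (leave-one-out when the focal belongs to the group), clamped
to [1/(2n+2), 1 − 1/(2n+2)]; Λ = 2(lnL_A − lnL_B).

## Differential scans

Near-fixation uses strict inequalities (>0.80 / <0.20) in either
orientation, mirroring the ">80% … <20%" rule.  χ² tests are classical
Pearson on 2×2 allele-count tables without continuity correction (the
expected-count coverage filter implies the classical test); whether
carrier or allele counts were used originally is unstated, and allele
counts are chosen for SNPs/indels while SVs use per-sample
presence/absence (SV genotypes are not dosage-resolved).  Adjustment is
Benjamini–Hochberg or Bonferroni via statsmodels; the suite cross-checks
BH against a by-hand step-up.

## Synthetic data: what it emulates and what it does not

Per-site ancestral frequencies are drawn U(0.05, 0.95) — kept interior so
every site is polymorphic in expectation and frequency-recovery tests are
well-posed — and group frequencies follow Balding–Nichols
Beta(p(1−F)/F, (1−p)(1−F)/F), one drift knob per group.  Sites are
unlinked except where structure is planted; a separate copy-with-mutation
founder-lineage process (per-bp lineage-switch probability) supplies
linked haplotypes for LD work, with an analytic halving distance of about
ln2/(2c) used as a factor-2 design check.  An alternative
`freq_spectrum="neutral"` mode draws allele counts ∝ 1/i (the neutral
SFS, F = 0 only); this is the regime in which θπ and θw agree in
expectation, and the neutrality test uses it.

Planted introgression copies a randomly chosen donor's full diploid
genotype across the tract, so recipient-vs-donor sharing is exactly 1
there.  Tracts for different recipients are laid non-overlapping: two
recipients carrying donor material over the same interval would inflate
each other's own-group sharing and mask the signal.  The tract-recovery
study conditions are divergence_F = 0.45 with ~300 SNPs per 100 Kb
window and 2 Mb tracts.  At mild drift (F ≈ 0.2) the tract-window ratio
under this model is analytically ≈ cross_base/((1 + 5·own_base)/6) ≈ 0.86
and cannot cross the 0.8 threshold; F = 0.45 reproduces the
strongly-contrasted regime of real between-continent pig group pairs, in
which flagged windows cover ≥ 80–100% of tract length with a ~0% null
flag rate.

The X block writes two complementary backgrounds (S flips N at 90% of
markers) onto assigned samples, with mosaics switching at specified
breakpoints and optional per-allele flip noise; males are haploid coded
as homozygous.  The toy genome is random sequence with non-overlapping
two-exon CDS genes (codon-multiple length, both strands, GFF3 phase set).

None of this emulates linkage beyond the planted structures, recombination
maps, mutation-rate heterogeneity, sequencing error or genotype
uncertainty.  Passing recovery tests therefore demonstrates correctness
of the estimators and scans under their stated models — not calibration
on real resequencing data, whose headline values (e.g. genome-wide θ or
F_ST levels) are outside what a desk-scale synthetic panel can reproduce.

## Problem sizes

The default test and acceptance runs use panels of 12–31 samples,
2 000–15 000 sites over 1–10 Mb contigs, 400 breakpoint simulations and
100 random trees; these sizes give sub-minute module runtimes while
keeping every Monte-Carlo assertion comfortably powered.

## Known limitations

* The D′ CI grid (0.001) bounds CI resolution; Haploview-compatible in
  spirit, not bit-for-bit.
* EM phasing is exact only up to 12 markers per window; long-range
  phasing must window and stitch.
* The admixture EM can require restarts at larger K; the likelihood
  surface is multimodal and only the best of the seeded restarts is kept.
* `read_vcf` loads everything into memory; panels beyond a few million
  records need chunking by region.
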