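"""Pairwise linkage disequilibrium, EM phasing, LD decay and Gabriel blocks.

For two biallelic sites with haplotype frequency ``p_AB`` and allele
frequencies ``p_A``, ``p_B``:

    D  = p_AB - p_A p_B
    r2 = D^2 / (p_A (1 - p_A) p_B (1 - p_B))
    D' = D / D_max   with the sign-appropriate D_max.

The D' confidence bounds come from a profile likelihood over D' on the
2x2 haplotype counts (grid step 0.001, 2.5%/97.5% bounds).  Haplotype
blocks follow the Gabriel confidence-interval definition: a pair is in
strong LD when CI_low >= 0.70 and CI_high >= 0.98, shows strong
recombination when CI_high < 0.90, and a block is a marker run whose
outermost pair is in strong LD with >= 95% of informative pairs strong;
blocks are accepted greedily longest-first without overlap.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRONG_LD_LOW = 0.70
STRONG_LD_HIGH = 0.98
RECOMB_HIGH = 0.90
BLOCK_STRONG_FRACTION = 0.95


@dataclass
class LDPair:
    i: int
    j: int
    distance: int
    D: float
    Dprime: float
    r2: float
    ci_low: float
    ci_high: float

    @property
    def strong_ld(self) -> bool:
        return self.ci_low >= STRONG_LD_LOW and self.ci_high >= STRONG_LD_HIGH

    @property
    def strong_recomb(self) -> bool:
        return self.ci_high < RECOMB_HIGH

    @property
    def informative(self) -> bool:
        return self.strong_ld or self.strong_recomb


@dataclass
class LDBlock:
    start_index: int
    end_index: int
    start_pos: int
    end_pos: int
    n_markers: int
    strong_fraction: float


@dataclass
class DecayCurve:
    midpoints: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    half_decay_distance: float | None
    half_max_r2: float

    @property
    def reached(self) -> bool:
        return self.half_decay_distance is not None


class MonomorphicSiteError(ValueError):
    """LD is undefined when a site is monomorphic in the haplotype set."""


def _hap_counts(hap_i: np.ndarray, hap_j: np.ndarray):
    both = (hap_i >= 0) & (hap_j >= 0)
    a, b = hap_i[both], hap_j[both]
    n11 = int(((a == 1) & (b == 1)).sum())
    n10 = int(((a == 1) & (b == 0)).sum())
    n01 = int(((a == 0) & (b == 1)).sum())
    n00 = int(((a == 0) & (b == 0)).sum())
    return n11, n10, n01, n00


def ld_from_counts(counts):
    """Core LD quantities from the four haplotype counts.

    Accepts counts in the order (n11, n10, n01, n00) where allele "1" at
    each site is the alt allele.  Returns (D, Dprime_abs, r2, pA, pB).
    """
    n11, n10, n01, n00 = counts
    n = n11 + n10 + n01 + n00
    if n == 0:
        raise MonomorphicSiteError("no complete haplotypes")
    pA = (n11 + n10) / n
    pB = (n11 + n01) / n
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise MonomorphicSiteError("monomorphic site; LD undefined")
    pAB = n11 / n
    D = pAB - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = abs(D) / dmax if dmax > 0 else 0.0
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return D, min(dprime, 1.0), min(r2, 1.0), pA, pB


def dprime_ci(counts, grid_step: float = 0.001, lower_q: float = 0.025, upper_q: float = 0.975):
    """Profile-likelihood confidence bounds on |D'| from haplotype counts.

    Allele frequencies are fixed at their MLEs; the likelihood of each |D'|
    on a uniform grid is normalized and the (2.5%, 97.5%) bounds of the
    resulting distribution returned.
    """
    n11, n10, n01, n00 = counts
    n = n11 + n10 + n01 + n00
    pA = (n11 + n10) / n
    pB = (n11 + n01) / n
    D_obs = n11 / n - pA * pB
    if D_obs < 0:
        # relabel site B alleles so D >= 0; |D'| unchanged
        n11, n10, n01, n00 = n10, n11, n00, n01
        pB = 1 - pB
    dmax = min(pA * (1 - pB), (1 - pA) * pB)
    if dmax <= 0:
        return 0.0, 0.0
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    D = grid * dmax
    f11 = np.clip(pA * pB + D, 1e-12, 1.0)
    f10 = np.clip(pA * (1 - pB) - D, 1e-12, 1.0)
    f01 = np.clip((1 - pA) * pB - D, 1e-12, 1.0)
    f00 = np.clip((1 - pA) * (1 - pB) + D, 1e-12, 1.0)
    loglik = n11 * np.log(f11) + n10 * np.log(f10) + n01 * np.log(f01) + n00 * np.log(f00)
    lik = np.exp(loglik - loglik.max())
    cdf = np.cumsum(lik)
    cdf /= cdf[-1]
    low = float(grid[np.searchsorted(cdf, lower_q)])
    high = float(grid[np.searchsorted(cdf, upper_q)])
    return low, high


def pairwise_ld(hap_i: np.ndarray, hap_j: np.ndarray, pos_i: int = 0, pos_j: int = 0,
                i: int = 0, j: int = 0) -> LDPair:
    """LD summary for one ordered marker pair from phased haplotypes."""
    counts = _hap_counts(hap_i, hap_j)
    D, dprime, r2, _, _ = ld_from_counts(counts)
    lo, hi = dprime_ci(counts)
    return LDPair(i, j, abs(pos_j - pos_i), D, dprime, r2, lo, hi)


# ---------------------------------------------------------------------------
# EM haplotype phasing
# ---------------------------------------------------------------------------

MAX_PHASE_MARKERS = 12


def _compatible_pairs(genotype):
    """All ordered haplotype pairs (as tuples) compatible with one genotype.

    Missing entries (-1) are treated as unconstrained.
    """
    sites = []
    for g in genotype:
        if g == 0:
            sites.append([(0, 0)])
        elif g == 2:
            sites.append([(1, 1)])
        elif g == 1:
            sites.append([(0, 1), (1, 0)])
        else:  # missing
            sites.append([(0, 0), (0, 1), (1, 0), (1, 1)])
    pairs = []
    for combo in itertools.product(*sites):
        h1 = tuple(c[0] for c in combo)
        h2 = tuple(c[1] for c in combo)
        pairs.append((h1, h2))
    return pairs


def em_phase_window(genotypes, tol: float = 1e-6, max_iter: int = 1000):
    """EM haplotype phasing for a window of m <= 12 biallelic markers.

    ``genotypes`` is (n_individuals, m) with entries 0/1/2 (-1 missing).
    Returns ``(freqs, phases)``: a dict haplotype-tuple -> frequency and,
    per individual, ``(h1, h2, posterior)`` for the most probable phase.
    The E-step splits each ambiguous genotype across compatible ordered
    pairs proportionally to the product of current haplotype frequencies.
    """
    G = np.asarray(genotypes)
    n, m = G.shape
    if m > MAX_PHASE_MARKERS:
        raise ValueError(
            f"window has {m} markers; phase at most {MAX_PHASE_MARKERS} "
            "markers at a time (use windowed phasing)"
        )
    pair_lists = [_compatible_pairs(G[i]) for i in range(n)]
    hap_space = sorted({h for pl in pair_lists for p in pl for h in p})
    idx = {h: k for k, h in enumerate(hap_space)}
    H = len(hap_space)
    f = np.full(H, 1.0 / H)

    pair_idx = [
        np.array([[idx[h1], idx[h2]] for h1, h2 in pl], dtype=int)
        for pl in pair_lists
    ]
    prev_ll = -np.inf
    for _ in range(max_iter):
        counts = np.zeros(H)
        ll = 0.0
        for pi in pair_idx:
            w = f[pi[:, 0]] * f[pi[:, 1]]
            tot = w.sum()
            if tot <= 0:
                w = np.full(len(w), 1.0 / len(w))
                tot = 1.0
            else:
                ll += np.log(tot)
                w = w / tot
            np.add.at(counts, pi[:, 0], w)
            np.add.at(counts, pi[:, 1], w)
        f = counts / counts.sum()
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll

    freqs = {h: float(f[idx[h]]) for h in hap_space if f[idx[h]] > 1e-9}
    phases = []
    for pi, pl in zip(pair_idx, pair_lists):
        w = f[pi[:, 0]] * f[pi[:, 1]]
        tot = w.sum()
        post = w / tot if tot > 0 else np.full(len(w), 1.0 / len(w))
        # merge ordered duplicates (h1, h2)/(h2, h1) into unordered phases
        best_k = int(np.argmax(post))
        h1, h2 = pl[best_k]
        unordered = post[best_k]
        for k, (a, b) in enumerate(pl):
            if k != best_k and (a, b) == (h2, h1):
                unordered += post[k]
        phases.append((h1, h2, float(unordered)))
    return freqs, phases


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def ld_decay(
    positions: np.ndarray,
    haps: np.ndarray,
    max_distance: int = 500_000,
    bin_width: int = 5_000,
) -> DecayCurve:
    """Binned mean r2 against inter-marker distance, with half-max distance.

    All intra-contig pairs within ``max_distance`` are binned at
    ``bin_width``; the half-decay distance is the first distance (linear
    interpolation between bin midpoints) at which mean r2 falls to half its
    maximum, or None when never reached.
    """
    positions = np.asarray(positions)
    poly = [k for k in range(haps.shape[0])
            if 0 < (haps[k][haps[k] >= 0]).mean() < 1]
    if len(poly) < 2:
        raise ValueError("need >= 2 polymorphic sites")
    n_bins = int(np.ceil(max_distance / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for a in range(len(poly)):
        for b in range(a + 1, len(poly)):
            i, j = poly[a], poly[b]
            dist = abs(int(positions[j]) - int(positions[i]))
            if dist > max_distance or dist == 0:
                continue
            try:
                _, _, r2, _, _ = ld_from_counts(_hap_counts(haps[i], haps[j]))
            except MonomorphicSiteError:
                continue
            k = min(dist // bin_width, n_bins - 1)
            sums[k] += r2
            counts[k] += 1
    if counts.sum() == 0:
        raise ValueError("no marker pair within max_distance")
    used = counts > 0
    mids = (np.arange(n_bins) * bin_width + bin_width / 2.0)[used]
    means = (sums[used] / counts[used])
    half = means.max() / 2.0
    half_dist = None
    for k in range(len(means)):
        if means[k] <= half:
            if k == 0:
                half_dist = float(mids[0])
            else:
                x0, x1 = mids[k - 1], mids[k]
                y0, y1 = means[k - 1], means[k]
                half_dist = float(x0 + (y0 - half) * (x1 - x0) / (y0 - y1))
            break
    return DecayCurve(mids, means, counts[used], half_dist, float(half))


# ---------------------------------------------------------------------------
# Gabriel blocks and marker thinning
# ---------------------------------------------------------------------------

def compute_ld_pairs(positions, haps, max_distance=500_000, min_maf=0.0):
    """LDPair for each ordered in-range marker pair; None where undefined.

    Markers failing the MAF filter are excluded entirely (their pairs are
    absent, matching a pre-filtering step).
    Returns (pairs dict keyed by (i, j), kept marker indices).
    """
    positions = np.asarray(positions)
    if not np.all(np.diff(positions) >= 0):
        raise ValueError("markers must be ordered by position")
    kept = []
    for k in range(haps.shape[0]):
        h = haps[k][haps[k] >= 0]
        if h.size == 0:
            continue
        maf = min(h.mean(), 1 - h.mean())
        if maf > min_maf or (min_maf == 0.0 and 0 < h.mean() < 1):
            kept.append(k)
    pairs = {}
    for a in range(len(kept)):
        for b in range(a + 1, len(kept)):
            i, j = kept[a], kept[b]
            if abs(int(positions[j]) - int(positions[i])) > max_distance:
                continue
            try:
                pairs[(i, j)] = pairwise_ld(
                    haps[i], haps[j], int(positions[i]), int(positions[j]), i, j
                )
            except MonomorphicSiteError:
                pairs[(i, j)] = None
    return pairs, kept


def _span_is_block(pairs, kept, a, b):
    """Gabriel test for the candidate span kept[a] .. kept[b]."""
    outer = pairs.get((kept[a], kept[b]))
    if outer is None or not outer.strong_ld:
        return False, 0.0
    informative = strong = 0
    for x in range(a, b + 1):
        for y in range(x + 1, b + 1):
            p = pairs.get((kept[x], kept[y]))
            if p is None or not p.informative:
                continue
            informative += 1
            if p.strong_ld:
                strong += 1
    if informative == 0:
        return False, 0.0
    frac = strong / informative
    return frac >= BLOCK_STRONG_FRACTION, frac


def gabriel_blocks(
    positions,
    haps,
    min_maf: float = 0.0,
    max_distance: int = 500_000,
) -> list:
    """Haplotype blocks by the Gabriel confidence-interval method.

    Candidate spans whose outermost pair is in strong LD and with >= 95%
    of informative pairs strong are accepted greedily, longest (in bp)
    first, without marker overlap.
    """
    positions = np.asarray(positions)
    pairs, kept = compute_ld_pairs(positions, haps, max_distance, min_maf)
    candidates = []
    for a in range(len(kept)):
        for b in range(a + 1, len(kept)):
            ok, frac = _span_is_block(pairs, kept, a, b)
            if ok:
                span = int(positions[kept[b]]) - int(positions[kept[a]])
                candidates.append((span, a, b, frac))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    taken = np.zeros(len(kept), dtype=bool)
    blocks = []
    for span, a, b, frac in candidates:
        if taken[a : b + 1].any():
            continue
        taken[a : b + 1] = True
        blocks.append(
            LDBlock(
                kept[a], kept[b],
                int(positions[kept[a]]), int(positions[kept[b]]),
                b - a + 1, frac,
            )
        )
    blocks.sort(key=lambda bl: bl.start_pos)
    return blocks


def thin_markers(positions, min_gap: int = 3_000) -> list:
    """Greedy thinning: keep the first marker, then each >= min_gap onward."""
    positions = list(positions)
    if any(positions[k] > positions[k + 1] for k in range(len(positions) - 1)):
        raise ValueError("positions must be sorted ascending")
    kept = []
    last = None
    for k, p in enumerate(positions):
        if last is None or p - last >= min_gap:
            kept.append(k)
            last = p
    return kept
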