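"""Windowed haplotype-sharing introgression scan between group pairs.

For every 100 Kb window with at least 10 SNPs, and whenever at least three
comparisons are possible per group, each focal pig's mean allele sharing
with its own group (S_own) and with the other group (S_cross) is computed;
the ratio R = S_own / S_cross below 0.8 flags putative introgression.
Sharing between two diploid genotypes at a SNP is IBS/2: 1 for identical
genotypes, 0.5 for one shared allele, 0 for none.  A separate criterion
flags windows where >= 90% of SNPs are shared with some member of the
other group.  A per-window likelihood-ratio statistic compares the focal
genotype's fit to each group's allele frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeTable, make_interval
from .stats import iter_windows

logger = logging.getLogger(__name__)

RATIO_THRESHOLD = 0.8
HIGH_SHARING_THRESHOLD = 0.90


@dataclass
class SharingWindow:
    sample: str
    contig: str
    start: int
    end: int
    window_index: int
    n_snps: int
    s_own: float
    s_cross: float
    ratio: float
    introgressed: bool
    cross_group: str


@dataclass
class IntrogressionSegment:
    sample: str
    contig: str
    start: int
    end: int
    donor_group: str
    mean_ratio: float
    n_windows: int


def pairwise_sharing(dos_i: np.ndarray, dos_j: np.ndarray) -> float:
    """Mean allele-sharing score over SNPs genotyped in both samples.

    Dosage-coded genotypes: score = 1 - |a - b| / 2.  NaN when no SNP is
    comparable.
    """
    both = ~np.isnan(dos_i) & ~np.isnan(dos_j)
    if not both.any():
        return float("nan")
    return float(np.mean(1.0 - np.abs(dos_i[both] - dos_j[both]) / 2.0))


def _window_masks(table: GenotypeTable, window: int):
    contigs = table.variants["contig"].to_numpy()
    positions = table.variants["pos"].to_numpy()
    for contig in dict.fromkeys(contigs):
        clen = table.contig_lengths.get(contig, int(positions[contigs == contig].max()))
        for w, (start, end) in enumerate(iter_windows(clen, window)):
            mask = (contigs == contig) & (positions >= start) & (positions <= end)
            yield contig, w, start, end, mask


def sharing_ratio_scan(
    table: GenotypeTable,
    group_pair: tuple,
    window: int = 100_000,
    min_snps: int = 10,
    min_comparisons: int = 3,
    ratio_threshold: float = RATIO_THRESHOLD,
) -> pd.DataFrame:
    """Per-pig sharing-ratio scan over non-overlapping windows.

    Windows failing the SNP or comparison minima are skipped (not emitted).
    Returns one row per (focal pig, eligible window).
    """
    ga, gb = group_pair
    members = {g: table.samples_in_group(g) for g in (ga, gb)}
    for g in (ga, gb):
        if not members[g]:
            raise ValueError(f"unknown or empty group label {g!r}")
    dos = table.dosage()
    sidx = {s: table.sample_index(s) for s in table.samples}
    rows = []
    for contig, w, start, end, mask in _window_masks(table, window):
        if mask.sum() < min_snps:
            continue
        d = dos[mask]
        present = {
            s: ~np.isnan(d[:, sidx[s]]) for g in (ga, gb) for s in members[g]
        }
        for focal_group, cross_group in ((ga, gb), (gb, ga)):
            for focal in members[focal_group]:
                own_scores, cross_scores = [], []
                for other in members[focal_group]:
                    if other == focal:
                        continue
                    sc = pairwise_sharing(d[:, sidx[focal]], d[:, sidx[other]])
                    if not np.isnan(sc):
                        own_scores.append(sc)
                for other in members[cross_group]:
                    sc = pairwise_sharing(d[:, sidx[focal]], d[:, sidx[other]])
                    if not np.isnan(sc):
                        cross_scores.append(sc)
                if len(own_scores) < min_comparisons or len(cross_scores) < min_comparisons:
                    continue
                s_own = float(np.mean(own_scores))
                s_cross = float(np.mean(cross_scores))
                ratio = s_own / s_cross if s_cross > 0 else float("inf")
                rows.append(
                    SharingWindow(
                        focal, contig, start, end, w, int(mask.sum()),
                        s_own, s_cross, ratio, ratio < ratio_threshold, cross_group,
                    )
                )
    return pd.DataFrame([vars(r) for r in rows])


def high_sharing_regions(
    table: GenotypeTable,
    group_pair: tuple,
    window: int = 100_000,
    min_snps: int = 10,
    threshold: float = HIGH_SHARING_THRESHOLD,
) -> pd.DataFrame:
    """Windows where a focal pig shares >= ``threshold`` of SNPs cross-group.

    The window statistic is the maximum, over other-group members, of the
    fraction of comparable SNPs at which the two genotypes are identical
    (sharing score 1); a planted tract reaches fraction 1.0 against its
    donor, while unrelated diverged samples stay far below 0.9.
    """
    ga, gb = group_pair
    members = {g: table.samples_in_group(g) for g in (ga, gb)}
    for g in (ga, gb):
        if not members[g]:
            raise ValueError(f"unknown or empty group label {g!r}")
    dos = table.dosage()
    sidx = {s: table.sample_index(s) for s in table.samples}
    rows = []
    for contig, w, start, end, mask in _window_masks(table, window):
        if mask.sum() < min_snps:
            continue
        d = dos[mask]
        for focal_group, cross_group in ((ga, gb), (gb, ga)):
            for focal in members[focal_group]:
                best = float("nan")
                for other in members[cross_group]:
                    a, b = d[:, sidx[focal]], d[:, sidx[other]]
                    both = ~np.isnan(a) & ~np.isnan(b)
                    if not both.any():
                        continue
                    frac = float(np.mean(a[both] == b[both]))
                    if np.isnan(best) or frac > best:
                        best = frac
                if np.isnan(best):
                    continue
                rows.append(
                    {"sample": focal, "contig": contig, "start": start, "end": end,
                     "window_index": w, "n_snps": int(mask.sum()),
                     "shared_snp_fraction": best,
                     "introgressed": best >= threshold,
                     "cross_group": cross_group}
                )
    return pd.DataFrame(rows)


def merge_flagged_windows(windows: pd.DataFrame, gap_tolerance: int = 0) -> list:
    """Merge consecutive flagged windows per focal pig into segments.

    ``gap_tolerance`` is the number of unflagged (or missing) windows
    allowed inside one segment; default 0 (strict adjacency).
    """
    if windows.empty:
        return []
    flagged = windows[windows["introgressed"]].sort_values(
        ["sample", "contig", "window_index"]
    )
    segments = []
    for (sample, contig, cross), grp in flagged.groupby(
        ["sample", "contig", "cross_group"], sort=True
    ):
        cur = None
        for _, row in grp.iterrows():
            if cur is not None and row["window_index"] - cur["last_w"] <= gap_tolerance + 1:
                cur["end"] = row["end"]
                cur["ratios"].append(row.get("ratio", np.nan))
                cur["n"] += 1
                cur["last_w"] = row["window_index"]
            else:
                if cur is not None:
                    segments.append(cur)
                cur = {
                    "sample": sample, "contig": contig, "start": row["start"],
                    "end": row["end"], "ratios": [row.get("ratio", np.nan)],
                    "n": 1, "last_w": row["window_index"], "cross": cross,
                }
        if cur is not None:
            segments.append(cur)
    return [
        IntrogressionSegment(
            s["sample"], s["contig"], int(s["start"]), int(s["end"]), s["cross"],
            float(np.nanmean(s["ratios"])) if not all(np.isnan(s["ratios"])) else float("nan"),
            s["n"],
        )
        for s in segments
    ]


def window_lrt(
    table: GenotypeTable,
    focal: str,
    group_a: str,
    group_b: str,
    variant_mask,
) -> float:
    """Likelihood-ratio statistic for the focal genotype's group ancestry.

    Per group G, lnL_G sums log f_G over the focal pig's carried alleles in
    the window, with allele frequencies clamped to
    ``[1/(2 n_G + 2), 1 - 1/(2 n_G + 2)]``; frequencies are leave-one-out
    when the focal pig belongs to the group.  Returns
    ``Lambda = 2 (lnL_A - lnL_B)``; positive favors group A ancestry.
    """
    fi = table.sample_index(focal)
    lnl = {}
    for g in (group_a, group_b):
        members = [s for s in table.samples_in_group(g) if s != focal]
        if not members:
            raise ValueError(f"group {g} has no members besides the focal pig")
        freq = table.allele_freq(members, variant_mask)
        clamp = 1.0 / (2.0 * len(members) + 2.0)
        freq = np.clip(freq, clamp, 1.0 - clamp)
        g_alleles = table.genotypes[variant_mask][:, fi, :]
        total = 0.0
        used = 0
        for col in (0, 1):
            a = g_alleles[:, col]
            ok = (a >= 0) & ~np.isnan(freq)
            total += float(
                np.sum(np.where(a[ok] == 1, np.log(freq[ok]), np.log(1 - freq[ok])))
            )
            used += int(ok.sum())
        if used == 0:
            return float("nan")
        lnl[g] = total
    return 2.0 * (lnl[group_a] - lnl[group_b])
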