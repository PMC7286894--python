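"""X-chromosome LD-block haplotype classification and breakpoint mapping.

Inside a declared low-recombination block, each haplotype is recoded
relative to the reference genome (0 = same allele, 1 = opposite).  Two
ancestral backgrounds are defined by anchor groups — S from southern
Chinese samples, N from European samples plus northern wild boars — as
per-marker majority consensuses.  Every sample is then classified as pure
N, pure S, a recombinant N/S mosaic, or unclassified; mosaics are
segmented by a dynamic program with a switch penalty, and each switch is
reported as the open interval between the last informative marker
consistent with the left background and the first informative marker
consistent with the right background.  Per-sample intervals are clustered
into recombination-interval groups whose maximal ranges bound the
conserved core between them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeTable, GenomicInterval, make_interval

logger = logging.getLogger(__name__)

DEFAULT_PURITY = 0.95
DEFAULT_SWITCH_PENALTY = 3.0  # mismatch-equivalents per background switch


@dataclass
class RefRelativeMatrix:
    """Haplotype rows x block markers; 0 same-as-reference, 1 opposite."""

    rows: list                    # haplotype row labels, e.g. "LW_01.0"
    row_samples: list             # sample each row belongs to
    positions: np.ndarray         # marker bp positions
    values: np.ndarray            # (n_rows, n_markers) int8; -1 missing
    block: GenomicInterval | None = None


@dataclass
class BreakpointInterval:
    contig: str
    start: int                    # last informative marker matching left bg
    end: int                      # first informative marker matching right bg
    sample: str = ""
    left: str = ""
    right: str = ""

    def as_interval(self) -> GenomicInterval:
        return make_interval(self.contig, self.start, self.end, self.sample)


@dataclass
class HaplotypeCall:
    sample: str
    row: str
    label: str                    # N | S | recombinant-k | unclassified
    match_n: float
    match_s: float
    breakpoints: list = field(default_factory=list)


def encode_reference_relative(
    table: GenotypeTable,
    block: GenomicInterval,
    reference_alleles=None,
    mode: str = "haplotypes",
) -> RefRelativeMatrix:
    """Recode block genotypes relative to the reference genome's alleles.

    ``reference_alleles`` is the allele index (0=REF, 1=ALT) carried by the
    reference genome at each block marker; by default the VCF REF allele
    (index 0).  In the default ``"haplotypes"`` mode each sample
    contributes its two phased haplotypes as separate rows (a male's
    homozygously-coded haploid X yields two identical rows); unphased
    heterozygotes raise a phase error.
    """
    mask = table.region_mask(block.contig, block.start, block.end)
    if mask.sum() == 0:
        raise ValueError("block contains no markers")
    positions = table.variants.loc[mask, "pos"].to_numpy()
    if reference_alleles is None:
        reference_alleles = np.zeros(int(mask.sum()), dtype=np.int8)
    reference_alleles = np.asarray(reference_alleles)
    if reference_alleles.shape[0] != mask.sum() or (reference_alleles < 0).any():
        raise ValueError("reference allele required for every block marker")
    haps = table.haplotypes(variant_mask=mask)  # (m, 2n); raises PhaseError
    rows, row_samples, values = [], [], []
    for si, s in enumerate(table.samples):
        for h in (0, 1):
            col = haps[:, 2 * si + h]
            v = np.where(col < 0, -1, (col != reference_alleles).astype(np.int8))
            rows.append(f"{s}.{h}")
            row_samples.append(s)
            values.append(v)
    return RefRelativeMatrix(
        rows, row_samples, positions, np.array(values, dtype=np.int8), block
    )


def _consensus(values: np.ndarray) -> np.ndarray:
    """Per-marker majority over rows; -1 where nothing observed."""
    out = np.full(values.shape[1], -1, dtype=np.int8)
    for m in range(values.shape[1]):
        col = values[:, m]
        col = col[col >= 0]
        if col.size:
            out[m] = 1 if col.mean() >= 0.5 else 0
    return out


def _match_fraction(row, consensus):
    use = (row >= 0) & (consensus >= 0)
    if not use.any():
        return np.nan
    return float((row[use] == consensus[use]).mean())


def localize_breakpoints(
    row: np.ndarray,
    cons_n: np.ndarray,
    cons_s: np.ndarray,
    positions: np.ndarray,
    contig: str = "X",
    switch_penalty: float = DEFAULT_SWITCH_PENALTY,
    sample: str = "",
):
    """Segment one haplotype row into N/S backgrounds; report switch intervals.

    A Viterbi-style dynamic program over markers charges one unit per
    mismatch to the active background and ``switch_penalty`` per background
    change, then each change is localized between flanking informative
    markers (markers where the two consensuses differ).

    Returns ``(state_path, intervals)`` where state_path holds "N"/"S" per
    scored marker.
    """
    informative = (cons_n >= 0) & (cons_s >= 0) & (cons_n != cons_s)
    if not informative.any():
        raise ValueError("no informative markers between backgrounds")
    scored = np.where((row >= 0) & (cons_n >= 0) & (cons_s >= 0))[0]
    if scored.size == 0:
        raise ValueError("no scorable markers in row")
    cost_n = (row[scored] != cons_n[scored]).astype(float)
    cost_s = (row[scored] != cons_s[scored]).astype(float)
    m = scored.size
    # DP over two states
    dp = np.zeros((m, 2))
    back = np.zeros((m, 2), dtype=int)
    dp[0] = [cost_n[0], cost_s[0]]
    for k in range(1, m):
        for st, cost in ((0, cost_n[k]), (1, cost_s[k])):
            stay = dp[k - 1, st]
            switch = dp[k - 1, 1 - st] + switch_penalty
            if switch < stay:
                dp[k, st] = switch + cost
                back[k, st] = 1 - st
            else:
                dp[k, st] = stay + cost
                back[k, st] = st
    st = int(np.argmin(dp[-1]))
    path = np.empty(m, dtype=int)
    path[-1] = st
    for k in range(m - 1, 0, -1):
        path[k - 1] = back[k, path[k]]
    states = np.where(path == 0, "N", "S")

    intervals = []
    cons = {0: cons_n, 1: cons_s}

    def _bound(k, background, direction):
        # nearest informative marker matching the background, confirmed by
        # the next informative marker in the same direction (an isolated
        # match is treated as a possible genotyping flip and skipped);
        # falls back to the nearest match when no confirmed one exists
        rng_ = range(k, -1, -1) if direction < 0 else range(k, m)
        matches = [
            scored[x] for x in rng_
            if informative[scored[x]] and row[scored[x]] == cons[background][scored[x]]
        ]
        mismatches = [
            scored[x] for x in rng_
            if informative[scored[x]] and row[scored[x]] == 1 - cons[background][scored[x]]
        ]
        for gi, g in enumerate(matches):
            if gi + 1 < len(matches):
                between = [
                    x for x in mismatches
                    if (matches[gi + 1] < x < g if direction < 0 else g < x < matches[gi + 1])
                ]
                if not between:
                    return int(positions[g])
            else:
                return int(positions[g])
        return None

    for k in range(1, m):
        if path[k] == path[k - 1]:
            continue
        left_bg, right_bg = path[k - 1], path[k]
        left_pos = _bound(k - 1, left_bg, -1)
        right_pos = _bound(k, right_bg, +1)
        if left_pos is None or right_pos is None:
            continue
        intervals.append(
            BreakpointInterval(
                contig, left_pos, right_pos, sample,
                "N" if left_bg == 0 else "S", "N" if right_bg == 0 else "S",
            )
        )
    return states, intervals


def call_major_haplotypes(
    matrix: RefRelativeMatrix,
    groups: dict,
    anchors: dict,
    purity: float = DEFAULT_PURITY,
    switch_penalty: float = DEFAULT_SWITCH_PENALTY,
):
    """Classify every haplotype row as N, S, recombinant-k or unclassified.

    ``groups`` maps sample -> group label; ``anchors`` maps "N"/"S" to the
    group labels anchoring each background consensus.  A row is N or S when
    its match fraction over informative markers reaches ``purity`` for
    exactly one background; otherwise a mosaic segmentation is attempted
    and accepted as recombinant-k (k switches) when every segment matches
    its background at >= purity.
    """
    for key in ("N", "S"):
        anchor_rows = [
            r for r, s in enumerate(matrix.row_samples)
            if groups.get(s) in anchors.get(key, ())
        ]
        if not anchor_rows:
            raise ValueError(f"anchor set for background {key} is empty")
    rows_n = [r for r, s in enumerate(matrix.row_samples) if groups.get(s) in anchors["N"]]
    rows_s = [r for r, s in enumerate(matrix.row_samples) if groups.get(s) in anchors["S"]]
    cons_n = _consensus(matrix.values[rows_n])
    cons_s = _consensus(matrix.values[rows_s])
    informative = (cons_n >= 0) & (cons_s >= 0) & (cons_n != cons_s)

    calls = []
    contig = matrix.block.contig if matrix.block else "X"
    for r, label in enumerate(matrix.rows):
        row = matrix.values[r]
        mn = _match_fraction(row[informative], cons_n[informative])
        ms = _match_fraction(row[informative], cons_s[informative])
        sample = matrix.row_samples[r]
        if not np.isnan(mn) and mn >= purity and (np.isnan(ms) or ms < purity):
            calls.append(HaplotypeCall(sample, label, "N", mn, ms))
            continue
        if not np.isnan(ms) and ms >= purity and (np.isnan(mn) or mn < purity):
            calls.append(HaplotypeCall(sample, label, "S", mn, ms))
            continue
        # try a mosaic fit
        try:
            states, intervals = localize_breakpoints(
                row, cons_n, cons_s, matrix.positions, contig,
                switch_penalty, sample,
            )
        except ValueError:
            calls.append(HaplotypeCall(sample, label, "unclassified", mn, ms))
            continue
        ok = len(intervals) >= 1 and _segments_pure(
            row, cons_n, cons_s, states, informative, purity
        )
        if ok:
            calls.append(
                HaplotypeCall(sample, label, f"recombinant-{len(intervals)}",
                              mn, ms, intervals)
            )
        else:
            calls.append(HaplotypeCall(sample, label, "unclassified", mn, ms))
    return cons_n, cons_s, calls


def _segments_pure(row, cons_n, cons_s, states, informative, purity):
    scored = np.where((row >= 0) & (cons_n >= 0) & (cons_s >= 0))[0]
    seg_start = 0
    for k in range(1, len(states) + 1):
        if k == len(states) or states[k] != states[seg_start]:
            idx = scored[seg_start:k]
            idx = idx[informative[idx]]
            if idx.size:
                cons = cons_n if states[seg_start] == "N" else cons_s
                if (row[idx] == cons[idx]).mean() < purity:
                    return False
            seg_start = k
    return True


@dataclass
class AggregatedIntervals:
    ranges: list            # maximal range per interval group (GenomicInterval)
    cores: list             # conserved core(s) between consecutive groups
    members: list           # list of BreakpointInterval per group


def aggregate_recomb_intervals(calls) -> AggregatedIntervals:
    """Cluster per-sample breakpoint intervals; derive maximal ranges + core.

    Intervals are clustered by overlap; each group's maximal range is the
    union (min start, max end).  The conserved core between consecutive
    groups runs from the left group's inner bound (range end) to the right
    group's inner bound (range start).
    """
    intervals = [bp for c in calls for bp in getattr(c, "breakpoints", [])]
    if not intervals:
        return AggregatedIntervals([], [], [])
    intervals.sort(key=lambda b: (b.start, b.end))
    groups = []
    cur = [intervals[0]]
    cur_end = intervals[0].end
    for bp in intervals[1:]:
        if bp.start <= cur_end:  # >= 1 bp intersection on inclusive intervals
            cur.append(bp)
            cur_end = max(cur_end, bp.end)
        else:
            groups.append(cur)
            cur = [bp]
            cur_end = bp.end
    groups.append(cur)
    ranges = [
        make_interval(g[0].contig, min(b.start for b in g), max(b.end for b in g),
                      f"interval_{k + 1}")
        for k, g in enumerate(groups)
    ]
    cores = [
        make_interval(ranges[k].contig, ranges[k].end, ranges[k + 1].start,
                      f"core_{k + 1}")
        for k in range(len(ranges) - 1)
    ]
    return AggregatedIntervals(ranges, cores, groups)


def calls_to_frame(calls) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": c.sample, "row": c.row, "label": c.label,
                "match_N": round(c.match_n, 6) if not np.isnan(c.match_n) else np.nan,
                "match_S": round(c.match_s, 6) if not np.isnan(c.match_s) else np.nan,
                "breakpoints": ";".join(f"{b.start}-{b.end}" for b in c.breakpoints),
            }
            for c in calls
        ]
    )
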