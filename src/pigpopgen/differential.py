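"""Group-contrast variant scans for body-size candidate discovery.

Three scans mirror the candidate-gene workflow for a panel split into
small and large pigs (or any two groups):

* near-fixation filter — alt-allele frequency strictly > 0.80 in one group
  and strictly < 0.20 in the other (either orientation), optionally
  restricted to nonsynonymous SNPs;
* Pearson chi-square on 2x2 allele-count tables (no continuity
  correction) for indels, with Bonferroni or Benjamini–Hochberg
  adjustment, preceded by a >= 5-genotyped-samples-per-group filter;
* top-K structural variants by chi-square on per-sample presence/absence
  with BH-adjusted P below alpha.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class DifferentialHit:
    variant_index: int
    freq_1: float
    freq_2: float
    statistic: float
    p_raw: float
    p_adjusted: float
    method: str


def _group_samples(table, group, by: str):
    col = table.metadata[by]
    return [s for s in table.samples if col[s] == group]


def near_fixation_scan(
    table,
    group_1: str,
    group_2: str,
    hi: float = 0.80,
    lo: float = 0.20,
    by: str = "size_class",
    effects=None,
    effect_filter: str | None = None,
) -> pd.DataFrame:
    """Variants near fixation for opposite alleles in the two groups.

    Keeps variants with frequency > ``hi`` in one group and < ``lo`` in the
    other (strict inequalities, either orientation).  ``effects`` plus
    ``effect_filter`` restrict the scan to one effect label (e.g.
    ``"nonsynonymous"``).
    """
    s1 = _group_samples(table, group_1, by)
    s2 = _group_samples(table, group_2, by)
    if not s1 or not s2:
        raise ValueError(f"empty group among ({group_1!r}, {group_2!r}) by {by!r}")
    f1 = table.allele_freq(s1)
    f2 = table.allele_freq(s2)
    keep = ((f1 > hi) & (f2 < lo)) | ((f2 > hi) & (f1 < lo))
    keep &= ~np.isnan(f1) & ~np.isnan(f2)
    if effect_filter is not None:
        keep &= np.asarray(pd.Series(effects) == effect_filter)
    idx = np.where(keep)[0]
    out = table.variants.iloc[idx].copy()
    out["variant_index"] = idx
    out[f"freq_{group_1}"] = f1[idx]
    out[f"freq_{group_2}"] = f2[idx]
    out["method"] = "near_fixation"
    return out.reset_index(drop=True)


def group_chisq(counts_a, counts_b):
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    ``counts_a``/``counts_b`` are (allele-1 count, allele-0 count) per
    group.  Returns (chi2, P); a zero margin yields (nan, nan) with a
    warning.
    """
    a, b = counts_a
    c, d = counts_b
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table; chi-square undefined")
        return float("nan"), float("nan")
    n = table.sum()
    chi2 = n * (a * d - b * c) ** 2 / (
        (a + b) * (c + d) * (a + c) * (b + d)
    )
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def adjust_pvalues(pvalues, method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment (Benjamini–Hochberg or Bonferroni).

    Order is preserved; input values must lie in [0, 1].
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    finite = p[~np.isnan(p)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("P values must be in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    key = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    ok = ~np.isnan(p)
    out = np.full_like(p, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method=key)[1]
    return out


def genotyped_counts(table, samples) -> np.ndarray:
    """Per-variant count of genotyped (non-missing) samples in a set."""
    cols = [table.sample_index(s) for s in samples]
    return (table.genotypes[:, cols, :] >= 0).all(axis=2).sum(axis=1)


def coverage_filter(table, group_1: str, group_2: str, min_per_group: int = 5,
                    by: str = "size_class") -> np.ndarray:
    """Boolean mask of variants with >= min genotyped samples in each group."""
    s1 = _group_samples(table, group_1, by)
    s2 = _group_samples(table, group_2, by)
    return (genotyped_counts(table, s1) >= min_per_group) & (
        genotyped_counts(table, s2) >= min_per_group
    )


def allele_counts(table, samples):
    """(alt, ref) allele counts per variant over a sample set."""
    cols = [table.sample_index(s) for s in samples]
    g = table.genotypes[:, cols, :]
    valid = g >= 0
    alt = np.where(valid, g, 0).sum(axis=(1, 2))
    total = valid.sum(axis=(1, 2))
    return alt, total - alt


def chisq_scan(
    table,
    group_1: str,
    group_2: str,
    by: str = "size_class",
    method: str = "bonferroni",
    alpha: float = 0.05,
    variant_mask=None,
) -> pd.DataFrame:
    """Allele-count chi-square scan with multiple-testing adjustment."""
    s1 = _group_samples(table, group_1, by)
    s2 = _group_samples(table, group_2, by)
    idx = (
        np.arange(table.n_variants)
        if variant_mask is None
        else np.where(np.asarray(variant_mask))[0]
    )
    alt1, ref1 = allele_counts(table, s1)
    alt2, ref2 = allele_counts(table, s2)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in idx:
            chi2, p = group_chisq((alt1[i], ref1[i]), (alt2[i], ref2[i]))
            rows.append((i, chi2, p))
    df = pd.DataFrame(rows, columns=["variant_index", "chi2", "p_raw"])
    df["p_adjusted"] = adjust_pvalues(df["p_raw"].to_numpy(), method)
    df["significant"] = df["p_adjusted"] < alpha
    df["method"] = f"chisq_{'fdr' if method == 'BH' else method}"
    n1 = alt1[idx] + ref1[idx]
    n2 = alt2[idx] + ref2[idx]
    df[f"freq_{group_1}"] = np.where(n1 > 0, alt1[idx] / np.maximum(n1, 1), np.nan)
    df[f"freq_{group_2}"] = np.where(n2 > 0, alt2[idx] / np.maximum(n2, 1), np.nan)
    return df


def top_k_sv(
    presence: pd.DataFrame,
    groups: pd.Series,
    group_1: str,
    group_2: str,
    k: int = 100,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Top-K structural variants by group-biased presence/absence.

    ``presence`` is samples x SVs boolean; chi-square is computed on
    carrier counts per group, P values BH-adjusted, hits with adjusted
    P < alpha ranked ascending by (adjusted, raw) and truncated to ``k``.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    s1 = [s for s in presence.index if groups[s] == group_1]
    s2 = [s for s in presence.index if groups[s] == group_2]
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sv in presence.columns:
            c1 = int(presence.loc[s1, sv].sum())
            c2 = int(presence.loc[s2, sv].sum())
            chi2, p = group_chisq((c1, len(s1) - c1), (c2, len(s2) - c2))
            rows.append((sv, c1, c2, chi2, p))
    df = pd.DataFrame(rows, columns=["sv", "carriers_1", "carriers_2", "chi2", "p_raw"])
    df["p_adjusted"] = adjust_pvalues(df["p_raw"].to_numpy(), "BH")
    hits = df[df["p_adjusted"] < alpha].sort_values(
        ["p_adjusted", "p_raw", "sv"], kind="mergesort"
    )
    return hits.head(k).reset_index(drop=True)
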