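"""Pairwise LD, EM phasing, decay curves, Gabriel blocks and thinning."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pigpopgen import simulate as sim
from pigpopgen.ld import (
    BLOCK_STRONG_FRACTION, DecayCurve, MonomorphicSiteError, LDPair,
    compute_ld_pairs, dprime_ci, em_phase_window, gabriel_blocks, ld_decay,
    ld_from_counts, pairwise_ld, thin_markers,
)


def haps_from_strings(*haps):
    """Columns of haplotypes like 'AB' with uppercase = allele 1."""
    arr = np.array(
        [[1 if c.isupper() else 0 for c in h] for h in haps], dtype=np.int8
    )
    return arr.T  # (sites, haplotypes)


class TestPairwiseLd:
    def test_perfect_ld(self):
        h = haps_from_strings("AB", "AB", "ab", "ab")
        p = pairwise_ld(h[0], h[1])
        assert p.r2 == pytest.approx(1.0)
        assert p.Dprime == pytest.approx(1.0)

    def test_equilibrium_zero(self):
        # all four gametes at independence frequencies
        h = haps_from_strings("AB", "Ab", "aB", "ab")
        p = pairwise_ld(h[0], h[1])
        assert p.D == pytest.approx(0.0)
        assert p.r2 == pytest.approx(0.0)

    def test_hand_counts(self):
        """{AB, AB, aB, ab}: D = 0.125, r2 = 1/3, |D'| = 1."""
        h = haps_from_strings("AB", "AB", "aB", "ab")
        p = pairwise_ld(h[0], h[1])
        assert p.D == pytest.approx(0.125)
        assert p.r2 == pytest.approx(1 / 3)
        assert p.Dprime == pytest.approx(1.0)

    def test_monomorphic_sentinel(self):
        h = haps_from_strings("AB", "AB", "Ab", "Ab")
        with pytest.raises(MonomorphicSiteError):
            pairwise_ld(h[0], h[1])

    @given(
        st.tuples(
            st.integers(0, 20), st.integers(0, 20),
            st.integers(0, 20), st.integers(0, 20),
        ).filter(
            lambda c: 0 < c[0] + c[1] < sum(c) and 0 < c[0] + c[2] < sum(c)
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_r2_equals_squared_pearson(self, counts):
        """r2 equals the squared Pearson correlation of indicator vectors."""
        n11, n10, n01, n00 = counts
        x = np.r_[np.ones(n11 + n10), np.zeros(n01 + n00)]
        y = np.r_[np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)]
        _, _, r2, _, _ = ld_from_counts(counts)
        assert r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-9)

    def test_ci_tightens_with_sample_size(self):
        lo_small, _ = dprime_ci((10, 0, 5, 5))
        lo_big, _ = dprime_ci((100, 0, 50, 50))
        assert lo_big > lo_small


class TestEmPhasing:
    def test_unambiguous_plus_double_het(self):
        """AABB, aabb and AaBb: the double het phases as AB|ab."""
        g = np.array([[2, 2], [0, 0], [1, 1]])
        freqs, phases = em_phase_window(g)
        h1, h2, post = phases[2]
        assert {h1, h2} == {(1, 1), (0, 0)}
        assert post > 0.9
        assert freqs[(1, 1)] == pytest.approx(0.5, abs=0.01)

    def test_all_homozygous_direct_count(self):
        g = np.array([[2, 0], [2, 0], [0, 2]])
        freqs, phases = em_phase_window(g)
        assert freqs[(1, 0)] == pytest.approx(2 / 3)
        assert freqs[(0, 1)] == pytest.approx(1 / 3)

    def test_single_het_is_tied(self):
        freqs, phases = em_phase_window(np.array([[1, 1]]))
        assert phases[0][2] == pytest.approx(0.5)

    def test_matches_direct_counting_when_unambiguous(self):
        rng = np.random.default_rng(3)
        haps = rng.integers(0, 2, size=(30, 2, 4))
        # individuals with at most one het site are unambiguous
        g = haps.sum(axis=1)
        keep = (g == 1).sum(axis=1) <= 1
        g = g[keep]
        freqs, _ = em_phase_window(g)
        direct = {}
        for i in range(len(g)):
            row = g[i]
            hets = np.where(row == 1)[0]
            base = tuple((row // 2).astype(int) + (row == 2).astype(int) * 0)
            h = tuple(1 if row[k] == 2 else 0 for k in range(4))
            if len(hets) == 0:
                pair = (h, h)
            else:
                a = list(h)
                b = list(h)
                a[hets[0]] = 1
                b[hets[0]] = 0
                pair = (tuple(a), tuple(b))
            for hp in pair:
                direct[hp] = direct.get(hp, 0) + 1
        total = sum(direct.values())
        for hp, c in direct.items():
            assert freqs.get(hp, 0.0) == pytest.approx(c / total, abs=1e-3)

    def test_capacity_bound(self):
        with pytest.raises(ValueError, match="windowed"):
            em_phase_window(np.zeros((2, 13), dtype=int))


class TestLdDecay:
    def test_all_perfect_ld_sentinel(self):
        h = np.tile(np.array([1, 1, 0, 0], dtype=np.int8), (6, 1))
        curve = ld_decay(np.arange(6) * 1000 + 1, h, max_distance=50_000)
        assert not curve.reached

    def test_hand_interpolation(self):
        """Bin means 0.6 then 0.2: crossing at the interpolated midpoint."""
        # construct two bins directly via the dataclass logic used in ld_decay:
        # distances ~2.5k (r2=0.6 avg) and ~7.5k (r2=0.2 avg) is hard to plant
        # exactly with integer haplotypes, so check the interpolation rule on
        # a curve computed from planted pairs with known r2 values.
        # sites: A-B at distance 2000 (r2 = 1), A-C at 7000 (r2 = 0)
        h = haps_from_strings("ABC", "ABc", "abC", "abc")
        curve = ld_decay(np.array([1, 2001, 7001]), h, max_distance=10_000)
        # bins: [0,5k): pairs AB (r2=1) and BC (dist 5000 -> bin 1)
        assert curve.mean_r2[0] == pytest.approx(1.0)
        assert curve.mean_r2[1] == pytest.approx(0.0)
        # half max = 0.5 crossing between midpoints 2500 and 7500
        assert curve.half_decay_distance == pytest.approx(5000.0)

    def test_copy_with_mutation_design_value(self):
        c = 5e-5
        pos, haps = sim.simulate_linked_haplotypes(40, 400, 500_000, c, seed=2)
        curve = ld_decay(pos, haps)
        design = np.log(2) / (2 * c)  # lineage-survival halving distance
        assert curve.reached
        assert design / 2 <= curve.half_decay_distance <= design * 2

    def test_no_pairs_in_range_rejected(self):
        h = haps_from_strings("AB", "Ab", "aB", "ab")
        with pytest.raises(ValueError, match="no marker pair"):
            ld_decay(np.array([1, 10_000_000]), h, max_distance=1000)


def brute_force_gabriel(positions, haps, max_distance=500_000):
    """Exhaustive span enumeration with direct recounting (oracle)."""
    pairs, kept = compute_ld_pairs(positions, haps, max_distance, 0.0)
    spans = []
    for a in range(len(kept)):
        for b in range(a + 1, len(kept)):
            outer = pairs.get((kept[a], kept[b]))
            if outer is None or not outer.strong_ld:
                continue
            inf = [
                p
                for x, y in itertools.combinations(range(a, b + 1), 2)
                for p in [pairs.get((kept[x], kept[y]))]
                if p is not None and p.informative
            ]
            if inf and sum(p.strong_ld for p in inf) / len(inf) >= BLOCK_STRONG_FRACTION:
                spans.append((positions[kept[b]] - positions[kept[a]], a, b))
    spans.sort(key=lambda s: (-s[0], s[1]))
    chosen = []
    used = set()
    for span, a, b in spans:
        if any(x in used for x in range(a, b + 1)):
            continue
        used.update(range(a, b + 1))
        chosen.append((kept[a], kept[b]))
    return sorted(chosen)


class TestGabrielBlocks:
    def _tight_haps(self, pattern, n_copies=25):
        """Haplotype matrix with a small number of distinct haplotypes."""
        return np.tile(np.array(pattern, dtype=np.int8), (1, n_copies))

    def test_three_markers_perfect_ld_one_block(self):
        # two haplotypes 111/000 at 60% / 40%, 50 copies: tight CIs
        base = np.array([[1, 1, 1], [1, 1, 1], [1, 1, 1], [0, 0, 0], [0, 0, 0]]).T
        haps = self._tight_haps(base, 10)
        blocks = gabriel_blocks(np.array([100, 200, 300]), haps)
        assert len(blocks) == 1
        assert (blocks[0].start_index, blocks[0].end_index) == (0, 2)

    def test_recombination_pair_splits_blocks(self):
        rng = np.random.default_rng(7)
        left = rng.integers(0, 2, size=60)
        right = rng.integers(0, 2, size=60)
        haps = np.array([left, left, right, right])  # 2 perfect-LD runs
        blocks = gabriel_blocks(np.array([1, 101, 10_001, 10_101]), haps)
        assert len(blocks) == 2
        assert {(b.start_index, b.end_index) for b in blocks} == {(0, 1), (2, 3)}

    def test_equilibrium_no_blocks(self):
        rng = np.random.default_rng(11)
        haps = rng.integers(0, 2, size=(5, 200)).astype(np.int8)
        blocks = gabriel_blocks(np.arange(5) * 100 + 1, haps)
        assert blocks == []

    def test_matches_brute_force_enumeration(self):
        """Greedy output equals exhaustive span enumeration (<= 12 markers)."""
        rng = np.random.default_rng(13)
        for trial in range(8):
            m = int(rng.integers(4, 13))
            # blocky structure: consecutive duplicated markers + noise
            core = rng.integers(0, 2, size=(max(2, m // 3), 60))
            rows = [core[rng.integers(0, core.shape[0])] for _ in range(m)]
            haps = np.array(
                [
                    np.where(rng.random(60) < 0.05, 1 - r, r)
                    for r in rows
                ],
                dtype=np.int8,
            )
            positions = np.sort(rng.choice(100_000, size=m, replace=False))
            got = sorted(
                (b.start_index, b.end_index)
                for b in gabriel_blocks(positions, haps)
            )
            assert got == brute_force_gabriel(positions, haps)

    def test_blocks_never_overlap_and_satisfy_95_rule(self):
        rng = np.random.default_rng(17)
        core = rng.integers(0, 2, size=(3, 80))
        haps = np.array(
            [core[min(k // 4, 2)] for k in range(12)], dtype=np.int8
        )
        positions = np.arange(12) * 500 + 1
        blocks = gabriel_blocks(positions, haps)
        pairs, kept = compute_ld_pairs(positions, haps)
        covered = set()
        for b in blocks:
            span = set(range(b.start_index, b.end_index + 1))
            assert not span & covered
            covered |= span
            inf = strong = 0
            for x, y in itertools.combinations(sorted(span), 2):
                p = pairs.get((x, y))
                if p is not None and p.informative:
                    inf += 1
                    strong += p.strong_ld
            assert inf > 0 and strong / inf >= BLOCK_STRONG_FRACTION

    def test_unordered_markers_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            gabriel_blocks(np.array([5, 1]), np.zeros((2, 4), dtype=np.int8))


class TestThinMarkers:
    def test_greedy_trace(self):
        assert thin_markers([0, 1000, 2500, 3100, 6200], 3000) == [0, 3, 4]

    def test_empty_and_zero_gap(self):
        assert thin_markers([], 3000) == []
        assert thin_markers([5, 6, 7], 0) == [0, 1, 2]

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            thin_markers([10, 5], 100)
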