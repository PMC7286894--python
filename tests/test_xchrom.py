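"""X-block haplotype coding, N/S classification and breakpoint localization."""

import numpy as np
import pytest

from pigpopgen import simulate as sim
from pigpopgen.io import PhaseError, make_interval
from pigpopgen.xchrom import (
    BreakpointInterval, RefRelativeMatrix, aggregate_recomb_intervals,
    call_major_haplotypes, encode_reference_relative, localize_breakpoints,
)
from conftest import make_table


def simple_matrix(rows_dict, positions=None, groups=None):
    samples = list(rows_dict)
    values = np.array([rows_dict[s] for s in samples], dtype=np.int8)
    positions = positions if positions is not None else np.arange(values.shape[1]) * 10 + 1
    return (
        RefRelativeMatrix(
            [f"{s}.0" for s in samples], samples, np.asarray(positions), values,
            make_interval("X", int(positions[0]), int(positions[-1])),
        ),
        groups or {},
    )


class TestEncode:
    def _table(self, genotypes, **kw):
        return make_table(genotypes, contig="X", **kw)

    def test_reference_identical_all_zero(self):
        t = self._table(np.zeros((5, 2, 2)))
        m = encode_reference_relative(t, make_interval("X", 1, 1000))
        assert (m.values == 0).all()

    def test_reference_opposite_all_one(self):
        t = self._table(np.ones((5, 2, 2)))
        m = encode_reference_relative(t, make_interval("X", 1, 1000))
        assert (m.values == 1).all()

    def test_unphased_het_raises(self):
        t = self._table([[[0, 1]]], phased=False)
        with pytest.raises(PhaseError):
            encode_reference_relative(t, make_interval("X", 1, 1000))

    def test_both_haplotypes_as_rows(self):
        t = self._table([[[0, 1]]], phased=True)
        m = encode_reference_relative(t, make_interval("X", 1, 1000))
        assert m.values.shape == (2, 1)
        assert sorted(m.values[:, 0]) == [0, 1]


class TestCallMajorHaplotypes:
    def _clean(self, n_markers=40, n_extra=0, extra_rows=None):
        rng = np.random.default_rng(5)
        n_bg = rng.integers(0, 2, n_markers)
        s_bg = 1 - n_bg
        rows = {}
        groups = {}
        for i in range(4):
            rows[f"eu{i}"] = n_bg
            groups[f"eu{i}"] = "Europe"
            rows[f"cs{i}"] = s_bg
            groups[f"cs{i}"] = "CnSouth"
        for name, (row, grp) in (extra_rows or {}).items():
            rows[name] = row
            groups[name] = grp
        m, _ = simple_matrix(rows)
        return m, groups, n_bg, s_bg

    def test_two_clean_clusters_no_recombinants(self):
        m, groups, *_ = self._clean()
        _, _, calls = call_major_haplotypes(
            m, groups, {"N": ("Europe",), "S": ("CnSouth",)}
        )
        labels = {c.label for c in calls}
        assert labels == {"N", "S"}

    def test_planted_single_switch_recombinant(self):
        rng = np.random.default_rng(5)  # same backgrounds as _clean
        n_bg = rng.integers(0, 2, 40)
        s_bg = 1 - n_bg
        mosaic = np.r_[n_bg[:20], s_bg[20:]]
        m, groups, *_ = self._clean(extra_rows={"rec": (mosaic, "CnNorth")})
        _, _, calls = call_major_haplotypes(
            m, groups, {"N": ("Europe",), "S": ("CnSouth",)}
        )
        rec = [c for c in calls if c.sample == "rec"][0]
        assert rec.label == "recombinant-1"
        assert len(rec.breakpoints) == 1
        bp = rec.breakpoints[0]
        # switch planted between marker 19 (pos 191) and marker 20 (pos 201)
        assert bp.start <= 191 and bp.end >= 201

    def test_half_match_no_mosaic_unclassified(self):
        rng = np.random.default_rng(8)
        n_bg = rng.integers(0, 2, 40)
        noise = np.where(rng.random(40) < 0.5, n_bg, 1 - n_bg)
        m, groups, *_ = self._clean(extra_rows={"odd": (noise, "CnNorth")})
        _, _, calls = call_major_haplotypes(
            m, groups, {"N": ("Europe",), "S": ("CnSouth",)}
        )
        odd = [c for c in calls if c.sample == "odd"][0]
        assert odd.label == "unclassified"

    def test_empty_anchor_rejected(self):
        m, groups, *_ = self._clean()
        with pytest.raises(ValueError, match="anchor"):
            call_major_haplotypes(m, groups, {"N": ("Europe",), "S": ("nope",)})


class TestLocalizeBreakpoints:
    def test_clean_switch_interval(self):
        cons_n = np.zeros(10, dtype=np.int8)
        cons_s = np.ones(10, dtype=np.int8)
        row = np.r_[np.zeros(5), np.ones(5)].astype(np.int8)
        positions = np.array([10, 20, 30, 40, 50, 60, 70, 80, 90, 100])
        _, ivs = localize_breakpoints(row, cons_n, cons_s, positions)
        assert len(ivs) == 1
        assert (ivs[0].start, ivs[0].end) == (50, 60)

    def test_uninformative_markers_never_bound(self):
        cons_n = np.array([0, 0, 0, 0, 0, 0], dtype=np.int8)
        cons_s = np.array([1, 0, 1, 1, 0, 1], dtype=np.int8)  # markers 1, 4 uninformative
        row = np.array([0, 0, 0, 1, 0, 1], dtype=np.int8)
        positions = np.array([10, 20, 30, 40, 50, 60])
        _, ivs = localize_breakpoints(row, cons_n, cons_s, positions, switch_penalty=1.0)
        assert len(ivs) == 1
        # bounded by informative markers 30 and 40, not the uninformative 20/50
        assert (ivs[0].start, ivs[0].end) == (30, 40)

    def test_no_informative_markers_rejected(self):
        cons = np.zeros(5, dtype=np.int8)
        with pytest.raises(ValueError, match="informative"):
            localize_breakpoints(cons, cons, cons, np.arange(5) * 10 + 1)

    def test_noisy_mosaic_containment(self):
        """Recovered interval contains the true breakpoint in >= 95% of
        noisy mosaics (2% allele flips).

        Monte Carlo check: the hypothesis "containment probability >= 0.95"
        is rejected only when the observed count falls below the 0.001
        binomial quantile under p = 0.95, so seed-to-seed fluctuation does
        not produce spurious failures.
        """
        from scipy.stats import binom

        rng = np.random.default_rng(99)
        hits = trials = 0
        for _ in range(400):
            m = 200
            positions = np.sort(rng.choice(1_000_000, m, replace=False))
            cons_n = rng.integers(0, 2, m).astype(np.int8)
            cons_s = np.where(rng.random(m) < 0.9, 1 - cons_n, cons_n).astype(np.int8)
            b = int(rng.integers(200_000, 800_000))
            row = np.where(positions <= b, cons_n, cons_s).astype(np.int8)
            row = np.where(rng.random(m) < 0.02, 1 - row, row).astype(np.int8)
            _, ivs = localize_breakpoints(row, cons_n, cons_s, positions)
            trials += 1
            if len(ivs) == 1 and ivs[0].start <= b <= ivs[0].end:
                hits += 1
        assert hits >= binom.ppf(0.001, trials, 0.95)


class TestAggregate:
    def _call(self, *ivs):
        class C:
            breakpoints = [
                BreakpointInterval("X", a, b, "s") for a, b in ivs
            ]
        return C()

    def test_union_of_overlapping_intervals(self):
        agg = aggregate_recomb_intervals([self._call((30, 40), (25, 38))])
        assert len(agg.ranges) == 1
        assert (agg.ranges[0].start, agg.ranges[0].end) == (25, 40)

    def test_core_between_two_groups(self):
        agg = aggregate_recomb_intervals([self._call((10, 20), (80, 95))])
        assert [(r.start, r.end) for r in agg.ranges] == [(10, 20), (80, 95)]
        assert [(c.start, c.end) for c in agg.cores] == [(20, 80)]
        assert agg.cores[0].length_bp == 60

    def test_printed_core_length(self):
        """Endpoints 46,419,569 / 56,819,762 give a 10.40 Mb core."""
        from pigpopgen.io import segment_length

        agg = aggregate_recomb_intervals(
            [self._call((46_219_219, 46_419_569), (56_819_762, 57_752_631))]
        )
        core = agg.cores[0]
        bp, mb = segment_length(core.start, core.end)
        assert bp == 10_400_193
        assert mb == 10.40

    def test_no_recombinants_empty(self):
        agg = aggregate_recomb_intervals([])
        assert agg.ranges == [] and agg.cores == []


class TestRoundTrip:
    def test_simulated_mosaics_fully_recovered(self):
        """Noise-free mosaics: 100% correct labels, breakpoints contained."""
        cfg = sim.SimConfig(
            n_per_group={"CnSouth": 5, "CnNorth": 6, "Europe": 5},
            n_sites=1500, contig_lengths={"X": 1_000_000},
            divergence_F={"CnSouth": 0.1, "CnNorth": 0.1, "Europe": 0.1},
            seed=11,
        )
        t, truth = sim.simulate_populations(cfg)
        assignments = {s: "S" for s in t.samples_in_group("CnSouth")}
        assignments.update({s: "N" for s in t.samples_in_group("Europe")})
        cn = t.samples_in_group("CnNorth")
        assignments.update({cn[0]: "N", cn[1]: "N"})
        assignments[cn[2]] = (400_000,)
        assignments[cn[3]] = (300_000, 700_000)
        t, truth = sim.simulate_x_mosaic(
            t, truth, ("X", 100_000, 900_000, assignments), np.random.default_rng(5)
        )
        m = encode_reference_relative(t, make_interval("X", 100_000, 900_000))
        groups = t.metadata["group"].to_dict()
        _, _, calls = call_major_haplotypes(
            m, groups, {"S": ("CnSouth",), "N": ("Europe",)}
        )
        by_sample = {}
        for c in calls:
            by_sample.setdefault(c.sample, []).append(c)
        for s, assign in assignments.items():
            expected = truth.x_labels[s]
            for c in by_sample[s]:
                if expected == "recombinant":
                    k = len(truth.x_breakpoints[s])
                    assert c.label == f"recombinant-{k}"
                    for b_true, iv in zip(sorted(truth.x_breakpoints[s]),
                                          sorted(c.breakpoints, key=lambda x: x.start)):
                        assert iv.start <= b_true <= iv.end
                else:
                    assert c.label == expected
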