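import numpy as np
import pandas as pd
import pytest

from pigpopgen.io import GenotypeTable, VARIANT_COLUMNS
from pigpopgen import simulate as sim


def make_table(genotypes, samples=None, groups=None, positions=None,
               contig="chr1", phased=True, contig_length=None, size_classes=None):
    """Build a small GenotypeTable from a (sites, samples, 2) array."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_var, n_samp = g.shape[0], g.shape[1]
    samples = samples or [f"s{i}" for i in range(n_samp)]
    groups = groups or ["A"] * n_samp
    positions = positions if positions is not None else (np.arange(n_var) + 1) * 100
    variants = pd.DataFrame(
        {"contig": contig, "pos": positions, "ref": "A", "alt": "G", "vclass": "SNP"}
    )[VARIANT_COLUMNS]
    meta = pd.DataFrame(
        {
            "group": groups,
            "sex": ["F"] * n_samp,
            "size_class": size_classes or ["NA"] * n_samp,
        },
        index=samples,
    )
    ph = np.full((n_var, n_samp), phased, dtype=bool)
    lengths = {contig: contig_length or int(max(positions)) + 100}
    return GenotypeTable(variants, g, ph, samples, meta, lengths)


def random_additive_tree(n_taxa, rng):
    """Random binary tree: returns (path-length matrix, true non-trivial
    leaf bipartitions as frozensets of frozensets of taxon indices)."""
    leafsets = {i: frozenset([i]) for i in range(n_taxa)}
    adj = {i: [] for i in range(n_taxa)}
    next_id = n_taxa
    active = list(range(n_taxa))
    splits = set()
    everything = frozenset(range(n_taxa))
    while len(active) > 1:
        i, j = rng.choice(len(active), 2, replace=False)
        a, b = active[i], active[j]
        new = next_id
        next_id += 1
        adj[new] = []
        for child in (a, b):
            w = float(rng.uniform(0.1, 1.0))
            adj[new].append((child, w))
            adj[child].append((new, w))
        leafsets[new] = leafsets[a] | leafsets[b]
        if 1 < len(leafsets[new]) < n_taxa - 1:
            splits.add(frozenset((leafsets[new], everything - leafsets[new])))
        active = [x for x in active if x not in (a, b)] + [new]
    D = np.zeros((n_taxa, n_taxa))
    for s in range(n_taxa):
        dist = {s: 0.0}
        stack = [s]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for t in range(n_taxa):
            D[s, t] = dist[t]
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D, splits


@pytest.fixture(scope="session")
def diverged_pair():
    """Two groups simulated at strong drift (F = 0.2), one contig."""
    cfg = sim.SimConfig(
        n_per_group={"CnSouth": 6, "CnNorth": 6},
        n_sites=2000,
        contig_lengths={"chr1": 2_000_000},
        divergence_F={"CnSouth": 0.2, "CnNorth": 0.2},
        seed=101,
    )
    return sim.simulate_populations(cfg)


TRACT_CONFIG = dict(
    n_per_group={"CnSouth": 6, "CnNorth": 6},
    n_sites=15_000,
    contig_lengths={"chr1": 5_000_000},
    divergence_F={"CnSouth": 0.45, "CnNorth": 0.45},
    seed=202,
)

TRACT_SPEC = [
    ("CnNorth", "CnSouth_01", "chr1", 500_001, 2_500_000),
    ("CnNorth", "CnSouth_02", "chr1", 2_500_001, 4_500_000),
]


@pytest.fixture(scope="session")
def tract_dataset():
    """Strongly diverged pair with two planted 2 Mb introgression tracts."""
    table, truth = sim.simulate_populations(sim.SimConfig(**TRACT_CONFIG))
    rng = np.random.default_rng(203)
    return sim.plant_introgression_tracts(table, truth, TRACT_SPEC, rng)
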