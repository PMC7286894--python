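"""Population-structure inference: p-distance NJ tree, PCA, admixture EM.

The distance is the diploid allele-sharing p-distance ``1 - IBS/2``
(pairwise-complete over non-missing sites).  The tree is built with the
Saitou–Nei neighbor-joining algorithm; negative branch lengths are clamped
to zero with the excess moved to the sister branch.  PCA follows the usual
genotype-matrix convention: dosages centered and scaled by sqrt(p(1-p)).
Admixture uses the unsupervised binomial mixture model

    g_il ~ Binomial(2, sum_k q_ik f_kl)

fit by expectation-maximization with seeded random restarts; the
log-likelihood is non-decreasing at every step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    names: list
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.names), len(self.names)):
            raise ValueError("distance matrix shape inconsistent with names")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)


def p_distance_matrix(table: GenotypeTable) -> DistanceMatrix:
    """Diploid allele-sharing p-distance ``1 - IBS/2`` between all samples.

    With biallelic dosages a, b the per-site distance is ``|a - b| / 2``;
    the pair value is its mean over sites where both are genotyped.
    """
    if table.n_samples < 2:
        raise ValueError("need >= 2 samples")
    d = table.dosage()  # (sites, samples), NaN missing
    n = table.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(d[:, i]) & ~np.isnan(d[:, j])
            if not both.any():
                raise ValueError(
                    f"no comparable sites for pair ({table.samples[i]}, {table.samples[j]})"
                )
            out[i, j] = out[j, i] = float(np.mean(np.abs(d[both, i] - d[both, j]) / 2.0))
    return DistanceMatrix(list(table.samples), out)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.6g}"


def neighbor_joining(dist: DistanceMatrix) -> str:
    """Saitou–Nei neighbor joining; returns an unrooted newick string.

    At each step the pair minimizing the Q-criterion is joined; branch
    lengths follow the standard formulas.  A negative branch length is
    clamped to 0 and the deficit moved to its sister so the pair's total
    path length is preserved.
    """
    names = list(dist.names)
    n = len(names)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    D = dist.values.copy()
    nodes = [name for name in names]  # newick fragment per active node
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_s, j_s = np.unravel_index(np.argmin(Q), Q.shape)
        if i_s > j_s:
            i_s, j_s = j_s, i_s
        i, j = active[i_s], active[j_s]
        dij = sub[i_s, j_s]
        li = 0.5 * dij + (r[i_s] - r[j_s]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        # distances from the new node to the rest
        new_row = np.zeros(D.shape[0] + 1)
        for k_s, k in enumerate(active):
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (sub[i_s, k_s] + sub[j_s, k_s] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_row) - 1] = new_row[:-1]
        D[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(f"({nodes[i]}:{_fmt(li)},{nodes[j]}:{_fmt(lj)})")
        active = [k for k in active if k not in (i, j)] + [D.shape[0] - 1]

    # resolve the final three nodes as a star (three-point formulas)
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    return f"({nodes[a]}:{_fmt(la)},{nodes[b]}:{_fmt(lb)},{nodes[c]}:{_fmt(lc)});"


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_genotypes(table: GenotypeTable):
    """PCA of the genotype matrix (dosage 0/1/2).

    Columns (sites) are mean-imputed, centered, and scaled by
    ``sqrt(p (1 - p))``; monomorphic columns are dropped.  Returns
    ``(eigenvalues, coordinates)`` with eigenvalues sorted descending and
    coordinates ``(n_samples, n_components)`` = eigenvectors scaled by
    sqrt(eigenvalue).
    """
    if table.n_samples < 2:
        raise ValueError("need >= 2 samples")
    G = table.dosage().T.astype(float)  # samples x sites
    col_mean = np.nanmean(G, axis=0)
    inds = np.where(np.isnan(G))
    G[inds] = np.take(col_mean, inds[1])
    p = col_mean / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all columns monomorphic")
    X = (G[:, poly] - col_mean[poly]) / np.sqrt(p[poly] * (1 - p[poly]))
    cov = X @ X.T / X.shape[1]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.maximum(vals[order], 0.0)
    vecs = vecs[:, order]
    coords = vecs * np.sqrt(vals)[None, :]
    return vals, coords


# ---------------------------------------------------------------------------
# admixture EM
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureFit:
    Q: np.ndarray                 # (n_samples, K) ancestry proportions
    F: np.ndarray                 # (K, n_sites) component allele frequencies
    loglik_trace: list
    K: int
    samples: list = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


def _admixture_loglik(G, M, Q, F) -> float:
    P = np.clip(Q @ F, 1e-12, 1 - 1e-12)
    ll = np.where(M, G * np.log(P) + (2 - G) * np.log(1 - P), 0.0)
    return float(ll.sum())


def admixture_em(
    table_or_dosage,
    K: int,
    seed: int = 0,
    max_iter: int = 10_000,
    tol: float = 1e-6,
    n_restarts: int = 5,
) -> AdmixtureFit:
    """Unsupervised admixture by EM on the binomial mixture likelihood.

    Multiple seeded restarts are run and the best-likelihood fit returned.
    Missing genotypes contribute nothing to the likelihood.  A degenerate
    (empty) component triggers a re-seeded restart.
    """
    if isinstance(table_or_dosage, GenotypeTable):
        G = table_or_dosage.dosage().T
        samples = list(table_or_dosage.samples)
    else:
        G = np.asarray(table_or_dosage, dtype=float)
        samples = [f"s{i}" for i in range(G.shape[0])]
    n, L = G.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        warnings.warn(f"K={K} exceeds sample count {n}")
    M = ~np.isnan(G)
    G0 = np.where(M, G, 0.0)
    Ln = M.sum(axis=1)  # usable sites per individual

    if K == 1:
        F = (G0.sum(axis=0) / np.maximum(2.0 * M.sum(axis=0), 1e-12))[None, :]
        Q = np.ones((n, 1))
        return AdmixtureFit(Q, F, [_admixture_loglik(G0, M, Q, F)], 1, samples)

    rng = np.random.default_rng(seed)
    best = None
    restart = 0
    attempts = 0
    while restart < n_restarts and attempts < 4 * n_restarts:
        attempts += 1
        Q = rng.dirichlet(np.ones(K), size=n)
        F = np.clip(rng.random((K, L)), 0.05, 0.95)
        trace = []
        prev = -np.inf
        for _ in range(max_iter):
            PA = np.clip(Q @ F, 1e-12, 1.0)          # P(allele 1)
            PB = np.clip(Q @ (1 - F), 1e-12, 1.0)    # P(allele 0)
            GA = np.where(M, G0 / PA, 0.0)           # alt alleles / denom
            GB = np.where(M, (2 - G0) / PB, 0.0)
            # expected ancestry-k allele counts
            EQ = Q * (GA @ F.T + GB @ (1 - F).T)     # (n, K)
            Fnum = F * (Q.T @ GA)                    # (K, L)
            Fden = Fnum + (1 - F) * (Q.T @ GB)
            Q = EQ / np.maximum(2.0 * Ln, 1e-12)[:, None]
            Q = Q / Q.sum(axis=1, keepdims=True)
            F = np.clip(Fnum / np.maximum(Fden, 1e-12), 1e-6, 1 - 1e-6)
            ll = _admixture_loglik(G0, M, Q, F)
            trace.append(ll)
            if ll - prev < tol and np.isfinite(prev):
                break
            prev = ll
        if Q.sum(axis=0).min() < 1e-6:  # empty component: re-seed
            logger.info("degenerate admixture component; re-seeding restart")
            continue
        restart += 1
        if best is None or trace[-1] > best.loglik:
            best = AdmixtureFit(Q, F, trace, K, samples)
    return best
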