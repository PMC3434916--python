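"""Population structure: Hudson F_ST, net divergence Da, neighbor-joining,
haplotype grouping, and model-based admixture clustering with Evanno ΔK.

The admixture sampler is a Gibbs sampler for the standard admixture model with
uncorrelated allele frequencies: each allele copy carries a latent cluster of
origin, cluster allele frequencies get Dirichlet(lambda + counts) updates with
lambda = 1, individual membership vectors get Dirichlet(alpha + counts)
updates, and the symmetric Dirichlet concentration alpha is updated by a
Metropolis step under a uniform prior on (0, 10]. The data log-probability is
estimated as mean(lnL) - var(lnL)/2 over post-burn-in samples. Cluster labels
are arbitrary per run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .seq_core import LocusAlignment, MultiLocusDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Differentiation statistics
# ---------------------------------------------------------------------------

def _pair_diffs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All pairwise Hamming distances between rows of a and rows of b."""
    return (a[:, None, :] != b[None, :, :]).sum(axis=2)


def _mean_within(mat: np.ndarray) -> float:
    n = mat.shape[0]
    if n < 2:
        return float("nan")
    d = _pair_diffs(mat, mat)
    iu = np.triu_indices(n, 1)
    return float(d[iu].mean())


def fst_hudson(x: np.ndarray, y: np.ndarray) -> float | None:
    """Hudson/Slatkin/Maddison F_ST = 1 - Hw/Hb on unmasked haplotype matrices.

    Hw averages the two within-population mean pairwise differences; Hb is the
    mean between-population pairwise difference. Returns None when Hb = 0
    (both populations monomorphic and identical).
    """
    hw = (_mean_within(x) + _mean_within(y)) / 2.0
    hb = float(_pair_diffs(x, y).mean())
    if hb == 0:
        return None
    return 1.0 - hw / hb


def fst_matrix(ds: MultiLocusDataset) -> dict[str, pd.DataFrame]:
    """Per-locus pairwise population F_ST tables."""
    pops = ds.popmap.populations()
    out = {}
    for aln in ds.loci:
        unmasked = ~aln.mask
        mats = {}
        for pop in pops:
            idx = [i for i, ind in enumerate(aln.individual_ids) if ds.popmap.population[ind] == pop]
            mats[pop] = aln.seqs[idx][:, unmasked]
        m = pd.DataFrame(index=pops, columns=pops, dtype=float)
        for i, p1 in enumerate(pops):
            m.loc[p1, p1] = 0.0
            for p2 in pops[i + 1 :]:
                if mats[p1].shape[0] < 2 or mats[p2].shape[0] < 2:
                    raise ValueError(f"{aln.locus_name}: {p1}/{p2} needs >= 2 haplotypes each")
                f = fst_hudson(mats[p1], mats[p2])
                m.loc[p1, p2] = m.loc[p2, p1] = np.nan if f is None else f
        out[aln.locus_name] = m
    return out


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix must have zero diagonal")
        self.matrix = m


def da_matrix(ds: MultiLocusDataset) -> DistanceMatrix:
    """Net nucleotide differences Da = Dxy - (pi_x + pi_y)/2 between
    populations, on concatenated unmasked sites across loci. Small negative
    entries from the net correction are legal and preserved."""
    pops = ds.popmap.populations()
    concat = {}
    for pop in pops:
        rows = []
        for aln in ds.loci:
            idx = [i for i, ind in enumerate(aln.individual_ids) if ds.popmap.population[ind] == pop]
            rows.append(aln.seqs[idx][:, ~aln.mask])
        concat[pop] = np.concatenate(rows, axis=1)
    m = np.zeros((len(pops), len(pops)))
    within = {p: _mean_within(concat[p]) for p in pops}
    for i, p1 in enumerate(pops):
        for j in range(i + 1, len(pops)):
            p2 = pops[j]
            dxy = float(_pair_diffs(concat[p1], concat[p2]).mean())
            m[i, j] = m[j, i] = dxy - (within[p1] + within[p2]) / 2.0
    return DistanceMatrix(labels=pops, matrix=m)


# ---------------------------------------------------------------------------
# Neighbor joining (Saitou–Nei)
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> str:
    """Newick tree from a distance matrix by standard Q-matrix neighbor
    joining. Negative branch lengths are truncated to zero with the deficit
    transferred to the adjacent (sister) branch."""
    labels = list(dm.labels)
    if len(labels) < 3:
        raise ValueError("NJ needs >= 3 taxa")
    d = dm.matrix.astype(float).copy()
    nodes = [f"{lab}" for lab in labels]

    def fix_negative(la: float, lb: float) -> tuple[float, float]:
        if la < 0:
            lb += -la
            la = 0.0
        if lb < 0:
            la += -lb
            lb = 0.0
        return la, lb

    while len(nodes) > 2:
        r = len(nodes)
        sums = d.sum(axis=1)
        q = (r - 2) * d - sums[:, None] - sums[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = d[i, j] - li
        li, lj = fix_negative(li, lj)
        new_node = f"({nodes[i]}:{li:.6g},{nodes[j]}:{lj:.6g})"
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        d2 = np.zeros((r - 1, r - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [new_node]
    # final pair: the remaining distance sits on the single connecting branch
    la = max(d[0, 1], 0.0)
    return f"({nodes[0]},{nodes[1]}:{la:.6g});"


# ---------------------------------------------------------------------------
# Haplotype grouping (single linkage)
# ---------------------------------------------------------------------------

def group_haplotypes(aln: LocusAlignment, max_diff: int = 0) -> np.ndarray:
    """Allele codes per haplotype row: single-linkage clusters of distinct
    haplotypes at Hamming distance <= max_diff on unmasked columns.
    max_diff = 0 reduces to identity grouping. Codes are deterministic given
    the sorted order of distinct haplotypes."""
    if max_diff < 0:
        raise ValueError("max_diff must be >= 0")
    sub = aln.seqs[:, ~aln.mask]
    keys = ["".join(row) for row in sub]
    distinct = sorted(set(keys))
    arr = np.array([list(k) for k in distinct], dtype="U1")
    m = len(distinct)
    parent = list(range(m))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(m):
        for j in range(i + 1, m):
            if (arr[i] != arr[j]).sum() <= max_diff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    roots = sorted({find(i) for i in range(m)})
    code_of_root = {r: c for c, r in enumerate(roots)}
    code_of_key = {k: code_of_root[find(i)] for i, k in enumerate(distinct)}
    return np.array([code_of_key[k] for k in keys], dtype=int)


def dataset_to_alleles(
    ds: MultiLocusDataset, max_diff: int = 0
) -> tuple[np.ndarray, list[str]]:
    """(N individuals, L loci, 2 copies) allele-code array for clustering."""
    individuals = ds.individuals
    N, L = len(individuals), len(ds.loci)
    X = np.zeros((N, L, 2), dtype=int)
    for l, aln in enumerate(ds.loci):
        codes = group_haplotypes(aln, max_diff)
        by_ind: dict[str, list[int]] = {}
        for ind, c in zip(aln.individual_ids, codes):
            by_ind.setdefault(ind, []).append(c)
        for i, ind in enumerate(individuals):
            X[i, l, :] = by_ind[ind]
    return X, individuals


# ---------------------------------------------------------------------------
# Admixture clustering
# ---------------------------------------------------------------------------

def _kmeans_labels(X: np.ndarray, J: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Hard K-partition of individuals by k-means on one-hot allele dosages."""
    N, L, C = X.shape
    offs = np.concatenate([[0], np.cumsum(J)])
    feat = np.zeros((N, int(J.sum())))
    for l in range(L):
        for c in range(C):
            np.add.at(feat, (np.arange(N), offs[l] + X[:, l, c]), 1.0)
    if K == 1:
        return np.zeros(N, dtype=int)
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=K, n_init=1, random_state=int(rng.integers(2**31)))
    return km.fit_predict(feat)


@dataclass
class ClusterRun:
    K: int
    Q: np.ndarray  # (N, K) membership fractions
    lnP: float
    alpha_trace: np.ndarray
    seed: int | None
    burn_in: int
    reps: int
    mean_lnL: float = 0.0
    var_lnL: float = 0.0
    lnL_trace: np.ndarray | None = None


def admixture_fit(
    alleles: np.ndarray,
    K: int,
    burn_in: int = 5000,
    reps: int = 20000,
    seed: int | None = None,
    lam: float = 1.0,
    alpha_prior_max: float = 10.0,
    alpha_step: float = 0.25,
    thin_q: int = 10,
) -> ClusterRun:
    """Gibbs sampler for the admixture model on (N, L, 2) allele codes.

    ``reps`` iterations follow ``burn_in``; Q is averaged (thinned) and lnP is
    the mean-minus-half-variance estimator over post-burn-in lnL samples.
    """
    if K < 1:
        raise ValueError("K >= 1 required")
    if burn_in < 0 or reps <= 0:
        raise ValueError("reps > burn_in >= 0 required")
    X = np.asarray(alleles, dtype=int)
    N, L, C = X.shape
    J = X.max(axis=(0, 2)) + 1  # alleles per locus
    Jmax = int(J.max())
    valid = np.zeros((L, Jmax), bool)
    for l in range(L):
        valid[l, : J[l]] = True
    if (J == 1).all() and K > 1:
        logger.warning("monomorphic dataset with K=%d: Q converges to symmetric", K)

    rng = np.random.default_rng(seed)
    Q = rng.dirichlet(np.ones(K), size=N)
    # warm-start from a k-means partition of the one-hot allele matrix:
    # cluster frequencies initialised from the partition counts give every
    # run a data-driven, specialised starting point, so chains reach the
    # stationary region within a short burn-in even when K exceeds the true
    # structure (the stationary distribution itself is unaffected)
    labels = _kmeans_labels(X, J, K, rng)
    P = np.zeros((K, L, Jmax))
    for k in range(K):
        members = np.flatnonzero(labels == k)
        cnt = np.zeros((L, Jmax))
        if members.size:
            for l in range(L):
                vals, c = np.unique(X[members][:, l, :], return_counts=True)
                cnt[l, vals] = c
        g0 = np.maximum(rng.standard_gamma((lam + cnt) * valid), 1e-300) * valid
        P[k] = g0 / g0.sum(axis=1, keepdims=True)
    alpha = 1.0
    l_idx = np.broadcast_to(np.arange(L)[None, :, None], X.shape)

    lnls = []
    alphas = []
    q_sum = np.zeros_like(Q)
    q_samples = 0
    total = burn_in + reps
    for it in range(total):
        # P(copy of individual i at locus l with allele x came from k)
        pk = P[:, l_idx, X]  # (K, N, L, 2)
        w = Q.T[:, :, None, None] * pk
        tot_w = w.sum(axis=0)
        w /= tot_w[None]
        u = rng.random((N, L, C))
        Z = (w.cumsum(axis=0) < u[None]).sum(axis=0)
        Z = np.minimum(Z, K - 1)

        # allele-frequency update: Dirichlet(lambda + counts)
        counts = np.zeros((K, L, Jmax))
        np.add.at(counts, (Z.ravel(), l_idx.ravel(), X.ravel()), 1.0)
        shape = (lam + counts) * valid[None]
        g = rng.standard_gamma(shape)
        g_sum = g.sum(axis=2, keepdims=True)
        P = np.divide(g, g_sum, out=np.zeros_like(g), where=g_sum > 0)

        # membership update: Dirichlet(alpha + counts); tiny clip keeps the
        # alpha Metropolis step finite when gamma draws underflow
        zc = np.zeros((N, K))
        np.add.at(zc, (np.repeat(np.arange(N), L * C), Z.ravel()), 1.0)
        Q = np.maximum(rng.standard_gamma(alpha + zc), 1e-300)
        Q /= Q.sum(axis=1, keepdims=True)
        Q = np.clip(Q, 1e-12, None)
        Q /= Q.sum(axis=1, keepdims=True)

        # alpha Metropolis step (uniform prior on (0, alpha_prior_max])
        if K > 1:
            prop = alpha + rng.normal(0.0, alpha_step)
            if 0.0 < prop <= alpha_prior_max:
                lq = np.log(Q).sum()

                def logtarget(a: float) -> float:
                    return N * (gammaln(K * a) - K * gammaln(a)) + (a - 1.0) * lq

                if np.log(rng.random()) < logtarget(prop) - logtarget(alpha):
                    alpha = prop

        if it >= burn_in:
            pk = P[:, l_idx, X]
            like = (Q.T[:, :, None, None] * pk).sum(axis=0)
            lnls.append(float(np.log(like).sum()))
            alphas.append(alpha)
            if (it - burn_in) % thin_q == 0:
                q_sum += Q
                q_samples += 1

    lnls_arr = np.asarray(lnls)
    mean_lnl = float(lnls_arr.mean())
    var_lnl = float(lnls_arr.var(ddof=1)) if len(lnls_arr) > 1 else 0.0
    q_mean = q_sum / q_samples
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    return ClusterRun(
        K=K,
        Q=q_mean,
        lnP=mean_lnl - var_lnl / 2.0,
        alpha_trace=np.asarray(alphas),
        seed=seed,
        burn_in=burn_in,
        reps=reps,
        mean_lnL=mean_lnl,
        var_lnL=var_lnl,
        lnL_trace=lnls_arr,
    )


# ---------------------------------------------------------------------------
# Evanno ΔK
# ---------------------------------------------------------------------------

@dataclass
class DeltaKTable:
    table: pd.DataFrame
    selected_k: int
    flags: list[str] = field(default_factory=list)


def select_k(runs: dict[int, list[ClusterRun]]) -> DeltaKTable:
    """Evanno ΔK model selection from replicate runs over a K range.

    ΔK(K) = mean_r |lnP_r(K-1) + lnP_r(K+1) - 2 lnP_r(K)| / sd_r(lnP(K)),
    defined for interior K only; K* is the argmax. Requires >= 3 consecutive
    K values with >= 2 runs each.
    """
    ks = sorted(runs)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    n_runs = {k: len(runs[k]) for k in ks}
    if min(n_runs.values()) < 2:
        raise ValueError("need >= 2 runs per K")
    r_min = min(n_runs.values())
    lnp = {k: np.array([run.lnP for run in runs[k][:r_min]]) for k in ks}
    rows = []
    flags: list[str] = []
    for k in ks:
        row = {
            "K": k,
            "mean_lnP": float(lnp[k].mean()),
            "sd_lnP": float(lnp[k].std(ddof=1)),
            "second_diff": np.nan,
            "delta_k": np.nan,
        }
        if ks[0] < k < ks[-1]:
            second = np.abs(lnp[k - 1] + lnp[k + 1] - 2.0 * lnp[k])
            row["second_diff"] = float(second.mean())
            sd = row["sd_lnP"]
            if sd == 0:
                row["delta_k"] = np.inf
                flags.append(f"K={k}: sd(lnP)=0, delta_k infinite")
            else:
                row["delta_k"] = row["second_diff"] / sd
        rows.append(row)
    df = pd.DataFrame(rows)
    interior = df.dropna(subset=["delta_k"])
    selected = int(interior.loc[interior["delta_k"].idxmax(), "K"])
    return DeltaKTable(table=df, selected_k=selected, flags=flags)
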