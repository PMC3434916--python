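"""Coalescent simulation engines and recombination utilities.

Conventions
-----------
All mutation parameters are on the per-locus IMa scale: theta = 4*N_e*u with u
the locus mutation rate per generation, migration rates are per mutation
(m = m_gen / u), and divergence time t is in mutational units (t = T_gen * u).
Internally time is measured so that one locus mutation per lineage per unit
corresponds to u = 1; a deme of parameter theta then has haploid-lineage
pairwise coalescence rate 2/theta.

The standard-neutral simulator (no recombination) is a direct Kingman-tree
sampler supporting fixed-S conditioning: exactly S mutations are placed on the
genealogy with probability proportional to branch length, matching the "number
of polymorphic sites given" convention used for the Tajima's D null. The
two-deme isolation-with-migration simulator and the two-locus tables used for
composite-likelihood rho estimation are built on msprime.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import msprime
import numpy as np


@dataclass
class IMParameters:
    """Six-parameter isolation-with-migration model (IMa scaling).

    theta_sm, theta_b, theta_A : 4*N_e*u per locus for the two descendant
        groups and their ancestor.
    m_sm : migration rate per mutation into the sm group from b (forward in
        time); m_b the reverse direction.
    t : divergence time in mutational units.
    """

    theta_sm: float
    theta_b: float
    theta_A: float
    m_sm: float
    m_b: float
    t: float

    def __post_init__(self) -> None:
        for name in ("theta_sm", "theta_b", "theta_A", "m_sm", "m_b", "t"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.theta_sm == self.theta_b == self.theta_A == 0:
            raise ValueError("at least one theta must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.theta_sm, self.theta_b, self.theta_A, self.m_sm, self.m_b, self.t])

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "IMParameters":
        return cls(*[float(v) for v in x])


PARAM_NAMES = ("theta_sm", "theta_b", "theta_A", "m_sm", "m_b", "t")


@dataclass
class CoalescentSample:
    """Binary haplotype matrix from one simulated locus.

    ``matrix`` is (n_haplotypes, S) of 0/1 (0 = ancestral); ``positions`` are
    strictly increasing in [0, 1); ``populations`` labels each haplotype row.
    """

    matrix: np.ndarray
    positions: np.ndarray
    populations: np.ndarray
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def S(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# Standard-neutral Kingman sampler (no recombination)
# ---------------------------------------------------------------------------

def _branch_spectrum(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and descendant-leaf counts of one Kingman genealogy.

    Time in units of 2N generations (coalescence rate k(k-1)/2 among k
    lineages); returns arrays of length 2n-2 (root branch excluded).
    """
    birth = np.zeros(2 * n - 1)
    counts = np.zeros(2 * n - 1, dtype=np.int64)
    counts[:n] = 1
    lengths = np.zeros(2 * n - 2)
    active = list(range(n))
    t = 0.0
    nxt = n
    for k in range(n, 1, -1):
        t += rng.exponential(2.0 / (k * (k - 1)))
        i = int(rng.integers(k))
        a = active[i]
        active[i] = active[-1]
        active.pop()
        j = int(rng.integers(k - 1))
        b = active[j]
        lengths[a] = t - birth[a]
        lengths[b] = t - birth[b]
        counts[nxt] = counts[a] + counts[b]
        birth[nxt] = t
        active[j] = nxt
        nxt += 1
    return lengths, counts[: 2 * n - 2]


def _genealogy_with_leafsets(
    n: int, rng: np.random.Generator
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Like :func:`_branch_spectrum` but also returns each branch's leaf set."""
    birth = np.zeros(2 * n - 1)
    leafsets: list[np.ndarray | None] = [np.array([i]) for i in range(n)] + [None] * (n - 1)
    lengths = np.zeros(2 * n - 2)
    active = list(range(n))
    t = 0.0
    nxt = n
    for k in range(n, 1, -1):
        t += rng.exponential(2.0 / (k * (k - 1)))
        i = int(rng.integers(k))
        a = active[i]
        active[i] = active[-1]
        active.pop()
        j = int(rng.integers(k - 1))
        b = active[j]
        lengths[a] = t - birth[a]
        lengths[b] = t - birth[b]
        leafsets[nxt] = np.concatenate([leafsets[a], leafsets[b]])
        birth[nxt] = t
        active[j] = nxt
        nxt += 1
    return lengths, leafsets[: 2 * n - 2]  # type: ignore[return-value]


def simulate_fixed_s_pi(
    n: int, S: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean pairwise difference counts from ``reps`` fixed-S neutral genealogies.

    Fast path for the Tajima's D null: a mutation on a branch with k descendant
    leaves contributes k(n-k) pairwise differences, so no site matrix is built.
    """
    npairs = n * (n - 1) / 2.0
    out = np.empty(reps)
    for r in range(reps):
        lengths, counts = _branch_spectrum(n, rng)
        p = lengths / lengths.sum()
        muts = rng.multinomial(S, p)
        out[r] = (muts * counts * (n - counts)).sum() / npairs
    return out


def sim_neutral(
    n: int,
    S: int | None = None,
    theta: float | None = None,
    rho: float = 0.0,
    seed: int | None = None,
) -> CoalescentSample:
    """Simulate one standard-neutral sample under infinite sites.

    Exactly one of ``S`` (fixed number of segregating sites, placed on the
    genealogy proportionally to branch length) or ``theta`` (Poisson mutation
    number with mean theta/2 per unit of total branch length in 2N units) must
    be given. ``rho`` is the per-locus scaled recombination rate 4*N_e*c*L;
    when positive, an ancestral recombination graph over [0, 1) is used.
    """
    if n < 2:
        raise ValueError("n >= 2 required")
    if (S is None) == (theta is None):
        raise ValueError("give exactly one of S (fixed) or theta")
    rng = np.random.default_rng(seed)
    if rho > 0:
        return _sim_neutral_recomb(n, S, theta, rho, rng, seed)
    lengths, leafsets = _genealogy_with_leafsets(n, rng)
    if S is None:
        total = lengths.sum()
        S = int(rng.poisson(theta / 2.0 * total))
    p = lengths / lengths.sum()
    branch_of_mut = rng.choice(len(lengths), size=S, p=p) if S > 0 else np.array([], int)
    positions = np.sort(rng.random(S))
    matrix = np.zeros((n, S), dtype=np.int8)
    for col, b in enumerate(branch_of_mut):
        matrix[leafsets[b], col] = 1
    return CoalescentSample(
        matrix=matrix,
        positions=positions,
        populations=np.array(["pop0"] * n),
        seed=seed,
        metadata={"mode": "fixed_S" if theta is None else "fixed_theta", "rho": rho},
    )


def _sim_neutral_recomb(
    n: int,
    S: int | None,
    theta: float | None,
    rho: float,
    rng: np.random.Generator,
    seed: int | None,
) -> CoalescentSample:
    # N = 0.5 haploid lineages: theta = 2*N*u -> u = theta per locus per
    # generation, and likewise rho = 2*N*r -> r = rho over the unit interval.
    ms_seed = int(rng.integers(1, 2**31))
    ts = msprime.sim_ancestry(
        samples=n,
        ploidy=1,
        population_size=0.5,
        sequence_length=1.0,
        recombination_rate=rho,
        discrete_genome=False,
        random_seed=ms_seed,
    )
    if theta is not None:
        mts = msprime.sim_mutations(
            ts,
            rate=theta,
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
            random_seed=int(rng.integers(1, 2**31)),
        )
        matrix = mts.genotype_matrix().T.astype(np.int8)
        positions = np.array([s.position for s in mts.sites()])
    else:
        positions, matrix = _place_fixed_s(ts, S, rng)
    return CoalescentSample(
        matrix=matrix,
        positions=positions,
        populations=np.array(["pop0"] * n),
        seed=seed,
        metadata={"mode": "fixed_S" if theta is None else "fixed_theta", "rho": rho},
    )


def _place_fixed_s(ts, S: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Place exactly S infinite-site mutations on a (possibly recombining)
    tree sequence, proportional to branch length integrated over span."""
    trees = []
    weights = []
    for tree in ts.trees():
        tl = tree.total_branch_length
        span = tree.interval.right - tree.interval.left
        trees.append((tree.interval.left, tree.interval.right))
        weights.append(tl * span)
    weights = np.asarray(weights)
    probs = weights / weights.sum()
    tree_of_mut = rng.choice(len(trees), size=S, p=probs)
    n = ts.num_samples
    cols = np.zeros((S, n), dtype=np.int8)
    positions = np.empty(S)
    tree_list = [ts.at_index(i) for i in range(ts.num_trees)]
    for k, ti in enumerate(tree_of_mut):
        tree = tree_list[ti]
        left, right = trees[ti]
        positions[k] = rng.uniform(left, right)
        # choose a branch proportional to its length
        nodes = [u for u in tree.nodes() if tree.parent(u) != -1]
        blens = np.array([tree.branch_length(u) for u in nodes])
        u = nodes[int(rng.choice(len(nodes), p=blens / blens.sum()))]
        for leaf in tree.samples(u):
            cols[k, leaf] = 1
    order = np.argsort(positions)
    return positions[order], cols[order].T.copy()


# ---------------------------------------------------------------------------
# Two-deme isolation-with-migration simulator
# ---------------------------------------------------------------------------

def _im_demography(params: IMParameters) -> msprime.Demography:
    """IMa scaling -> msprime demography with u = 1 per locus per generation.

    With haploid lineages (ploidy=1) and deme size N, E[pairwise diversity]
    = 2*N*u; setting N = theta/2 with u = 1 gives E[pi] = theta. Migration is
    set backwards in time: lineages in sm jump to b at rate m_sm, which is the
    forward-in-time gene flow into sm from b (the IMa m_sm convention). The
    split time is t generations since t = T_gen * u and u = 1.
    """
    eps = 1e-9  # msprime requires positive sizes
    dem = msprime.Demography()
    dem.add_population(name="sm", initial_size=max(params.theta_sm, eps) / 2.0)
    dem.add_population(name="b", initial_size=max(params.theta_b, eps) / 2.0)
    dem.add_population(name="anc", initial_size=max(params.theta_A, eps) / 2.0)
    if params.m_sm > 0:
        dem.set_migration_rate(source="sm", dest="b", rate=params.m_sm)
    if params.m_b > 0:
        dem.set_migration_rate(source="b", dest="sm", rate=params.m_b)
    dem.add_population_split(time=max(params.t, eps), derived=["sm", "b"], ancestral="anc")
    return dem


def sim_im(
    params: IMParameters,
    n_sm: int,
    n_b: int,
    locus_scale: float = 1.0,
    seed: int | None = None,
) -> CoalescentSample:
    """Simulate one locus under the two-deme IM model (infinite sites).

    ``locus_scale`` multiplies the locus mutation rate (relative mutation
    weight); haplotype rows are ordered sm first, then b.
    """
    return next(sim_im_replicates(params, n_sm, n_b, [locus_scale], seed=seed))


def sim_im_replicates(
    params: IMParameters,
    n_sm: int,
    n_b: int,
    locus_scales: Sequence[float],
    seed: int | None = None,
) -> Iterator[CoalescentSample]:
    """Simulate independent loci (one per entry of ``locus_scales``)."""
    if n_sm + n_b < 2:
        raise ValueError("need at least 2 haplotypes in total")
    rng = np.random.default_rng(seed)
    dem = _im_demography(params)
    samples = {}
    if n_sm > 0:
        samples["sm"] = n_sm
    if n_b > 0:
        samples["b"] = n_b
    anc_seed = int(rng.integers(1, 2**31))
    replicates = msprime.sim_ancestry(
        samples=samples,
        ploidy=1,
        demography=dem,
        sequence_length=1.0,
        discrete_genome=False,
        random_seed=anc_seed,
        num_replicates=len(locus_scales),
    )
    pops = np.array(["sm"] * n_sm + ["b"] * n_b)
    for scale, ts in zip(locus_scales, replicates):
        mts = msprime.sim_mutations(
            ts,
            rate=float(scale),
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
            random_seed=int(rng.integers(1, 2**31)),
        )
        matrix = mts.genotype_matrix().T.astype(np.int8)
        positions = np.array([s.position for s in mts.sites()])
        yield CoalescentSample(
            matrix=matrix,
            positions=positions,
            populations=pops,
            seed=seed,
            metadata={"locus_scale": float(scale)},
        )


# ---------------------------------------------------------------------------
# Four-gamete test
# ---------------------------------------------------------------------------

def _biallelic_columns(seqs: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices and 0/1 codings of unmasked bi-allelic segregating columns."""
    cols = []
    codes = []
    for j in range(seqs.shape[1]):
        if mask[j]:
            continue
        vals = np.unique(seqs[:, j])
        if len(vals) == 2:
            cols.append(j)
            codes.append((seqs[:, j] == vals[1]).astype(np.int8))
    if not cols:
        return np.array([], int), np.zeros((seqs.shape[0], 0), np.int8)
    return np.array(cols), np.column_stack(codes)


def four_gamete_incompatible(col_a: np.ndarray, col_b: np.ndarray) -> bool:
    """True if two bi-allelic 0/1 columns show all four gametes."""
    gametes = {(int(a), int(b)) for a, b in zip(col_a, col_b)}
    return len(gametes) == 4


def longest_nonrecombining_block(
    aln_or_matrix,
    positions: np.ndarray | None = None,
    length: int | None = None,
) -> tuple[int, int]:
    """Maximal contiguous alignment interval with no four-gamete violation.

    Accepts a LocusAlignment (uses unmasked bi-allelic columns) or a 0/1 site
    matrix plus integer column ``positions`` and total alignment ``length``.
    Returns a 0-based half-open interval; ties resolved to the leftmost start.
    With fewer than 2 segregating sites the whole alignment is returned.
    """
    if positions is None:
        aln = aln_or_matrix
        cols, mat = _biallelic_columns(aln.seqs, aln.mask)
        L = aln.aligned_length
    else:
        mat = np.asarray(aln_or_matrix)
        cols = np.asarray(positions)
        L = int(length)
    S = mat.shape[1]
    if S < 2:
        return (0, L)
    # left[j]: smallest l with sites l..j pairwise compatible
    best_start, best_end = 0, 0
    l = 0
    for j in range(S):
        for i in range(j - 1, l - 1, -1):
            if four_gamete_incompatible(mat[:, i], mat[:, j]):
                l = max(l, i + 1)
                break  # sites left of i cannot raise l further once i+1 > l
        start = int(cols[l - 1]) + 1 if l > 0 else 0
        end = int(cols[j + 1]) if j + 1 < S else L
        if end - start > best_end - best_start:
            best_start, best_end = start, end
    return (best_start, best_end)


# ---------------------------------------------------------------------------
# Composite-likelihood rho estimation (two-locus Monte-Carlo tables)
# ---------------------------------------------------------------------------

PAIR_RHO_GRID = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0)

_TABLE_CACHE: dict = {}


def _canonical_config(col_a: np.ndarray, col_b: np.ndarray) -> tuple[int, int, int]:
    """Canonical two-site sample configuration (minor-allele coded)."""
    n = len(col_a)
    a = col_a if col_a.sum() * 2 <= n else 1 - col_a
    b = col_b if col_b.sum() * 2 <= n else 1 - col_b
    ma, mb = int(a.sum()), int(b.sum())
    n11 = int((a & b).sum())
    if ma > mb or (ma == mb and n11 > min(ma, mb) - n11):
        a, b = b, a
        ma, mb = mb, ma
        n11 = int((a & b).sum())
    return (ma, mb, n11)


def _two_locus_table(
    n: int, mc_reps: int, seed: int, pair_grid: Sequence[float] = PAIR_RHO_GRID
) -> dict[float, dict[tuple, int]]:
    """Monte-Carlo counts of two-site configurations at each pair-rho value.

    Each replicate simulates a two-site ancestry with scaled recombination
    rho_pair between the sites and places exactly one mutation on each
    marginal genealogy proportional to branch length.
    """
    rng = np.random.default_rng(seed)
    table: dict[float, dict[tuple, int]] = {}
    for rho_pair in pair_grid:
        counts: dict[tuple, int] = {}
        anc = msprime.sim_ancestry(
            samples=n,
            ploidy=1,
            population_size=0.5,
            sequence_length=2.0,
            recombination_rate=rho_pair,  # midpoints 0.5 and 1.5 are 1 apart: 2*N*r*d = rho_pair
            discrete_genome=False,
            random_seed=int(rng.integers(1, 2**31)),
            num_replicates=mc_reps,
        )
        for ts in anc:
            cols = []
            for x in (0.5, 1.5):
                tree = ts.at(x)
                nodes = [u for u in tree.nodes() if tree.parent(u) != -1]
                blens = np.array([tree.branch_length(u) for u in nodes])
                u = nodes[int(rng.choice(len(nodes), p=blens / blens.sum()))]
                col = np.zeros(n, np.int8)
                col[list(tree.samples(u))] = 1
                cols.append(col)
            key = _canonical_config(cols[0], cols[1])
            counts[key] = counts.get(key, 0) + 1
        table[float(rho_pair)] = counts
    return table


def _get_two_locus_table(
    n: int, mc_reps: int, seed: int, cache_dir: str | Path | None
) -> dict[float, dict[tuple, int]]:
    key = (n, mc_reps, seed, PAIR_RHO_GRID)
    if key in _TABLE_CACHE:
        return _TABLE_CACHE[key]
    path = None
    if cache_dir is not None:
        digest = hashlib.sha256(repr(key).encode()).hexdigest()[:16]
        path = Path(cache_dir) / f"two_locus_{digest}.json"
        if path.exists():
            raw = json.loads(path.read_text())
            table = {
                float(r): {tuple(map(int, k.split(","))): v for k, v in cfg.items()}
                for r, cfg in raw.items()
            }
            _TABLE_CACHE[key] = table
            return table
    table = _two_locus_table(n, mc_reps, seed)
    _TABLE_CACHE[key] = table
    if path is not None:
        path.parent.mkdir(parents=True, exist_ok=True)
        serial = {
            str(r): {",".join(map(str, k)): v for k, v in cfg.items()} for r, cfg in table.items()
        }
        path.write_text(json.dumps(serial))
    return table


def estimate_rho(
    aln_or_matrix,
    positions: np.ndarray | None = None,
    length: int | None = None,
    grid: Sequence[float] = (0.0, 0.001, 0.002, 0.005, 0.01, 0.02, 0.05),
    mc_reps: int = 400,
    seed: int = 0,
    cache_dir: str | Path | None = None,
    max_pairs: int = 500,
) -> float | None:
    """Composite-likelihood estimate of the per-site population recombination
    parameter rho = 4*N_e*c.

    For every pair of bi-allelic segregating sites the two-locus configuration
    likelihood is looked up (log-interpolated in pair-rho) from a Monte-Carlo
    table keyed by sample size; the composite log-likelihood is summed over
    pairs and maximised over ``grid`` (per-site rho values). Returns None when
    fewer than 2 usable sites exist.
    """
    if positions is None:
        aln = aln_or_matrix
        cols, mat = _biallelic_columns(aln.seqs, aln.mask)
        L = aln.aligned_length
    else:
        mat = np.asarray(aln_or_matrix)
        cols = np.asarray(positions)
        L = int(length) if length is not None else int(cols.max()) + 1
    S = mat.shape[1]
    if S < 2:
        return None
    n = mat.shape[0]
    table = _get_two_locus_table(n, mc_reps, seed, cache_dir)
    pair_grid = np.array(sorted(table))
    support: set[tuple] = set()
    for cfg in table.values():
        support |= set(cfg)

    pairs = [(i, j) for i in range(S) for j in range(i + 1, S)]
    if len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in idx]
    configs = [
        (_canonical_config(mat[:, i], mat[:, j]), float(abs(cols[j] - cols[i]))) for i, j in pairs
    ]
    support |= {c for c, _ in configs}
    n_cells = max(len(support), 1)

    # log P(config | rho_pair) on the table grid, with add-half smoothing
    def log_p(config: tuple, rho_pair: float) -> float:
        rho_pair = min(max(rho_pair, pair_grid[0]), pair_grid[-1])
        k = int(np.searchsorted(pair_grid, rho_pair))
        if k == 0 or pair_grid[k - 1] == rho_pair or (k < len(pair_grid) and pair_grid[k] == rho_pair):
            k = int(np.argmin(np.abs(pair_grid - rho_pair)))
            lo = hi = k
            w = 0.0
        else:
            lo, hi = k - 1, k
            w = (rho_pair - pair_grid[lo]) / (pair_grid[hi] - pair_grid[lo])

        def lp(gridpoint: float) -> float:
            cfg = table[float(gridpoint)]
            reps = sum(cfg.values())
            return float(np.log((cfg.get(config, 0) + 0.25) / (reps + 0.25 * n_cells)))

        if lo == hi:
            return lp(pair_grid[lo])
        return (1 - w) * lp(pair_grid[lo]) + w * lp(pair_grid[hi])

    best_rho, best_ll = None, -np.inf
    for rho_site in grid:
        ll = sum(log_p(cfg, rho_site * d) for cfg, d in configs)
        if ll > best_ll:
            best_ll, best_rho = ll, float(rho_site)
    return best_rho
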