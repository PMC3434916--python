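"""Isolation-with-migration inference and downstream demographic conversions.

The six-parameter IM model (theta_sm, theta_b, theta_A, m_sm, m_b, t; IMa
scaling) is fitted by Gaussian synthetic likelihood over a fixed
summary-statistic vector: per-group segregating sites, pairwise diversity,
haplotype diversity and Tajima's D (aggregated over loci), Hudson's F_ST, and
shared/fixed/private polymorphism counts between the groups. Moments are
estimated from replicate IM simulations at each evaluated parameter point with
common random numbers, and the objective is maximised by a Sobol pilot search
followed by Nelder-Mead inside the prior box. Marginal profiles on a grid give
peaks and 90% highest-density intervals by profile mass.

Each locus enters through its longest four-gamete-clean block (the IM model
assumes no intralocus recombination).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2, qmc

from . import coalsim
from .coalsim import PARAM_NAMES, CoalescentSample, IMParameters
from .neutrality import tajima_d
from .seq_core import MultiLocusDataset
from .sumstats import harmonic

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Summary statistics on binary haplotype matrices
# ---------------------------------------------------------------------------

def _mean_pairwise_binary(mat: np.ndarray) -> float:
    n = mat.shape[0]
    if n < 2:
        return 0.0
    c = mat.sum(axis=0)
    return float((c * (n - c)).sum() / (n * (n - 1) / 2.0))


def _hd_binary(mat: np.ndarray) -> float:
    n = mat.shape[0]
    if n < 2:
        return 0.0
    _, counts = np.unique(mat, axis=0, return_counts=True)
    p = counts / n
    return float(n / (n - 1) * (1.0 - (p**2).sum()))


def locus_summaries(mat: np.ndarray, n_sm: int) -> np.ndarray:
    """15 summaries of one locus: per-group S, pi, D, Hd; F_ST; shared/fixed/
    private polymorphism counts; mean and minimum between-group distances
    (the latter is sensitive to recent migrants). ``mat`` rows are sm
    haplotypes then b."""
    sm, b = mat[:n_sm], mat[n_sm:]
    out = np.zeros(15)
    for g, (grp, base) in enumerate(((sm, 0), (b, 4))):
        n = grp.shape[0]
        c = grp.sum(axis=0)
        seg = (c > 0) & (c < n)
        S = int(seg.sum())
        pi = _mean_pairwise_binary(grp)
        D = tajima_d(pi, S, n) if n >= 2 and S > 0 else 0.0
        out[base : base + 4] = [S, pi, D if D is not None else 0.0, _hd_binary(grp)]
    f = None
    if sm.shape[0] >= 2 and b.shape[0] >= 2:
        hw = (_mean_pairwise_binary(sm) + _mean_pairwise_binary(b)) / 2.0
        hb = float((sm[:, None, :] != b[None, :, :]).sum(axis=2).mean())
        f = 1.0 - hw / hb if hb > 0 else 0.0
    out[8] = f if f is not None else 0.0
    c_sm, c_b = sm.sum(axis=0), b.sum(axis=0)
    n_sm_, n_b_ = sm.shape[0], b.shape[0]
    poly_sm = (c_sm > 0) & (c_sm < n_sm_)
    poly_b = (c_b > 0) & (c_b < n_b_)
    mono_sm_1, mono_sm_0 = c_sm == n_sm_, c_sm == 0
    mono_b_1, mono_b_0 = c_b == n_b_, c_b == 0
    out[9] = float((poly_sm & poly_b).sum())  # shared
    out[10] = float(((mono_sm_1 & mono_b_0) | (mono_sm_0 & mono_b_1)).sum())  # fixed
    out[11] = float((poly_sm & ~poly_b).sum())  # private sm
    out[12] = float((poly_b & ~poly_sm).sum())  # private b
    if sm.shape[0] >= 1 and b.shape[0] >= 1 and mat.shape[1] > 0:
        cross = (sm[:, None, :] != b[None, :, :]).sum(axis=2)
        out[13] = float(cross.mean())
        out[14] = float(cross.min())
    return out


def dataset_summary_vector(loci_stats: list[np.ndarray]) -> np.ndarray:
    """Aggregate per-locus summaries: means of all 15 plus the across-locus
    standard deviations of per-group S, pi and the between-group mean
    distance (20 components)."""
    arr = np.vstack(loci_stats)
    means = arr.mean(axis=0)
    sds = arr[:, [0, 1, 4, 5, 13]].std(ddof=0, axis=0)
    return np.concatenate([means, sds])


@dataclass
class IMDataConfig:
    """Sampling configuration extracted from the observed data."""

    n_sm: int
    n_b: int
    locus_scales: np.ndarray  # relative mutation weights, mean 1
    locus_names: list[str] = field(default_factory=list)
    blocks: dict[str, tuple[int, int]] = field(default_factory=dict)


def observed_im_summaries(
    ds: MultiLocusDataset,
) -> tuple[np.ndarray, IMDataConfig]:
    """Reduce each locus to its longest four-gamete-clean block and compute
    the observed summary vector plus the sampling configuration (per-locus
    relative mutation weights proportional to block length)."""
    sm_inds = set(ds.popmap.individuals_of_group("sumatra_malay"))
    b_inds = set(ds.popmap.individuals_of_group("borneo"))
    if not sm_inds or not b_inds:
        raise ValueError("both group labels (sumatra_malay, borneo) required")
    stats = []
    lengths = []
    blocks = {}
    n_sm = n_b = None
    for aln in ds.loci:
        start, end = coalsim.longest_nonrecombining_block(aln)
        blocks[aln.locus_name] = (start, end)
        lengths.append(end - start)
        sel = np.zeros(aln.aligned_length, bool)
        sel[start:end] = True
        sub_mask = aln.mask | ~sel
        order = [i for i, ind in enumerate(aln.individual_ids) if ind in sm_inds] + [
            i for i, ind in enumerate(aln.individual_ids) if ind in b_inds
        ]
        k_sm = sum(1 for ind in aln.individual_ids if ind in sm_inds)
        _, mat = coalsim._biallelic_columns(aln.seqs[order], sub_mask)
        stats.append(locus_summaries(mat, k_sm))
        n_sm, n_b = k_sm, len(order) - k_sm
    scales = np.asarray(lengths, float)
    scales = scales / scales.mean()
    cfg = IMDataConfig(
        n_sm=n_sm,
        n_b=n_b,
        locus_scales=scales,
        locus_names=[a.locus_name for a in ds.loci],
        blocks=blocks,
    )
    return dataset_summary_vector(stats), cfg


# ---------------------------------------------------------------------------
# Synthetic-likelihood objective
# ---------------------------------------------------------------------------

def simulate_summary_vectors(
    params: IMParameters,
    cfg: IMDataConfig,
    n_datasets: int,
    seed: int,
) -> np.ndarray:
    """Summary vectors of ``n_datasets`` datasets simulated at ``params``."""
    L = len(cfg.locus_scales)
    scales = np.tile(cfg.locus_scales, n_datasets)
    sams = coalsim.sim_im_replicates(params, cfg.n_sm, cfg.n_b, scales, seed=seed)
    vecs = []
    batch: list[np.ndarray] = []
    for sam in sams:
        batch.append(locus_summaries(sam.matrix, cfg.n_sm))
        if len(batch) == L:
            vecs.append(dataset_summary_vector(batch))
            batch = []
    return np.vstack(vecs)


def synthetic_loglik(
    params: IMParameters,
    obs_vec: np.ndarray,
    cfg: IMDataConfig,
    sims_per_eval: int,
    seed: int,
    ridge: float = 1e-3,
) -> float:
    """Gaussian synthetic log-likelihood with diagonal covariance.

    Common random numbers: the same ``seed`` at every evaluated point makes
    the objective a deterministic function of the parameters.
    """
    sims = simulate_summary_vectors(params, cfg, sims_per_eval, seed)
    mu = sims.mean(axis=0)
    var = sims.var(axis=0, ddof=1) + ridge + (ridge * np.abs(mu)) ** 2
    resid = obs_vec - mu
    return float(-0.5 * ((resid**2 / var) + np.log(2.0 * np.pi * var)).sum())


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

DEFAULT_PRIORS = {
    "theta_sm": 20.0,
    "theta_b": 30.0,
    "theta_A": 10.0,
    "m_sm": 5.0,
    "m_b": 5.0,
    "t": 5.0,
}

DEFAULT_SETTINGS = {
    "sims_per_eval": 20,
    "n_pilot": 128,
    "nm_maxfev": 100,
    "profile_points": 11,
    "refine_fraction": 0.35,
    "coord_cycles": 2,
    "coord_points": 15,
    "hpd_mass": 0.90,
    "ridge": 1e-3,
}


@dataclass
class IMFit:
    estimates: IMParameters
    hpd: dict[str, tuple[float, float]]
    max_loglik: float
    priors: dict[str, float]
    settings: dict
    seed: int
    config: IMDataConfig
    boundary_flags: list[str] = field(default_factory=list)
    profiles: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


class _Objective:
    """Deterministic (common-random-numbers) objective with an evaluation
    cache; the cache doubles as the sample cloud for profile construction."""

    def __init__(self, obs_vec, cfg, sims_per_eval, seed, ridge):
        self.obs_vec = obs_vec
        self.cfg = cfg
        self.sims_per_eval = sims_per_eval
        self.seed = seed
        self.ridge = ridge
        self.history_x: list[np.ndarray] = []
        self.history_ll: list[float] = []

    def __call__(self, x: np.ndarray) -> float:
        x = np.maximum(np.asarray(x, float), 0.0)
        try:
            params = IMParameters.from_array(x)
        except ValueError:
            return -np.inf
        ll = synthetic_loglik(
            params, self.obs_vec, self.cfg, self.sims_per_eval, self.seed, self.ridge
        )
        self.history_x.append(x.copy())
        self.history_ll.append(ll)
        return ll


def _maximise(
    obj: _Objective,
    lower: np.ndarray,
    upper: np.ndarray,
    seed: int,
    n_pilot: int,
    nm_maxfev: int,
    refine_fraction: float,
    x0: np.ndarray | None = None,
    coord_cycles: int = 2,
    coord_points: int = 15,
) -> tuple[np.ndarray, float]:
    """Successive Sobol refinement over the prior box, Nelder-Mead polish,
    then coordinate-wise grid sweeps."""
    dim = len(lower)
    lo_r, hi_r = lower.copy(), upper.copy()
    all_x: list[np.ndarray] = []
    all_ll: list[float] = []
    if x0 is not None:
        all_x.append(np.clip(np.asarray(x0, float), lower, upper))
        all_ll.append(obj(all_x[-1]))
    # successive Sobol refinement: shrink the search box around the best
    # points over a few rounds (wide prior -> refined box)
    round_sizes = [n_pilot, max(n_pilot // 2, 16), max(n_pilot // 2, 16)]
    for rnd, size in enumerate(round_sizes):
        sampler = qmc.Sobol(d=dim, scramble=True, seed=seed + rnd)
        pts = lo_r + sampler.random(size) * (hi_r - lo_r)
        vals = np.array([obj(p) for p in pts])
        all_x.extend(pts)
        all_ll.extend(vals.tolist())
        hx = np.vstack(all_x)
        hll = np.asarray(all_ll)
        top = hx[np.argsort(-hll)[: max(6, dim)]]
        pad = 0.15 * (hi_r - lo_r)
        lo_r = np.clip(top.min(axis=0) - pad, lower, upper)
        hi_r = np.clip(top.max(axis=0) + pad, lower, upper)
    hx = np.vstack(all_x)
    hll = np.asarray(all_ll)
    best_x = hx[int(np.argmax(hll))]
    best_ll = float(hll.max())

    span = np.maximum((upper - lower) * refine_fraction, hi_r - lo_r)
    lo2 = np.clip(best_x - span, lower, upper)
    hi2 = np.clip(best_x + span, lower, upper)

    def neg(x: np.ndarray) -> float:
        xc = np.clip(x, lo2, hi2)
        penalty = float(np.abs(x - xc).sum()) * 1e3
        return -obj(xc) + penalty

    res = minimize(
        neg,
        best_x,
        method="Nelder-Mead",
        options={"maxfev": nm_maxfev, "xatol": 1e-3, "fatol": 1e-3},
    )
    x_hat = np.clip(res.x, lo2, hi2)
    ll_hat = obj(x_hat)
    if ll_hat < best_ll:
        x_hat, ll_hat = best_x, best_ll

    # coordinate-wise grid sweeps over the full prior box: cheap and robust
    # on the theta/migration ridges of this model
    for _ in range(coord_cycles):
        improved = False
        for k in range(dim):
            grid = np.linspace(lower[k], upper[k], coord_points)
            for v in grid:
                xt = x_hat.copy()
                xt[k] = v
                ll = obj(xt)
                if ll > ll_hat:
                    x_hat, ll_hat = xt, ll
                    improved = True
        if not improved:
            break
    return x_hat, float(ll_hat)


def _profile_hpd(
    obj: _Objective,
    x_hat: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    k: int,
    n_points: int,
    mass: float,
) -> tuple[float, tuple[float, float], np.ndarray, np.ndarray]:
    grid = np.linspace(lower[k], upper[k], n_points)
    lls = np.empty(n_points)
    for i, v in enumerate(grid):
        x = x_hat.copy()
        x[k] = v
        lls[i] = obj(x)
    # approximate the profile by folding in the cached evaluation cloud:
    # the best cached value near each grid point bounds the profile from below
    if obj.history_x:
        hx = np.vstack(obj.history_x)
        hll = np.asarray(obj.history_ll)
        half = (grid[1] - grid[0]) / 2.0 if n_points > 1 else np.inf
        for i, v in enumerate(grid):
            near = np.abs(hx[:, k] - v) <= half
            if near.any():
                lls[i] = max(lls[i], float(hll[near].max()))
    w = np.exp(lls - lls.max())
    w /= w.sum()
    order = np.argsort(-w)
    included = np.zeros(n_points, bool)
    acc = 0.0
    for idx in order:
        included[idx] = True
        acc += w[idx]
        if acc >= mass:
            break
    sel = grid[included]
    peak = float(grid[int(np.argmax(lls))])
    # each grid point represents a cell of half-step width on either side
    half = (grid[1] - grid[0]) / 2.0 if n_points > 1 else 0.0
    lo = max(float(sel.min()) - half, float(lower[k]))
    hi = min(float(sel.max()) + half, float(upper[k]))
    return peak, (lo, hi), grid, lls


def fit_im_from_summaries(
    obs_vec: np.ndarray,
    cfg: IMDataConfig,
    priors: dict[str, float] | None = None,
    settings: dict | None = None,
    seed: int = 0,
    compute_profiles: bool = True,
) -> IMFit:
    """Fit the six-parameter IM model to an observed summary vector."""
    priors = {**DEFAULT_PRIORS, **(priors or {})}
    st = {**DEFAULT_SETTINGS, **(settings or {})}
    lower = np.zeros(6)
    upper = np.array([priors[p] for p in PARAM_NAMES])
    obj = _Objective(obs_vec, cfg, st["sims_per_eval"], seed, st["ridge"])
    x_hat, ll_hat = _maximise(
        obj, lower, upper, seed, st["n_pilot"], st["nm_maxfev"], st["refine_fraction"],
        coord_cycles=st["coord_cycles"], coord_points=st["coord_points"],
    )
    hpd = {}
    profiles = {}
    flags = []
    estimates = list(x_hat)
    if compute_profiles:
        for k, name in enumerate(PARAM_NAMES):
            peak, interval, grid, lls = _profile_hpd(
                obj, x_hat, lower, upper, k, st["profile_points"], st["hpd_mass"]
            )
            better = lls.max() > ll_hat
            if better:
                x_hat = x_hat.copy()
                x_hat[k] = peak
                ll_hat = float(lls.max())
            estimates[k] = peak
            hpd[name] = interval
            profiles[name] = (grid, lls)
            if peak >= upper[k] * 0.99:
                flags.append(f"{name}: estimate at prior boundary (prior too small)")
    else:
        for k, name in enumerate(PARAM_NAMES):
            hpd[name] = (float(lower[k]), float(upper[k]))
    est = IMParameters.from_array(estimates)
    for k, name in enumerate(PARAM_NAMES):
        lo, hi = hpd[name]
        hpd[name] = (min(lo, estimates[k]), max(hi, estimates[k]))
    return IMFit(
        estimates=est,
        hpd=hpd,
        max_loglik=ll_hat,
        priors=priors,
        settings=st,
        seed=seed,
        config=cfg,
        boundary_flags=flags,
        profiles=profiles,
    )


def fit_im(
    ds: MultiLocusDataset,
    priors: dict[str, float] | None = None,
    settings: dict | None = None,
    seed: int = 0,
) -> IMFit:
    """Fit the IM model to a dataset with two group labels (four-gamete-clean
    blocks are extracted automatically and reported in the fit config)."""
    obs_vec, cfg = observed_im_summaries(ds)
    return fit_im_from_summaries(obs_vec, cfg, priors, settings, seed)


# ---------------------------------------------------------------------------
# Nested-model LLR tests
# ---------------------------------------------------------------------------

NESTED_MODELS = {
    "m_sm=0": {"fixed": {"m_sm": 0.0}, "tied": [], "df": 1},
    "m_b=0": {"fixed": {"m_b": 0.0}, "tied": [], "df": 1},
    "m_sm=m_b": {"fixed": {}, "tied": [("m_sm", "m_b")], "df": 1},
    "m_sm=m_b=0": {"fixed": {"m_sm": 0.0, "m_b": 0.0}, "tied": [], "df": 2},
    "theta_sm=theta_b": {"fixed": {}, "tied": [("theta_sm", "theta_b")], "df": 1},
    "theta_sm=theta_A": {"fixed": {}, "tied": [("theta_sm", "theta_A")], "df": 1},
    "theta_b=theta_A": {"fixed": {}, "tied": [("theta_b", "theta_A")], "df": 1},
    "theta_sm=theta_b=theta_A": {
        "fixed": {},
        "tied": [("theta_sm", "theta_b", "theta_A")],
        "df": 2,
    },
}


def mixed_chi2_sf(llr: float) -> float:
    """p-value under the boundary null: half point mass at 0, half chi2(1)."""
    if llr < 0:
        raise ValueError("LLR must be >= 0")
    if llr == 0:
        return 1.0
    return float(0.5 * chi2.sf(llr, 1))


def _project_onto_constraint(
    x_full: np.ndarray, fixed: dict[str, float], tied: list[tuple[str, ...]]
) -> np.ndarray:
    """Project a full-model point onto a nested model's constraint set."""
    idx_of = {p: i for i, p in enumerate(PARAM_NAMES)}
    x = np.asarray(x_full, float).copy()
    for p, v in fixed.items():
        x[idx_of[p]] = v
    for group in tied:
        mean = float(np.mean([x[idx_of[p]] for p in group]))
        for p in group:
            x[idx_of[p]] = mean
    return x


def _constrained_fit(
    obs_vec: np.ndarray,
    cfg: IMDataConfig,
    priors: dict[str, float],
    settings: dict,
    seed: int,
    fixed: dict[str, float],
    tied: list[tuple[str, ...]],
    x0_full: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Maximise the same objective under equality/zero constraints; returns
    the full 6-vector at the optimum and its log-likelihood."""
    st = settings
    rep = {}  # param -> leader param of its tied group
    for group in tied:
        for p in group[1:]:
            rep[p] = group[0]
    free = [p for p in PARAM_NAMES if p not in fixed and p not in rep]
    idx_of = {p: i for i, p in enumerate(PARAM_NAMES)}

    def expand(z: np.ndarray) -> np.ndarray:
        x = np.zeros(6)
        for i, p in enumerate(free):
            x[idx_of[p]] = z[i]
        for p, v in fixed.items():
            x[idx_of[p]] = v
        for p, leader in rep.items():
            x[idx_of[p]] = x[idx_of[leader]]
        return x

    base = _Objective(obs_vec, cfg, st["sims_per_eval"], seed, st["ridge"])

    class Reduced:
        n_evals = 0

        def __call__(self, z: np.ndarray) -> float:
            return base(expand(z))

    robj = Reduced()
    lower = np.zeros(len(free))
    upper = np.array([priors[p] for p in free])
    z0 = None
    if x0_full is not None:
        # warm start: project the full-model optimum onto the constraint so
        # the nested optimum is never worse than the projected point
        z0 = np.empty(len(free))
        for i, p in enumerate(free):
            if any(p == group[0] for group in tied):
                group = next(g for g in tied if g[0] == p)
                z0[i] = float(np.mean([x0_full[idx_of[q]] for q in group]))
            else:
                z0[i] = x0_full[idx_of[p]]
    z_hat, ll = _maximise(
        robj, lower, upper, seed, st["n_pilot"], st["nm_maxfev"], st["refine_fraction"],
        x0=z0,
        coord_cycles=st["coord_cycles"], coord_points=st["coord_points"],
    )
    projected = expand(np.clip(z0, lower, upper)) if z0 is not None else None
    return expand(z_hat), ll, projected


@dataclass
class NestedTest:
    model: str
    llr: float
    reference: str
    p: float
    rejected: bool
    converged: bool


@dataclass
class NestedTestTable:
    tests: dict[str, NestedTest]
    isolation_verdict: str
    full_loglik: float


def nested_model_tests(
    fit: IMFit,
    obs_vec: np.ndarray | None = None,
    alpha: float = 0.05,
    models: list[str] | None = None,
) -> NestedTestTable:
    """Likelihood-ratio tests of the nested-model menu against the full fit.

    Ordinary models use chi2 with df = number of constraints. The isolation
    model uses the two-step ladder: full vs {m_sm=m_b} on chi2(1), then
    {m_sm=m_b} vs {m_sm=m_b=0} on the mixed chi2 (half point mass at zero);
    the isolation model is accepted only if neither step rejects.
    """
    if obs_vec is None:
        raise ValueError("pass the observed summary vector used for the fit")
    cfg, priors, st, seed = fit.config, fit.priors, fit.settings, fit.seed
    full_ll = fit.max_loglik
    names = models if models is not None else list(NESTED_MODELS)
    if "m_sm=m_b" not in names:
        names = names + ["m_sm=m_b"]
    if "m_sm=m_b=0" not in names:
        names = names + ["m_sm=m_b=0"]
    results: dict[str, NestedTest] = {}
    lls: dict[str, float] = {}
    x0_full = fit.estimates.as_array()
    xs: dict[str, list[np.ndarray]] = {}
    for name in names:
        spec = NESTED_MODELS[name]
        x, ll, proj = _constrained_fit(
            obs_vec, cfg, priors, st, seed, spec["fixed"], spec["tied"], x0_full=x0_full
        )
        lls[name] = ll
        xs[name] = [x] if proj is None else [x, proj]

    # a nested optimum above the full one signals full-model non-convergence:
    # re-optimize the full model warm-started from the best nested point
    best_nested = max(lls, key=lls.get)
    if lls[best_nested] > full_ll + 1e-6:
        obj = _Objective(obs_vec, cfg, st["sims_per_eval"], seed, st["ridge"])
        lower = np.zeros(6)
        upper = np.array([priors[p] for p in PARAM_NAMES])
        x_re, ll_re = _maximise(
            obj, lower, upper, seed, st["n_pilot"], st["nm_maxfev"], st["refine_fraction"],
            x0=xs[best_nested][0],
            coord_cycles=st["coord_cycles"], coord_points=st["coord_points"],
        )
        if ll_re > full_ll:
            full_ll = ll_re
            x0_full = x_re

    # the (possibly re-optimised) full point projected onto each constraint
    # is always a valid nested candidate
    for name in names:
        spec = NESTED_MODELS[name]
        xs[name].append(_project_onto_constraint(x0_full, spec["fixed"], spec["tied"]))

    # LLRs are computed by re-scoring every optimum out-of-sample: the same
    # higher-precision objective averaged over fresh seeds, so each
    # optimiser's advantage from tuning to its own Monte-Carlo noise cancels
    hp_sims = st["sims_per_eval"] * st.get("llr_sims_factor", 4)
    n_score_seeds = st.get("llr_score_seeds", 5)

    def hp_ll(x: np.ndarray) -> float:
        params = IMParameters.from_array(np.maximum(x, 0.0))
        return float(
            np.mean(
                [
                    synthetic_loglik(
                        params, obs_vec, cfg, hp_sims, seed + 9973 * (k + 1), st["ridge"]
                    )
                    for k in range(n_score_seeds)
                ]
            )
        )

    # per model, keep the better of (optimiser point, projected warm start):
    # the optimiser can chase low-precision noise away from a sound optimum
    full_ll = hp_ll(x0_full)
    lls = {name: max(hp_ll(x) for x in cands) for name, cands in xs.items()}

    for name in names:
        spec = NESTED_MODELS[name]
        ll = lls[name]
        llr = 2.0 * (full_ll - ll)
        converged = llr >= -1e-6
        llr = max(llr, 0.0)
        p = float(chi2.sf(llr, spec["df"]))
        results[name] = NestedTest(name, llr, f"chi2({spec['df']})", p, p < alpha, converged)

    # isolation ladder
    llr1 = max(2.0 * (full_ll - lls["m_sm=m_b"]), 0.0)
    p1 = float(chi2.sf(llr1, 1))
    llr2 = max(2.0 * (lls["m_sm=m_b"] - lls["m_sm=m_b=0"]), 0.0)
    p2 = mixed_chi2_sf(llr2)
    results["m_sm=m_b"] = NestedTest("m_sm=m_b", llr1, "chi2(1)", p1, p1 < alpha, True)
    results["m_sm=m_b=0"] = NestedTest(
        "m_sm=m_b=0", llr2, "mixed 0.5*chi2(1)", p2, p2 < alpha, True
    )
    verdict = "accepted" if (p1 >= alpha and p2 >= alpha) else "rejected"
    return NestedTestTable(tests=results, isolation_verdict=verdict, full_loglik=full_ll)


# ---------------------------------------------------------------------------
# Conversion to demographic units
# ---------------------------------------------------------------------------

@dataclass
class DemographicTable:
    """Converted quantities at the two mutation-rate brackets.

    Exact identities: N_e = theta/(4V), T = t/u, 2Nm = theta*m/2 for each
    recorded input (u = geometric-mean annual rate per locus; V = u * gen_years).
    """

    ne: dict[str, dict[str, float]]  # bracket -> {sm, b, A}
    t_years: dict[str, float]
    two_nm: dict[str, float]  # direction -> 2Nm (rate-independent)
    inputs: dict

    def as_dict(self) -> dict:
        return {
            "ne": self.ne,
            "t_years": self.t_years,
            "two_nm": self.two_nm,
            "inputs": self.inputs,
        }


def convert_parameters(
    est: IMParameters,
    u_syn_min: float,
    u_syn_max: float,
    gen_years: float,
    locus_meta: list[dict] | None = None,
    annual_rates: tuple[float, float] | None = None,
) -> DemographicTable:
    """Convert IMa-scale estimates to demographic quantities.

    Either supply per-locus metadata (``silent_sites``, ``replacement_sites``,
    ``ka_ks`` each) so the per-locus annual rate u_syn*silent +
    u_syn*KaKs*replacement is computed and geometric-mean averaged, or supply
    the two geometric-mean per-locus annual rates directly via
    ``annual_rates`` (min, max).
    """
    if annual_rates is not None:
        rates = {"min": annual_rates[0], "max": annual_rates[1]}
    else:
        if not locus_meta:
            raise ValueError("locus_meta or annual_rates required")
        rates = {}
        for label, u_syn in (("min", u_syn_min), ("max", u_syn_max)):
            per_locus = [
                u_syn * m["silent_sites"] + u_syn * m["ka_ks"] * m["replacement_sites"]
                for m in locus_meta
            ]
            if any(r <= 0 for r in per_locus):
                raise ValueError("zero per-locus mutation rate")
            rates[label] = float(np.exp(np.mean(np.log(per_locus))))
    ne = {}
    t_years = {}
    for label, u in rates.items():
        if u <= 0:
            raise ValueError("zero mutation rate")
        V = u * gen_years
        ne[label] = {
            "sm": est.theta_sm / (4.0 * V),
            "b": est.theta_b / (4.0 * V),
            "A": est.theta_A / (4.0 * V),
        }
        t_years[label] = est.t / u
    two_nm = {"sm": est.theta_sm * est.m_sm / 2.0, "b": est.theta_b * est.m_b / 2.0}
    return DemographicTable(
        ne=ne,
        t_years=t_years,
        two_nm=two_nm,
        inputs={
            "u_syn_min": u_syn_min,
            "u_syn_max": u_syn_max,
            "gen_years": gen_years,
            "annual_rates": rates,
            "locus_meta": locus_meta,
        },
    )


# ---------------------------------------------------------------------------
# Tajima's D under the fitted demographic model
# ---------------------------------------------------------------------------

def demographic_null_tajima(
    params: IMParameters,
    cfg: IMDataConfig,
    observed_d: dict[str, list[float | None]],
    reps: int = 1000,
    seed: int = 0,
) -> dict:
    """Empirical two-sided p-values for observed Tajima's D under the fitted
    IM model.

    ``observed_d`` maps scope ('pooled', 'sm', 'b') to per-locus observed D
    (None where S = 0). Each replicate simulates every locus at the fitted
    parameters with the observed sampling configuration and per-locus
    mutation weights; p-values are reported per locus and for the
    across-locus average D, with missing simulated D dropped pairwise.
    """
    rng = np.random.default_rng(seed)
    L = len(cfg.locus_scales)
    scopes = ("pooled", "sm", "b")
    sims = {s: np.full((reps, L), np.nan) for s in scopes}
    scales = np.tile(cfg.locus_scales, reps)
    sams = coalsim.sim_im_replicates(
        params, cfg.n_sm, cfg.n_b, scales, seed=int(rng.integers(1, 2**31))
    )
    for idx, sam in enumerate(sams):
        r, l = divmod(idx, L)
        mat = sam.matrix
        groups = {"pooled": mat, "sm": mat[: cfg.n_sm], "b": mat[cfg.n_sm :]}
        for s, g in groups.items():
            n = g.shape[0]
            c = g.sum(axis=0)
            S = int(((c > 0) & (c < n)).sum())
            d = tajima_d(_mean_pairwise_binary(g), S, n) if S > 0 else None
            if d is not None:
                sims[s][r, l] = d

    def emp_p(values: np.ndarray, obs: float) -> float:
        vals = values[~np.isnan(values)]
        if vals.size == 0:
            return float("nan")
        lo = float(np.mean(vals <= obs))
        hi = float(np.mean(vals >= obs))
        return min(1.0, 2.0 * min(lo, hi))

    out: dict = {"per_locus": {}, "average": {}, "reps": reps, "seed": seed}
    for s in scopes:
        obs = observed_d.get(s)
        if obs is None:
            continue
        locus_ps = []
        for l in range(L):
            if obs[l] is None:
                locus_ps.append(None)
            else:
                locus_ps.append(emp_p(sims[s][:, l], obs[l]))
        out["per_locus"][s] = locus_ps
        obs_valid = [d for d in obs if d is not None]
        if obs_valid:
            obs_avg = float(np.mean(obs_valid))
            sim_avg = np.nanmean(sims[s], axis=1)
            out["average"][s] = {"observed_D": obs_avg, "p_two_sided": emp_p(sim_avg, obs_avg)}
    return out
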