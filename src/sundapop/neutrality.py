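"""Neutrality tests: Tajima's D with fixed-S coalescent nulls, the multilocus
average-D test, the McDonald–Kreitman test, Ka/Ks, and the multilocus HKA test.

The simulated nulls condition on the observed number of segregating sites
(mutations placed on standard-neutral genealogies proportionally to branch
length), matching the convention of giving the observed number of polymorphic
sites to the coalescent. Fisher's exact test is two-tailed by the
point-probability rule and the G-test carries no Williams or continuity
correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2, fisher_exact

from . import coalsim
from .seq_core import (
    LocusAlignment,
    MultiLocusDataset,
    SiteClassification,
    classify_sites,
    consensus_sequence,
)
from .sumstats import SummaryStats, harmonic, summary_stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """The a1, a2, b1, b2, c1, c2, e1, e2 normalising constants."""
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d(mean_pairwise: float, S: int, n: int) -> float | None:
    """Tajima's D from the mean pairwise difference count and S; None if S=0."""
    if S == 0:
        return None
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return float((mean_pairwise - S / c["a1"]) / np.sqrt(var))


def tajima_d_from_stats(stats: SummaryStats) -> float | None:
    return tajima_d(stats.mean_pairwise, stats.S, stats.n)


@dataclass
class TajimaResult:
    D: float | None
    S: int
    n: int
    null_interval: tuple[float, float] | None
    p_two_sided: float | None
    reps: int
    seed: int | None


def _empirical_two_sided_p(sims: np.ndarray, observed: float) -> float:
    lo = float(np.mean(sims <= observed))
    hi = float(np.mean(sims >= observed))
    return min(1.0, 2.0 * min(lo, hi))


def neutral_interval(
    n: int,
    S: int,
    reps: int = 10000,
    seed: int | None = None,
    d_obs: float | None = None,
) -> tuple[float, float, float | None, np.ndarray]:
    """Fixed-S standard-neutral null for Tajima's D.

    Returns the empirical (2.5%, 97.5%) interval, the two-sided empirical
    p-value of ``d_obs`` (None if not given), and the simulated D values.
    """
    if S < 1:
        raise ValueError("S >= 1 required for a simulated null")
    rng = np.random.default_rng(seed)
    pis = coalsim.simulate_fixed_s_pi(n, S, reps, rng)
    c = tajima_constants(n)
    sd = np.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))
    sims = (pis - S / c["a1"]) / sd
    lo, hi = np.quantile(sims, [0.025, 0.975])
    p = _empirical_two_sided_p(sims, d_obs) if d_obs is not None else None
    return float(lo), float(hi), p, sims


def tajima_test(
    aln: LocusAlignment,
    individuals: list[str] | None = None,
    reps: int = 10000,
    seed: int | None = None,
    classification: SiteClassification | None = None,
) -> TajimaResult:
    """Tajima's D for one locus/sample with its fixed-S simulated null."""
    stats = summary_stats(aln, individuals, classification)
    D = tajima_d_from_stats(stats)
    if D is None:
        return TajimaResult(None, 0, stats.n, None, None, reps, seed)
    lo, hi, p, _ = neutral_interval(stats.n, stats.S, reps, seed, d_obs=D)
    return TajimaResult(D, stats.S, stats.n, (lo, hi), p, reps, seed)


def multilocus_d_test(
    ds: MultiLocusDataset,
    individuals: list[str] | None = None,
    reps: int = 10000,
    seed: int | None = None,
) -> dict:
    """Two-sided p for the across-loci average Tajima's D.

    Each replicate simulates every informative locus (S >= 1) independently at
    its own n and fixed S and averages D across loci; loci with S = 0 are
    dropped from the observed and simulated averages alike.
    """
    rng = np.random.default_rng(seed)
    obs_ds = []
    configs = []
    for aln in ds.loci:
        stats = summary_stats(aln, individuals)
        D = tajima_d_from_stats(stats)
        if D is None:
            logger.warning("%s: S=0, dropped from the multilocus average", aln.locus_name)
            continue
        obs_ds.append(D)
        configs.append((stats.n, stats.S))
    if len(configs) < 2:
        raise ValueError("need >= 2 loci with S >= 1")
    observed = float(np.mean(obs_ds))
    sims = np.zeros(reps)
    for n, S in configs:
        pis = coalsim.simulate_fixed_s_pi(n, S, reps, rng)
        c = tajima_constants(n)
        sd = np.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))
        sims += (pis - S / c["a1"]) / sd
    sims /= len(configs)
    return {
        "observed_average_D": observed,
        "per_locus_D": obs_ds,
        "p_two_sided": _empirical_two_sided_p(sims, observed),
        "null_interval": tuple(np.quantile(sims, [0.025, 0.975])),
        "reps": reps,
        "seed": seed,
    }


# ---------------------------------------------------------------------------
# McDonald–Kreitman test
# ---------------------------------------------------------------------------

@dataclass
class MKTable:
    fixed_syn: int
    fixed_rep: int
    poly_syn: int
    poly_rep: int
    fisher_p: float
    g_stat: float | None
    g_p: float | None


def mk_test(fixed_syn: int, fixed_rep: int, poly_syn: int, poly_rep: int) -> MKTable:
    """McDonald–Kreitman 2x2 test: [syn, rep] x [fixed, polymorphic].

    Fisher is two-tailed by summing probabilities of all same-margin tables
    whose point probability does not exceed the observed table's; the G
    statistic is 2*sum O*ln(O/E) on chi-square df=1, uncorrected. A zero
    margin degenerates to fisher_p = 1.
    """
    table = np.array([[fixed_syn, poly_syn], [fixed_rep, poly_rep]])
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
        logger.warning("MK table has a zero margin; Fisher p degenerate at 1")
        return MKTable(fixed_syn, fixed_rep, poly_syn, poly_rep, 1.0, None, None)
    fisher_p = float(fisher_exact(table, alternative="two-sided")[1])
    O = table.astype(float)
    E = np.outer(O.sum(1), O.sum(0)) / O.sum()
    nz = O > 0
    g = float(2.0 * (O[nz] * np.log(O[nz] / E[nz])).sum())
    return MKTable(fixed_syn, fixed_rep, poly_syn, poly_rep, fisher_p, g, float(chi2.sf(g, 1)))


def mk_counts(
    aln: LocusAlignment,
    outgroup: np.ndarray,
    classification: SiteClassification | None = None,
) -> dict[str, int]:
    """Count fixed/polymorphic synonymous and replacement sites against a
    single outgroup individual's consensus.

    Sites that are both polymorphic within the focal sample and divergent from
    the outgroup count as polymorphic only (standard MK convention). Columns
    where the outgroup carries a gap are skipped. Only coding columns enter.
    """
    if classification is None:
        _, classification = classify_sites(aln)
    og = consensus_sequence(np.atleast_2d(outgroup))
    counts = {"fixed_syn": 0, "fixed_rep": 0, "poly_syn": 0, "poly_rep": 0}
    for j in range(aln.aligned_length):
        if classification.mask[j] or og[j] == "-":
            continue
        col = aln.seqs[:, j]
        bases, freq = np.unique(col, return_counts=True)
        if len(bases) > 1:
            order = np.argsort(-freq)
            a, b = bases[order[0]], bases[order[1]]
            cat = classification.variant_category(j, a, b)
            if cat == "synonymous":
                counts["poly_syn"] += 1
            elif cat == "replacement":
                counts["poly_rep"] += 1
        else:
            if bases[0] != og[j]:
                cat = classification.variant_category(j, bases[0], og[j])
                if cat == "synonymous":
                    counts["fixed_syn"] += 1
                elif cat == "replacement":
                    counts["fixed_rep"] += 1
    return counts


# ---------------------------------------------------------------------------
# Ka/Ks (Nei–Gojobori with Jukes–Cantor correction)
# ---------------------------------------------------------------------------

def _ng_site_counts(codon: str, table: dict[str, str]) -> tuple[float, float]:
    aa = table[codon]
    syn = 0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if table[mut] == aa:
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def _ng_path_diffs(c1: str, c2: str, table: dict[str, str]) -> tuple[float, float]:
    """Average synonymous/nonsynonymous differences over all mutation paths."""
    from itertools import permutations

    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_tot = rep_tot = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        cur = c1
        syn = rep = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if table[cur] == "*" or table[nxt] == "*":
                ok = False
                break
            if table[cur] == table[nxt]:
                syn += 1
            else:
                rep += 1
            cur = nxt
        if ok:
            syn_tot += syn
            rep_tot += rep
            n_paths += 1
    if n_paths == 0:  # every path crosses a stop; fall back to counting all paths
        for order in permutations(diff_pos):
            cur = c1
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if table[cur] == table[nxt]:
                    syn_tot += 1
                else:
                    rep_tot += 1
                cur = nxt
            n_paths += 1
    return syn_tot / n_paths, rep_tot / n_paths


def ka_ks(
    aln: LocusAlignment,
    outgroup_hap: np.ndarray,
    classification: SiteClassification | None = None,
) -> tuple[float, float, float | None]:
    """Ka, Ks and their ratio between the focal consensus and an outgroup
    haplotype (Nei–Gojobori proportions, Jukes–Cantor corrected).

    Codons containing masked columns or gaps in either sequence are skipped.
    Returns (Ka, Ks, Ka/Ks) with the ratio None when Ks = 0.
    """
    from .seq_core import _CODON_TABLE

    if classification is None:
        _, classification = classify_sites(aln)
    if not aln.exon_intervals:
        raise ValueError(f"{aln.locus_name}: coding annotation required for Ka/Ks")
    focal = classification.consensus
    og = np.asarray(outgroup_hap)
    syn_sites = rep_sites = 0.0
    syn_diff = rep_diff = 0.0
    for start, end, frame in aln.exon_intervals:
        for cs in range(start + frame, end, 3):
            cols = [cs, cs + 1, cs + 2]
            if classification.mask[cols].any():
                continue
            c1 = "".join(focal[cols])
            c2 = "".join(og[cols])
            if "-" in c1 or "-" in c2:
                continue
            if _CODON_TABLE[c1] == "*" or _CODON_TABLE[c2] == "*":
                continue
            s1, r1 = _ng_site_counts(c1, _CODON_TABLE)
            s2, r2 = _ng_site_counts(c2, _CODON_TABLE)
            syn_sites += (s1 + s2) / 2.0
            rep_sites += (r1 + r2) / 2.0
            sd, rd = _ng_path_diffs(c1, c2, _CODON_TABLE)
            syn_diff += sd
            rep_diff += rd

    def jc(p: float) -> float:
        if p >= 0.75:
            raise ValueError("proportion too large for Jukes-Cantor correction")
        return float(-0.75 * np.log(1.0 - 4.0 * p / 3.0))

    ks = jc(syn_diff / syn_sites) if syn_sites > 0 else 0.0
    ka = jc(rep_diff / rep_sites) if rep_sites > 0 else 0.0
    ratio = ka / ks if ks > 0 else None
    return ka, ks, ratio


# ---------------------------------------------------------------------------
# Multilocus HKA test
# ---------------------------------------------------------------------------

@dataclass
class HKAResult:
    loci: list[str]
    obs_poly: np.ndarray
    obs_div: np.ndarray
    exp_poly: np.ndarray
    exp_div: np.ndarray
    var_poly: np.ndarray
    var_div: np.ndarray
    theta_hat: np.ndarray
    t_hat: float
    chi2_total: float
    df: int
    p: float


def hka_test(
    observed_poly: np.ndarray,
    observed_div: np.ndarray,
    sample_sizes: np.ndarray,
    locus_names: list[str] | None = None,
) -> HKAResult:
    """Classical multilocus HKA estimating equations.

    Per locus i: E[S_i] = theta_i * a_{n_i}, Var[S_i] = E[S_i] + theta_i^2 *
    b_{n_i}; divergence against a single outgroup sequence E[D_i] =
    theta_i * (T + 1) (equal current and ancestral sizes), Var[D_i] = E[D_i] +
    theta_i^2. A shared T and per-locus theta_i solve the totals exactly;
    the statistic sums standardised squared deviations over both sides with
    df = L - 1.
    """
    S = np.asarray(observed_poly, float)
    D = np.asarray(observed_div, float)
    n = np.asarray(sample_sizes, int)
    L = len(S)
    if L < 2:
        raise ValueError("HKA needs >= 2 loci")
    if D.sum() == 0:
        raise ValueError("no divergence at any locus: T is unidentifiable")
    a = np.array([harmonic(int(k)) for k in n])
    b = np.array([harmonic(int(k), 2) for k in n])
    tot = S + D

    def residual(T: float) -> float:
        theta = tot / (a + T + 1.0)
        return float((theta * (T + 1.0)).sum() - D.sum())

    lo, hi = -0.999, 1e6
    t_hat = brentq(residual, lo, hi)
    theta = tot / (a + t_hat + 1.0)
    exp_poly = theta * a
    exp_div = theta * (t_hat + 1.0)
    var_poly = exp_poly + theta**2 * b
    var_div = exp_div + theta**2
    x2 = float(((S - exp_poly) ** 2 / var_poly).sum() + ((D - exp_div) ** 2 / var_div).sum())
    df = L - 1
    return HKAResult(
        loci=locus_names or [f"locus{i}" for i in range(L)],
        obs_poly=S,
        obs_div=D,
        exp_poly=exp_poly,
        exp_div=exp_div,
        var_poly=var_poly,
        var_div=var_div,
        theta_hat=theta,
        t_hat=float(t_hat),
        chi2_total=x2,
        df=df,
        p=float(chi2.sf(x2, df)),
    )


def hka_from_dataset(
    ds: MultiLocusDataset, individuals: list[str] | None = None
) -> HKAResult:
    """HKA inputs measured from a dataset with per-locus outgroup haplotypes:
    polymorphism = segregating sites; divergence = mean differences between
    focal haplotypes and the outgroup consensus on jointly ungapped columns."""
    S, D, n, names = [], [], [], []
    for aln in ds.loci:
        if aln.locus_name not in ds.outgroups:
            raise ValueError(f"{aln.locus_name}: outgroup required for HKA")
        sub = aln.subset(individuals) if individuals is not None else aln
        stats = summary_stats(sub)
        og = consensus_sequence(np.atleast_2d(ds.outgroups[aln.locus_name]))
        ok = (~sub.mask) & (og != "-")
        div = float((sub.seqs[:, ok] != og[ok]).sum(axis=1).mean())
        S.append(stats.S)
        D.append(div)
        n.append(stats.n)
        names.append(aln.locus_name)
    return hka_test(np.array(S), np.array(D), np.array(n), names)
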