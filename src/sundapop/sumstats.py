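"""Per-sample, per-locus diversity statistics and the population summary table.

Nucleotide diversity pi is reported per site within each site category
(total / silent / synonymous / replacement), dividing summed pairwise
differences of that category by the category's fractional site count.
Haplotype diversity Hd uses the n/(n-1) bias correction, with distinct
haplotypes defined on the unmasked columns of the whole locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seq_core import (
    LocusAlignment,
    MultiLocusDataset,
    SiteClassification,
    classify_sites,
    site_counts,
)

logger = logging.getLogger(__name__)

CATEGORIES = ("total", "silent", "synonymous", "replacement")


def harmonic(n: int, power: int = 1) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i^power."""
    return float(sum(1.0 / i**power for i in range(1, n)))


@dataclass
class SummaryStats:
    """Diversity summaries for one sample at one locus."""

    n: int
    S: int
    pi: dict[str, float | None]  # per category, None when the category has no sites
    Hd: float
    theta_w: float
    mean_pairwise: float
    diffs: dict[str, float] | None = None  # summed pairwise difference counts
    sites: dict[str, float] | None = None  # fractional site counts per category


def _category_diffs(
    seqs: np.ndarray, classification: SiteClassification
) -> tuple[dict[str, float], int]:
    """Summed pairwise difference counts per category and segregating-site count."""
    n = seqs.shape[0]
    diffs = {"total": 0.0, "silent": 0.0, "synonymous": 0.0, "replacement": 0.0}
    S = 0
    unmasked = np.flatnonzero(~classification.mask)
    sub = seqs[:, unmasked]
    varying = unmasked[(sub != sub[0]).any(axis=0)]
    for j in varying:
        col = seqs[:, j]
        bases, counts = np.unique(col, return_counts=True)
        if len(bases) < 2:
            continue
        S += 1
        for a_i in range(len(bases)):
            for b_i in range(a_i + 1, len(bases)):
                npairs = float(counts[a_i] * counts[b_i])
                diffs["total"] += npairs
                cat = classification.variant_category(j, bases[a_i], bases[b_i])
                if cat == "intron":
                    diffs["silent"] += npairs
                elif cat == "synonymous":
                    diffs["silent"] += npairs
                    diffs["synonymous"] += npairs
                elif cat == "replacement":
                    diffs["replacement"] += npairs
    return diffs, S


def haplotype_diversity(seqs: np.ndarray, mask: np.ndarray) -> float:
    """Bias-corrected haplotype diversity Hd = n/(n-1) * (1 - sum p_k^2)."""
    n = seqs.shape[0]
    keys = ["".join(row) for row in seqs[:, ~mask]]
    _, counts = np.unique(keys, return_counts=True)
    p = counts / n
    return float(n / (n - 1) * (1.0 - (p**2).sum()))


def summary_stats(
    aln: LocusAlignment,
    individuals: list[str] | None = None,
    classification: SiteClassification | None = None,
) -> SummaryStats:
    """Diversity statistics for one locus, optionally restricted to a subset
    of individuals. Raises on fewer than two haplotypes."""
    if individuals is not None:
        aln = aln.subset(individuals)
    n = aln.n_haplotypes
    if n < 2:
        raise ValueError(f"{aln.locus_name}: need >= 2 haplotypes, got {n}")
    if classification is None:
        counts, cls = classify_sites(aln)
    else:
        cls = classification
        counts = site_counts(cls)
    sites = {
        "total": counts.n_total,
        "silent": counts.n_silent,
        "synonymous": counts.n_synonymous,
        "replacement": counts.n_replacement,
    }
    diffs, S = _category_diffs(aln.seqs, cls)
    npairs = n * (n - 1) / 2.0
    pi = {
        cat: (diffs[cat] / (npairs * sites[cat]) if sites[cat] > 0 else None)
        for cat in CATEGORIES
    }
    a_n = harmonic(n)
    theta_w = S / (a_n * sites["total"]) if sites["total"] > 0 else float("nan")
    return SummaryStats(
        n=n,
        S=S,
        pi=pi,
        Hd=haplotype_diversity(aln.seqs, aln.mask),
        theta_w=theta_w,
        mean_pairwise=diffs["total"] / npairs,
        diffs=diffs,
        sites=sites,
    )


def _pooled_row(per_locus: list[SummaryStats], label_n: int) -> dict:
    """Pool pi as total differences / total category sites across loci;
    average Hd as an unweighted mean over loci."""
    row: dict[str, float | None] = {}
    npairs = label_n * (label_n - 1) / 2.0
    for cat in CATEGORIES:
        tot_d = sum(s.diffs[cat] for s in per_locus)
        tot_sites = sum(s.sites[cat] for s in per_locus)
        row[f"pi_{cat}"] = tot_d / (npairs * tot_sites) if tot_sites > 0 else None
    row["Hd"] = float(np.mean([s.Hd for s in per_locus]))
    row["S"] = int(sum(s.S for s in per_locus))
    row["n"] = label_n
    return row


def population_table(
    ds: MultiLocusDataset,
    include_groups: bool = True,
) -> pd.DataFrame:
    """Per-(population x locus) statistics plus per-population averages over
    loci and a pooled total-sample row (and group rows when requested).

    Cells for populations with fewer than two haplotypes at a locus are left
    missing with a logged warning, and pooled averages use the remaining loci.
    """
    classifications = {a.locus_name: classify_sites(a)[1] for a in ds.loci}
    rows = []

    def sample_rows(label: str, individuals: list[str]) -> None:
        per_locus = []
        for aln in ds.loci:
            sub_ids = [i for i in individuals if i in aln.individuals]
            if 2 * len(sub_ids) < 2:
                logger.warning("%s at %s: fewer than 2 haplotypes, cell missing", label, aln.locus_name)
                continue
            s = summary_stats(aln, sub_ids, classifications[aln.locus_name])
            per_locus.append(s)
            rows.append(
                {
                    "sample": label,
                    "locus": aln.locus_name,
                    "n": s.n,
                    "S": s.S,
                    "Hd": s.Hd,
                    **{f"pi_{c}": s.pi[c] for c in CATEGORIES},
                    "theta_w": s.theta_w,
                    "mean_pairwise": s.mean_pairwise,
                }
            )
        if per_locus:
            pooled = _pooled_row(per_locus, 2 * len(individuals))
            rows.append({"sample": label, "locus": "average", **pooled})

    for pop in ds.popmap.populations():
        sample_rows(pop, ds.popmap.individuals_of(pop))
    if include_groups:
        for grp in ("sumatra_malay", "borneo"):
            inds = ds.popmap.individuals_of_group(grp)
            if inds:
                sample_rows(f"group:{grp}", inds)
    sample_rows("Total", ds.individuals)
    return pd.DataFrame(rows)
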