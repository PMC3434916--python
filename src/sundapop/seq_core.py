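"""Core containers and I/O for multilocus phased haplotype data.

Input model: per-locus FASTA alignments holding two phased haplotypes per
diploid individual (record ids like ``IND123_h1`` / ``IND123_h2``), a
population map assigning each individual to a population and a group
(``sumatra_malay`` / ``borneo`` / ``unassigned``), and a per-locus exon
annotation. Alignment gaps are handled by masking every column that contains
a gap in any haplotype of a locus, so coordinates stay stable while gapped
columns are excluded from every downstream statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

VALID_BASES = frozenset("ACGT-")
GROUPS = ("sumatra_malay", "borneo", "unassigned")

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


def _as_char_matrix(seqs: Sequence[str]) -> np.ndarray:
    return np.array([list(s.upper()) for s in seqs], dtype="U1")


@dataclass
class LocusAlignment:
    """One locus: equal-length phased haplotypes plus exon annotation.

    ``mask`` marks alignment columns excluded from analysis (True = masked);
    it is initialised to the gap-containing columns and is idempotent under
    re-application.
    """

    locus_name: str
    individual_ids: list[str]
    seqs: np.ndarray  # (n_haplotypes, aligned_length) of single characters
    exon_intervals: list[tuple[int, int, int]] = field(default_factory=list)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.seqs.ndim != 2:
            raise ValueError(f"{self.locus_name}: sequence matrix must be 2-D")
        if len(self.individual_ids) != self.seqs.shape[0]:
            raise ValueError(f"{self.locus_name}: one individual id per haplotype required")
        bad = set(np.unique(self.seqs)) - VALID_BASES
        if bad:
            raise ValueError(
                f"{self.locus_name}: ambiguity/invalid characters {sorted(bad)} "
                "not allowed (haplotypes must be fully resolved A/C/G/T/-)"
            )
        counts: dict[str, int] = {}
        for ind in self.individual_ids:
            counts[ind] = counts.get(ind, 0) + 1
        wrong = {k: v for k, v in counts.items() if v != 2}
        if wrong:
            raise ValueError(f"{self.locus_name}: individuals without exactly 2 haplotypes: {wrong}")
        gap_mask = (self.seqs == "-").any(axis=0)
        if self.mask is None:
            self.mask = gap_mask
        else:
            self.mask = np.asarray(self.mask, bool) | gap_mask
        self._check_exons()

    def _check_exons(self) -> None:
        L = self.aligned_length
        prev_end = -1
        for start, end, frame in sorted(self.exon_intervals):
            if not (0 <= start < end <= L):
                raise ValueError(f"{self.locus_name}: exon ({start},{end}) out of bounds")
            if start < prev_end:
                raise ValueError(f"{self.locus_name}: overlapping exon intervals")
            if (end - start - frame) % 3 != 0:
                raise ValueError(
                    f"{self.locus_name}: exon ({start},{end}) frame {frame} not a whole "
                    "number of codons"
                )
            prev_end = end

    @property
    def aligned_length(self) -> int:
        return self.seqs.shape[1]

    @property
    def n_haplotypes(self) -> int:
        return self.seqs.shape[0]

    @property
    def individuals(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individual_ids:
            seen.setdefault(ind)
        return list(seen)

    @property
    def n_effective_sites(self) -> int:
        return int((~self.mask).sum())

    def haplotypes_of(self, individual: str) -> np.ndarray:
        idx = [i for i, ind in enumerate(self.individual_ids) if ind == individual]
        return self.seqs[idx]

    def subset(self, individuals: Iterable[str]) -> "LocusAlignment":
        keep = set(individuals)
        idx = [i for i, ind in enumerate(self.individual_ids) if ind in keep]
        return LocusAlignment(
            locus_name=self.locus_name,
            individual_ids=[self.individual_ids[i] for i in idx],
            seqs=self.seqs[idx].copy(),
            exon_intervals=list(self.exon_intervals),
            mask=self.mask.copy(),
        )


@dataclass
class PopulationMap:
    """individual -> (population, group) assignment."""

    population: dict[str, str]
    group: dict[str, str]

    def __post_init__(self) -> None:
        bad = {i: g for i, g in self.group.items() if g not in GROUPS}
        if bad:
            raise ValueError(f"unknown group labels: {bad}; allowed: {GROUPS}")

    @property
    def individuals(self) -> list[str]:
        return list(self.population)

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population.values():
            seen.setdefault(p)
        return list(seen)

    def individuals_of(self, population: str) -> list[str]:
        return [i for i, p in self.population.items() if p == population]

    def individuals_of_group(self, group: str) -> list[str]:
        return [i for i, g in self.group.items() if g == group]

    def group_of_population(self, population: str) -> str:
        groups = {self.group[i] for i in self.individuals_of(population)}
        if len(groups) != 1:
            raise ValueError(f"population {population} spans groups {groups}")
        return groups.pop()

    def subset(self, individuals: Iterable[str]) -> "PopulationMap":
        keep = [i for i in self.population if i in set(individuals)]
        return PopulationMap(
            population={i: self.population[i] for i in keep},
            group={i: self.group[i] for i in keep},
        )


@dataclass
class SiteCounts:
    """Effective site totals for one locus (fractional, Nei–Gojobori counting)."""

    n_total: float
    n_intron: float
    n_synonymous: float
    n_replacement: float

    @property
    def n_silent(self) -> float:
        return self.n_intron + self.n_synonymous


# per-column region codes
INTRON, CODING, EXCLUDED = 0, 1, 2


@dataclass
class SiteClassification:
    """Per-column site categories plus variant classification in codon context."""

    region: np.ndarray  # int code per column (INTRON/CODING/EXCLUDED)
    consensus: np.ndarray  # majority base per column ('U1')
    codon_start: np.ndarray  # for CODING columns: start column of the codon, else -1
    syn_fraction: np.ndarray  # for CODING columns: fraction of the 3 changes synonymous
    mask: np.ndarray

    def variant_category(self, col: int, base_a: str, base_b: str) -> str | None:
        """Category of a single-base difference at ``col`` ('intron', 'synonymous',
        'replacement'), or None for masked/excluded columns or identical bases."""
        if base_a == base_b or self.mask[col]:
            return None
        code = self.region[col]
        if code == EXCLUDED:
            return None
        if code == INTRON:
            return "intron"
        s = self.codon_start[col]
        codon = list(self.consensus[s : s + 3])
        pos = col - s
        codon[pos] = base_a
        aa_a = _CODON_TABLE["".join(codon)]
        codon[pos] = base_b
        aa_b = _CODON_TABLE["".join(codon)]
        return "synonymous" if aa_a == aa_b else "replacement"


def consensus_sequence(seqs: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Majority base per column (gaps ignored; ties broken alphabetically)."""
    L = seqs.shape[1]
    out = np.empty(L, dtype="U1")
    for j in range(L):
        col = seqs[:, j]
        col = col[col != "-"]
        if col.size == 0:
            out[j] = "-"
            continue
        bases, counts = np.unique(col, return_counts=True)
        out[j] = bases[np.lexsort((bases, -counts))][0]
    return out


def classify_sites(aln: LocusAlignment) -> tuple[SiteCounts, SiteClassification]:
    """Classify alignment columns into intron/coding and count fractional sites.

    Each unmasked intronic column counts 1.0 silent site. Each codon of the
    majority-consensus sequence contributes fractional synonymous/replacement
    site counts by enumerating its nine possible single-base changes (equal
    pathway weighting); changes to or from stop codons count as replacement.
    Codons overlapping a masked column are excluded entirely (0 sites); a stop
    codon in the reference frame triggers a warning and is counted as
    non-coding (its columns revert to intronic/silent).
    """
    L = aln.aligned_length
    mask = aln.mask
    region = np.full(L, INTRON, dtype=int)
    codon_start = np.full(L, -1, dtype=int)
    syn_fraction = np.zeros(L)
    consensus = consensus_sequence(aln.seqs, mask)

    for start, end, frame in aln.exon_intervals:
        # partial-frame leading bases are not part of a complete codon here
        region[start : start + frame] = EXCLUDED
        for cs in range(start + frame, end, 3):
            cols = [cs, cs + 1, cs + 2]
            if mask[cols].any():
                region[cols] = EXCLUDED
                continue
            codon = "".join(consensus[cols])
            aa = _CODON_TABLE[codon]
            if aa == "*":
                warnings.warn(
                    f"{aln.locus_name}: stop codon {codon} in reference frame at "
                    f"column {cs}; counted as non-coding",
                    stacklevel=2,
                )
                region[cols] = INTRON
                continue
            region[cols] = CODING
            codon_start[cols] = cs
            for pos in range(3):
                n_syn = 0
                for alt in "ACGT":
                    if alt == codon[pos]:
                        continue
                    mut = codon[:pos] + alt + codon[pos + 1 :]
                    if _CODON_TABLE[mut] == aa:
                        n_syn += 1
                syn_fraction[cs + pos] = n_syn / 3.0

    cls = SiteClassification(
        region=region,
        consensus=consensus,
        codon_start=codon_start,
        syn_fraction=syn_fraction,
        mask=mask.copy(),
    )
    return site_counts(cls), cls


def site_counts(cls: SiteClassification) -> SiteCounts:
    """Fractional site totals implied by a per-column classification."""
    unmasked = ~cls.mask
    is_intron = unmasked & (cls.region == INTRON)
    is_coding = unmasked & (cls.region == CODING)
    return SiteCounts(
        n_total=float(unmasked.sum()),
        n_intron=float(is_intron.sum()),
        n_synonymous=float(cls.syn_fraction[is_coding].sum()),
        n_replacement=float((1.0 - cls.syn_fraction[is_coding]).sum()),
    )


@dataclass
class MultiLocusDataset:
    """Per-locus alignments + population map + optional outgroup haplotypes."""

    loci: list[LocusAlignment]
    popmap: PopulationMap
    outgroups: dict[str, np.ndarray] = field(default_factory=dict)  # locus -> (k, L)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        inds = set(self.popmap.individuals)
        for aln in self.loci:
            missing = inds - set(aln.individuals)
            extra = set(aln.individuals) - inds
            if extra:
                raise ValueError(f"{aln.locus_name}: individuals not in population map: {sorted(extra)}")
            if missing:
                raise ValueError(f"{aln.locus_name}: individuals missing from alignment: {sorted(missing)}")

    @property
    def locus_names(self) -> list[str]:
        return [a.locus_name for a in self.loci]

    @property
    def individuals(self) -> list[str]:
        return self.popmap.individuals

    def locus(self, name: str) -> LocusAlignment:
        for a in self.loci:
            if a.locus_name == name:
                return a
        raise KeyError(name)

    def subset(self, individuals: Iterable[str]) -> "MultiLocusDataset":
        individuals = list(individuals)
        return MultiLocusDataset(
            loci=[a.subset(individuals) for a in self.loci],
            popmap=self.popmap.subset(individuals),
            outgroups=dict(self.outgroups),
            metadata=dict(self.metadata),
        )


def _parse_haplotype_id(record_id: str, sep: str) -> tuple[str, str]:
    ind, _, hap = record_id.rpartition(sep)
    if not ind or not hap:
        raise ValueError(f"cannot parse haplotype id {record_id!r} with separator {sep!r}")
    return ind, hap


def load_popmap(path: str | Path) -> PopulationMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual", "population", "group"}
    if not required <= set(df.columns):
        raise ValueError(f"population map needs columns {sorted(required)}")
    if df["individual"].duplicated().any():
        dup = df.loc[df["individual"].duplicated(), "individual"].tolist()
        raise ValueError(f"duplicated individuals in population map: {dup}")
    return PopulationMap(
        population=dict(zip(df["individual"], df["population"])),
        group=dict(zip(df["individual"], df["group"])),
    )


def load_annotation(path: str | Path) -> dict[str, list[tuple[int, int, int]]]:
    df = pd.read_csv(path, sep="\t", dtype={"locus": str, "start": int, "end": int, "frame": int})
    out: dict[str, list[tuple[int, int, int]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.locus, []).append((row.start, row.end, row.frame))
    return out


def load_dataset(
    fasta_paths: Mapping[str, str | Path] | Sequence[str | Path],
    popmap_path: str | Path,
    annotation_path: str | Path | None = None,
    outgroup_paths: Mapping[str, str | Path] | None = None,
    hap_separator: str = "_",
) -> MultiLocusDataset:
    """Read per-locus FASTA files, the population map, and exon annotation.

    ``fasta_paths`` maps locus name -> file (or is a list of files whose stems
    name the loci). Gap-containing columns are masked, not deleted.
    """
    if not isinstance(fasta_paths, Mapping):
        fasta_paths = {Path(p).stem: p for p in fasta_paths}
    popmap = load_popmap(popmap_path)
    annotation = load_annotation(annotation_path) if annotation_path else {}
    loci = []
    for locus_name, path in fasta_paths.items():
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"{path}: no sequences")
        lengths = {len(r.seq) for r in records}
        if len(lengths) != 1:
            offender = [r.id for r in records if len(r.seq) != len(records[0].seq)]
            raise ValueError(f"{locus_name}: unequal sequence lengths (e.g. {offender[:3]})")
        ids = [_parse_haplotype_id(r.id, hap_separator)[0] for r in records]
        unknown = set(ids) - set(popmap.individuals)
        if unknown:
            raise ValueError(f"{locus_name}: individuals missing from population map: {sorted(unknown)}")
        loci.append(
            LocusAlignment(
                locus_name=locus_name,
                individual_ids=ids,
                seqs=_as_char_matrix([str(r.seq) for r in records]),
                exon_intervals=annotation.get(locus_name, []),
            )
        )
    outgroups = {}
    if outgroup_paths:
        for locus_name, path in outgroup_paths.items():
            recs = list(SeqIO.parse(str(path), "fasta"))
            outgroups[locus_name] = _as_char_matrix([str(r.seq) for r in recs])
    return MultiLocusDataset(loci=loci, popmap=popmap, outgroups=outgroups)


def save_dataset(ds: MultiLocusDataset, outdir: str | Path, hap_separator: str = "_") -> dict[str, Path]:
    """Write FASTA per locus + popmap.tsv (+ outgroup FASTAs); returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for aln in ds.loci:
        p = outdir / f"{aln.locus_name}.fasta"
        hap_index: dict[str, int] = {}
        with open(p, "w") as fh:
            for ind, row in zip(aln.individual_ids, aln.seqs):
                hap_index[ind] = hap_index.get(ind, 0) + 1
                fh.write(f">{ind}{hap_separator}h{hap_index[ind]}\n{''.join(row)}\n")
        paths[aln.locus_name] = p
    pm = ds.popmap
    pd.DataFrame(
        {
            "individual": pm.individuals,
            "population": [pm.population[i] for i in pm.individuals],
            "group": [pm.group[i] for i in pm.individuals],
        }
    ).to_csv(outdir / "popmap.tsv", sep="\t", index=False)
    rows = []
    for aln in ds.loci:
        for s, e, f in aln.exon_intervals:
            rows.append({"locus": aln.locus_name, "start": s, "end": e, "frame": f})
    pd.DataFrame(rows, columns=["locus", "start", "end", "frame"]).to_csv(
        outdir / "annotation.tsv", sep="\t", index=False
    )
    for locus_name, mat in ds.outgroups.items():
        p = outdir / f"{locus_name}.outgroup.fasta"
        with open(p, "w") as fh:
            for k, row in enumerate(mat):
                fh.write(f">outgroup{hap_separator}h{k + 1}\n{''.join(row)}\n")
    return paths


# ---------------------------------------------------------------------------
# Hybrid detection
# ---------------------------------------------------------------------------

@dataclass
class HybridRecord:
    individual: str
    assignments: dict[str, tuple[str, str] | None]  # locus -> (species_h1, species_h2)
    n_support: int
    flagged: bool


@dataclass
class HybridReport:
    records: dict[str, HybridRecord]
    min_loci: int

    @property
    def flagged_individuals(self) -> list[str]:
        return [i for i, r in self.records.items() if r.flagged]


def _nearest_species(
    hap: np.ndarray, refs: Mapping[str, np.ndarray], unmasked: np.ndarray
) -> str | None:
    """Species whose reference set holds the nearest neighbour (None on ties)."""
    best: dict[str, int] = {}
    for species, mat in refs.items():
        d = (mat[:, unmasked] != hap[unmasked]).sum(axis=1)
        best[species] = int(d.min())
    dmin = min(best.values())
    winners = [s for s, d in best.items() if d == dmin]
    return winners[0] if len(winners) == 1 else None


def flag_hybrids(
    ds: MultiLocusDataset,
    refs: Mapping[str, Mapping[str, np.ndarray]],
    min_loci: int | None = None,
) -> tuple[HybridReport, MultiLocusDataset]:
    """Detect F1-like interspecific hybrids and return the filtered dataset.

    ``refs`` maps species name -> {locus name -> reference haplotype matrix}.
    At each locus, each haplotype of each individual is assigned to the species
    holding its nearest reference (Hamming distance on unmasked columns); a
    nearest-neighbour tie makes that locus uninformative. An individual is
    flagged when its two haplotypes assign to two different species at
    >= ``min_loci`` loci (default: every locus), and flagged individuals are
    removed from the returned dataset.
    """
    if not refs:
        raise ValueError("at least one reference species required")
    if min_loci is None:
        min_loci = len(ds.loci)
    records: dict[str, HybridRecord] = {}
    for ind in ds.individuals:
        assignments: dict[str, tuple[str, str] | None] = {}
        n_support = 0
        for aln in ds.loci:
            locus_refs = {sp: mats[aln.locus_name] for sp, mats in refs.items() if aln.locus_name in mats}
            if not locus_refs:
                assignments[aln.locus_name] = None
                continue
            unmasked = ~aln.mask
            h1, h2 = aln.haplotypes_of(ind)
            s1 = _nearest_species(h1, locus_refs, unmasked)
            s2 = _nearest_species(h2, locus_refs, unmasked)
            if s1 is None or s2 is None:
                assignments[aln.locus_name] = None  # tie: uninformative
                continue
            assignments[aln.locus_name] = (s1, s2)
            if s1 != s2:
                n_support += 1
        flagged = n_support >= min_loci
        records[ind] = HybridRecord(ind, assignments, n_support, flagged)
    report = HybridReport(records=records, min_loci=min_loci)
    keep = [i for i in ds.individuals if not records[i].flagged]
    return report, ds.subset(keep)
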