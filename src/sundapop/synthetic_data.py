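"""Synthetic multilocus datasets with the statistical structure the analysis
assumes: two diverged population groups under an isolation-with-migration
history, admixed populations, one planted interspecific F1 hybrid, a diverged
donor species for hybrid detection, and a deep outgroup for divergence-based
tests.

The ``paper_like`` scenario reproduces the study design this package targets:
seven populations of 12/12/12/12/12/6/12 diploid individuals (78 total), five
nuclear loci of aligned lengths 1111/1229/1248/1075/1277 bp (5940 bp) with one
or two exons covering roughly 30% of each locus, IM parameters near the
published fit, one admixed population per group, and a single F1 hybrid
carrying one donor-lineage haplotype at every locus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np
import pandas as pd

from .coalsim import IMParameters
from .seq_core import MultiLocusDataset, LocusAlignment, PopulationMap, save_dataset

NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass
class PopulationSpec:
    name: str
    size: int  # diploid individuals
    group: str  # sumatra_malay / borneo
    admixture_q: float | None = None  # P(haplotype copy originates from sm); None = pure


@dataclass
class LocusSpec:
    name: str
    length: int
    exon_intervals: list[tuple[int, int, int]]
    scale: float = 1.0  # relative mutation weight


@dataclass
class Scenario:
    name: str
    populations: list[PopulationSpec]
    im: IMParameters
    loci: list[LocusSpec]
    hybrid_population: str | None = None  # first individual of this population
    hybrid_divergence: float = 10.0  # donor-lineage split, mutational units
    outgroup_divergence: float = 20.0
    replacement_singleton_fraction: float = 0.5  # purifying-selection emulation

    def __post_init__(self) -> None:
        if any(p.size <= 0 for p in self.populations):
            raise ValueError("population sizes must be positive")
        if any(not (0 <= (p.admixture_q or 0) <= 1) for p in self.populations):
            raise ValueError("admixture proportions must be in [0, 1]")
        if any(l.length <= 0 for l in self.loci):
            raise ValueError("locus lengths must be positive")


def _default_exons(length: int) -> list[tuple[int, int, int]]:
    """One or two exons covering ~30% of the locus, whole codons, frame 0."""
    e1_len = 3 * round(0.15 * length / 3)
    e2_len = 3 * round(0.15 * length / 3)
    s1 = round(0.10 * length)
    s2 = round(0.55 * length)
    return [(s1, s1 + e1_len, 0), (s2, s2 + e2_len, 0)]


def paper_like(seed_offset: int = 0) -> Scenario:
    pops = [
        PopulationSpec("Seremban", 12, "sumatra_malay"),
        PopulationSpec("Mersing", 12, "sumatra_malay"),
        PopulationSpec("NanjakMakmur", 12, "sumatra_malay"),
        PopulationSpec("Asialog", 12, "sumatra_malay", admixture_q=0.5),
        PopulationSpec("SariBumiKusuma", 12, "borneo"),
        PopulationSpec("ITCIKaryaUtama", 6, "borneo", admixture_q=0.5),
        PopulationSpec("Sumalindo", 12, "borneo"),
    ]
    lengths = {"GapC": 1111, "GBSSI": 1229, "PgiC": 1248, "SBE2": 1075, "SODH": 1277}
    mean_len = float(np.mean(list(lengths.values())))
    # the IM-scale thetas refer to the non-recombining core of each locus
    # (roughly a third of the alignment); the full-locus mutation weight is
    # scaled up by the inverse core fraction so per-site diversity lands on
    # the observed scale
    core_fraction = 1.0 / 3.0
    loci = [
        LocusSpec(name, L, _default_exons(L), scale=(L / mean_len) / core_fraction)
        for name, L in lengths.items()
    ]
    return Scenario(
        name="paper_like",
        populations=pops,
        im=IMParameters(
            theta_sm=4.367, theta_b=11.2873, theta_A=1.1677, m_sm=0.755, m_b=0.045, t=0.685
        ),
        loci=loci,
        hybrid_population="NanjakMakmur",
    )


def two_pop_recovery(
    n_loci: int = 20,
    individuals_per_group: int = 20,
    im: IMParameters | None = None,
) -> Scenario:
    """Clean two-population design for parameter-recovery experiments: no
    admixture, no hybrid, equal locus lengths."""
    pops = [
        PopulationSpec("SM", individuals_per_group, "sumatra_malay"),
        PopulationSpec("B", individuals_per_group, "borneo"),
    ]
    loci = [LocusSpec(f"L{i + 1}", 1000, _default_exons(1000)) for i in range(n_loci)]
    return Scenario(
        name="two_pop_recovery",
        populations=pops,
        im=im
        or IMParameters(theta_sm=4.0, theta_b=11.0, theta_A=1.2, m_sm=0.75, m_b=0.05, t=0.7),
        loci=loci,
        hybrid_population=None,
    )


@dataclass
class GeneratedDataset:
    dataset: MultiLocusDataset
    refs: dict[str, dict[str, np.ndarray]]  # species -> locus -> haplotype matrix
    manifest: dict


def _scenario_demography(sc: Scenario) -> msprime.Demography:
    eps = 1e-9
    dem = msprime.Demography()
    dem.add_population(name="sm", initial_size=max(sc.im.theta_sm, eps) / 2.0)
    dem.add_population(name="b", initial_size=max(sc.im.theta_b, eps) / 2.0)
    dem.add_population(name="anc", initial_size=max(sc.im.theta_A, eps) / 2.0)
    dem.add_population(name="donor", initial_size=max(sc.im.theta_A, eps) / 2.0)
    dem.add_population(name="anc2", initial_size=max(sc.im.theta_A, eps) / 2.0)
    dem.add_population(name="og", initial_size=max(sc.im.theta_A, eps) / 2.0)
    dem.add_population(name="anc3", initial_size=max(sc.im.theta_A, eps) / 2.0)
    if sc.im.m_sm > 0:
        dem.set_migration_rate(source="sm", dest="b", rate=sc.im.m_sm)
    if sc.im.m_b > 0:
        dem.set_migration_rate(source="b", dest="sm", rate=sc.im.m_b)
    dem.add_population_split(time=max(sc.im.t, eps), derived=["sm", "b"], ancestral="anc")
    dem.add_population_split(time=sc.hybrid_divergence, derived=["anc", "donor"], ancestral="anc2")
    dem.add_population_split(time=sc.outgroup_divergence, derived=["anc2", "og"], ancestral="anc3")
    return dem


def generate(
    scenario: Scenario, seed: int, outdir: str | Path | None = None
) -> GeneratedDataset:
    """Simulate a full on-disk-equivalent dataset for a scenario.

    Haplotype copies of admixed populations draw their deme of origin
    independently per locus with the population's admixture proportion; the
    hybrid individual's first haplotype comes from the donor lineage at every
    locus. Two further donor haplotypes become the reference individual of the
    donor species and two deep-outgroup haplotypes are attached per locus.
    Same seed, byte-identical output.
    """
    rng = np.random.default_rng(seed)
    sc = scenario
    individuals: list[str] = []
    pop_of: dict[str, str] = {}
    group_of: dict[str, str] = {}
    q_of: dict[str, float | None] = {}
    for pop in sc.populations:
        for i in range(pop.size):
            ind = f"{pop.name}_{i + 1:02d}"
            individuals.append(ind)
            pop_of[ind] = pop.name
            group_of[ind] = pop.group
            q_of[ind] = pop.admixture_q
    hybrid_ind = None
    if sc.hybrid_population is not None:
        hybrid_ind = f"{sc.hybrid_population}_01"

    dem = _scenario_demography(sc)
    loci_alignments = []
    outgroups: dict[str, np.ndarray] = {}
    refs: dict[str, dict[str, np.ndarray]] = {"focal": {}, "donor_species": {}}
    origins_manifest: dict[str, dict[str, list[str]]] = {}

    # pick focal reference individuals: first of the first pure population in
    # each group (their own haplotypes double as conspecific references)
    focal_ref_inds = []
    for grp in ("sumatra_malay", "borneo"):
        for pop in sc.populations:
            if pop.group == grp and pop.admixture_q is None:
                cand = f"{pop.name}_01"
                if cand != hybrid_ind:
                    focal_ref_inds.append(cand)
                    break

    for locus in sc.loci:
        # deme of origin per haplotype copy
        origin: dict[tuple[str, int], str] = {}
        for ind in individuals:
            for copy in (0, 1):
                if ind == hybrid_ind and copy == 0:
                    origin[(ind, copy)] = "donor"
                elif q_of[ind] is not None:
                    origin[(ind, copy)] = "sm" if rng.random() < q_of[ind] else "b"
                else:
                    origin[(ind, copy)] = "sm" if group_of[ind] == "sumatra_malay" else "b"
        n_sm = sum(1 for v in origin.values() if v == "sm")
        n_b = sum(1 for v in origin.values() if v == "b")
        n_donor_data = sum(1 for v in origin.values() if v == "donor")
        samples = {"sm": n_sm, "b": n_b, "donor": n_donor_data + 2, "og": 2}
        ts = msprime.sim_ancestry(
            samples=samples,
            ploidy=1,
            demography=dem,
            sequence_length=1.0,
            discrete_genome=False,
            random_seed=int(rng.integers(1, 2**31)),
        )
        mts = msprime.sim_mutations(
            ts,
            rate=locus.scale,
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
            random_seed=int(rng.integers(1, 2**31)),
        )
        binary = mts.genotype_matrix().T.astype(np.int8)  # (n_total, S)
        S = binary.shape[1]
        if S > locus.length:
            raise ValueError(
                f"{locus.name}: simulated {S} segregating sites exceed length {locus.length}"
            )
        # sample index pools in msprime's population order (dict order above)
        pools = {
            "sm": list(range(n_sm)),
            "b": list(range(n_sm, n_sm + n_b)),
            "donor": list(range(n_sm + n_b, n_sm + n_b + n_donor_data + 2)),
            "og": list(range(n_sm + n_b + n_donor_data + 2, n_sm + n_b + n_donor_data + 4)),
        }
        row_of: dict[tuple[str, int], int] = {}
        taken = {k: 0 for k in pools}
        for ind in individuals:
            for copy in (0, 1):
                deme = origin[(ind, copy)]
                row_of[(ind, copy)] = pools[deme][taken[deme]]
                taken[deme] += 1
        donor_ref_rows = pools["donor"][taken["donor"] : taken["donor"] + 2]
        og_rows = pools["og"]

        nucs, site_cols = _binary_to_nucleotides(binary, locus, rng, sc, n_focal=2 * len(individuals), row_order=None)

        # assemble aligned matrices in popmap order
        focal_rows = []
        ids = []
        for ind in individuals:
            for copy in (0, 1):
                focal_rows.append(nucs[row_of[(ind, copy)]])
                ids.append(ind)
        aln = LocusAlignment(
            locus_name=locus.name,
            individual_ids=ids,
            seqs=np.vstack(focal_rows),
            exon_intervals=list(locus.exon_intervals),
        )
        loci_alignments.append(aln)
        outgroups[locus.name] = nucs[og_rows]
        refs["donor_species"][locus.name] = nucs[donor_ref_rows]
        focal_ref_rows = [row_of[(ind, c)] for ind in focal_ref_inds for c in (0, 1)]
        refs["focal"][locus.name] = nucs[focal_ref_rows]
        origins_manifest[locus.name] = {
            ind: [origin[(ind, 0)], origin[(ind, 1)]] for ind in individuals
        }

    popmap = PopulationMap(population=dict(pop_of), group=dict(group_of))
    ds = MultiLocusDataset(
        loci=loci_alignments,
        popmap=popmap,
        outgroups=outgroups,
        metadata={"scenario": sc.name, "seed": seed},
    )
    manifest = {
        "scenario": sc.name,
        "seed": seed,
        "hybrid_individual": hybrid_ind,
        "populations": {
            p.name: {"size": p.size, "group": p.group, "admixture_q": p.admixture_q}
            for p in sc.populations
        },
        "im_parameters": dict(zip(("theta_sm", "theta_b", "theta_A", "m_sm", "m_b", "t"), sc.im.as_array().tolist())),
        "loci": {
            l.name: {"length": l.length, "exons": l.exon_intervals, "scale": l.scale}
            for l in sc.loci
        },
        "origins": origins_manifest,
        "focal_reference_individuals": focal_ref_inds,
    }
    if outdir is not None:
        outdir = Path(outdir)
        save_dataset(ds, outdir)
        (outdir / "truth_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        for species, mats in refs.items():
            for locus_name, mat in mats.items():
                p = outdir / f"{locus_name}.refs.{species}.fasta"
                with open(p, "w") as fh:
                    for k, row in enumerate(mat):
                        fh.write(f">{species}_h{k + 1}\n{''.join(row)}\n")
    return GeneratedDataset(dataset=ds, refs=refs, manifest=manifest)


def _binary_to_nucleotides(
    binary: np.ndarray,
    locus: LocusSpec,
    rng: np.random.Generator,
    sc: Scenario,
    n_focal: int,
    row_order=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Map 0/1 site columns onto a nucleotide background of the locus length.

    The ancestral background is random with exon codons drawn from non-stop
    codons; each segregating site gets a distinct column and a derived base
    drawn from the three alternatives (infinite sites preserved). A fraction
    of replacement variants among the focal rows is re-assigned to a single
    random focal haplotype, emulating purifying selection keeping
    nonsynonymous variants at low frequency.
    """
    L = locus.length
    S = binary.shape[1]
    background = rng.choice(list("ACGT"), size=L)
    exonic = np.zeros(L, bool)
    for s, e, f in locus.exon_intervals:
        for cs in range(s + f, e, 3):
            codon = NON_STOP_CODONS[int(rng.integers(len(NON_STOP_CODONS)))]
            background[cs : cs + 3] = list(codon)
            exonic[cs : cs + 3] = True
    site_cols = np.sort(rng.choice(L, size=S, replace=False))
    nucs = np.tile(background, (binary.shape[0], 1))
    for k, col in enumerate(site_cols):
        anc = background[col]
        alts = [b for b in "ACGT" if b != anc]
        if exonic[col]:
            # avoid derived alleles that put a stop codon into the reference
            # frame (keeps the majority-consensus frame open)
            safe = [b for b in alts if not _creates_stop(background, col, b, locus)] or alts
            der = safe[int(rng.integers(len(safe)))]
        else:
            der = alts[int(rng.integers(3))]
        carriers = binary[:, k] == 1
        # phenomenological purifying selection on replacement changes
        if exonic[col] and sc.replacement_singleton_fraction > 0:
            cat = _change_category(background, col, anc, der, locus)
            if cat == "replacement" and rng.random() < sc.replacement_singleton_fraction:
                focal_carriers = carriers[:n_focal]
                if focal_carriers.any() and not focal_carriers.all():
                    carriers = carriers.copy()
                    carriers[:n_focal] = False
                    carriers[int(rng.integers(n_focal))] = True
        nucs[carriers, col] = der
    return nucs, site_cols


def _frame_offset(col: int, locus: LocusSpec) -> int:
    for s, e, f in locus.exon_intervals:
        if s + f <= col < e:
            return (col - s - f) % 3
    return 0


def _creates_stop(background: np.ndarray, col: int, alt: str, locus: LocusSpec) -> bool:
    from .seq_core import _CODON_TABLE

    for s, e, f in locus.exon_intervals:
        if s + f <= col < e:
            pos = (col - s - f) % 3
            cs = col - pos
            if cs + 3 > e:
                return False
            codon = "".join(background[cs : cs + 3])
            mut = codon[:pos] + alt + codon[pos + 1 :]
            return _CODON_TABLE[mut] == "*"
    return False


def _change_category(
    background: np.ndarray, col: int, anc: str, der: str, locus: LocusSpec
) -> str | None:
    from .seq_core import _CODON_TABLE

    for s, e, f in locus.exon_intervals:
        if s + f <= col < e:
            pos = (col - s - f) % 3
            cs = col - pos
            if cs + 3 > e:
                return None
            codon = "".join(background[cs : cs + 3])
            mut = codon[:pos] + der + codon[pos + 1 :]
            if _CODON_TABLE[codon] == "*" or _CODON_TABLE[mut] == "*":
                return "replacement"
            return "synonymous" if _CODON_TABLE[codon] == _CODON_TABLE[mut] else "replacement"
    return None


def mk_fixture() -> pd.DataFrame:
    """The five published McDonald–Kreitman 2x2 tables (fixed/polymorphic x
    synonymous/replacement counts) for GapC, GBSSI, PgiC, SBE2 and SODH."""
    rows = [
        ("GapC", 3, 4, 10, 2),
        ("GBSSI", 12, 1, 23, 29),
        ("PgiC", 2, 1, 13, 9),
        ("SBE2", 1, 2, 4, 2),
        ("SODH", 1, 3, 7, 2),
    ]
    return pd.DataFrame(
        rows, columns=["locus", "fixed_syn", "fixed_rep", "poly_syn", "poly_rep"]
    ).set_index("locus")
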