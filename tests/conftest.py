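import numpy as np
import pytest

from sundapop import synthetic_data
from sundapop.seq_core import LocusAlignment, MultiLocusDataset, PopulationMap, flag_hybrids


def make_aln(seqs, exons=(), name="L1", ids=None):
    """Tiny alignment builder: one individual per two consecutive sequences."""
    seqs = list(seqs)
    if ids is None:
        ids = [f"IND{i // 2 + 1}" for i in range(len(seqs))]
    return LocusAlignment(
        locus_name=name,
        individual_ids=ids,
        seqs=np.array([list(s) for s in seqs], dtype="U1"),
        exon_intervals=list(exons),
    )


def make_dataset(loci_seqs, pops=None, groups=None, exons=None):
    """Dataset from {locus: [seq, ...]}; populations default to one pop."""
    loci = []
    n_ind = None
    for name, seqs in loci_seqs.items():
        ex = (exons or {}).get(name, ())
        aln = make_aln(seqs, ex, name=name)
        loci.append(aln)
        n_ind = len(aln.individuals)
    inds = [f"IND{i + 1}" for i in range(n_ind)]
    pops = pops or {i: "P1" for i in inds}
    groups = groups or {i: "unassigned" for i in inds}
    return MultiLocusDataset(
        loci=loci,
        popmap=PopulationMap(population=pops, group=groups),
    )


@pytest.fixture(scope="session")
def paper_like_generated():
    return synthetic_data.generate(synthetic_data.paper_like(), seed=1)


@pytest.fixture(scope="session")
def filtered_paper_like(paper_like_generated):
    report, ds = flag_hybrids(paper_like_generated.dataset, paper_like_generated.refs)
    return report, ds
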