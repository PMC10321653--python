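import numpy as np
import pytest

from kumquatpop import synth
from kumquatpop.vcfio import GenotypeMatrix, PopulationMap, ANC_REF


@pytest.fixture(scope="session")
def default_cohort():
    """Study-condition cohort (71 ingroup + 15 outgroup accessions)."""
    return synth.simulate_cohort(seed=11)


@pytest.fixture(scope="session")
def intro_cohort():
    """Cohort with 25% cultivated tracts planted into every WILDAPO sample."""
    cfg = synth.CohortConfig(introgression={"WILDAPO": ("CULAPO", 0.25)})
    return synth.simulate_cohort(cfg, seed=7)


def matrix_from_arrays(gt, pos=None, chrom="chr1", hap=None, anc=None, **kw):
    """Small hand-built genotype matrix for unit tests."""
    gt = np.asarray(gt, dtype=np.int8)
    n, s = gt.shape
    pos = np.arange(1, s + 1) if pos is None else np.asarray(pos)
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        chrom=np.full(s, chrom, dtype=object), pos=pos,
        ref=np.full(s, "A", dtype=object), alt=np.full(s, "T", dtype=object),
        gt=gt, hap=hap,
        anc=(np.full(s, ANC_REF, dtype=np.int8) if anc is None
             else np.asarray(anc, dtype=np.int8)),
        **kw)


def matrix_from_tree_sequence(ts, chrom="chr1"):
    """Diploid genotype matrix from an msprime/tskit tree sequence.

    Consecutive haploid samples are paired into diploids; the tskit
    ancestral state is REF, so the matrix arrives pre-polarized.
    """
    G = ts.genotype_matrix()            # (sites, haplotypes)
    n_hap = G.shape[1]
    assert n_hap % 2 == 0
    hap = np.ascontiguousarray(G.T.reshape(n_hap // 2, 2, -1).astype(np.int8))
    gt = hap.sum(axis=1).astype(np.int8)
    pos = np.maximum(1, np.round([s.position for s in ts.sites()]).astype(np.int64))
    pos = np.maximum.accumulate(pos + np.arange(len(pos)) * 0)  # keep sorted
    return matrix_from_arrays(gt, pos=pos, chrom=chrom, hap=hap)


def single_group_popmap(gm, group="G"):
    return PopulationMap({s: group for s in gm.samples})
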