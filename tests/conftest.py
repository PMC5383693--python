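import numpy as np
import pytest

from ndrscape import (
    ChromSizes,
    SimParams,
    compute_occupancy,
    call_nucleosomes,
    delta_ndr,
    ndr_lengths,
    sample_fragments,
    sample_genome,
    wilcoxon_one_sample,
)


@pytest.fixture
def small_sizes():
    return ChromSizes({"chrI": 50, "chrII": 30})


@pytest.fixture(scope="session")
def sim_small():
    """A 20-gene noise-free landscape shared by read-only tests."""
    params = SimParams(n_genes=20, seed=7)
    sizes, tss, truth = sample_genome(params)
    return params, sizes, tss, truth


def run_delta_pipeline(seed: int, mutant_shrink: int, n_genes: int = 200, depth: float = 50.0):
    """Simulate, pile up fragments, call nucleosomes, and test ΔNDR.

    Returns (median delta in bp, Wilcoxon p, number of gene pairs).
    """
    params = SimParams(
        n_genes=n_genes, mutant_shrink=mutant_shrink, depth=depth, seed=seed
    )
    sizes, tss, truth = sample_genome(params)
    records = {}
    for cond in ("wt", "mutant"):
        occ = compute_occupancy(sample_fragments(truth, cond, params), sizes)
        records[cond], _ = ndr_lengths(call_nucleosomes(occ, 100), tss, 1000)
    deltas = delta_ndr(records["mutant"], records["wt"])
    result = wilcoxon_one_sample(deltas["delta"])
    return float(deltas["delta"].median()), result.pvalue, len(deltas)
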