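import numpy as np
import pandas as pd
import pytest

from tierseq.coverage import ROW_INDEX_NAMES, GenomeIndex, PositionTable
from tierseq.synthetic import SimConfig, simulate_experiment

LIBS = ["wt_1", "wt_2", "wt_3", "mut_1", "mut_2", "mut_3"]
CONDITIONS = {l: "wild_type" if l.startswith("wt") else "mutant" for l in LIBS}


def make_table(counts, libs=None, conditions=None, replicon="chr", strand="+"):
    """PositionTable from a dense matrix; rows become positions 1..n."""
    counts = np.asarray(counts, dtype="int64")
    libs = libs or LIBS[: counts.shape[1]]
    conditions = conditions or {l: CONDITIONS.get(l, "wild_type") for l in libs}
    index = pd.MultiIndex.from_tuples(
        [(replicon, strand, i + 1) for i in range(len(counts))],
        names=ROW_INDEX_NAMES,
    )
    return PositionTable(pd.DataFrame(counts, index=index, columns=libs), conditions)


@pytest.fixture
def toy_genome():
    seq = "AATTACGGTACGCGCGATATCGCGTACGATCGGCTAGCTAAGGCTT"
    return {"chr": GenomeIndex("chr", len(seq), seq)}


@pytest.fixture(scope="session")
def default_bundle():
    """Moderate-scale synthetic experiment shared by recovery-style tests."""
    return simulate_experiment(
        SimConfig(seed=11, genome_length=120_000, n_genes=80,
                  n_cleavage_sites=120, n_enriched_sites=120)
    )
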