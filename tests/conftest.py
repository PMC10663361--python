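import numpy as np
import pandas as pd
import pytest

from primescan.genomic_core import GeneAnnotation, GenomicInterval
from primescan.io_formats import ExpressionTable
from primescan.synthetic_data import SimulationConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_intervals(rng, n, n_chroms=3, span=2000, max_len=150):
    out = []
    for _ in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def make_genes(positions, chrom="chr1", prefix="G", is_tf=False):
    """Genes with TSS at the given positions, 1 kb bodies."""
    return [
        GeneAnnotation(f"{prefix}{i:03d}", f"S{i:03d}", p,
                       GenomicInterval(chrom, p, p + 1000, "+"), "+", is_tf)
        for i, p in enumerate(positions)
    ]


def make_expression(data, stages, reps):
    """ExpressionTable from a dict gene -> list of per-sample counts."""
    cols = [f"{s}_rep{r}" for s in stages for r in range(1, reps + 1)]
    return ExpressionTable(pd.DataFrame(data, index=cols).T)


@pytest.fixture(scope="session")
def small_config():
    # a reduced world for fast unit tests (6 planted primed pairs per
    # transition); the acceptance suite uses the full default config
    return SimulationConfig(seed=13, n_genes=180, n_elements=60,
                            n_chromosomes=4, chrom_length=1_000_000,
                            n_background_fragments=40)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory, small_config):
    out = tmp_path_factory.mktemp("sim_small")
    paths, truth = simulate(small_config, out)
    return paths, truth, small_config
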