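import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helper module

from meiocross.genome import ChromosomeLayout, GenomeLayout, arabidopsis_layout
from meiocross.genotype_blocks import F2BlockSet


@pytest.fixture(scope="session")
def layout() -> GenomeLayout:
    """Five-chromosome plant-genome layout used by the simulation tests."""
    return arabidopsis_layout()


@pytest.fixture
def toy_layout() -> GenomeLayout:
    """A single 100-kb chromosome with a central centromere."""
    return GenomeLayout([ChromosomeLayout("chr", 100_000, 45_000, 55_000, 30_000, 70_000)])


def blockset(rows, layout, n=None) -> F2BlockSet:
    df = pd.DataFrame(rows, columns=["indiv", "chrom", "start", "end", "state"])
    return F2BlockSet(df, layout, n_individuals=n)


@pytest.fixture
def simple_blocks(toy_layout) -> F2BlockSet:
    """One individual, P1 - HET - P1 along the toy chromosome."""
    return blockset(
        [
            ("f1", "chr", 1, 10_000, "P1"),
            ("f1", "chr", 12_000, 30_000, "HET"),
            ("f1", "chr", 31_000, 50_000, "P1"),
        ],
        toy_layout,
    )
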