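import numpy as np
import pytest

from beetmbs.genmap import ChromosomeMap, GeneticMap


@pytest.fixture
def two_chrom_map() -> GeneticMap:
    """Tiny two-chromosome map for fast simulator tests."""
    c1 = ChromosomeMap(
        name="chr1",
        length_bp=100_000,
        positions=np.array([1_000, 20_000, 50_000, 80_000]),
        cm=np.array([0.0, 10.0, 40.0, 70.0]),
    )
    c2 = ChromosomeMap(
        name="chr2",
        length_bp=60_000,
        positions=np.array([5_000, 30_000]),
        cm=np.array([0.0, 25.0]),
    )
    return GeneticMap((c1, c2))


def single_locus_map(cm_positions, length_bp: int = 1_000_000) -> GeneticMap:
    """One chromosome with variants at the given cM positions (bp spread evenly)."""
    cm = np.asarray(cm_positions, dtype=float)
    pos = np.linspace(1_000, length_bp - 1_000, num=len(cm)).astype(np.int64)
    return GeneticMap(
        (ChromosomeMap(name="chr1", length_bp=length_bp, positions=pos, cm=cm),)
    )
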