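import numpy as np
import pytest

from srnarefine.coverage import ConditionCoverage, StrandedCoverage
from srnarefine.genome import Feature, GenomeAnnotation


def make_condition(label, tracks):
    """ConditionCoverage from {(chrom, strand): array} of normalized values."""
    averaged = {
        key: StrandedCoverage(key[0], key[1], np.asarray(vals, dtype=float), normalized=True)
        for key, vals in tracks.items()
    }
    return ConditionCoverage(label, averaged)


@pytest.fixture
def tiny_genome():
    """1-kb single-chromosome genome with two plus-strand genes."""
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=1000))
    features = [
        Feature("geneA", "c1", 100, 300, "+", "gene"),
        Feature("geneB", "c1", 600, 800, "+", "gene"),
    ]
    return GenomeAnnotation(chromosomes={"c1": seq}, features=features)


@pytest.fixture
def featureless_genome():
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list("ACGT"), size=1000))
    return GenomeAnnotation(chromosomes={"c1": seq}, features=[])


@pytest.fixture(scope="session")
def small_dataset():
    from srnarefine.simulate import SMALL_PRESET, simulate_genome

    return simulate_genome(SMALL_PRESET)
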