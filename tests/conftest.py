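import numpy as np
import pytest

from cofun_instab.io_formats import (
    CNProfileSet,
    ExpressionMatrix,
    GeneSetCollection,
    InstabilityScores,
)


@pytest.fixture
def toy_expression() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(8)]
    samples = [f"s{j}" for j in range(6)]
    return ExpressionMatrix(genes, samples, rng.normal(size=(8, 6)))


@pytest.fixture
def toy_scores(toy_expression) -> InstabilityScores:
    rng = np.random.default_rng(7)
    return InstabilityScores(
        list(toy_expression.sample_ids), rng.normal(size=toy_expression.n_samples)
    )


@pytest.fixture
def toy_sets() -> GeneSetCollection:
    return GeneSetCollection(
        ["S1", "S2", "S3"],
        ["", "", ""],
        [
            frozenset({"g0", "g1", "g2", "g3", "g4"}),
            frozenset({"g3", "g4", "g5", "g6", "g7"}),
            frozenset({"g0", "g2", "g4", "g6", "g7"}),
        ],
    )


def make_profiles(states, conditions=None, bins_per_chrom=None, n_chrom=1):
    """Build a CNProfileSet from a (cells, bins) state array."""
    states = np.asarray(states, dtype=np.int64)
    n_cells, n_bins = states.shape
    if bins_per_chrom is None:
        bins_per_chrom = n_bins // n_chrom
    assert n_chrom * bins_per_chrom == n_bins
    chroms = np.repeat([f"chr{i+1}" for i in range(n_chrom)], bins_per_chrom).astype(
        object
    )
    starts = np.tile(np.arange(bins_per_chrom, dtype=np.int64) * 100, n_chrom)
    ends = starts + 100
    if conditions is None:
        conditions = ["CTRL"] * n_cells
    cells = [f"cell{i}" for i in range(n_cells)]
    return CNProfileSet(cells, list(conditions), chroms, starts, ends, states)
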