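from __future__ import annotations

import numpy as np
import pytest

from hmcscan.coverage import coverage_matrix
from hmcscan.expression import ExpressionMatrix
from hmcscan.intervals import ChromSizes, GenomicInterval, IntervalSet
from hmcscan.simulate import (
    SimulationParams,
    simulate_counts,
    simulate_peaks,
    simulate_truth,
)

DEFAULT_SEED = 1


def random_interval_set(rng: np.random.Generator, n: int, length: int,
                        chrom: str = "chrT") -> IntervalSet:
    """n random intervals on a toy chromosome of the given length."""
    starts = rng.integers(0, length - 1, size=n)
    spans = rng.integers(1, max(length // 10, 2), size=n)
    ivs = [GenomicInterval(chrom, int(s), int(min(s + sp, length)))
           for s, sp in zip(starts, spans) if s < min(s + sp, length)]
    return IntervalSet(ivs)


@pytest.fixture(scope="session")
def toy_chrom_sizes() -> ChromSizes:
    return ChromSizes({"chrT": 50_000}, sex_chroms=set())


@pytest.fixture(scope="session")
def default_truth():
    """Standard synthetic dataset truth (default generator conditions)."""
    return simulate_truth(SimulationParams(), seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_peaks(default_truth):
    return simulate_peaks(default_truth)


@pytest.fixture(scope="session")
def default_coverage(default_truth, default_peaks):
    return coverage_matrix(default_truth.genes, default_peaks)


@pytest.fixture(scope="session")
def default_expression(default_truth):
    counts, meta = simulate_counts(default_truth)
    return ExpressionMatrix(counts, meta)


@pytest.fixture(scope="session")
def replicate_map(default_truth):
    """Coverage sample -> its two expression replicate sample names."""
    return {
        cell: [f"{cell}_r1", f"{cell}_r2"]
        for cell in default_truth.coverage_targets.columns
    }
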