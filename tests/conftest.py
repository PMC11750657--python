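import numpy as np
import pandas as pd
import pytest

from survsig import (
    CohortSimConfig,
    ExpressionMatrix,
    PhenotypeLabels,
    simulate_cohort,
)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples with hand-checkable values."""
    return ExpressionMatrix(
        pd.DataFrame(
            {
                "s1": [1.0, 2.0, 5.0],
                "s2": [2.0, 4.0, 5.0],
                "s3": [3.0, 6.0, 5.0],
                "s4": [4.0, 8.0, 5.0],
            },
            index=["GA", "GB", "GC"],
        )
    )


@pytest.fixture
def tiny_labels() -> PhenotypeLabels:
    return PhenotypeLabels(
        {"s1": "survivor", "s2": "survivor", "s3": "non_survivor", "s4": "non_survivor"}
    )


@pytest.fixture
def small_cohort():
    """A 100-gene, 30+30 cohort with 5 planted genes at a strong effect."""
    config = CohortSimConfig(
        n_genes=100,
        n_survivors=30,
        n_nonsurvivors=30,
        planted_genes=["PG1", "PG2", "PG3", "PG4", "PG5"],
        effect_size=2.0,
        gene_sd=1.0,
        seed=7,
    )
    return simulate_cohort(config)


def brute_force_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Independent oracle: direct positive/negative pair counting, ties half."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_force_bh(p_values: np.ndarray) -> np.ndarray:
    """Independent step-up BH oracle: q_i = min over j>=rank(i) of m*p_(j)/j, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, m * p[idx] / rank)
        q[idx] = running_min
    return q
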