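"""Two-group differential expression with fold-change and FDR filtering.

The contrast is always alternative-class minus reference-class on the log2
scale (non_survivor minus survivor for patient cohorts, perturbed minus
control for perturbation experiments).  P-values come from a two-sided Welch
two-sample t test by default (Student t available via ``equal_var=True``);
FDR is Benjamini-Hochberg across all genes in the matrix.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ContractError, ExpressionMatrix, GeneSet, PhenotypeLabels

logger = logging.getLogger("survsig")


@dataclass(frozen=True)
class DegRecord:
    """One gene's differential-expression result for a two-group contrast."""

    gene: str
    log2fc: float
    p_value: float
    fdr: float
    direction: str  # "up" iff log2fc > 0, else "down"


def differential_expression(
    matrix: ExpressionMatrix,
    labels: PhenotypeLabels,
    equal_var: bool = False,
) -> list[DegRecord]:
    """Per-gene two-sided t test of alternative vs reference class.

    Requires at least two samples per class.  A gene with zero variance in
    both classes gets p = 1 (with a logged note) rather than NaN so that
    downstream set algebra stays total.
    """
    labels.check_matches(matrix)
    labels.require_both_classes("differential expression")
    counts = labels.counts()
    small = [c for c, n in counts.items() if n < 2]
    if small:
        raise ContractError(f"classes {small} have fewer than 2 samples: {counts}")

    alt_mask = labels.mask(matrix.sample_ids, labels.alternative)
    alt = matrix.values[:, alt_mask]
    ref = matrix.values[:, ~alt_mask]
    log2fc = alt.mean(axis=1) - ref.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(alt, ref, axis=1, equal_var=equal_var)
    p = np.asarray(p, dtype=float)

    degenerate = (alt.var(axis=1) == 0) & (ref.var(axis=1) == 0)
    if degenerate.any() or np.isnan(p).any():
        n_flat = int((degenerate | np.isnan(p)).sum())
        logger.info("%d gene(s) with undefined t statistic set to p=1", n_flat)
    p = np.where(np.isnan(p) | degenerate, 1.0, p)

    fdr = multipletests(p, method="fdr_bh")[1]
    return [
        DegRecord(
            gene=g,
            log2fc=float(lfc),
            p_value=float(pv),
            fdr=float(q),
            direction="up" if lfc > 0 else "down",
        )
        for g, lfc, pv, q in zip(matrix.gene_ids, log2fc, p, fdr)
    ]


def filter_degs(
    records: Iterable[DegRecord],
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
) -> GeneSet:
    """Genes passing both filters in either direction.

    Retains genes with linear fold change ``2**|log2fc|`` strictly above
    ``fc_threshold`` AND FDR strictly below ``fdr_threshold``; up- and
    down-regulated genes both count.
    """
    if fc_threshold <= 0 or fdr_threshold <= 0:
        raise ContractError("thresholds must be positive")
    keep = {
        r.gene
        for r in records
        if 2.0 ** abs(r.log2fc) > fc_threshold and r.fdr < fdr_threshold
    }
    return GeneSet("degs", frozenset(keep))


def deg_frame(records: Sequence[DegRecord]) -> pd.DataFrame:
    """DEG records as a DataFrame indexed by gene."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "log2fc": [r.log2fc for r in records],
            "p_value": [r.p_value for r in records],
            "fdr": [r.fdr for r in records],
            "direction": [r.direction for r in records],
        }
    ).set_index("gene")


def write_deg_table(records: Sequence[DegRecord], path: str | Path) -> None:
    deg_frame(records).to_csv(Path(path), sep="\t")
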