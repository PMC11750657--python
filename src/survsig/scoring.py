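"""Weighted z-score survival scoring and risk-group classification.

The survival score of sample *s* under a signature of *n* genes is

    score(s) = sum_{i=1..n} W_i * (e_is - mu_i) / S_i

where e_is is the log2 expression of gene i in sample s, and mu_i and S_i are
the mean and standard deviation (n-1 denominator) of gene i over ALL samples
of the dataset being scored, pooling outcome classes.  With sign-convention
weights, lower scores indicate worse prognosis; samples are classified into
high-/low-score groups around the mean (or median) score of the dataset.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ContractError, ExpressionMatrix
from .signature import WeightedSignature

logger = logging.getLogger("survsig")

HIGH = "high_score"
LOW = "low_score"


@dataclass
class StandardizationStats:
    """Per-gene mean and standard deviation over all samples of one dataset."""

    mean: pd.Series
    sd: pd.Series
    dropped_missing: list[str] = field(default_factory=list)
    dropped_zero_var: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return self.mean.index.tolist()


@dataclass
class ScoreTable:
    """Per-sample survival scores plus the provenance needed to reuse them."""

    scores: pd.Series
    signature: WeightedSignature
    stats: StandardizationStats
    missing_genes: list[str] = field(default_factory=list)


@dataclass
class RiskGrouping:
    groups: pd.Series  # sample -> high_score / low_score
    threshold: float
    rule: str


def standardize(matrix: ExpressionMatrix, genes: Sequence[str]) -> StandardizationStats:
    """Compute mu_i and S_i for ``genes`` over all samples, pooling classes.

    Genes absent from the matrix or with zero variance are dropped with a
    logged warning; if nothing remains, that is a contract error.  Requires
    at least two samples (the n-1 denominator needs them).
    """
    if matrix.n_samples < 2:
        raise ContractError("standardization needs at least 2 samples")
    present, missing = matrix.present_genes(genes)
    if missing:
        logger.warning("genes missing from matrix dropped from signature: %s", missing)
    if not present:
        raise ContractError("no signature gene is present in the matrix")

    sub = matrix.data.loc[present]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    zero_var = sd.index[sd == 0].tolist()
    if zero_var:
        logger.warning("zero-variance genes dropped from signature: %s", zero_var)
        mean = mean.drop(zero_var)
        sd = sd.drop(zero_var)
    if mean.empty:
        raise ContractError("all signature genes were dropped (missing or constant)")
    return StandardizationStats(mean, sd, dropped_missing=missing, dropped_zero_var=zero_var)


def survival_score(
    matrix: ExpressionMatrix,
    signature: WeightedSignature,
    stats: StandardizationStats | None = None,
) -> ScoreTable:
    """Score every sample of ``matrix`` with ``signature``.

    By default mu_i and S_i are recomputed from ``matrix`` itself (each
    cohort standardized against itself).  Passing precomputed ``stats``
    (e.g. frozen from a discovery cohort for deployment-style scoring) is
    allowed as long as the stats' genes are a subset of the signature's.
    """
    if stats is None:
        stats = standardize(matrix, signature.genes)
    extra = set(stats.genes) - set(signature.genes)
    if extra:
        raise ContractError(f"stats contain genes outside the signature: {sorted(extra)}")

    usable, missing = matrix.present_genes(stats.genes)
    if missing:
        logger.warning("stats genes absent from scored matrix: %s", missing)
    if not usable:
        raise ContractError("no usable signature gene in the scored matrix")

    weights = signature.as_series().loc[usable]
    z = matrix.data.loc[usable].sub(stats.mean.loc[usable], axis=0).div(
        stats.sd.loc[usable], axis=0
    )
    scores = z.mul(weights, axis=0).sum(axis=0)
    scores.name = "score"
    all_missing = sorted(set(stats.dropped_missing) | set(missing))
    return ScoreTable(scores, signature, stats, missing_genes=all_missing)


def classify(scores: ScoreTable | pd.Series, rule: str = "mean") -> RiskGrouping:
    """Split samples at the mean (default) or median score.

    Samples strictly above the threshold form the high-score (lower-risk)
    group; ties at the threshold go to the low-score group, so "above the
    mean" is strict.
    """
    series = scores.scores if isinstance(scores, ScoreTable) else scores
    if len(series) < 2:
        raise ContractError("classification needs at least 2 samples")
    if rule == "mean":
        threshold = float(series.mean())
    elif rule == "median":
        threshold = float(series.median())
    else:
        raise ContractError(f"unknown rule {rule!r}; use 'mean' or 'median'")
    groups = pd.Series(
        np.where(series > threshold, HIGH, LOW), index=series.index, name="group"
    )
    return RiskGrouping(groups, threshold, rule)


def write_score_table(
    table: ScoreTable,
    grouping: RiskGrouping,
    path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write sample/score/group TSV plus an optional JSON metadata sidecar."""
    frame = pd.DataFrame({"score": table.scores, "group": grouping.groups})
    frame.index.name = "sample_id"
    frame.to_csv(Path(path), sep="\t")
    if metadata_path is not None:
        meta = {
            "signature_genes": list(table.signature.genes),
            "signature_weights": list(table.signature.weights),
            "provenance": table.signature.provenance,
            "rule": grouping.rule,
            "threshold": grouping.threshold,
            "missing_genes": table.missing_genes,
            "dropped_zero_var": table.stats.dropped_zero_var,
            "mu": {g: float(v) for g, v in table.stats.mean.items()},
            "sd": {g: float(v) for g, v in table.stats.sd.items()},
        }
        Path(metadata_path).write_text(json.dumps(meta, indent=2) + "\n")
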