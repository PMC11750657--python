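"""Weighted running-sum (GSEA-style) enrichment with phenotype permutations.

Genes are ranked by a class-contrast metric (signal-to-noise by default,
computed as reference-class minus alternative-class, i.e. survivor minus
non-survivor).  Walking down the ranked list, the running sum increments by
|metric|^exponent (normalized over the set's members) at each set member and
decrements by 1/(N - N_hit) elsewhere; the enrichment score (ES) is the
signed extremum of that walk.  With exponent 0 this reduces to the classic
Kolmogorov-Smirnov statistic between member and non-member rank positions.

Significance comes from phenotype permutation: labels are reshuffled, genes
re-ranked, and ES recomputed; NES divides the observed ES by the mean
magnitude of same-sign permuted ES, and the one-sided p uses the add-one
rule among same-sign permutations.  FDR across gene sets is Benjamini-
Hochberg on those p-values (a deliberate simplification of the original
NES-based FDR estimator).
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import ContractError, ExpressionMatrix, GeneSet, PhenotypeLabels

logger = logging.getLogger("survsig")

METRICS = ("snr", "t_stat", "log2fc")


@dataclass
class RankedList:
    """All matrix genes ordered by descending metric (alphabetical tie-break)."""

    genes: list[str]
    metric: np.ndarray


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float = float("nan")
    p_value: float = float("nan")
    fdr: float = float("nan")
    running_curve: np.ndarray = field(default=None)
    leading_edge: GeneSet = field(default=None)


def _metric_values(
    values: np.ndarray, ref_mask: np.ndarray, metric: str
) -> np.ndarray:
    a, b = values[:, ref_mask], values[:, ~ref_mask]
    if metric == "log2fc":
        return a.mean(axis=1) - b.mean(axis=1)
    if metric == "t_stat":
        with np.errstate(divide="ignore", invalid="ignore"):
            t, _ = sps.ttest_ind(a, b, axis=1, equal_var=False)
        return np.nan_to_num(np.asarray(t, dtype=float), nan=0.0)
    # snr
    sd_sum = a.std(axis=1, ddof=1) + b.std(axis=1, ddof=1)
    diff = a.mean(axis=1) - b.mean(axis=1)
    flat = sd_sum == 0
    if flat.any():
        logger.warning("%d gene(s) with zero pooled sd get metric 0", int(flat.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(flat, 0.0, diff / np.where(flat, 1.0, sd_sum))
    return snr


def _order(genes: Sequence[str], metric: np.ndarray) -> np.ndarray:
    # descending metric, alphabetical within ties
    return np.lexsort((np.asarray(genes, dtype=object), -metric))


def rank_genes(
    matrix: ExpressionMatrix, labels: PhenotypeLabels, metric: str = "snr"
) -> RankedList:
    """Rank all genes by the class-contrast ``metric`` (reference minus alternative)."""
    if metric not in METRICS:
        raise ContractError(f"unknown metric {metric!r}; use one of {METRICS}")
    labels.check_matches(matrix)
    counts = labels.counts()
    minimum = 3 if metric == "snr" else 2
    if min(counts.values()) < minimum:
        raise ContractError(
            f"metric {metric!r} needs >= {minimum} samples per class; got {counts}"
        )
    ref_mask = labels.mask(matrix.sample_ids, labels.reference)
    values = _metric_values(matrix.values, ref_mask, metric)
    idx = _order(matrix.gene_ids, values)
    return RankedList(
        genes=[matrix.gene_ids[i] for i in idx], metric=values[idx]
    )


def _running_sum(
    metric_sorted: np.ndarray, hit: np.ndarray, exponent: float
) -> np.ndarray:
    n = len(metric_sorted)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ContractError("gene set has no overlap with the ranked list")
    if n_hit == n:
        raise ContractError("gene set covers the entire ranked list")
    w = np.abs(metric_sorted) ** exponent
    hit_w = np.where(hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all member metrics are exactly zero: fall back to equal steps
        hit_w = hit.astype(float)
        denom = float(n_hit)
    steps = hit_w / denom - (~hit).astype(float) / (n - n_hit)
    return np.cumsum(steps)


def _signed_extremum(curve: np.ndarray) -> tuple[float, int]:
    hi, lo = float(curve.max()), float(curve.min())
    if hi >= -lo:
        return hi, int(curve.argmax())
    return lo, int(curve.argmin())


def running_enrichment_score(
    ranked: RankedList, gene_set: GeneSet, exponent: float = 1.0
) -> EnrichmentResult:
    """ES and running curve of ``gene_set`` against a ranked list.

    The curve starts from 0 and returns to 0 at the end of the list; the ES
    is its signed extremum.  The leading edge contains the set members at or
    before the extremum (after it, for negative ES).
    """
    hit = np.array([g in gene_set.genes for g in ranked.genes])
    curve = _running_sum(ranked.metric, hit, exponent)
    es, pos = _signed_extremum(curve)
    if es >= 0:
        leading = [g for g, h in zip(ranked.genes[: pos + 1], hit[: pos + 1]) if h]
    else:
        leading = [g for g, h in zip(ranked.genes[pos:], hit[pos:]) if h]
    return EnrichmentResult(
        set_name=gene_set.name,
        es=es,
        running_curve=curve,
        leading_edge=GeneSet(f"{gene_set.name}_leading_edge", frozenset(leading)),
    )


def permutation_significance(
    matrix: ExpressionMatrix,
    labels: PhenotypeLabels,
    gene_sets: Sequence[GeneSet],
    n_perm: int = 1000,
    seed: int = 0,
    exponent: float = 1.0,
    metric: str = "snr",
) -> list[EnrichmentResult]:
    """Phenotype-permutation ES significance for each gene set.

    For each of ``n_perm`` permutations the outcome labels are reshuffled
    across samples, genes re-ranked, and ES recomputed per set.  Per set:
    NES = ES / mean(|permuted ES| of the same sign); p is the add-one
    fraction of same-sign permuted ES at least as extreme; FDR across sets
    is BH on p.  Deterministic for a fixed seed.
    """
    if n_perm < 10:
        raise ContractError("n_perm must be >= 10")
    labels.require_both_classes("permutation significance")
    observed_rank = rank_genes(matrix, labels, metric=metric)
    observed = [
        running_enrichment_score(observed_rank, gs, exponent=exponent)
        for gs in gene_sets
    ]

    gene_ids = matrix.gene_ids
    values = matrix.values
    membership = np.array(
        [[g in gs.genes for g in gene_ids] for gs in gene_sets]
    )  # sets x genes
    ref_mask = labels.mask(matrix.sample_ids, labels.reference)
    n_ref = int(ref_mask.sum())

    rng = np.random.default_rng(seed)
    perm_es = np.empty((n_perm, len(gene_sets)))
    for p in range(n_perm):
        perm = rng.permutation(len(ref_mask))
        mask = np.zeros(len(ref_mask), dtype=bool)
        mask[perm[:n_ref]] = True
        met = _metric_values(values, mask, metric)
        idx = _order(gene_ids, met)
        met_sorted = met[idx]
        for s in range(len(gene_sets)):
            curve = _running_sum(met_sorted, membership[s][idx], exponent)
            perm_es[p, s], _ = _signed_extremum(curve)

    p_values = np.empty(len(gene_sets))
    for s, res in enumerate(observed):
        es = res.es
        same_sign = perm_es[:, s] >= 0 if es >= 0 else perm_es[:, s] < 0
        extreme = np.abs(perm_es[same_sign, s]) >= abs(es)
        p_values[s] = (1 + extreme.sum()) / (1 + same_sign.sum())
        mean_mag = np.abs(perm_es[same_sign, s]).mean() if same_sign.any() else np.nan
        res.nes = float(es / mean_mag) if mean_mag and np.isfinite(mean_mag) else float("nan")
        res.p_value = float(p_values[s])
    fdr = multipletests(p_values, method="fdr_bh")[1]
    for res, q in zip(observed, fdr):
        res.fdr = float(q)
    return observed


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Result table: set, ES, NES, p, FDR, leading-edge size."""
    return pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "leading_edge_size": [
                len(r.leading_edge) if r.leading_edge is not None else 0
                for r in results
            ],
        }
    ).set_index("set")
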