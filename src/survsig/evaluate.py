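"""Prognostic-power machinery: ROC/AUC, cross-cohort composites, and nulls.

The AUC here is the rank statistic: the probability that a randomly chosen
positive sample outscores a randomly chosen negative one, with ties counted
half — the normalized Mann-Whitney U.  The ROC curve is the exact step curve
over distinct score thresholds, whose trapezoidal area equals that AUC.

Whether a signature beats chance is judged against an empirical null: random
size-matched gene sets drawn from a universe (whole genome, or a restricted
list such as survival-associated genes), each re-weighted from the discovery
contrast exactly like the observed signature, scored on every cohort, and
summarized by the sum of per-cohort AUCs.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import ContractError, ExpressionMatrix, GeneSet, PhenotypeLabels
from .dge import DegRecord, differential_expression
from .scoring import ScoreTable

logger = logging.getLogger("survsig")

Cohort = tuple[ExpressionMatrix, PhenotypeLabels]


@dataclass
class RocResult:
    """Stepwise ROC curve: distinct thresholds (descending) with an implicit
    (sens=0, spec=1) starting point; ``auc`` is the trapezoidal area."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


@dataclass
class NullDistribution:
    """AUC-sum draws for random size-matched signatures vs an observed value."""

    draws: np.ndarray
    observed: float
    universe: str
    k: int
    n_draws: int
    seed: int
    empirical_p: float
    cohort_draws: np.ndarray = field(default=None)  # (n_draws, n_cohorts)
    cohort_observed: np.ndarray = field(default=None)

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.draws, q))


def _score_series(scores: ScoreTable | pd.Series) -> pd.Series:
    return scores.scores if isinstance(scores, ScoreTable) else scores


def _split_scores(
    scores: ScoreTable | pd.Series, labels: PhenotypeLabels, positive: str | None
) -> tuple[np.ndarray, np.ndarray]:
    series = _score_series(scores)
    positive = labels.reference if positive is None else positive
    if positive not in labels.classes:
        raise ContractError(f"positive class {positive!r} not in {labels.classes}")
    values = series.to_numpy(dtype=float)
    pos_mask = labels.mask(series.index, positive)
    pos, neg = values[pos_mask], values[~pos_mask]
    if len(pos) == 0 or len(neg) == 0:
        raise ContractError("both outcome classes must be present for ROC/AUC")
    return pos, neg


def auc(
    scores: ScoreTable | pd.Series,
    labels: PhenotypeLabels,
    positive: str | None = None,
) -> float:
    """Rank-based AUC with ties counted half.

    ``positive`` defaults to the labels' reference class (survivor), matching
    the orientation in which higher scores mean better prognosis.
    """
    pos, neg = _split_scores(scores, labels, positive)
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def roc_curve(
    scores: ScoreTable | pd.Series,
    labels: PhenotypeLabels,
    positive: str | None = None,
) -> RocResult:
    """Exact step ROC over all distinct score thresholds.

    At threshold t a sample is called positive when its score is >= t;
    thresholds run from high to low, so sensitivity is non-decreasing and
    specificity non-increasing along the arrays.
    """
    pos, neg = _split_scores(scores, labels, positive)
    scores_all = np.concatenate([pos, neg])
    is_pos = np.concatenate([np.ones(len(pos), bool), np.zeros(len(neg), bool)])
    order = np.argsort(-scores_all, kind="mergesort")
    sorted_scores = scores_all[order]
    sorted_pos = is_pos[order]

    # last index of each tie block = cumulative counts at that threshold
    distinct = np.where(np.diff(sorted_scores))[0]
    last = np.r_[distinct, len(sorted_scores) - 1]
    tp = np.cumsum(sorted_pos)[last]
    fp = np.cumsum(~sorted_pos)[last]
    sens = tp / len(pos)
    fpr = fp / len(neg)
    area = float(np.trapezoid(np.r_[0.0, sens], np.r_[0.0, fpr]))
    return RocResult(
        thresholds=sorted_scores[last],
        sensitivity=sens,
        specificity=1.0 - fpr,
        auc=area,
    )


def auc_sum(per_cohort_auc: Sequence[float]) -> float:
    """Sum of per-cohort AUCs — the cross-cohort composite statistic."""
    values = [float(v) for v in per_cohort_auc]
    if len(values) < 1:
        raise ContractError("auc_sum needs at least one cohort AUC")
    if any(not 0.0 <= v <= 1.0 for v in values):
        raise ContractError(f"AUC values must lie in [0, 1]: {values}")
    return float(sum(values))


def _sign_weights(log2fc: np.ndarray) -> np.ndarray:
    # down in non-survivors (log2fc <= 0) -> +1; up -> -1
    return np.where(log2fc > 0, -1.0, 1.0)


def random_signature_null(
    cohorts: Sequence[Cohort],
    universe: GeneSet,
    k: int,
    n_draws: int,
    seed: int,
    weight_mode: str = "sign",
    observed_genes: Iterable[str] | None = None,
    deg_records: Sequence[DegRecord] | None = None,
    positive: str | None = None,
) -> NullDistribution:
    """Empirical null of the AUC-sum over random size-``k`` signatures.

    Each draw samples k genes uniformly without replacement from ``universe``
    (restricted to genes measured with non-zero variance in every cohort),
    derives weights from the discovery-cohort contrast exactly as the
    pipeline would (``weight_mode``: sign, log2fc or unit), scores every
    cohort against its own standardization stats, and records the sum of
    per-cohort AUCs.  The observed signature's genes are re-weighted the
    same way, and its one-sided empirical p uses the add-one rule

        p = (1 + #{draws >= observed}) / (n_draws + 1)

    so p is never exactly zero.  Deterministic for a fixed seed.
    """
    if n_draws < 1:
        raise ContractError("n_draws must be >= 1")
    if not cohorts:
        raise ContractError("at least one cohort is required")
    if weight_mode not in ("sign", "log2fc", "unit"):
        raise ContractError(f"unknown weight mode {weight_mode!r}")

    # usable universe: genes measured with positive variance everywhere
    usable = set(universe.genes)
    z_matrices: list[pd.DataFrame] = []
    pos_masks: list[np.ndarray] = []
    for matrix, labels in cohorts:
        labels.check_matches(matrix)
        mean = matrix.data.mean(axis=1)
        sd = matrix.data.std(axis=1, ddof=1)
        ok = sd.index[sd > 0]
        usable &= set(ok)
        z = matrix.data.loc[ok].sub(mean.loc[ok], axis=0).div(sd.loc[ok], axis=0)
        z_matrices.append(z)
        pos_label = labels.reference if positive is None else positive
        pos_masks.append(labels.mask(matrix.sample_ids, pos_label))
    usable_list = sorted(usable)
    if k > len(usable_list):
        raise ContractError(
            f"k={k} exceeds the usable universe of {len(usable_list)} genes"
        )

    if weight_mode != "unit":
        if deg_records is None:
            deg_records = differential_expression(*cohorts[0])
        lfc = {r.gene: r.log2fc for r in deg_records}
        missing = [g for g in usable_list if g not in lfc]
        if missing:
            raise ContractError(
                f"{len(missing)} universe genes lack a discovery DEG record"
            )

    def weights_for(genes: list[str]) -> np.ndarray:
        if weight_mode == "unit":
            return np.ones(len(genes))
        fc = np.array([lfc[g] for g in genes])
        return _sign_weights(fc) if weight_mode == "sign" else -fc

    def composite(genes: list[str]) -> tuple[float, np.ndarray]:
        w = weights_for(genes)
        per_cohort = np.empty(len(cohorts))
        for c, (z, pos_mask) in enumerate(zip(z_matrices, pos_masks)):
            sample_scores = w @ z.loc[genes].to_numpy()
            ranks = rankdata(sample_scores)
            n_pos = int(pos_mask.sum())
            n_neg = len(sample_scores) - n_pos
            u = ranks[pos_mask].sum() - n_pos * (n_pos + 1) / 2.0
            per_cohort[c] = u / (n_pos * n_neg)
        return float(per_cohort.sum()), per_cohort

    rng = np.random.default_rng(seed)
    usable_arr = np.array(usable_list)
    draws = np.empty(n_draws)
    cohort_draws = np.empty((n_draws, len(cohorts)))
    for d in range(n_draws):
        genes = list(usable_arr[rng.choice(len(usable_arr), size=k, replace=False)])
        draws[d], cohort_draws[d] = composite(genes)

    if observed_genes is not None:
        obs_genes = sorted({str(g).strip().upper() for g in observed_genes})
        dropped = [g for g in obs_genes if g not in usable]
        if dropped:
            logger.warning("observed genes unusable in some cohort dropped: %s", dropped)
            obs_genes = [g for g in obs_genes if g in usable]
        if not obs_genes:
            raise ContractError("no observed signature gene is usable in every cohort")
        observed, cohort_observed = composite(obs_genes)
        empirical_p = float((1 + (draws >= observed).sum()) / (n_draws + 1))
    else:
        observed, cohort_observed, empirical_p = float("nan"), None, float("nan")

    return NullDistribution(
        draws=draws,
        observed=observed,
        universe=universe.name,
        k=k,
        n_draws=n_draws,
        seed=seed,
        empirical_p=empirical_p,
        cohort_draws=cohort_draws,
        cohort_observed=cohort_observed,
    )


def gene_correlation(matrix: ExpressionMatrix, genes: Sequence[str]) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix over the signature genes.

    Requires >= 3 samples and all genes present.  A zero-variance gene has
    no defined correlation: its row and column are NaN (flagged, not
    silently zero) with a logged warning.
    """
    if matrix.n_samples < 3:
        raise ContractError("correlation needs at least 3 samples")
    present, missing = matrix.present_genes(genes)
    if missing:
        raise ContractError(f"genes absent from matrix: {missing}")
    sub = matrix.data.loc[present]
    sd = sub.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(sub.to_numpy())
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    flat = sd.to_numpy() == 0
    if flat.any():
        logger.warning("zero-variance genes flagged NaN in correlation matrix: %s",
                       sd.index[flat].tolist())
        corr[flat, :] = np.nan
        corr[:, flat] = np.nan
    return pd.DataFrame(corr, index=present, columns=present)


@dataclass
class PcaResult:
    """First two principal components of the signature-gene submatrix."""

    coordinates: pd.DataFrame  # samples x [PC1, PC2]
    variance_ratio: np.ndarray  # fraction of variance per component
    loadings: pd.DataFrame  # genes x [PC1, PC2]

    @property
    def combined_variance(self) -> float:
        return float(self.variance_ratio[:2].sum())


def pca_projection(matrix: ExpressionMatrix, genes: Sequence[str]) -> PcaResult:
    """Centered PCA of samples in signature-gene space (first two components).

    Component signs are canonicalized so the largest-magnitude loading of
    each component is positive.
    """
    if matrix.n_samples < 3:
        raise ContractError("PCA needs at least 3 samples")
    present, missing = matrix.present_genes(genes)
    if missing:
        logger.warning("genes absent from matrix dropped from PCA: %s", missing)
    if len(present) < 2:
        raise ContractError("PCA needs at least 2 usable genes")

    x = matrix.data.loc[present].to_numpy().T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float((s**2).sum())
    var_ratio = (s**2) / total if total > 0 else np.zeros_like(s)

    n_comp = min(2, len(s))
    coords = u[:, :n_comp] * s[:n_comp]
    load = vt[:n_comp].T
    for j in range(n_comp):
        lead = np.argmax(np.abs(load[:, j]))
        if load[lead, j] < 0:
            load[:, j] = -load[:, j]
            coords[:, j] = -coords[:, j]

    cols = [f"PC{j + 1}" for j in range(n_comp)]
    return PcaResult(
        coordinates=pd.DataFrame(coords, index=matrix.sample_ids, columns=cols),
        variance_ratio=var_ratio[:n_comp],
        loadings=pd.DataFrame(load, index=present, columns=cols),
    )
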