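"""Synthetic transcriptomic cohorts with planted outcome-associated signal.

Two generators cover the two kinds of experiment the pipeline consumes:

* :func:`simulate_cohort` — an outcome-labelled patient cohort in which a
  chosen subset of genes carries an additive mean shift (on the log2 scale)
  in the non-survivor arm, optionally sharing a single-factor correlation
  block.
* :func:`simulate_perturbation` — a control-vs-perturbed experiment with
  planted signed log2 fold changes, emulating an overexpression study.

Noise is i.i.d. normal on the log2 scale.  Per-gene baselines are drawn once
per simulation so matrices look like log2 microarray intensities; downstream
scoring is invariant to per-gene affine shifts, so baselines carry no signal.
All output is deterministic for a fixed seed.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .core import (
    ConfigError,
    ExpressionMatrix,
    GeneSet,
    NON_SURVIVOR,
    PhenotypeLabels,
    SURVIVOR,
)


@dataclass
class CohortSimConfig:
    """World for an outcome-labelled cohort.

    Defaults mirror the discovery-cohort setting the pipeline is validated
    against: 1,000 genes, 187 survivors vs 78 non-survivors, a per-gene
    effect of 1.0 standard deviation on planted genes, unit gene noise, and
    no planted correlation (a shared-factor block is opt-in).
    """

    n_genes: int = 1000
    n_survivors: int = 187
    n_nonsurvivors: int = 78
    planted_genes: Sequence[str] = ()
    effect_size: float = 1.0
    gene_sd: float = 1.0
    block_correlation: float = 0.0
    direction: Mapping[str, float] | None = None
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if self.n_survivors < 1 or self.n_nonsurvivors < 1:
            raise ConfigError("both cohort arms must be positive")
        if self.gene_sd <= 0:
            raise ConfigError("gene_sd must be positive")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ConfigError("block_correlation must lie in [0, 1)")
        planted = [str(g).strip().upper() for g in self.planted_genes]
        if len(set(planted)) != len(planted):
            raise ConfigError("planted_genes contains duplicates")
        if len(planted) > self.n_genes:
            raise ConfigError(
                f"{len(planted)} planted genes exceed the {self.n_genes}-gene universe"
            )
        if self.direction is not None:
            missing = set(self.direction) - set(planted)
            if missing:
                raise ConfigError(f"direction given for non-planted genes: {sorted(missing)}")
        if not np.isfinite(self.effect_size):
            raise ConfigError("effect_size must be finite")


@dataclass
class PerturbSimConfig:
    """World for a control-vs-perturbed experiment with planted log2 fold changes."""

    n_genes: int = 1000
    n_control: int = 5
    n_perturbed: int = 5
    planted_degs: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if self.n_control < 2 or self.n_perturbed < 2:
            raise ConfigError("n_control and n_perturbed must both be >= 2")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        planted = [str(g).strip().upper() for g in self.planted_degs]
        if len(set(planted)) != len(planted):
            raise ConfigError("planted_degs contains duplicate genes")
        if len(planted) > self.n_genes:
            raise ConfigError("planted_degs exceed the gene universe")
        if not all(np.isfinite(list(self.planted_degs.values()))):
            raise ConfigError("planted log2 fold changes must be finite")


def _gene_universe(planted: list[str], n_genes: int) -> list[str]:
    taken = set(planted)
    background = []
    i = 1
    while len(background) < n_genes - len(planted):
        name = f"G{i:05d}"
        if name not in taken:
            background.append(name)
        i += 1
    return planted + background


def _base_matrix(
    rng: np.random.Generator,
    genes: list[str],
    n_samples: int,
    sd: float,
    baseline_mean: float,
    baseline_sd: float,
) -> np.ndarray:
    baseline = rng.normal(baseline_mean, baseline_sd, size=len(genes))
    noise = rng.standard_normal((len(genes), n_samples))
    return baseline[:, None] + sd * noise


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[ExpressionMatrix, PhenotypeLabels, GeneSet]:
    """Draw one cohort; returns (matrix, labels, planted truth set).

    Planted genes receive an additive shift of ``effect_size`` (sign per the
    optional ``direction`` map, default +1 = up in non-survivors) in the
    non-survivor arm, and share pairwise correlation ``block_correlation``
    through one latent factor per sample: each planted gene is
    ``sqrt(rho) * L_s + sqrt(1 - rho) * eps`` before scaling by ``gene_sd``,
    so the pairwise correlation between planted genes is exactly ``rho``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    planted = [str(g).strip().upper() for g in config.planted_genes]
    genes = _gene_universe(planted, config.n_genes)
    n_samples = config.n_survivors + config.n_nonsurvivors

    values = _base_matrix(
        rng, genes, n_samples, config.gene_sd, config.baseline_mean, config.baseline_sd
    )

    if planted and config.block_correlation > 0:
        rho = config.block_correlation
        k = len(planted)
        latent = rng.standard_normal(n_samples)
        fresh = rng.standard_normal((k, n_samples))
        base_offsets = rng.normal(config.baseline_mean, config.baseline_sd, size=k)
        values[:k] = base_offsets[:, None] + config.gene_sd * (
            np.sqrt(rho) * latent[None, :] + np.sqrt(1.0 - rho) * fresh
        )

    sample_ids = [f"P{i:04d}" for i in range(1, n_samples + 1)]
    outcome = [SURVIVOR] * config.n_survivors + [NON_SURVIVOR] * config.n_nonsurvivors
    nonsurv = np.array([o == NON_SURVIVOR for o in outcome])

    if planted:
        directions = np.array(
            [float((config.direction or {}).get(g, 1.0)) for g in planted]
        )
        values[: len(planted), nonsurv] += (directions * config.effect_size)[:, None]

    matrix = ExpressionMatrix.from_arrays(genes, sample_ids, values)
    labels = PhenotypeLabels(dict(zip(sample_ids, outcome)))
    truth = GeneSet("planted", frozenset(planted))
    return matrix, labels, truth


def simulate_perturbation(
    config: PerturbSimConfig,
) -> tuple[ExpressionMatrix, PhenotypeLabels, GeneSet]:
    """Draw one control-vs-perturbed experiment; classes are (control, perturbed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    planted = {str(g).strip().upper(): float(v) for g, v in config.planted_degs.items()}
    genes = _gene_universe(list(planted), config.n_genes)
    n_samples = config.n_control + config.n_perturbed

    values = _base_matrix(
        rng, genes, n_samples, config.noise_sd, config.baseline_mean, config.baseline_sd
    )
    perturbed_cols = np.arange(n_samples) >= config.n_control
    for row, gene in enumerate(planted):
        values[row, perturbed_cols] += planted[gene]

    sample_ids = [f"E{i:03d}" for i in range(1, n_samples + 1)]
    outcome = ["control"] * config.n_control + ["perturbed"] * config.n_perturbed
    matrix = ExpressionMatrix.from_arrays(genes, sample_ids, values)
    labels = PhenotypeLabels(
        dict(zip(sample_ids, outcome)), classes=("control", "perturbed")
    )
    truth = GeneSet("planted_degs", frozenset(planted))
    return matrix, labels, truth
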