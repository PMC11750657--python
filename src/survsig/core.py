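"""Core containers shared across the pipeline.

The pipeline works on three kinds of objects: a log2-scale expression matrix
(genes in rows, samples in columns), per-sample binary outcome labels, and
named gene sets.  All gene symbols are uppercased at ingest so that set
algebra between files from different sources behaves predictably.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("survsig")

SURVIVOR = "survivor"
NON_SURVIVOR = "non_survivor"

#: Default outcome coding: (reference class, alternative class).  Group
#: contrasts throughout the package are alternative minus reference, so with
#: this default a positive log2 fold change means "higher in non-survivors".
DEFAULT_CLASSES = (SURVIVOR, NON_SURVIVOR)


class SurvsigError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(SurvsigError, ValueError):
    """A file could not be parsed into the expected structure."""


class ContractError(SurvsigError, ValueError):
    """An operation was called with inputs that violate its contract."""


class ConfigError(SurvsigError, ValueError):
    """A simulation or run configuration is invalid."""


def _normalize_symbol(symbol: object) -> str:
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A named, unordered collection of gene symbols (uppercased)."""

    name: str
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "genes", frozenset(_normalize_symbol(g) for g in self.genes)
        )

    @property
    def sorted_genes(self) -> list[str]:
        """Members in deterministic alphabetical order."""
        return sorted(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: object) -> bool:
        return _normalize_symbol(symbol) in self.genes

    def __iter__(self):
        return iter(self.sorted_genes)

    def intersection(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        return GeneSet(
            name if name is not None else f"{self.name}&{other.name}",
            self.genes & other.genes,
        )


class ExpressionMatrix:
    """Log2 expression values over unique genes x unique samples.

    Wraps a :class:`pandas.DataFrame` with genes in rows (index) and samples
    in columns.  Validation enforces uppercased unique gene symbols, unique
    sample identifiers, finite values, and at least one gene and two samples.
    """

    def __init__(self, data: pd.DataFrame):
        data = data.copy()
        data.index = pd.Index([_normalize_symbol(g) for g in data.index], name="gene")
        data.columns = pd.Index([str(c) for c in data.columns], name="sample")
        try:
            data = data.astype(float)
        except (TypeError, ValueError) as exc:
            raise ContractError(f"expression values must be numeric: {exc}") from exc

        if data.shape[0] < 1:
            raise ContractError("expression matrix needs at least 1 gene")
        if data.shape[1] < 2:
            raise ContractError("expression matrix needs at least 2 samples")
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ContractError(f"duplicate gene ids after uppercasing: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ContractError(f"duplicate sample ids: {dups}")
        if not np.isfinite(data.to_numpy()).all():
            raise ContractError("expression matrix contains non-finite values")
        self.data = data

    @classmethod
    def from_arrays(
        cls,
        gene_ids: Iterable[str],
        sample_ids: Iterable[str],
        values: np.ndarray,
    ) -> "ExpressionMatrix":
        return cls(pd.DataFrame(values, index=list(gene_ids), columns=list(sample_ids)))

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def present_genes(self, genes: Iterable[str]) -> tuple[list[str], list[str]]:
        """Split ``genes`` into (present, missing) against this matrix."""
        index = set(self.data.index)
        present, missing = [], []
        for g in (_normalize_symbol(g) for g in genes):
            (present if g in index else missing).append(g)
        return present, missing

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"


class PhenotypeLabels:
    """Per-sample two-class outcome labels.

    ``classes`` is an ordered pair ``(reference, alternative)``; group
    differences downstream are always alternative minus reference.  The
    default coding is (survivor, non_survivor); perturbation experiments use
    (control, perturbed).
    """

    def __init__(
        self,
        outcome: Mapping[str, str] | pd.Series,
        classes: tuple[str, str] = DEFAULT_CLASSES,
    ):
        series = pd.Series(outcome, dtype=object)
        series.index = pd.Index([str(s) for s in series.index], name="sample")
        if series.index.has_duplicates:
            raise ContractError("duplicate sample ids in phenotype labels")
        if len(classes) != 2 or classes[0] == classes[1]:
            raise ContractError(f"classes must be two distinct labels, got {classes!r}")
        bad = set(series) - set(classes)
        if bad:
            raise ContractError(f"outcome values {sorted(bad)} not in classes {classes}")
        self.outcome = series
        self.classes = (str(classes[0]), str(classes[1]))

    @property
    def reference(self) -> str:
        return self.classes[0]

    @property
    def alternative(self) -> str:
        return self.classes[1]

    @property
    def sample_ids(self) -> list[str]:
        return self.outcome.index.tolist()

    def counts(self) -> dict[str, int]:
        return {c: int((self.outcome == c).sum()) for c in self.classes}

    def require_both_classes(self, context: str = "this operation") -> None:
        counts = self.counts()
        if min(counts.values()) == 0:
            raise ContractError(f"{context} requires both outcome classes; got {counts}")

    def check_matches(self, matrix: ExpressionMatrix) -> None:
        if set(self.sample_ids) != set(matrix.sample_ids):
            raise ContractError("label sample ids do not match the expression matrix")

    def mask(self, sample_ids: Iterable[str], which: str) -> np.ndarray:
        """Boolean mask over ``sample_ids`` for membership in class ``which``."""
        if which not in self.classes:
            raise ContractError(f"unknown class {which!r}; classes are {self.classes}")
        lookup = self.outcome.to_dict()
        try:
            return np.array([lookup[str(s)] == which for s in sample_ids])
        except KeyError as exc:
            raise ContractError(f"sample {exc.args[0]!r} has no phenotype label") from exc

    def __len__(self) -> int:
        return len(self.outcome)


class InteractionTable:
    """Pairwise protein interactions with a combined confidence score in [0, 1]."""

    COLUMNS = ("protein_a", "protein_b", "combined_score")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ContractError(f"interaction table missing columns {missing}")
        frame = frame.loc[:, list(self.COLUMNS)].copy()
        for col in ("protein_a", "protein_b"):
            frame[col] = frame[col].map(_normalize_symbol)
        frame["combined_score"] = frame["combined_score"].astype(float)
        scores = frame["combined_score"].to_numpy()
        if ((scores < 0) | (scores > 1)).any() or not np.isfinite(scores).all():
            raise ContractError("combined_score values must lie in [0, 1]")
        if (frame["protein_a"] == frame["protein_b"]).any():
            raise ContractError("interaction table contains self-pairs")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)
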