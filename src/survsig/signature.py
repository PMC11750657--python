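"""Signature construction: gene-set intersection and per-gene weights.

A signature is built by intersecting a process-associated gene set (e.g.
genes perturbed by, or interacting with, a regulator of interest) with the
set of survival-associated DEGs, then assigning each gene a weight for the
risk score.  How the original weights were defined is not recoverable from
the source analysis, so three conventions are offered:

* ``sign`` (default) — W = +1 for genes DOWN in non-survivors, -1 for genes
  UP in non-survivors.  This is the weakest assumption that makes higher
  scores mean better prognosis.
* ``log2fc`` — W = -log2fc (same orientation, magnitude-weighted).
* ``unit`` — W = 1 for every gene (orientation-blind).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ContractError, GeneSet
from .dge import DegRecord

logger = logging.getLogger("survsig")

WEIGHT_MODES = ("sign", "log2fc", "unit")


@dataclass(frozen=True)
class WeightedSignature:
    """Ordered gene list with finite non-zero per-gene weights."""

    genes: tuple[str, ...]
    weights: tuple[float, ...]
    provenance: str = "custom"

    def __post_init__(self) -> None:
        genes = tuple(str(g).strip().upper() for g in self.genes)
        weights = tuple(float(w) for w in self.weights)
        if len(genes) != len(weights):
            raise ContractError("genes and weights must have equal length")
        if len(genes) < 1:
            raise ContractError("a signature needs at least one gene")
        if len(set(genes)) != len(genes):
            raise ContractError("signature contains duplicate genes")
        if not all(np.isfinite(w) and w != 0 for w in weights):
            raise ContractError("weights must be finite and non-zero")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "weights", weights)

    @property
    def n(self) -> int:
        return len(self.genes)

    def weight_of(self, gene: str) -> float:
        try:
            return self.weights[self.genes.index(gene.upper())]
        except ValueError:
            raise ContractError(f"gene {gene!r} not in signature") from None

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.genes), name="weight")


def intersect_signature(assoc: GeneSet, survival_degs: GeneSet) -> GeneSet:
    """Common genes between a process-associated set and the survival DEGs.

    Symmetric; the result is reported in alphabetical order.  An empty
    intersection is returned (with a logged warning), leaving the decision
    to the caller.
    """
    if len(assoc) == 0 or len(survival_degs) == 0:
        raise ContractError("both gene sets must be non-empty")
    common = assoc.intersection(survival_degs)
    if len(common) == 0:
        logger.warning(
            "empty intersection between %r and %r", assoc.name, survival_degs.name
        )
    return common


def assign_weights(
    genes: GeneSet | Iterable[str],
    deg_records: Sequence[DegRecord] = (),
    mode: str = "sign",
    provenance: str = "custom",
) -> WeightedSignature:
    """Build a :class:`WeightedSignature` over ``genes`` (alphabetical order).

    For modes other than ``unit`` every gene must have a DEG record from the
    survivor/non-survivor contrast (log2fc = non_survivor - survivor).
    """
    if mode not in WEIGHT_MODES:
        raise ContractError(f"unknown weight mode {mode!r}; use one of {WEIGHT_MODES}")
    ordered = sorted({str(g).strip().upper() for g in genes})
    if not ordered:
        raise ContractError("cannot build a signature from an empty gene collection")

    if mode == "unit":
        return WeightedSignature(tuple(ordered), (1.0,) * len(ordered), provenance)

    lookup = {r.gene: r for r in deg_records}
    weights = []
    for gene in ordered:
        record = lookup.get(gene)
        if record is None:
            raise ContractError(f"gene {gene!r} has no DEG record (mode={mode!r})")
        if mode == "sign":
            weights.append(1.0 if record.direction == "down" else -1.0)
        else:  # log2fc
            if record.log2fc == 0:
                raise ContractError(
                    f"gene {gene!r} has log2fc == 0; zero weights are not allowed"
                )
            weights.append(-record.log2fc)
    return WeightedSignature(tuple(ordered), tuple(weights), provenance)


def write_signature(signature: WeightedSignature, path: str | Path) -> None:
    """Serialize as TSV: gene, weight, provenance."""
    pd.DataFrame(
        {
            "gene": list(signature.genes),
            "weight": list(signature.weights),
            "provenance": signature.provenance,
        }
    ).to_csv(Path(path), sep="\t", index=False)


def read_signature(path: str | Path) -> WeightedSignature:
    frame = pd.read_csv(Path(path), sep="\t")
    provenance = str(frame["provenance"].iloc[0]) if "provenance" in frame else "custom"
    return WeightedSignature(
        tuple(frame["gene"].astype(str)), tuple(frame["weight"].astype(float)), provenance
    )


def signature_to_gene_set(signature: WeightedSignature) -> GeneSet:
    """Drop weights, keeping only membership (warns: weights are lost)."""
    logger.warning("converting signature %r to a plain gene set drops its weights",
                   signature.provenance)
    return GeneSet(signature.provenance, frozenset(signature.genes))
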