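"""Readers and writers for the plain-text formats the pipeline touches.

Formats
-------
* Expression: TSV/CSV, genes in rows, samples in columns, header row required.
* Gene sets: GMT (name, description, then tab-separated gene symbols).
* Labels: two-column TSV ``sample_id<TAB>outcome``.
* Interactions: three-column TSV ``protein_a  protein_b  combined_score``.
* Config: flat YAML key/value file, copied verbatim next to run outputs.
"""

from __future__ import annotations

import logging
import shutil
from collections.abc import Sequence
from pathlib import Path

import pandas as pd
import yaml

from .core import (
    ConfigError,
    ContractError,
    DEFAULT_CLASSES,
    ExpressionMatrix,
    GeneSet,
    InteractionTable,
    ParseError,
    PhenotypeLabels,
)

logger = logging.getLogger("survsig")

_SEPARATORS = {"tsv": "\t", "csv": ","}


def _sep(dialect: str) -> str:
    try:
        return _SEPARATORS[dialect]
    except KeyError:
        raise ContractError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'") from None


def read_expression_matrix(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a genes-by-samples expression table.

    The first column holds gene symbols and the header row holds sample ids.
    Duplicate gene rows (after uppercasing) are collapsed by arithmetic mean
    with a logged warning.  Any cell that does not parse as a finite number
    raises :class:`ParseError` naming the offending gene and sample.
    """
    path = Path(path)
    sep = _sep(dialect)
    with path.open() as handle:
        header = handle.readline().rstrip("\n").split(sep)
    samples = header[1:]
    if not samples or any(not s.strip() for s in samples):
        raise ParseError(f"{path}: malformed header: empty or missing sample ids")
    if len(set(samples)) != len(samples):
        raise ParseError(f"{path}: malformed header: duplicate sample ids")
    try:
        raw = pd.read_csv(
            path, sep=sep, index_col=0, dtype=str, keep_default_na=False, header=None,
            skiprows=1, names=["gene", *samples],
        )
    except Exception as exc:
        raise ParseError(f"{path}: could not read table: {exc}") from exc

    probe = raw.apply(pd.to_numeric, errors="coerce")
    if probe.isna().any().any():
        bad = probe.isna()
        gene = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[gene]][0]
        raise ParseError(
            f"{path}: non-numeric value {raw.loc[gene, sample]!r} "
            f"for gene {gene!r}, sample {sample!r}"
        )
    numeric = raw.astype(float)  # float() parsing is round-trip exact

    numeric.index = numeric.index.str.strip().str.upper()
    if numeric.index.has_duplicates:
        dups = numeric.index[numeric.index.duplicated()].unique().tolist()
        logger.warning("%s: collapsing duplicate gene rows by mean: %s", path, dups)
        numeric = numeric.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(numeric)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, dialect: str = "tsv"
) -> None:
    # %.17g keeps the round-trip bit-exact for doubles
    matrix.data.to_csv(Path(path), sep=_sep(dialect), float_format="%.17g")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file, preserving file order.

    Each non-blank line is ``name<TAB>description<TAB>gene1<TAB>gene2...``;
    a line with fewer than three fields (i.e. an empty set) is rejected.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene (got {len(fields)} fields)"
                )
            genes = [f for f in fields[2:] if f.strip()]
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {fields[0]!r} is empty")
            sets.append(GeneSet(fields[0], frozenset(genes)))
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path: str | Path, description: str = "na") -> None:
    with Path(path).open("w") as handle:
        for gs in gene_sets:
            handle.write("\t".join([gs.name, description, *gs.sorted_genes]) + "\n")


def read_labels(
    path: str | Path, classes: tuple[str, str] = DEFAULT_CLASSES
) -> PhenotypeLabels:
    """Read two-column ``sample_id<TAB>outcome`` labels (no header)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, keep_default_na=False)
    if frame.shape[1] != 2:
        raise ParseError(f"{path}: expected exactly 2 columns, got {frame.shape[1]}")
    series = pd.Series(frame.iloc[:, 1].values, index=frame.iloc[:, 0].values)
    try:
        return PhenotypeLabels(series, classes=classes)
    except ContractError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_labels(labels: PhenotypeLabels, path: str | Path) -> None:
    labels.outcome.to_csv(Path(path), sep="\t", header=False)


def read_interactions(path: str | Path) -> InteractionTable:
    """Read a three-column ``protein_a  protein_b  combined_score`` TSV."""
    frame = pd.read_csv(
        Path(path), sep="\t", header=None, names=list(InteractionTable.COLUMNS)
    )
    try:
        return InteractionTable(frame)
    except ContractError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def filter_interactions(
    table: InteractionTable, focus: str, min_score: float = 0.7
) -> GeneSet:
    """First-shell partners of ``focus`` with combined score strictly above ``min_score``.

    The strict inequality mirrors the usual confidence-cutoff convention for
    interaction databases ("scores greater than 0.7").  A focus protein absent
    from the table yields an empty set with a logged warning, not an error.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ContractError(f"min_score must lie in [0, 1], got {min_score}")
    focus = str(focus).strip().upper()
    frame = table.frame
    hits_a = frame.loc[(frame["protein_a"] == focus), :]
    hits_b = frame.loc[(frame["protein_b"] == focus), :]
    if hits_a.empty and hits_b.empty:
        logger.warning("focus protein %r absent from interaction table", focus)
        return GeneSet(f"{focus}_partners", frozenset())
    partners = set(hits_a.loc[hits_a["combined_score"] > min_score, "protein_b"])
    partners |= set(hits_b.loc[hits_b["combined_score"] > min_score, "protein_a"])
    return GeneSet(f"{focus}_partners", frozenset(partners))


def read_config(path: str | Path) -> dict[str, object]:
    """Read a flat key/value YAML config; nested structures are rejected."""
    path = Path(path)
    loaded = yaml.safe_load(path.read_text())
    if loaded is None:
        return {}
    if not isinstance(loaded, dict):
        raise ConfigError(f"{path}: config must be a mapping of key: value pairs")
    for key, value in loaded.items():
        if isinstance(value, (dict, list)):
            raise ConfigError(f"{path}: config key {key!r} is nested; flat values only")
    return dict(loaded)


def log_config(config_path: str | Path, out_dir: str | Path) -> Path:
    """Copy the run config verbatim into ``out_dir`` for provenance."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dest = out_dir / Path(config_path).name
    shutil.copyfile(config_path, dest)
    return dest
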