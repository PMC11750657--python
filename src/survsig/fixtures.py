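"""Packaged gene-set fixtures.

``deg_gs`` and ``ppi_gs`` are the published 12- and 7-gene Drp1-associated
signatures.  ``drp1_deg_genes``, ``drp1_ppi_genes`` and ``survival_genes``
are SYNTHETIC stand-ins for the supplementary source lists (the
Drp1-overexpression DEGs, the STRING first-shell DNM1L interactors, and the
sepsis-survival gene list), which are not published as plain text.  The
stand-ins are constructed so that their pairwise intersections reproduce the
published signature memberships exactly; they are suitable for exercising the
signature-construction logic, not for biological reuse.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from .core import GeneSet
from .io import read_gmt

_FIXTURE_FILES = {
    "deg_gs": "signatures.gmt",
    "ppi_gs": "signatures.gmt",
    "drp1_deg_genes": "synthetic_drp1_standin.gmt",
    "drp1_ppi_genes": "synthetic_drp1_standin.gmt",
    "survival_genes": "synthetic_drp1_standin.gmt",
}

FIXTURE_NAMES = tuple(_FIXTURE_FILES)


@lru_cache(maxsize=None)
def _load_file(filename: str) -> dict[str, GeneSet]:
    path = resources.files("survsig.data") / filename
    with resources.as_file(path) as real_path:
        return {gs.name: gs for gs in read_gmt(real_path)}


def load_fixture(name: str) -> GeneSet:
    """Return a packaged gene set by name.

    Valid names: ``deg_gs``, ``ppi_gs``, ``drp1_deg_genes``,
    ``drp1_ppi_genes``, ``survival_genes``.
    """
    try:
        filename = _FIXTURE_FILES[name]
    except KeyError:
        raise LookupError(
            f"unknown fixture {name!r}; valid names: {sorted(_FIXTURE_FILES)}"
        ) from None
    return _load_file(filename)[name]
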