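"""Packaged reference fixtures and their registry.

Each fixture is a small plain-text data file transcribed from the published
kisspeptin-system analyses (see the provenance header inside each file), is
checksummed, and parses through the package's standard readers.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path
from typing import Any, Callable

import pandas as pd

from .errors import FixtureError
from .formats import (
    read_annotation_tsv,
    read_presence_tsv,
)
from .model import AnnotationTable, GeneFamilyMap, PresenceMatrix, SpeciesTree

#: The eight receptor-flanking families delineating the Kissr tetra-paralogon.
KISSR_FAMILIES = frozenset(
    {"PALM", "PTBP", "GRIN3", "GADD45", "DIRAS", "ZCCHC", "LPAR", "ZNF644_WIZ"}
)

#: The eleven kisspeptin-flanking families delineating the Kiss tetra-paralogon.
KISS_FAMILIES = frozenset(
    {
        "TEAD", "NAV", "PPFIA", "KCNC", "GOLT1", "PLEKHA",
        "PPP1R15", "PIK3C2", "SYT", "GYS", "PTH",
    }
)


def _data_path(filename: str) -> Path:
    return Path(resources.files("kissevo").joinpath("data", filename))


def _read_tree_fixture(path: Path) -> SpeciesTree:
    return SpeciesTree.from_newick(path.read_text())


def _read_tsv_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


_REGISTRY: dict[str, tuple[str, Callable[[Path], Any], str]] = {
    "kissr_synteny": (
        "kissr_synteny.tsv",
        read_annotation_tsv,
        "522f5c2118e7f1e1f8f0787b32c82c2e24248315ae3ba18063ea5b47d5f2b0e0",
    ),
    "kiss_synteny": (
        "kiss_synteny.tsv",
        read_annotation_tsv,
        "6840822fbc6a1890b1ff1c9f8c22a83e07499a636667997329ab4da6e1e979f1",
    ),
    "presence_matrix": (
        "presence_matrix.tsv",
        read_presence_tsv,
        "ee2c6694b1c271c02775ae668b9fdbf67e717271540b58fdd560f8a935a3ff06",
    ),
    "species_tree": (
        "species_tree.nwk",
        _read_tree_fixture,
        "b3600d7e51b9e8ef43c2087641e163f64579dae42c041d41261553b0f17f731a",
    ),
    "kp10_reference": (
        "kp10_reference.tsv",
        _read_tsv_table,
        "456b27572db5dd4e157b0c81335b22967b0a99aad15757049352c5001515fdee",
    ),
    "predicted_kp10": (
        "predicted_kp10.tsv",
        _read_tsv_table,
        "54c62e7ca9b6675c68e491aaa97ac4f5ccc12f09978894f7924b2e0054823bd9",
    ),
}


def fixture_names() -> list[str]:
    return sorted(_REGISTRY)


def load_fixture(name: str, verify: bool = True):
    """Load a packaged fixture by registry name.

    Raises :class:`~kissevo.errors.FixtureError` for unknown names or when
    the packaged file does not match its recorded checksum.
    """
    try:
        filename, loader, sha = _REGISTRY[name]
    except KeyError:
        raise FixtureError(
            f"unknown fixture {name!r}; known: {fixture_names()}"
        ) from None
    path = _data_path(filename)
    if verify and not sha.startswith("__"):
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        if digest != sha:
            raise FixtureError(
                f"fixture {name!r} checksum mismatch: {digest} != {sha}"
            )
    return loader(path)


def fixture_family_map(name: str) -> GeneFamilyMap:
    """Family map derived from a packaged synteny fixture."""
    tables = load_fixture(name)
    return GeneFamilyMap.from_annotation(*tables.values())


def novel_decapeptides(
    predicted: pd.DataFrame, reference: pd.DataFrame
) -> list[str]:
    """Distinct predicted decapeptides absent from the previously known set.

    ``predicted`` needs a ``decapeptide`` column; ``reference`` needs
    ``decapeptide`` and ``status`` (rows with status ``known`` form the
    previously known set).
    """
    known = set(reference.loc[reference["status"] == "known", "decapeptide"])
    seen: dict[str, None] = {}
    for pep in predicted["decapeptide"]:
        if pep not in known:
            seen.setdefault(pep, None)
    return list(seen)
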