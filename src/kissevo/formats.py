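"""Readers and writers for the standard interchange formats.

Annotations travel as GFF3 (native, 1-based inclusive) or BED (converted at
the boundary); gene families as TSV; presence/absence matrices as TSV with
``1``/``0``/``?`` cells; species trees as newick with WGD events encoded as
branch comments (``[&wgd=1R,2R]`` after the node below the branch); sequences
as FASTA via Biopython.
"""

from __future__ import annotations

import urllib.parse
from pathlib import Path
from typing import Iterable, Union

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import KissevoError
from .model import (
    ABSENT,
    PRESENT,
    UNKNOWN,
    AnnotationTable,
    GeneFamilyMap,
    PresenceMatrix,
    SpeciesTree,
    to_internal_coordinates,
)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _esc(value: str) -> str:
    return urllib.parse.quote(str(value), safe=" :/().-_")


def _unesc(value: str) -> str:
    return urllib.parse.unquote(value)


def parse_gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        if not part or "=" not in part:
            continue
        key, value = part.split("=", 1)
        out[_unesc(key.strip())] = _unesc(value.strip())
    return out


def format_gff3_attributes(attrs: dict[str, str]) -> str:
    return ";".join(f"{_esc(k)}={_esc(v)}" for k, v in attrs.items() if v != "")


def read_gff3_annotation(path: PathLike, species: str | None = None) -> AnnotationTable:
    """Read gene features from a GFF3 file into an :class:`AnnotationTable`.

    Recognized attributes: ``ID`` (gene id), ``family_id``, ``symbol``,
    ``species``. Non-feature lines (comments, directives) are skipped.
    """
    path = Path(path)
    if not path.exists():
        raise KissevoError(f"cannot read GFF3 file: {path}")
    records: list[GeneRecord] = []
    inferred_species = species
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise KissevoError(f"{path}: malformed GFF3 line: {line[:80]}")
            seqid, _source, _type, start, end, _score, strand, _phase, attr_text = cols
            attrs = parse_gff3_attributes(attr_text)
            sp = attrs.get("species", species or "")
            if inferred_species is None and sp:
                inferred_species = sp
            records.append(
                to_internal_coordinates(
                    seqid,
                    int(start),
                    int(end),
                    "GFF3",
                    gene_id=attrs.get("ID", ""),
                    species=sp,
                    strand=strand if strand in "+-" else "+",
                    family_id=attrs.get("family_id") or None,
                    symbol=attrs.get("symbol", ""),
                )
            )
    return AnnotationTable(inferred_species or "", records)


def write_gff3_annotation(table: AnnotationTable, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in table:
            attrs = {
                "ID": rec.gene_id,
                "species": rec.species,
                "family_id": rec.family_id or "",
                "symbol": rec.symbol,
            }
            fh.write(
                "\t".join(
                    [
                        rec.seq_id,
                        "kissevo",
                        "gene",
                        str(rec.start),
                        str(rec.end),
                        ".",
                        rec.strand,
                        ".",
                        format_gff3_attributes(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED (0-based half-open; converted at this boundary)
# ---------------------------------------------------------------------------

def read_bed_annotation(path: PathLike, species: str = "") -> AnnotationTable:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            seqid, start, end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 else ""
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "+"
            records.append(
                to_internal_coordinates(
                    seqid, start, end, "BED",
                    gene_id=name, species=species, strand=strand,
                )
            )
    return AnnotationTable(species, records)


def write_bed_annotation(table: AnnotationTable, path: PathLike) -> None:
    with open(path, "w") as fh:
        for rec in table:
            fh.write(
                "\t".join(
                    [
                        rec.seq_id,
                        str(rec.start - 1),
                        str(rec.end),
                        rec.gene_id,
                        "0",
                        rec.strand,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Annotation / family TSV
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "species", "gene_id", "symbol", "seq_id", "start", "end", "strand", "family_id",
]


def read_annotation_tsv(path: PathLike) -> dict[str, AnnotationTable]:
    """Read a multi-species annotation TSV into per-species tables."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise KissevoError(f"{path}: missing columns {missing}")
    out: dict[str, AnnotationTable] = {}
    for species, group in df.groupby("species", sort=True):
        out[str(species)] = AnnotationTable.from_dataframe(str(species), group)
    return out


def write_annotation_tsv(tables: Iterable[AnnotationTable], path: PathLike) -> None:
    frames = [t.to_dataframe() for t in tables if len(t)]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=ANNOTATION_COLUMNS
    )
    df = df[["species", "gene_id", "symbol", "seq_id", "start", "end", "strand", "family_id"]]
    df.to_csv(path, sep="\t", index=False)


def read_family_tsv(path: PathLike) -> GeneFamilyMap:
    """Read a family TSV (columns: family_id, gene_id, species, symbol)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    fam = GeneFamilyMap()
    for row in df.itertuples(index=False):
        if pd.isna(row.family_id) or row.family_id == "":
            continue
        fam.add(str(row.family_id), str(row.gene_id))
    return fam


def write_family_tsv(tables: Iterable[AnnotationTable], path: PathLike) -> None:
    rows = []
    for table in tables:
        for rec in table:
            if rec.family_id is not None:
                rows.append(
                    {
                        "family_id": rec.family_id,
                        "gene_id": rec.gene_id,
                        "species": rec.species,
                        "symbol": rec.symbol,
                    }
                )
    pd.DataFrame(rows, columns=["family_id", "gene_id", "species", "symbol"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Presence matrix TSV (1 / 0 / ?)
# ---------------------------------------------------------------------------

def read_presence_tsv(path: PathLike) -> PresenceMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    mapping = {"1": PRESENT, "0": ABSENT, "?": UNKNOWN}
    try:
        converted = df.map(lambda v: mapping[str(v).strip()])
    except KeyError as exc:
        raise KissevoError(f"{path}: bad presence cell {exc}") from None
    return PresenceMatrix(converted)


def write_presence_tsv(matrix: PresenceMatrix, path: PathLike) -> None:
    rev = {PRESENT: "1", ABSENT: "0", UNKNOWN: "?"}
    out = matrix.df.map(lambda v: rev[v])
    out.index.name = "species"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Newick with WGD branch comments
# ---------------------------------------------------------------------------

def read_tree(path: PathLike) -> SpeciesTree:
    with open(path) as fh:
        return SpeciesTree.from_newick(fh.read())


def _newick_node(tree: SpeciesTree, node: dendropy.Node) -> str:
    label = tree.label(node)
    if node.is_leaf():
        text = label
    else:
        inner = ",".join(_newick_node(tree, c) for c in node.child_nodes())
        text = f"({inner}){label}"
    events = tree.wgd_on_branch(label)
    if events:
        text += f"[&wgd={','.join(events)}]"
    return text


def tree_to_newick(tree: SpeciesTree) -> str:
    """Newick string with WGD events re-emitted as branch comments."""
    return _newick_node(tree, tree.tree.seed_node) + ";"


def write_tree(tree: SpeciesTree, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{seq_id: sequence}`` dict."""
    path = Path(path)
    if not path.exists():
        raise KissevoError(f"cannot read FASTA file: {path}")
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: dict[str, str], path: PathLike, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
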