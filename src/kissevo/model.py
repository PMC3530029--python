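"""Core domain types: gene records, annotation tables, gene families,
WGD-annotated species trees, and presence/absence matrices.

Coordinate convention: 1-based, fully-closed intervals everywhere inside the
package. Conversion from 0-based half-open systems (BED) happens only at I/O
boundaries via :func:`to_internal_coordinates`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import dendropy
import pandas as pd

from .errors import (
    InconsistentOriginError,
    KissevoError,
    MalformedIntervalError,
)

STRANDS = ("+", "-")

#: Presence/absence cell states.
PRESENT, ABSENT, UNKNOWN = 1, 0, None


@dataclass(frozen=True)
class GeneRecord:
    """A located, stranded gene with an optional family assignment.

    ``start``/``end`` are 1-based inclusive base-pair coordinates on
    ``seq_id``. ``family_id`` groups paralogs/orthologs across species and may
    be ``None`` for loci without a family assignment (such genes are carried
    through but invisible to synteny scoring).
    """

    gene_id: str
    species: str
    seq_id: str
    start: int
    end: int
    strand: str
    family_id: Optional[str] = None
    symbol: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise MalformedIntervalError(
                f"{self.gene_id}: invalid interval {self.start}..{self.end}"
            )
        if self.strand not in STRANDS:
            raise KissevoError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def to_internal_coordinates(
    seq_id: str,
    start: int,
    end: int,
    dialect: str,
    *,
    gene_id: str = "",
    species: str = "",
    strand: str = "+",
    family_id: Optional[str] = None,
    symbol: str = "",
) -> GeneRecord:
    """Convert an externally formatted interval to a :class:`GeneRecord`.

    GFF3 intervals (1-based inclusive) pass through unchanged; BED intervals
    (0-based half-open) have their start incremented by one. An interval that
    is empty or inverted after conversion raises
    :class:`~kissevo.errors.MalformedIntervalError`.
    """
    dialect = dialect.upper()
    if dialect == "GFF3":
        s, e = start, end
    elif dialect == "BED":
        s, e = start + 1, end
    else:
        raise KissevoError(f"unknown coordinate dialect {dialect!r}")
    if s > e:
        raise MalformedIntervalError(
            f"{seq_id}:{start}-{end} ({dialect}) is empty after conversion"
        )
    return GeneRecord(
        gene_id=gene_id or f"{seq_id}:{s}-{e}",
        species=species,
        seq_id=seq_id,
        start=s,
        end=e,
        strand=strand,
        family_id=family_id,
        symbol=symbol,
    )


class AnnotationTable:
    """The ordered gene complement of one species' genome.

    Records are kept sorted by ``(seq_id, start)``; gene ids are unique.
    """

    def __init__(self, species: str, records: Iterable[GeneRecord] = ()):
        self.species = species
        self.records: list[GeneRecord] = sorted(
            records, key=lambda r: (r.seq_id, r.start, r.end, r.gene_id)
        )
        self._by_id: dict[str, GeneRecord] = {}
        for rec in self.records:
            if rec.gene_id in self._by_id:
                raise KissevoError(
                    f"duplicate gene_id {rec.gene_id!r} in {species}"
                )
            self._by_id[rec.gene_id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def get(self, gene_id: str) -> Optional[GeneRecord]:
        return self._by_id.get(gene_id)

    def seq_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.seq_id, None)
        return list(seen)

    def genes_on(self, seq_id: str) -> list[GeneRecord]:
        """Genes on one chromosome/scaffold, in coordinate order."""
        return [r for r in self.records if r.seq_id == seq_id]

    def subset(self, gene_ids: Iterable[str]) -> "AnnotationTable":
        wanted = set(gene_ids)
        return AnnotationTable(
            self.species, [r for r in self.records if r.gene_id in wanted]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "species": r.species,
                    "seq_id": r.seq_id,
                    "start": r.start,
                    "end": r.end,
                    "strand": r.strand,
                    "family_id": r.family_id,
                    "symbol": r.symbol,
                }
                for r in self.records
            ]
        )

    @classmethod
    def from_dataframe(cls, species: str, df: pd.DataFrame) -> "AnnotationTable":
        records = []
        for row in df.itertuples(index=False):
            fam = getattr(row, "family_id", None)
            if pd.isna(fam) or fam == "":
                fam = None
            records.append(
                GeneRecord(
                    gene_id=str(row.gene_id),
                    species=species,
                    seq_id=str(row.seq_id),
                    start=int(row.start),
                    end=int(row.end),
                    strand=str(row.strand),
                    family_id=fam,
                    symbol=str(getattr(row, "symbol", "") or ""),
                )
            )
        return cls(species, records)


class GeneFamilyMap:
    """family_id -> member gene_ids, possibly spanning species.

    Every gene id belongs to at most one family.
    """

    def __init__(self, families: Mapping[str, Iterable[str]] = (), names: Mapping[str, str] | None = None):
        self._members: dict[str, set[str]] = {}
        self._family_of: dict[str, str] = {}
        self.names: dict[str, str] = dict(names or {})
        if families:
            for fam, genes in dict(families).items():
                for g in genes:
                    self.add(fam, g)

    def add(self, family_id: str, gene_id: str) -> None:
        prev = self._family_of.get(gene_id)
        if prev is not None and prev != family_id:
            raise KissevoError(
                f"gene {gene_id!r} assigned to both {prev!r} and {family_id!r}"
            )
        self._members.setdefault(family_id, set()).add(gene_id)
        self._family_of[gene_id] = family_id

    def family_of(self, gene_id: str) -> Optional[str]:
        return self._family_of.get(gene_id)

    def members(self, family_id: str) -> frozenset[str]:
        return frozenset(self._members.get(family_id, ()))

    def family_ids(self) -> list[str]:
        return sorted(self._members)

    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, family_id: str) -> bool:
        return family_id in self._members

    @classmethod
    def from_annotation(cls, *tables: AnnotationTable) -> "GeneFamilyMap":
        """Build a family map from the family_id column of annotations."""
        fam = cls()
        for table in tables:
            for rec in table:
                if rec.family_id is not None:
                    fam.add(rec.family_id, rec.gene_id)
        return fam


_WGD_COMMENT = re.compile(r"&?wgd\s*=\s*([A-Za-z0-9_,\- ]+)")


@dataclass
class WgdEvent:
    """A whole-genome duplication assigned to a tree branch."""

    name: str  # e.g. "1R", "2R", "3R"
    branch: str  # label of the node below the branch


class SpeciesTree:
    """A rooted species tree whose branches may carry WGD events.

    Thin wrapper around a :class:`dendropy.Tree`. Each branch is identified by
    the label of the node below it (leaf taxon label, or internal clade label,
    or a synthesized ``node<k>``). WGD events are read from newick comments of
    the form ``[&wgd=1R,2R]`` attached to the node below the branch.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._label_nodes()
        self.wgd_events: list[WgdEvent] = []
        for node in tree.preorder_node_iter():
            for comment in node.comments or ():
                m = _WGD_COMMENT.search(comment)
                if m:
                    for name in m.group(1).split(","):
                        name = name.strip()
                        if name:
                            self.wgd_events.append(
                                WgdEvent(name=name, branch=self.label(node))
                            )

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            extract_comment_metadata=False,
            preserve_underscores=True,
        )
        return cls(tree)

    def as_newick(self) -> str:
        out = self.tree.as_string(schema="newick", suppress_rooting=True)
        return out.strip()

    def _label_nodes(self) -> None:
        self._labels: dict[int, str] = {}
        self._nodes: dict[str, dendropy.Node] = {}
        counter = 0
        for node in self.tree.preorder_node_iter():
            if node.taxon is not None:
                lbl = node.taxon.label
            elif node.label:
                lbl = node.label
            else:
                lbl = f"node{counter}"
                counter += 1
            if lbl in self._nodes:
                raise KissevoError(f"duplicate node label {lbl!r} in tree")
            self._labels[id(node)] = lbl
            self._nodes[lbl] = node

    # -- basic queries -----------------------------------------------------

    def label(self, node: dendropy.Node) -> str:
        return self._labels[id(node)]

    def node(self, label: str) -> dendropy.Node:
        try:
            return self._nodes[label]
        except KeyError:
            raise KissevoError(f"no tree node labeled {label!r}") from None

    @property
    def root_label(self) -> str:
        return self.label(self.tree.seed_node)

    def leaf_labels(self) -> list[str]:
        return [self.label(n) for n in self.tree.leaf_node_iter()]

    def branch_labels(self) -> list[str]:
        """All branches, identified by the node below each (root included:
        its 'branch' is the stem above the root)."""
        return [self.label(n) for n in self.tree.preorder_node_iter()]

    def children(self, label: str) -> list[str]:
        return [self.label(c) for c in self.node(label).child_nodes()]

    def parent(self, label: str) -> Optional[str]:
        p = self.node(label).parent_node
        return None if p is None else self.label(p)

    def leaves_under(self, label: str) -> list[str]:
        return [self.label(n) for n in self.node(label).leaf_iter()]

    def path_to_root(self, label: str) -> list[str]:
        """Branch labels from the given node up to and including the root
        stem."""
        out = []
        node = self.node(label)
        while node is not None:
            out.append(self.label(node))
            node = node.parent_node
        return out

    def wgd_on_path(self, leaf: str) -> list[str]:
        """Names of WGD events on the root-to-leaf path (root stem
        included)."""
        path = set(self.path_to_root(leaf))
        return [ev.name for ev in self.wgd_events if ev.branch in path]

    def wgd_on_branch(self, branch: str) -> list[str]:
        return [ev.name for ev in self.wgd_events if ev.branch == branch]


def expected_copies(tree: SpeciesTree, leaf: str) -> int:
    """Expected gene copy number at a leaf from WGD doubling alone.

    Each whole-genome duplication on the root-to-leaf path doubles the
    ancestral single-copy state: two rounds (1R+2R) give 4, an additional
    teleost-specific round (3R) gives 8, no WGD gives 1.
    """
    return 2 ** len(tree.wgd_on_path(leaf))


class PresenceMatrix:
    """Species x gene-lineage presence/absence with explicit unknowns.

    Cells are ``1`` (present), ``0`` (absent), or ``None`` (unknown; excluded
    from loss counting). Backed by a pandas DataFrame with object dtype.
    """

    def __init__(self, df: pd.DataFrame):
        def norm(v):
            # pandas ops turn None into NaN; fold both back to unknown
            if v is UNKNOWN or pd.isna(v):
                return UNKNOWN
            if v in (PRESENT, ABSENT):
                return v
            raise KissevoError(f"bad presence cell value {v!r}")

        values = [[norm(v) for v in row] for row in df.to_numpy()]
        self.df = pd.DataFrame(
            values, index=df.index, columns=df.columns, dtype=object
        )

    @property
    def species(self) -> list[str]:
        return list(self.df.index)

    @property
    def lineages(self) -> list[str]:
        return list(self.df.columns)

    def cell(self, species: str, lineage: str):
        return self.df.at[species, lineage]

    def present_species(self, lineage: str) -> list[str]:
        return [s for s in self.species if self.df.at[s, lineage] == PRESENT]

    def absent_species(self, lineage: str) -> list[str]:
        return [s for s in self.species if self.df.at[s, lineage] == ABSENT]

    def validate_against(self, tree: SpeciesTree) -> None:
        leaves = set(tree.leaf_labels())
        missing = [s for s in self.species if s not in leaves]
        if missing:
            raise InconsistentOriginError(
                f"matrix species not in tree: {missing}"
            )

    @classmethod
    def from_cells(
        cls,
        species: Sequence[str],
        lineages: Sequence[str],
        cells: Mapping[tuple[str, str], object],
    ) -> "PresenceMatrix":
        df = pd.DataFrame(
            ABSENT, index=list(species), columns=list(lineages), dtype=object
        )
        for (sp, lin), v in cells.items():
            df.at[sp, lin] = v
        return cls(df)
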