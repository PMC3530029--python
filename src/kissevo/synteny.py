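"""Microsynteny: neighborhoods, paralogon detection, gene classification,
and post-WGD duplicated-region detection.

A *paralogon* is a set of regions within one genome that descend from a
single ancestral region through whole-genome duplication; it is recognized by
paralogous gene families with members spread across the regions. Detection is
family-based: one neighborhood is built around every family-assigned gene,
co-linear neighborhoods on the same chromosome are merged into regions, and
regions sharing at least ``tau`` gene families are linked; connected
components of the resulting graph are the paralogons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import networkx as nx

from .errors import ConfigurationError, UnknownAnchorError
from .model import AnnotationTable, GeneFamilyMap, GeneRecord

Anchor = Union[str, tuple[str, int]]


@dataclass(frozen=True)
class Neighborhood:
    """A window of genes around an anchor on one chromosome/scaffold."""

    species: str
    seq_id: str
    anchor: Optional[Anchor]
    genes: tuple[GeneRecord, ...]

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.genes)

    @property
    def families(self) -> frozenset[str]:
        return frozenset(g.family_id for g in self.genes if g.family_id)

    @property
    def start(self) -> int:
        return min(g.start for g in self.genes)

    @property
    def end(self) -> int:
        return max(g.end for g in self.genes)

    @property
    def anchor_family(self) -> Optional[str]:
        if isinstance(self.anchor, str):
            for g in self.genes:
                if g.gene_id == self.anchor:
                    return g.family_id
        return None

    def contains_family(self, family_id: str) -> bool:
        return family_id in self.families


def build_neighborhood(
    annotation: AnnotationTable, anchor: Anchor, k: int
) -> Neighborhood:
    """The ``k`` genes on each side of the anchor (fewer at contig edges).

    The anchor may be a gene id or a ``(seq_id, position)`` pair; the anchor
    gene itself is included.
    """
    if k < 0:
        raise ConfigurationError("k must be >= 0")
    if isinstance(anchor, str):
        rec = annotation.get(anchor)
        if rec is None:
            raise UnknownAnchorError(
                f"anchor gene {anchor!r} not found in {annotation.species}"
            )
        seq_id = rec.seq_id
        genes = annotation.genes_on(seq_id)
        idx = next(i for i, g in enumerate(genes) if g.gene_id == anchor)
    else:
        seq_id, position = anchor
        genes = annotation.genes_on(seq_id)
        if not genes:
            raise UnknownAnchorError(
                f"no genes on {seq_id!r} in {annotation.species}"
            )
        idx = min(
            range(len(genes)),
            key=lambda i: (abs(genes[i].midpoint - position), i),
        )
    lo = max(0, idx - k)
    hi = min(len(genes), idx + k + 1)
    return Neighborhood(
        species=annotation.species,
        seq_id=seq_id,
        anchor=anchor,
        genes=tuple(genes[lo:hi]),
    )


def shared_family_count(
    a: Neighborhood,
    b: Neighborhood,
    exclude: Iterable[str] = (),
) -> int:
    """Number of gene families with members in both neighborhoods.

    Symmetric and bounded by the smaller family set. ``exclude`` removes
    families from the comparison (typically the query gene's own family, so
    that a shared kisspeptin locus does not count as synteny evidence for
    itself).
    """
    excluded = frozenset(exclude)
    return len((a.families & b.families) - excluded)


@dataclass(frozen=True)
class Paralogon:
    """Within-genome regions descended from one ancestral region via WGD."""

    species: str
    regions: tuple[Neighborhood, ...]
    supporting_families: frozenset[str]
    pair_support: Mapping[tuple[int, int], int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.regions)

    def region_keys(self) -> list[tuple[str, int]]:
        return [(r.seq_id, r.start) for r in self.regions]


def _regions_from_annotation(
    annotation: AnnotationTable, k: int
) -> list[Neighborhood]:
    """One merged region per run of overlapping family-gene neighborhoods.

    Every family-assigned gene seeds a window of ``k`` genes per side;
    overlapping windows on one chromosome are merged so that a physical
    region enters the paralogon graph exactly once.
    """
    regions: list[Neighborhood] = []
    for seq_id in annotation.seq_ids():
        genes = annotation.genes_on(seq_id)
        windows = []
        for idx, g in enumerate(genes):
            if g.family_id is None:
                continue
            windows.append((max(0, idx - k), min(len(genes) - 1, idx + k)))
        if not windows:
            continue
        windows.sort()
        merged = [windows[0]]
        for lo, hi in windows[1:]:
            mlo, mhi = merged[-1]
            if lo <= mhi + 1:
                merged[-1] = (mlo, max(mhi, hi))
            else:
                merged.append((lo, hi))
        for lo, hi in merged:
            regions.append(
                Neighborhood(
                    species=annotation.species,
                    seq_id=seq_id,
                    anchor=None,
                    genes=tuple(genes[lo : hi + 1]),
                )
            )
    regions.sort(key=lambda r: (r.seq_id, r.start))
    return regions


def detect_paralogons(
    annotation: AnnotationTable,
    family_map: Optional[GeneFamilyMap] = None,
    tau: int = 2,
    k: int = 15,
) -> list[Paralogon]:
    """Detect paralogons in one genome.

    Regions are linked when they share at least ``tau`` gene families;
    paralogons are the connected components with two or more regions, ordered
    by the ``(seq_id, start)`` of their leftmost region. ``family_map`` is
    accepted for interface symmetry; family membership is taken from the
    annotation's ``family_id`` column.
    """
    if tau < 1:
        raise ConfigurationError("tau must be >= 1")
    regions = _regions_from_annotation(annotation, k)
    if not regions:
        return []
    graph = nx.Graph()
    graph.add_nodes_from(range(len(regions)))
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            if shared_family_count(regions[i], regions[j]) >= tau:
                graph.add_edge(i, j)
    paralogons: list[Paralogon] = []
    for component in nx.connected_components(graph):
        if len(component) < 2:
            continue
        idxs = sorted(component)
        members = tuple(regions[i] for i in idxs)
        fam_regions: dict[str, int] = {}
        for r in members:
            for fam in r.families:
                fam_regions[fam] = fam_regions.get(fam, 0) + 1
        supporting = frozenset(f for f, n in fam_regions.items() if n >= 2)
        support = {
            (a, b): shared_family_count(members[a], members[b])
            for a in range(len(members))
            for b in range(a + 1, len(members))
        }
        paralogons.append(
            Paralogon(
                species=annotation.species,
                regions=members,
                supporting_families=supporting,
                pair_support=support,
            )
        )
    paralogons.sort(key=lambda p: (p.regions[0].seq_id, p.regions[0].start))
    return paralogons


def classify_gene(
    query: Neighborhood,
    references: Sequence[tuple[str, Neighborhood]],
    tau: int = 2,
    exclude_anchor_family: bool = True,
) -> Optional[str]:
    """Classify a gene by the best-matching labeled reference neighborhood.

    Returns the label whose reference shares the most gene families with the
    query, provided that maximum reaches ``tau`` and beats the runner-up
    label by at least 1; otherwise ``None`` (unclassified). A query on a
    mini-scaffold with no neighbors simply scores 0 everywhere and comes back
    unclassified, never an error.
    """
    if not references:
        raise ConfigurationError("classify_gene requires a non-empty reference set")
    exclude: set[str] = set()
    if exclude_anchor_family and query.anchor_family:
        exclude.add(query.anchor_family)
    best: dict[str, int] = {}
    for label, ref in references:
        score = shared_family_count(query, ref, exclude=exclude)
        if score > best.get(label, -1):
            best[label] = score
    ranked = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))
    top_label, top_score = ranked[0]
    runner_up = ranked[1][1] if len(ranked) > 1 else -1
    if top_score >= tau and top_score - runner_up >= 1:
        return top_label
    return None


@dataclass(frozen=True)
class DuplicatedRegionPair:
    """Two derived-genome regions matching one outgroup region (a WGD pair).

    ``missing_families`` lists the families present in the outgroup region
    but absent from at least one of the two derived copies — including, in
    the teleost 3R case, the kisspeptin/receptor gene itself when its
    duplicate was lost.
    """

    outgroup_region: Neighborhood
    derived_a: Neighborhood
    derived_b: Neighborhood
    missing_families: frozenset[str]


def detect_post_wgd_duplicates(
    derived: AnnotationTable,
    outgroup: AnnotationTable,
    family_map: Optional[GeneFamilyMap] = None,
    tau: int = 2,
    k: int = 15,
) -> list[DuplicatedRegionPair]:
    """Detect WGD-duplicated regions in a derived genome against an outgroup.

    The outgroup must lack the WGD under test. Each derived region is
    assigned to the outgroup region with which it shares the most gene
    families (requiring a unique maximum of at least ``tau``); outgroup
    regions claimed by two or more derived regions are reported as duplicated
    pairs together with the anchor families missing from the copies.
    """
    derived_regions = _regions_from_annotation(derived, k)
    outgroup_regions = _regions_from_annotation(outgroup, k)
    assignment: dict[int, list[int]] = {}
    for di, dr in enumerate(derived_regions):
        scores = [
            shared_family_count(dr, outgroup_regions[oi])
            for oi in range(len(outgroup_regions))
        ]
        if not scores:
            continue
        top = max(scores)
        if top < tau or scores.count(top) != 1:
            continue
        assignment.setdefault(scores.index(top), []).append(di)
    pairs: list[DuplicatedRegionPair] = []
    for oi in sorted(assignment):
        hits = assignment[oi]
        if len(hits) < 2:
            continue
        og = outgroup_regions[oi]
        for x in range(len(hits)):
            for y in range(x + 1, len(hits)):
                ra, rb = derived_regions[hits[x]], derived_regions[hits[y]]
                missing = frozenset(
                    fam
                    for fam in og.families
                    if fam not in ra.families or fam not in rb.families
                )
                pairs.append(
                    DuplicatedRegionPair(
                        outgroup_region=og,
                        derived_a=ra,
                        derived_b=rb,
                        missing_families=missing,
                    )
                )
    return pairs
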