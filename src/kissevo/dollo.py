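"""Dollo-parsimony reconstruction of gene-loss histories.

A gene lineage born on a given branch (here: a post-2R ohnolog born on the
vertebrate stem) can be lost any number of times but never regained. Under
that model the minimum-loss scenario for a presence/absence column is unique
and has a closed form: an internal node is *present* exactly when some
descendant leaf is present, and a loss is charged to every branch whose
parent is present but whose own subtree contains no present leaf. Unknown
cells are uninformative: a subtree with only unknown leaves neither forces
presence nor is charged a loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import dendropy
import pandas as pd

from .errors import InconsistentOriginError, NoObservationError
from .model import (
    PresenceMatrix,
    SpeciesTree,
    expected_copies,
)


@dataclass
class LineageScenario:
    """Minimal loss scenario for one gene lineage."""

    lineage: str
    origin: str
    losses: tuple[str, ...]  # branch labels (node below each lost branch)

    @property
    def loss_count(self) -> int:
        return len(self.losses)


def dollo_losses(
    matrix: PresenceMatrix,
    tree: SpeciesTree,
    origin: str,
    lineage: str,
) -> LineageScenario:
    """Single-origin Dollo reconstruction for one matrix column.

    ``origin`` is the branch (named by the node below it) on which the
    lineage arose; it must be on or above every present leaf. Raises
    :class:`NoObservationError` if no leaf is present and
    :class:`InconsistentOriginError` if a presence lies outside the origin's
    subtree.
    """
    matrix.validate_against(tree)
    present = set(matrix.present_species(lineage))
    absent = set(matrix.absent_species(lineage))
    if not present:
        raise NoObservationError(f"lineage {lineage!r} absent from all leaves")
    origin_node = tree.node(origin)
    in_subtree = set(tree.leaves_under(origin))
    outside = present - in_subtree
    if outside:
        raise InconsistentOriginError(
            f"lineage {lineage!r} present outside origin {origin!r}: {sorted(outside)}"
        )

    losses: list[str] = []

    def counts(node: dendropy.Node) -> tuple[int, int]:
        """(present leaves, absent leaves) under node; recurse and record
        losses at the highest branch whose subtree has no presence."""
        label = tree.label(node)
        if node.is_leaf():
            if label in present:
                return 1, 0
            if label in absent:
                return 0, 1
            return 0, 0  # unknown
        child_counts = [counts(c) for c in node.child_nodes()]
        n_p = sum(p for p, _ in child_counts)
        n_a = sum(a for _, a in child_counts)
        if n_p > 0:
            # node is present; any child subtree without presence but with an
            # observed absence is a loss branch
            for child, (p, a) in zip(node.child_nodes(), child_counts):
                if p == 0 and a > 0:
                    losses.append(tree.label(child))
        return n_p, n_a

    counts(origin_node)
    # deterministic order: preorder position of the loss branch
    order = {tree.label(n): i for i, n in enumerate(tree.tree.preorder_node_iter())}
    losses.sort(key=lambda lbl: order[lbl])
    return LineageScenario(lineage=lineage, origin=origin, losses=tuple(losses))


@dataclass
class ScenarioReport:
    """Aggregated loss scenarios across all lineages of a matrix."""

    scenarios: dict[str, LineageScenario]
    annotations: dict[str, str]  # lineages with no observation
    observed_counts: pd.DataFrame  # species x gene-group counts
    expected: dict[str, int]  # species -> 2^(#WGD on path)

    def losses_by_branch(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for scenario in self.scenarios.values():
            for branch in scenario.losses:
                out.setdefault(branch, []).append(scenario.lineage)
        return {b: sorted(v) for b, v in sorted(out.items())}

    def clade_max(self, tree: SpeciesTree, clade: str, group: str) -> int:
        """Maximum per-species observed count of a gene group in a clade."""
        leaves = [s for s in tree.leaves_under(clade) if s in self.observed_counts.index]
        if not leaves:
            return 0
        return int(self.observed_counts.loc[leaves, group].max())

    def deficit(self, species: str, group: str) -> int:
        return self.expected[species] - int(self.observed_counts.at[species, group])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for lineage, sc in self.scenarios.items():
            rows.append(
                {
                    "lineage": lineage,
                    "origin": sc.origin,
                    "loss_count": sc.loss_count,
                    "loss_branches": ";".join(sc.losses),
                }
            )
        for lineage, note in self.annotations.items():
            rows.append(
                {
                    "lineage": lineage,
                    "origin": "",
                    "loss_count": pd.NA,
                    "loss_branches": note,
                }
            )
        return pd.DataFrame(rows, columns=["lineage", "origin", "loss_count", "loss_branches"])


def _gene_group(lineage: str) -> str:
    """Group a lineage column under its gene symbol stem (Kissr-2 -> Kissr)."""
    stem = lineage.split("-")[0]
    return "".join(ch for ch in stem if not ch.isdigit())


def scenario_report(
    matrix: PresenceMatrix,
    tree: SpeciesTree,
    origins: Optional[Mapping[str, str]] = None,
    default_origin: Optional[str] = None,
) -> ScenarioReport:
    """Reconstruct loss scenarios for every lineage of a matrix.

    ``origins`` maps lineage -> origin branch; unmapped lineages fall back to
    ``default_origin`` (the root stem if not given), reflecting a post-2R
    origin for all ohnologs. Lineages observed in no leaf cannot be localized
    by the matrix and are reported as annotations (lost before or at the
    emergence of the sampled clade) rather than as computed branches.
    """
    origins = dict(origins or {})
    default_origin = default_origin or tree.root_label
    scenarios: dict[str, LineageScenario] = {}
    annotations: dict[str, str] = {}
    for lineage in matrix.lineages:
        origin = origins.get(lineage, default_origin)
        try:
            scenarios[lineage] = dollo_losses(matrix, tree, origin, lineage)
        except NoObservationError:
            annotations[lineage] = (
                "observed in no sampled species; "
                f"lost before or at the emergence of {origin}"
            )
    groups = sorted({_gene_group(l) for l in matrix.lineages})
    counts = pd.DataFrame(0, index=matrix.species, columns=groups)
    for lineage in matrix.lineages:
        group = _gene_group(lineage)
        for sp in matrix.present_species(lineage):
            counts.at[sp, group] += 1
    expected = {leaf: expected_copies(tree, leaf) for leaf in matrix.species}
    return ScenarioReport(
        scenarios=scenarios,
        annotations=annotations,
        observed_counts=counts,
        expected=expected,
    )
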