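"""Ground-truth simulators for the pipeline.

Two generators:

* :func:`simulate_wgd_history` evolves an ancestral gene region down a
  WGD-annotated species tree — every whole-genome duplication doubles each
  surviving region onto a fresh chromosome, and every gene copy can be lost
  independently on every branch — and emits per-leaf annotations plus a full
  event log. Replaying the log reproduces the final annotations exactly.

* :func:`plant_precursor_sequences` writes kisspeptin precursor genes
  (signal-peptide-like exon, optional GT..AG intron, final exon carrying a
  Kp(10) decapeptide and its cleavage/amidation motif) into random background
  sequence, with a truth table of exact coordinates.

The background model is deliberately simple (i.i.d. bases at a configurable
GC fraction, no repeats, no substitution process): it exercises the miner's
specificity and coordinate bookkeeping, not alignment-scale realism.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import CapacityError, KissevoError
from .miner import STOP_CODONS, _CODON_TABLE, reverse_complement
from .model import (
    ABSENT,
    PRESENT,
    UNKNOWN,
    AnnotationTable,
    GeneRecord,
    PresenceMatrix,
    SpeciesTree,
)

# ---------------------------------------------------------------------------
# WGD + loss history
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimRegion:
    """One genomic region during simulation; the id encodes its WGD path."""

    region_id: str
    genes: tuple[tuple[str, str], ...]  # (copy uid, family_id)

    def wgd_names(self) -> tuple[str, ...]:
        parts = self.region_id.split("-")[1:]
        return tuple(p[:-1] for p in parts)  # strip trailing a/b


@dataclass
class SimulatedHistory:
    """Event log plus final per-species annotations of one simulation."""

    seed: int
    loss_prob: float
    ancestral_families: tuple[str, ...]
    tree: SpeciesTree
    events: tuple[tuple, ...]  # ("wgd", branch, name) | ("loss", branch, region_id, uid)
    leaf_regions: dict[str, tuple[SimRegion, ...]]

    def annotations(self) -> dict[str, AnnotationTable]:
        out = {}
        for species, regions in self.leaf_regions.items():
            out[species] = _regions_to_annotation(species, regions)
        return out

    def copy_counts(self, family_id: str) -> dict[str, int]:
        """Surviving copies of one family per leaf species."""
        return {
            sp: sum(
                1
                for region in regions
                for _, fam in region.genes
                if fam == family_id
            )
            for sp, regions in self.leaf_regions.items()
        }

    def lineage_columns(self) -> list[str]:
        ids = set()
        for regions in self.leaf_regions.values():
            ids.update(r.region_id for r in regions)
        return sorted(ids)

    def presence_matrix(self, family_id: str) -> PresenceMatrix:
        """Per-leaf presence of each region-lineage copy of one family.

        A region id that cannot exist at a leaf (its WGD path is not the
        leaf's WGD path) is recorded as unknown.
        """
        species = sorted(self.leaf_regions)
        columns = self.lineage_columns()
        cells = {}
        for sp in species:
            have = {r.region_id: r for r in self.leaf_regions[sp]}
            for col in columns:
                if col in have:
                    present = any(fam == family_id for _, fam in have[col].genes)
                    cells[(sp, col)] = PRESENT if present else ABSENT
                else:
                    cells[(sp, col)] = UNKNOWN
        return PresenceMatrix.from_cells(species, columns, cells)

    def true_loss_branches(self, family_id: str) -> dict[str, set[str]]:
        """region_id -> branches on which that region's family copy was
        lost."""
        out: dict[str, set[str]] = {}
        for ev in self.events:
            if ev[0] == "loss":
                _, branch, region_id, uid = ev
                if uid.split(":")[0] == family_id:
                    out.setdefault(region_id, set()).add(branch)
        return out


def _regions_to_annotation(
    species: str, regions: Sequence[SimRegion]
) -> AnnotationTable:
    records = []
    for region in regions:
        for pos, (uid, fam) in enumerate(region.genes):
            start = pos * 10_000 + 1
            records.append(
                GeneRecord(
                    gene_id=f"{species}|{region.region_id}|{uid}",
                    species=species,
                    seq_id=region.region_id,
                    start=start,
                    end=start + 4_999,
                    strand="+",
                    family_id=fam,
                    symbol=fam,
                )
            )
    return AnnotationTable(species, records)


def _evolve(
    tree: SpeciesTree,
    ancestral_families: Sequence[str],
    loss_prob: float,
    *,
    rng: Optional[random.Random],
    replay_events: Optional[Sequence[tuple]] = None,
) -> tuple[tuple[tuple, ...], dict[str, tuple[SimRegion, ...]]]:
    """Shared engine for simulation (rng) and replay (recorded events)."""
    if not ancestral_families:
        raise KissevoError("ancestral region must be non-empty")
    root_region = SimRegion(
        region_id="R0",
        genes=tuple((f"{fam}:{i}", fam) for i, fam in enumerate(ancestral_families)),
    )
    replay_losses: set[tuple[str, str, str]] = set()
    if replay_events is not None:
        replay_losses = {
            (ev[1], ev[2], ev[3]) for ev in replay_events if ev[0] == "loss"
        }
    events: list[tuple] = []
    states: dict[str, tuple[SimRegion, ...]] = {}
    leaf_regions: dict[str, tuple[SimRegion, ...]] = {}

    for node in tree.tree.preorder_node_iter():
        branch = tree.label(node)
        parent = node.parent_node
        state = (
            (root_region,)
            if parent is None
            else states[tree.label(parent)]
        )
        # WGDs on this branch double every surviving region
        for wgd_name in tree.wgd_on_branch(branch):
            events.append(("wgd", branch, wgd_name))
            doubled: list[SimRegion] = []
            for region in state:
                for tag in ("a", "b"):
                    doubled.append(
                        SimRegion(
                            region_id=f"{region.region_id}-{wgd_name}{tag}",
                            genes=region.genes,
                        )
                    )
            state = tuple(doubled)
        # per-copy losses on this branch
        lost_state: list[SimRegion] = []
        for region in state:
            kept = []
            for uid, fam in region.genes:
                if replay_events is not None:
                    lose = (branch, region.region_id, uid) in replay_losses
                else:
                    lose = rng.random() < loss_prob
                if lose:
                    events.append(("loss", branch, region.region_id, uid))
                else:
                    kept.append((uid, fam))
            lost_state.append(SimRegion(region.region_id, tuple(kept)))
        states[branch] = tuple(lost_state)
        if node.is_leaf():
            leaf_regions[branch] = states[branch]
    return tuple(events), leaf_regions


def simulate_wgd_history(
    tree: SpeciesTree,
    ancestral_families: Sequence[str],
    loss_prob: float,
    seed: int,
) -> SimulatedHistory:
    """Simulate WGDs and per-branch gene losses down a species tree.

    On every branch, WGD events listed for that branch fire first (each
    doubles every region onto a fresh region id, suffixed ``-<name>a`` /
    ``-<name>b``), then every surviving gene copy is deleted independently
    with probability ``loss_prob``. Same seed and parameters give an
    identical history.
    """
    if not 0.0 <= loss_prob <= 1.0:
        raise KissevoError("loss_prob must lie in [0, 1]")
    rng = random.Random(seed)
    events, leaf_regions = _evolve(
        tree, ancestral_families, loss_prob, rng=rng
    )
    return SimulatedHistory(
        seed=seed,
        loss_prob=loss_prob,
        ancestral_families=tuple(ancestral_families),
        tree=tree,
        events=events,
        leaf_regions=leaf_regions,
    )


def replay_history(history: SimulatedHistory) -> dict[str, tuple[SimRegion, ...]]:
    """Re-derive the leaf regions purely from the recorded event log."""
    _, leaf_regions = _evolve(
        history.tree,
        history.ancestral_families,
        history.loss_prob,
        rng=None,
        replay_events=history.events,
    )
    return leaf_regions


# ---------------------------------------------------------------------------
# Sequence planting
# ---------------------------------------------------------------------------

_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_CODON_TABLE.items()):
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
_AMINO_ACIDS = sorted(set(_CODON_TABLE.values()) - {"*"})

VALID_PLANT_MOTIFS = ("GKR", "GKK", "GK-Stop")


@dataclass(frozen=True)
class PlantSpec:
    """One precursor to plant: decapeptide, processing motif, options."""

    name: str
    decapeptide: str
    motif: str
    premature_stop_offset: Optional[int] = None  # codons upstream of Kp(10)

    def __post_init__(self) -> None:
        if len(self.decapeptide) != 10:
            raise KissevoError(f"{self.name}: decapeptide must have 10 residues")
        if self.motif not in VALID_PLANT_MOTIFS:
            raise KissevoError(f"{self.name}: motif must be one of {VALID_PLANT_MOTIFS}")


@dataclass(frozen=True)
class PlantTruth:
    """Exact placement of one planted precursor."""

    name: str
    seq_id: str
    start: int
    end: int
    strand: str
    decapeptide: str
    motif: str
    decap_start: int
    decap_end: int
    premature_stop: bool


def _codons_for(peptide: str, rng: random.Random) -> str:
    return "".join(rng.choice(_AA_TO_CODONS[aa]) for aa in peptide)


def _random_peptide(n: int, rng: random.Random) -> str:
    return "".join(rng.choice(_AMINO_ACIDS) for _ in range(n))


def _random_bases(n: int, gc: float, rng: random.Random) -> str:
    weights = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choices("ACGT", weights=weights, k=n))


def _build_insert(
    spec: PlantSpec,
    intron: bool,
    gc: float,
    rng: random.Random,
    signal_codons: int = 20,
    filler_codons: int = 20,
) -> tuple[str, int, int, bool]:
    """Return (insert sequence, decapeptide lo, hi (0-based half-open within
    the insert), premature flag)."""
    signal = "ATG" + _codons_for(_random_peptide(signal_codons - 1, rng), rng)
    intron_seq = ""
    if intron:
        intron_seq = "GT" + _random_bases(rng.randint(80, 200), gc, rng) + "AG"
    filler = [rng.choice(_AA_TO_CODONS[aa]) for aa in _random_peptide(filler_codons, rng)]
    premature = False
    if spec.premature_stop_offset is not None:
        k = spec.premature_stop_offset
        if not 0 <= k < filler_codons:
            raise KissevoError(
                f"{spec.name}: premature stop offset {k} outside filler"
            )
        filler[filler_codons - k - 1] = "TGA"
        premature = True
    decap = _codons_for(spec.decapeptide, rng)
    if spec.motif == "GK-Stop":
        tail = _codons_for("GK", rng) + "TGA"
    else:
        tail = _codons_for(spec.motif, rng) + _codons_for(_random_peptide(3, rng), rng) + "TAA"
    exon2 = "".join(filler) + decap + tail
    insert = signal + intron_seq + exon2
    d_lo = len(signal) + len(intron_seq) + len("".join(filler))
    return insert, d_lo, d_lo + 30, premature


def plant_precursor_sequences(
    plants: Sequence[PlantSpec],
    background_length: int = 100_000,
    gc: float = 0.42,
    intron: bool = True,
    seed: int = 0,
    seq_id: str = "sim_chr1",
    random_strand: bool = True,
) -> tuple[dict[str, str], list[PlantTruth]]:
    """Plant kisspeptin precursor genes into random background sequence.

    Returns ``({seq_id: sequence}, truth)`` where the truth list records the
    exact span, strand, and decapeptide coordinates of every plant. Raises
    :class:`CapacityError` when the background cannot hold all inserts
    without overlap.
    """
    rng = random.Random(seed)
    background = list(_random_bases(background_length, gc, rng))
    occupied: list[tuple[int, int]] = []
    truth: list[PlantTruth] = []
    for spec in plants:
        insert, d_lo, d_hi, premature = _build_insert(spec, intron, gc, rng)
        L = len(insert)
        if L > background_length:
            raise CapacityError(
                f"background of {background_length} nt too short for {spec.name}"
            )
        strand = rng.choice("+-") if random_strand else "+"
        placed = None
        for _ in range(200):
            pos = rng.randrange(0, background_length - L + 1)  # 0-based
            if all(pos + L <= lo or pos >= hi for lo, hi in occupied):
                placed = pos
                break
        if placed is None:
            raise CapacityError(
                f"could not place {spec.name} in {background_length} nt "
                f"after 200 attempts"
            )
        occupied.append((placed, placed + L))
        seq_inserted = insert if strand == "+" else reverse_complement(insert)
        background[placed : placed + L] = list(seq_inserted)
        if strand == "+":
            decap_start = placed + d_lo + 1
            decap_end = placed + d_hi
        else:
            decap_start = placed + (L - d_hi) + 1
            decap_end = placed + (L - d_lo)
        truth.append(
            PlantTruth(
                name=spec.name,
                seq_id=seq_id,
                start=placed + 1,
                end=placed + L,
                strand=strand,
                decapeptide=spec.decapeptide,
                motif=spec.motif,
                decap_start=decap_start,
                decap_end=decap_end,
                premature_stop=premature,
            )
        )
    return {seq_id: "".join(background)}, truth


def truth_to_gff3(truth: Sequence[PlantTruth], path) -> None:
    """Write plant truth records as a GFF3 file."""
    from .formats import format_gff3_attributes

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in truth:
            attrs = {
                "ID": t.name,
                "decapeptide": t.decapeptide,
                "motif": t.motif,
                "decap_start": str(t.decap_start),
                "decap_end": str(t.decap_end),
                "premature_stop": "1" if t.premature_stop else "0",
            }
            fh.write(
                "\t".join(
                    [
                        t.seq_id,
                        "kissevo_sim",
                        "kiss_precursor",
                        str(t.start),
                        str(t.end),
                        ".",
                        t.strand,
                        ".",
                        format_gff3_attributes(attrs),
                    ]
                )
                + "\n"
            )
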