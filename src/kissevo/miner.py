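"""Kp(10)-anchored kisspeptin precursor mining.

Kisspeptin precursor genes are too divergent for whole-precursor homology
search: across vertebrates only the C-terminal decapeptide Kp(10) and its
processing signature are conserved. The miner therefore works from the
sequence alone: it enumerates maximal stop-free open reading frames in all six
frames, scans their translations with a position-specific Kp(10) consensus,
validates the downstream proteolytic-cleavage/alpha-amidation signature
(GKR, GKK, GK-stop, or a bare G-Basic), and records the nearest candidate
splice-acceptor ``AG`` upstream of the ORF as the putative intron 3' boundary
(kisspeptin coding sequence is split over two exons, with Kp(10) on the final
exon).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence, Union

from .errors import KissevoError
from .formats import PathLike, read_fasta

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_BASES = "ACGT"
_CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> None:
    from Bio.Seq import Seq

    for a in _BASES:
        for b in _BASES:
            for c in _BASES:
                codon = a + b + c
                _CODON_TABLE[codon] = str(Seq(codon).translate())


_build_codon_table()

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon; anything outside unambiguous ACGT becomes X.

    ``X`` never satisfies a consensus position, so assembly gaps (N runs) are
    conservatively ignored rather than matched.
    """
    return _CODON_TABLE.get(codon.upper(), "X")


def translate(seq: str) -> str:
    n = len(seq) // 3
    return "".join(translate_codon(seq[3 * i : 3 * i + 3]) for i in range(n))


# ---------------------------------------------------------------------------
# Kp(10) consensus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Kp10Consensus:
    """Position-specific Kp(10) matcher over 10 residues.

    ``allowed`` holds the permitted residues for positions 1..10;
    ``invariant`` names the positions that must match for a window to be
    reported at all; ``min_score`` is the minimum number of positions (out of
    10) whose residue falls in the allowed set.
    """

    allowed: tuple[frozenset[str], ...]
    invariant: frozenset[int]
    min_score: int = 10

    def __post_init__(self) -> None:
        if len(self.allowed) != 10:
            raise KissevoError("consensus must define exactly 10 positions")
        if not self.invariant <= set(range(1, 11)):
            raise KissevoError("invariant positions must lie in 1..10")
        if self.min_score > 10:
            raise KissevoError("min_score cannot exceed 10")

    def relaxed(self, min_score: int) -> "Kp10Consensus":
        return replace(self, min_score=min_score)


def default_consensus(min_score: int = 10) -> Kp10Consensus:
    """Consensus over the observed vertebrate Kp(10) states.

    Positions 2 (N), 4 (N), 6 (F), 7 (G), and 8 (L) are invariant across all
    known decapeptides; the variable positions admit the residue sets observed
    so far: 1 {Y,F}, 3 {W,R,L,F}, 5 {S,P,T}, 9 {R,K}, 10 {Y,F}.
    """
    sets = {
        1: "YF", 2: "N", 3: "WRLF", 4: "N", 5: "SPT",
        6: "F", 7: "G", 8: "L", 9: "RK", 10: "YF",
    }
    return Kp10Consensus(
        allowed=tuple(frozenset(sets[i]) for i in range(1, 11)),
        invariant=frozenset({2, 4, 6, 7, 8}),
        min_score=min_score,
    )


def scan_kp10(peptide: str, consensus: Kp10Consensus) -> list[tuple[int, int]]:
    """Scan a peptide for Kp(10)-like windows.

    Returns ``(offset, score)`` for every 0-based window offset where all
    invariant positions match and the per-position score reaches
    ``consensus.min_score``.
    """
    hits: list[tuple[int, int]] = []
    for off in range(len(peptide) - 9):
        window = peptide[off : off + 10]
        ok = all(window[i - 1] in consensus.allowed[i - 1] for i in consensus.invariant)
        if not ok:
            continue
        score = sum(window[i] in consensus.allowed[i] for i in range(10))
        if score >= consensus.min_score:
            hits.append((off, score))
    return hits


# ---------------------------------------------------------------------------
# ORF enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _LocalOrf:
    """An ORF in strand-local coordinates (0-based half-open nt range)."""

    lo: int
    hi: int
    frame: int
    preceded_by_stop: bool
    terminated_by_stop: bool


def _local_orfs(seq: str, min_length_codons: int) -> list[_LocalOrf]:
    out: list[_LocalOrf] = []
    n = len(seq)
    for frame in range(3):
        start = frame
        preceded = False
        pos = frame
        while pos + 3 <= n:
            codon = seq[pos : pos + 3].upper()
            if codon in STOP_CODONS:
                if pos > start and (pos - start) // 3 >= min_length_codons:
                    out.append(_LocalOrf(start, pos, frame, preceded, True))
                start = pos + 3
                preceded = True
            pos += 3
        if pos > start and (pos - start) // 3 >= min_length_codons:
            out.append(_LocalOrf(start, pos, frame, preceded, False))
    return out


def find_orfs(
    sequence: str, min_length_codons: int = 1
) -> list[tuple[int, int, str, int]]:
    """Enumerate maximal stop-free stretches in all six frames.

    Each ORF runs from the first in-frame position after a stop codon (or the
    sequence edge) to the last complete codon before the next stop (or edge);
    the terminating stop codon is not included. Coordinates are 1-based
    inclusive on the forward strand; ``frame`` is the 0..2 offset in the
    scanned orientation. Codons containing N translate to X and do not
    terminate an ORF.
    """
    if min_length_codons < 1:
        raise KissevoError("min_length_codons must be >= 1")
    if not sequence:
        return []
    n = len(sequence)
    result: list[tuple[int, int, str, int]] = []
    for orf in _local_orfs(sequence, min_length_codons):
        result.append((orf.lo + 1, orf.hi, "+", orf.frame))
    for orf in _local_orfs(reverse_complement(sequence), min_length_codons):
        result.append((n - orf.hi + 1, n - orf.lo, "-", orf.frame))
    result.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    return result


# ---------------------------------------------------------------------------
# Cleavage / amidation signature
# ---------------------------------------------------------------------------

#: Recognized motif classes, strongest first.
CLEAVAGE_MOTIFS = ("GKR", "GKK", "GK-Stop", "G-Basic", "none")


def classify_cleavage(context: str, orf_terminal_stop: bool = False) -> str:
    """Classify the residues immediately following a candidate decapeptide.

    The conserved neuropeptide processing signature is X-G-Basic(-Basic): the
    glycine donates the C-terminal amide, the basic residues are the
    proteolytic cleavage site. ``GKR`` and ``GKK`` are matched explicitly; a
    ``GK`` that runs straight into the ORF-terminal stop codon is ``GK-Stop``;
    any other glycine followed by a single basic residue is ``G-Basic``;
    everything else is ``none``.
    """
    if len(context) >= 3 and context[:3] == "GKR":
        return "GKR"
    if len(context) >= 3 and context[:3] == "GKK":
        return "GKK"
    if context == "GK" and orf_terminal_stop:
        return "GK-Stop"
    if len(context) >= 2 and context[0] == "G" and context[1] in "KR":
        return "G-Basic"
    return "none"


# ---------------------------------------------------------------------------
# Splice context
# ---------------------------------------------------------------------------

def find_splice_context(
    sequence: str, orf_start: int, window: int = 500
) -> Optional[int]:
    """Nearest candidate intron 3' boundary upstream of an ORF.

    Introns obey the GT..AG rule, so an ``AG`` dinucleotide just upstream of
    the ORF marks a plausible splice acceptor for the final (Kp(10)-bearing)
    exon. Returns the 1-based position of the ``A`` of the nearest upstream
    ``AG`` within ``window`` nt, or ``None``.
    """
    if not (1 <= orf_start <= len(sequence)):
        raise KissevoError(f"orf_start {orf_start} outside sequence")
    lo = max(1, orf_start - window)
    for pos in range(orf_start - 2, lo - 1, -1):
        if sequence[pos - 1 : pos + 1].upper() == "AG":
            return pos
    return None


# ---------------------------------------------------------------------------
# Precursor mining
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrecursorCall:
    """A mined kisspeptin precursor candidate.

    ``orf_start``/``orf_end`` are 1-based inclusive nucleotide coordinates on
    the forward strand of ``seq_id`` (for minus-strand calls the interval is
    the forward-strand projection of the ORF). ``decapeptide_offset`` counts
    residues between the ORF 5' end and the decapeptide.
    ``upstream_acceptor_position`` is reported in forward-strand coordinates
    of the base that is the acceptor ``A`` in the reading orientation.
    """

    seq_id: str
    strand: str
    frame: int
    orf_start: int
    orf_end: int
    decapeptide: str
    decapeptide_offset: int
    score: int
    cleavage_motif: str
    upstream_acceptor_position: Optional[int]
    flags: frozenset[str] = frozenset()

    @property
    def orf_length_nt(self) -> int:
        return self.orf_end - self.orf_start + 1


@dataclass(frozen=True)
class MinerParams:
    """Tunable parameters of the mining pipeline.

    ``min_orf_codons``: shortest ORF considered (codons). The shortest
    Kp(10)-bearing ORF observed in real genomes is 27 codons, so 20 keeps a
    margin without flooding the scan with micro-ORFs.
    ``require_cleavage``: suppress calls whose motif classifies as ``none``
    (permissive mode emits them).
    ``acceptor_window``: upstream search window (nt) for the splice acceptor.
    ``premature_stop_max_offset``: a call whose ORF is bounded upstream by an
    in-frame stop codon within this many codons of the decapeptide is flagged
    ``premature_stop``.
    """

    min_orf_codons: int = 20
    require_cleavage: bool = True
    acceptor_window: int = 500
    premature_stop_max_offset: int = 10


def mine_precursors(
    genome: Union[PathLike, Mapping[str, str]],
    consensus: Optional[Kp10Consensus] = None,
    params: Optional[MinerParams] = None,
) -> list[PrecursorCall]:
    """Run the full prediction pipeline over a genome.

    Composition of :func:`find_orfs`, :func:`scan_kp10`,
    :func:`classify_cleavage`, and :func:`find_splice_context`; output is
    deterministic, sorted by ``(seq_id, orf_start, strand, offset)``.
    """
    consensus = consensus or default_consensus()
    params = params or MinerParams()
    if isinstance(genome, (str,)) or hasattr(genome, "__fspath__"):
        sequences = read_fasta(genome)
    else:
        sequences = dict(genome)

    # an ORF shorter than the decapeptide itself can never carry a hit
    min_codons = max(params.min_orf_codons, 10)
    calls: list[PrecursorCall] = []
    for seq_id in sorted(sequences):
        seq = sequences[seq_id].upper()
        n = len(seq)
        for strand in "+-":
            local = seq if strand == "+" else reverse_complement(seq)
            for orf in _local_orfs(local, min_codons):
                peptide = translate(local[orf.lo : orf.hi])
                for offset, score in scan_kp10(peptide, consensus):
                    tail = peptide[offset + 10 :]
                    motif = classify_cleavage(tail[:3] if len(tail) > 2 else tail,
                                              orf.terminated_by_stop and len(tail) == 2)
                    if motif == "none" and params.require_cleavage:
                        continue
                    flags = set()
                    if (
                        orf.preceded_by_stop
                        and offset <= params.premature_stop_max_offset
                    ):
                        flags.add("premature_stop")
                    acceptor_local = find_splice_context(
                        local, orf.lo + 1, params.acceptor_window
                    )
                    if acceptor_local is None:
                        acceptor = None
                    elif strand == "+":
                        acceptor = acceptor_local
                    else:
                        acceptor = n - acceptor_local + 1
                    if strand == "+":
                        start, end = orf.lo + 1, orf.hi
                    else:
                        start, end = n - orf.hi + 1, n - orf.lo
                    calls.append(
                        PrecursorCall(
                            seq_id=seq_id,
                            strand=strand,
                            frame=orf.frame,
                            orf_start=start,
                            orf_end=end,
                            decapeptide=peptide[offset : offset + 10],
                            decapeptide_offset=offset,
                            score=score,
                            cleavage_motif=motif,
                            upstream_acceptor_position=acceptor,
                            flags=frozenset(flags),
                        )
                    )
    calls.sort(
        key=lambda c: (c.seq_id, c.orf_start, c.strand, c.decapeptide_offset)
    )
    return calls


# ---------------------------------------------------------------------------
# Call output
# ---------------------------------------------------------------------------

def write_calls_gff3(calls: Sequence[PrecursorCall], path: PathLike) -> None:
    from .formats import format_gff3_attributes

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(calls, 1):
            attrs = {
                "ID": f"kiss_candidate_{i}",
                "decapeptide": c.decapeptide,
                "cleavage_motif": c.cleavage_motif,
                "score": str(c.score),
                "flags": ",".join(sorted(c.flags)),
            }
            if c.upstream_acceptor_position is not None:
                attrs["upstream_acceptor"] = str(c.upstream_acceptor_position)
            fh.write(
                "\t".join(
                    [
                        c.seq_id,
                        "kissevo",
                        "kiss_precursor_candidate",
                        str(c.orf_start),
                        str(c.orf_end),
                        ".",
                        c.strand,
                        str(c.frame),
                        format_gff3_attributes(attrs),
                    ]
                )
                + "\n"
            )


def write_call_peptides(
    calls: Sequence[PrecursorCall],
    genome: Mapping[str, str],
    path: PathLike,
) -> None:
    """Write the translated ORF of each call as peptide FASTA."""
    from .formats import write_fasta

    out: dict[str, str] = {}
    for i, c in enumerate(calls, 1):
        seq = genome[c.seq_id][c.orf_start - 1 : c.orf_end]
        if c.strand == "-":
            seq = reverse_complement(seq)
        out[f"kiss_candidate_{i}_{c.seq_id}_{c.orf_start}"] = translate(seq)
    write_fasta(out, path)
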