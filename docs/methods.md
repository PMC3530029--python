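# Methods

This note documents the models and procedures implemented in `kissevo`,
the defaults they use and why, and the limits of what the synthetic data
can establish.

## Precursor mining

The miner treats a genome as plain nucleotide sequence and works outward
from the only conserved anchor a kisspeptin precursor offers: the
C-terminal decapeptide Kp(10) and the processing signature that follows it.

**ORF enumeration.** An ORF is a maximal stop-free codon run in one of the
six frames, from the first in-frame position after a stop codon (or the
sequence edge) to the last complete codon before the next stop (or edge).
The terminating stop codon is not part of the reported interval; published
ORF lengths sometimes include it, so none of the packaged tests depend on
that convention. Codons containing N (or any non-ACGT symbol) translate to
`X` and do not terminate an ORF: an assembly gap should neither split an
ORF nor ever satisfy a consensus position.

**Kp(10) consensus.** The default matcher encodes the residue states
observed across known vertebrate decapeptides: positions 2, 4, 6, 7, 8 are
invariant (N, N, F, G, L) and must match for a window to be considered;
positions 1 {Y,F}, 3 {W,R,L,F}, 5 {S,P,T}, 9 {R,K}, 10 {Y,F} are scored.
`min_score` defaults to 10 (all positions within the observed sets) and is
relaxable — `default_consensus(min_score=9)` admits one excursion outside
the observed sets, which is how a genuinely novel residue (the kind of
state that expanded the sets in the first place, e.g. an arginine at
position 3) would be found in a new genome. At full stringency the scan
produces no false calls on 100 kb of i.i.d. background.

**Cleavage/amidation signature.** Mature neuropeptides are released by
cleavage at basic residues and amidated from a following glycine, giving
X-G-Basic(-Basic). Classification is exact-match and ordered: `GKR`, `GKK`,
then `GK` running directly into the ORF-terminal stop (`GK-Stop`), then any
glycine followed by one basic residue (`G-Basic`), else `none`. Calls
classified `none` are suppressed by default because the signature is what
separates a chance consensus match from a processable precursor; permissive
mode (`require_cleavage=False`) emits them for exploratory scans.

**Splice context.** The Kp(10)-coding exon is the final exon of a two-exon
coding sequence, so a plausible intron 3′ boundary — the nearest upstream
`AG` — is reported with each call. The search window defaults to 500 nt
upstream of the ORF, comfortably covering the 81–396 bp range of reported
Kp(10)-bearing ORFs; no window size is prescribed by the underlying
biology, so the value is configurable.

**Premature stops.** A call is flagged `premature_stop` when its ORF is
bounded upstream by an in-frame stop codon within 10 codons of the
decapeptide (the reported coelacanth *Kiss3* case sits at 7). The flag is
descriptive only: such a gene may be a pseudogene or may simply have an
unusual exon structure, and the miner does not decide.

Coordinates in calls are always 1-based inclusive on the forward strand;
minus-strand calls report the forward-strand projection of the ORF, which
makes mining strand-symmetric: mining the reverse complement yields the
same calls with strands flipped and coordinates mirrored. Output ordering
is deterministic, sorted by (seq_id, orf_start, strand, offset).

## Microsynteny and paralogons

Within-genome paralogon detection is family-based. Every gene with a family
assignment seeds a neighborhood of k genes per side (default k = 15);
overlapping windows on one chromosome are merged so a physical region
enters the graph once. Windows are counted in genes, not base pairs,
because gene-order maps are robust to the very different assembly spans of
the genomes compared (chromosome-scale human versus scaffold-scale
coelacanth). Two regions are linked when they share at least τ gene
families; τ defaults to 2 because the weakest region link in the packaged
data (the Kiss3-type regions, sharing three families) must pass while
single-family links are indistinguishable from chance. Paralogons are the
connected components with ≥ 2 regions, ordered deterministically by their
leftmost region. Genes with no family assignment are carried through every
container but are invisible to scoring.

**Classification.** A query gene is labeled by the reference neighborhood
sharing the most families with it, excluding the query's own family (a
shared kisspeptin locus must not count as evidence for itself). The label
is accepted only when the best score reaches τ and beats the runner-up
label by at least 1; ties and sub-threshold scores return *unclassified*.
A gene alone on a mini-scaffold therefore scores zero everywhere and comes
back unclassified rather than raising — the realistic outcome for genes on
fragmentary assemblies.

**Post-WGD duplicate detection.** Comparing a 3R genome against an
unduplicated outgroup, each derived region is assigned to the outgroup
region with which it shares the most families, requiring a unique maximum
of at least τ. Best-hit assignment (rather than thresholding alone) is
deliberate: paralogous regions share families *by construction*, so a
derived region typically clears τ against several outgroup regions, and
only the maximum identifies its orthologous source; ambiguous maxima are
dropped rather than guessed. Outgroup regions claimed by two or more
derived regions are reported as WGD pairs together with the families
present in the outgroup region but missing from one or both copies — which
is how the loss of every 3R *Kissr* duplicate shows up.

The four receptor clades are reported as an unresolved polytomy: resolving
the 2R sister pairs requires an external gene phylogeny of a neighboring
family and is out of scope here.

## Dollo loss reconstruction

Each gene lineage is assumed gained exactly once — by default on the
post-2R stem, i.e. the root branch of the packaged tree — and never
regained; this matches how copy-number evolution after a WGD is reasoned
about, where independent re-gain is not a biologically available move. The
minimum-loss scenario under a single origin is unique and computed in
closed form: an internal node is *present* iff some descendant leaf is
present, and a loss is charged to every branch whose parent is present but
whose own subtree contains no present leaf. The test suite verifies this
closed form against exhaustive minimization over loss-branch subsets on
200 random trees of up to 8 leaves.

Unknown cells are uninformative, not imputed: a subtree containing only
unknowns neither forces presence above it nor gets charged a loss (the
partially sequenced chondrichthyan situation). A lineage observed in no
sampled species (the fourth *Kiss* lineage) cannot be localized by the
matrix at all; it is reported as an annotation — lost before or at the
emergence of the sampled clade — never as a computed branch.

Expected copy numbers are 2^(#WGD on the root-to-leaf path), read from
`[&wgd=...]` newick branch comments; the scenario report tabulates
per-species observed counts per gene group, per-clade maxima, and deficits
against that expectation.

## Synthetic data

`simulate_wgd_history` evolves one ancestral region down the tree. On each
branch the branch's WGD events fire first, each doubling every surviving
region onto a fresh region id (`-1Ra`/`-1Rb` suffixes keep truth
traceable); then every gene copy is deleted independently with probability
`loss_prob`. Losses act on gene copies, never on whole regions, matching a
per-gene loss narrative; region-scale deletion is intentionally not
modeled. The event log is complete: replaying it from the ancestral state
reproduces the final annotations exactly, and the same seed always yields
the same history.

`plant_precursor_sequences` writes precursors as signal-peptide-like exon
(20 codons, ATG-initial), an optional GT..AG intron of 80–200 nt, and a
final exon of 20 filler codons, the decapeptide, and its motif followed by
a stop. Background is i.i.d. sequence at a configurable GC fraction
(default 0.42, a typical vertebrate bulk value). The generator emulates the
features the miner keys on — frame structure, signature context, splice
boundaries, both strands — and nothing else: no substitution process, no
repeats, no pseudogene decay, no realistic intergenic architecture.
Passing tests on planted genomes therefore establish the miner's
bookkeeping (recall on clean plants, strand symmetry, specificity against
random background), not its performance on real assemblies with repeats
and degenerate motifs.

Problem sizes in the packaged tests and the acceptance script — 50–100 kb
backgrounds, 12–20-family ancestral regions, 200 Dollo oracle trials at
≤ 8 leaves — were chosen as the smallest instances that exercise every
code path several times over; all results are size-stable well below these
values.

## Fixtures

The packaged fixtures transcribe the published analyses: family/region
memberships of the 8-family receptor tetra-paralogon and the 11-family
kisspeptin tetra-paralogon, the ten-species inventory, the WGD-annotated
tree, and the eight newly predicted decapeptides with motifs. Two caveats
are recorded in the files' provenance headers. First, the per-gene
locations are not available in machine-readable form, so fixture coordinates
are schematic (order-preserving, evenly spaced) and a few member symbols
are family placeholders; every quantity the package computes from these
fixtures depends only on membership and order, not on physical
coordinates. Second, the previously-known Kp(10) reference set is
reconstructed from the cited primary literature because the original
alignment is not available in machine-readable form; it is constrained to reproduce the published novelty
classification (four of the eight predictions novel, flagged per sequence).

One inconsistency in the source material is resolved in favor of the
loss-history account: the amphibian receptor complement is taken as
Kissr-1/-2/-3 (with Kissr-4 lost on the amphibian branch), which matches
the clade assignments and the loss narrative, over a passing remark
mapping a *Xenopus* receptor to Kissr-4.

## Known limitations

- The miner predicts the Kp(10)-bearing ORF only; it does not reconstruct
  the signal-peptide exon across the intron, delineate the mature Kp(54)
  or Kp(14) forms, or run homology search against external databases.
- Family-based synteny cannot separate tandem paralogs inside one
  neighborhood, and classification inherits whatever errors the input
  family assignments contain.
- Dollo reconstruction reports *a* minimum; where several loss placements
  tie (possible with sparse taxon sampling), the reconstruction is the
  canonical all-or-nothing one and ties are not enumerated.
- Proto-chromosome assignment of paralogons and probabilistic
  birth–death models of gene content are out of scope.
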