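# kissevo

Tools for reconstructing the evolutionary history of the vertebrate
kisspeptin system — the *Kiss* genes encoding kisspeptin precursors and the
*Kissr*/GPR54 genes encoding their receptors — from genomic sequence, gene
annotations, and a species tree.

The package is aimed at comparative genomicists and endocrinologists who
want to (i) locate kisspeptin precursor genes in newly sequenced genomes,
(ii) test whether a set of *Kiss*/*Kissr* loci descends from a single
pre-vertebrate ancestor through the two rounds of whole-genome duplication
(1R/2R) and the teleost-specific third round (3R), and (iii) reconstruct
when each gene lineage was lost across the vertebrate radiation.

## What it computes

**Kp(10)-anchored precursor mining.** Kisspeptin precursors are too
divergent for whole-precursor homology search; only the C-terminal
decapeptide Kp(10) — the minimal receptor-activating sequence — and its
processing signature are conserved. The miner enumerates all maximal
stop-free ORFs in six frames, scans translations with a position-specific
consensus over the ten Kp(10) positions (invariant N2, N4, F6, G7, L8;
observed sets at the variable positions), requires the downstream
cleavage/α-amidation signature X-G-Basic(-Basic) (GKR, GKK, GK-stop, or
G-Basic), and reports the nearest upstream `AG` splice acceptor, since the
Kp(10)-coding exon is the final exon of a two-exon coding sequence.

**Paralogon detection by microsynteny.** A *paralogon* is a set of regions
within one genome descended from one ancestral region via WGD. Regions are
k-gene neighborhoods around family-assigned loci, merged when co-linear;
two regions are linked when they share ≥ τ paralogous gene families
(default τ = 2); paralogons are connected components of the region graph.
The same scoring classifies a query gene into the Kiss1–4 / Kissr-1–4
nomenclature by its best-matching labeled reference neighborhood, and
detects post-3R duplicated region pairs against an unduplicated outgroup
genome, listing the anchor families (including *Kissr* itself) missing from
the duplicate copies.

**Dollo-parsimony loss histories.** Given a species × gene-lineage
presence/absence matrix and a rooted species tree whose branches carry WGD
annotations (`[&wgd=1R,2R]` newick comments), each lineage is assumed
gained once (on the post-2R vertebrate stem by default) and lost any number
of times, never regained. The unique minimum-loss scenario has a closed
form: a branch is charged a loss exactly when its subtree contains an
observed absence but no presence while its parent subtree contains one.
Expected copy numbers are 2^(#WGDs on the root-to-leaf path) — 4 after
1R+2R, 8 after 3R — and the report tabulates observed counts and deficits.

**Ground-truth simulation.** A generator evolves an ancestral gene region
down the tree (each WGD doubles every region; every gene copy is lost
independently per branch with probability `loss_prob`) and emits per-leaf
annotations plus a replayable event log; a second generator plants
precursor genes (signal exon, GT..AG intron, final exon with decapeptide +
motif) into random background sequence with exact truth coordinates.

## Worked example

Plant the three coelacanth decapeptides reported in the literature
(YNWNTFGLRY and FNFNPFGLRF followed by GKR; FNWNSFGLRF followed by GKK,
with a stop codon seven residues upstream) and mine them back:

```python
import kissevo as kv

plants = [
    kv.PlantSpec("coelacanth_Kp1", "YNWNTFGLRY", "GKR"),
    kv.PlantSpec("coelacanth_Kp2", "FNFNPFGLRF", "GKR"),
    kv.PlantSpec("coelacanth_Kp3", "FNWNSFGLRF", "GKK", premature_stop_offset=7),
]
fasta, truth = kv.plant_precursor_sequences(plants, background_length=50_000, seed=7)
for c in kv.mine_precursors(fasta):
    print(f"{c.seq_id}:{c.orf_start}-{c.orf_end} ({c.strand}) {c.decapeptide} "
          f"motif={c.cleavage_motif} offset={c.decapeptide_offset} "
          f"flags={sorted(c.flags) or '-'}")

matrix = kv.load_fixture("presence_matrix")
tree = kv.load_fixture("species_tree")
sc = kv.dollo_losses(matrix, tree, "osteichthyans", "Kissr-4")
print("Kissr-4 losses:", ", ".join(sc.losses))
```

which prints:

```
sim_chr1:21469-21537 (-) FNWNSFGLRF motif=GKK offset=7 flags=['premature_stop']
sim_chr1:23029-23136 (+) YNWNTFGLRY motif=GKR offset=20 flags=-
sim_chr1:33060-33209 (+) FNFNPFGLRF motif=GKR offset=34 flags=-
Kissr-4 losses: teleosts, xenopus, chicken, human
```

All three planted decapeptides are recovered with their correct motifs; the
third call is flagged `premature_stop` because its ORF is bounded upstream
by an in-frame stop only seven codons before the decapeptide. The Dollo
reconstruction places the four *Kissr-4* losses on the teleost stem and the
amphibian, bird, and eutherian branches — *Kissr-4* survives only in
spotted gar, coelacanth, lizard, and platypus.

A command-line interface mirrors the library
(`kissevo mine|paralogon|classify|dollo|simulate|run`; see `--help`).

## Packaged fixtures

`kissevo.load_fixture(name)` returns checksummed, plain-text transcriptions
of the published analyses: the 8-family *Kissr* and 11-family *Kiss*
tetra-paralogon memberships (`kissr_synteny`, `kiss_synteny`), the
ten-species gene inventory (`presence_matrix`), the WGD-annotated species
tree (`species_tree`), the Kp(10) reference alignment with novelty flags
(`kp10_reference`), and the eight newly predicted decapeptides with their
motifs (`predicted_kp10`). Each file carries a provenance header.

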