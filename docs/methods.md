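# Methods

## The annotation model

An NLR locus is modelled as a *motif chain*: an ordered run of short
conserved amino-acid motifs — coiled-coil (CC) motifs, nucleotide-binding
(NB) motifs of which one is the Walker-A P-loop and one the NB-ARC start,
and leucine-rich-repeat (LRR) motifs — encoded on one strand of a contig.
Scanning translates all six reading frames and reports every window
whose match count reaches the motif's threshold; same-strand hits within
a chaining gap (default 3000 bp) form a locus. Because NLRs cluster
tandemly, a chain is split before a new P-loop hit once the running
chain already contains an LRR hit: the minimal grammar that separates
adjacent gene copies sharing a contig. Completeness follows the
field-standard definition — P-loop + NB-ARC start + ≥ 1 LRR motif — and
pseudogene evidence is restricted to what the motif span itself shows:
an in-frame stop codon, or adjacent same-strand hits in incompatible
codon phases (the footprint of a frameshift). No finer gene-model
evidence is consulted.

The motif library is exchangeable input: consensus peptides with
per-motif mismatch budgets, with category tags and the two designated NB
flags. The package generates a synthetic library for testing; a real
motif set in the same format (consensus TSV) can be substituted.

## One identity definition

Every percent identity in the package is computed the same way:
edlib-backed alignment, identity = matching columns / alignment columns.
Contig de-redundancy, the rescue rule, orthologue and expression screens
use the *semi-global* (end-gap-free) form — the shorter sequence aligned
into the longer, terminal overhangs free — because capture-derived
contigs and transcripts differ mainly by end truncation; a contig wholly
contained in a longer one at high identity is redundant. Phylogenetic
p-distances use the global form (mismatches over aligned non-gap
columns). Two operations need gap *structure* rather than distance —
transcript-to-genome splice inference and private-indel calling — and
use an affine-gap global alignment (match +2, mismatch −3, open −10,
extend −0.5) instead, because a unit-cost edit distance scatters a long
gap whenever a few gap bases coincidentally match flanking sequence.

## Protein inference

A locus is extended by ±3000 bp (clipped at contig bounds), the best
homolog is chosen from a supplied protein set (highest translated
identity, ties by longer homolog coverage, then lexicographic id), and
the CDS is the ATG..stop ORF — with at most one GT..AG intron of
40–400 bp, searched only when the intronless reading stays below 99%
identity — whose translation best matches the homolog. Semi-global
identity is blind to an upstream in-frame ATG (the overhang aligns
free), so the start codon is refined afterwards with a global alignment,
which penalizes both overhang and truncation. Loci whose best homolog
falls below 40% identity are flagged unpredicted rather than fatal.

## Classification and screens

Domain annotations from two sources are merged per protein after an
e-value ≤ 1e-3 gate; same-name overlapping intervals take their union.
Names are normalized through a small alias map (Rx_N → CC, LRR_* → LRR)
because different annotation tools use different vocabularies. Proteins
without NB-ARC are rejected; composition over {CC, NB-ARC, LRR} yields
CNL/NL/CN/N, any other domain yields NLR-ID, and each integrated domain
is placed at the N or C terminal relative to the NB-ARC span
(overlapping = ambiguous). Class percentages are rounded half-up to one
decimal. Adjacent loci within 10 kb on one contig are paired; opposite
strands with facing 5' ends are head-to-head, facing 3' ends
tail-to-tail, same strand tandem.

Homoeologous-group assignment keeps the best hit per related genome
(bitscore, then identity, then lexicographic chromosome) and takes the
majority of chromosome numbers, with "Un" abstaining and ties left
unassigned. The orthologue screen requires > 80% identity, > 60%
coverage *and* the same homoeologous group as the query R gene; the
expression screen requires > 95% identity and > 90% coverage of the
locus CDS. Both thresholds are strict inequalities, so a candidate at
exactly 80.0% fails. Splice comparison operates on exon-boundary lists
(predicted vs transcript-implied), not raw alignments, making it robust
to point errors inside exons; the pipeline allows a 3-bp boundary
tolerance for alignment-equivalent junction placements.

## Phylogeny

Trees are built from the NB-ARC domain only, the one region alignable
across the family. Distances are pairwise-alignment p-distances — no
multiple alignment is computed; supplying pre-aligned (equal-length)
sequences overrides this. Neighbor joining is the classical Saitou–Nei
algorithm with two numerical conventions: Q-criterion ties are broken by
the lexicographically smallest pair of cluster labels (runs are thereby
reproducible and leaf-order invariant), and negative branch-length
estimates are clamped to zero with a flag on the tree. For additive
matrices the reconstruction is exact (path-length error < 1e-9 in the
test suite, machine precision in practice).

Bootstrap resampling needs columns, so the sequences are threaded onto
the coordinates of the longest input via pairwise alignment
(insertions relative to that reference are dropped). Replicates
re-weight per-pair mismatch/shared-column counts with a multinomial
column draw, which makes a 1000-replicate bootstrap a matrix-vector
product per replicate rather than a re-alignment. Support is the
percentage of replicate trees containing each internal bipartition.
The dropped-insertion simplification means columns private to shorter
sequences never contribute; for the conserved NB-ARC domain this loses
little signal, but supports on clades defined by long insertions would
be understated.

## The synthetic generator

The generator emulates what matters to the pipeline's logic, not
sequencing physics. Motifs are planted as exact amino-acid substrings
(detection difficulty comes only from configured mutations, keeping
truth unambiguous); background is i.i.d. at 45% GC, so motif false
positives are essentially impossible (a 14-mer with 2 allowed
mismatches has random-hit probability ~1e-13 per window) and specificity
on real, repeat-rich DNA is *not* demonstrated by these tests.
Pseudogenes use the two simplest realizations — one spacer codon
replaced by TAA, or a 1–2 bp deletion mid-chain. Partial loci omit
either the LRR block or the CC/NB head. Integrated-domain fusions append
an ID-category motif at the N or C side of complete chains. Tandem
contigs carry two chains separated by more than the chaining gap;
near-duplicate contigs are copies mutated to a configured identity
(default 97%). At most one intron is planted per locus, placed between
the first two motifs, with length a multiple of 3 and no stop codon in
the interrupted frame — so an unspliced reading stays open and the
frame-consistency pseudogene evidence stays specific to planted
frameshifts. Real introns do not respect these constraints; intron
*discovery* generality is therefore limited to what the homology search
can recover. Coordinates are 0-based half-open internally, converted at
I/O boundaries (GFF3 is 1-based inclusive).

Reference-hit tables place each locus's best hit on chromosome
`<group><genome letter>` per related genome; a configured fraction of
loci on arm 4VL receive group-7 chromosomes in all genomes, emulating an
ancestral 4L/7S translocation absent from the query species.
Transcripts are spliced CDSs of complete loci with i.i.d. substitution
errors. All randomness derives from one seed; identical configurations
give byte-identical outputs.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| dedup identity | 95% | greedy clustering threshold (percent) |
| rescue bounds | 95–99% | complete-NLR identity window for re-inclusion |
| DUST window / threshold | 64 / 2.0 | low-complexity soft-masking |
| chaining gap | 3000 bp | max same-strand hit gap inside a locus |
| flank | 3000 bp | locus extension before protein inference |
| homolog floor | 40% | below this, locus flagged unpredicted |
| e-value gate | 1e-3 | domain-annotation filter |
| pairing separation | 10 kb | max distance for linked-NLR pairs |
| orthologue screen | >80% / >60% | identity / coverage vs cloned R gene |
| expression screen | >95% / >90% | identity / coverage vs transcript |
| private indel min | 3 bp | marker-candidate indel length |
| bootstrap replicates | 1000 | reducible from the CLI |

## Problem sizes

The default pipeline run plants 30 loci on 40 contigs (6–14 kb) and
completes in a few seconds; the recovery experiment in the acceptance
script uses 200 loci on 220 contigs with pseudogene/partial/ID/tandem
rates of 0.2/0.15/0.1/0.1 and a 4VL discordance fraction of 0.5 —
scales at which every stage's behavior is exercised, chosen as
desk-scale stand-ins for a full enrichment assembly of ~1500 contigs.

## Known limitations

* TIR-domain NLRs are out of scope (monocot-style catalogs: TIR-motif
  carriers are still classed CNL when a CC is detected).
* The built-in domain caller is a coarse consensus scanner; on real
  proteins an HMM-based annotation (imported through the same TSV
  interface) should replace it.
* Gene models allow at most one intron and no UTRs or isoforms.
* Interspersed-repeat masking is reduced to low-complexity masking; a
  pre-masked FASTA can be supplied instead.
* Clade naming on the tree is left to the user; the package emits the
  Newick tree and motif-profile sidecar for display tools.
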