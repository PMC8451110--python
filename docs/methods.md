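# Methods

This note documents the models and procedures implemented in `nsltpkit`,
the defaults they ship with, and the reasoning behind the genuinely open
design choices.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Motif model and screening funnel

The family's diagnostic backbone is the eight-cysteine motif (8CM),
C-Xn-C-Xn-CC-Xn-CXC-Xn-C-Xn-C.  A motif placement is an 8-tuple of
cysteine positions in which C3/C4 are adjacent, exactly one residue
separates C5 and C6, and the five free gaps g1..g5 fall inside
configured bounds.  The default bounds, [2,40] [2,50] [2,60] [2,50]
[2,40] with a 160-residue maximum span, are deliberately generous:
screening should admit every spacing architecture present in the
catalog, and discrimination between types belongs to classification.
The scanner enumerates cysteine positions with bound pruning and is
tested against a brute-force oracle that checks all cysteine 8-subsets.
When several placements exist, the canonical one is the leftmost start,
then the smallest span.

Stages run in a fixed order — 8CM, signal sequence, GPI flagging,
proline-rich exclusion, storage-protein similarity, optional mature-length
cap — and a protein is charged to the *first* stage it fails, which makes
the funnel report conservative by construction (input = accepted + Σ
excluded, exactly).

**Signal sequences and GPI anchors.**  Production annotation uses neural
predictors for both signals; here they are transparent hydrophobicity
heuristics with override hooks (an annotations table of per-protein
cleavage/ω calls wins verbatim), so external predictions can be
injected without touching the pipeline.  The NSS heuristic takes the
first window of `nss_min_hydrophobic_run` (8) residues with mean
Kyte–Doolittle ≥ 1.5 that starts within the first 12 residues, and
places cleavage at the first small residue (A/G/S/C) after it.  The GPI
heuristic requires the C-terminal 25 residues to average KD ≥ 1.0 with
an ω-site candidate (S/G/A/N/D/C) 20–30 residues from the C-terminus;
the candidate nearest the C-terminus wins.  GPI-positive proteins are
*retained* and flagged — they are the type G members — and their mature
chain is truncated at ω−1.

The proline-rich rule inspects the segment strictly between the
cleavage site and C1: length ≥ 15 with (P+H+G)/length ≥ 0.35 excludes.
Storage-protein/inhibitor similarity is global-alignment identity ≥ 30%
to any sequence in a user-supplied exemplar set (none by default).  The
mature-length cap is **off** by default: the catalog itself contains
mature lengths up to 200 aa, so a hard cap of 120 would reject
catalogued members; it remains available as configuration.

## Physicochemistry

All five descriptors follow ExPASy/ProtParam conventions: average (not
monoisotopic) residue masses; net charge as the Henderson–Hasselbalch
sum over the Bjellqvist pKa set, including the residue-specific N- and
C-terminal values; pI by bisection on [0, 14] until |charge| < 1e-4
(net charge is strictly decreasing in pH, so the zero is unique — note
the stopping rule is on charge, which for weakly buffered peptides
leaves ~1e-3 pH of slack); the Guruprasad instability index
(10/L × Σ dipeptide weights); the Ikai aliphatic index; and GRAVY as the
mean Kyte–Doolittle score.  The published constant tables are taken from
Biopython's data modules at run time rather than re-transcribed.
Unknown residues ('X') use a documented neutral fallback: mass = mean of
the 20 standard residues, KD = 0, dipeptide weight 1.0, no ionizable
group.  Cohort summaries round at catalog precision (Mw to 1 Da, pI to
2 dp, length to integers) so printed means can be compared exactly.

The packaged catalog records the published per-protein values; whether
those were computed on precursor or mature chains is ambiguous in the
source material, so the package computes profiles for whatever sequence
it is given and the catalog is kept as data, not re-derived.

## Classification

Type assignment is a rule cascade: (1) GPI-positive ⇒ type G;
(2) otherwise the candidate types are the profiles whose g1..g5 ranges
all contain the spacing vector *and* whose intron expectation matches
the linked gene model (when a model is available — protein-only mode
simply drops the intron clause); (3) ties break by highest mean global
identity to the profile's exemplars, then by the lexicographically
smallest label; (4) no admissible profile, or best exemplar identity
below 30% where exemplars decide, ⇒ X.  Confidence is the mean exemplar
identity, 0.0 when typed by rules alone.

The shipped spacing ranges (`data/type_profiles.yaml`) follow the
Edstam-style classification literature; the source material prints no
numeric ranges, so these are editable configuration, not ground truth.
They are pairwise separable for types 1/2/D (each pair disjoint in at
least one gap), while type G overlaps type 1 in spacing — intentionally,
since G is decided by GPI status and its two-intron structure.

The 8CM alignment anchors the eight cysteines as fixed columns and
right-pads each free gap block to its per-cohort maximum width, so
cysteine columns are conserved by construction and alignment width is
8 + Σ max block widths + 1 (the CXC X column).  CXC polarity is
hydrophobic iff KD(X) > 0.

## Phylogeny

Distances are p-distances with pairwise deletion of gapped columns
(complete deletion is available); a pair with no comparable columns is
an error, except inside bootstrap replicates where it maps to the
maximum distance 1.0 (a resample can drop all shared columns).  Trees
are built with Saitou–Nei neighbour-joining: standard Q-criterion,
deterministic tie-breaks (smallest Q, then the lexicographically
smallest pair of subtree labels), negative branch lengths clamped to 0.
NJ is exact on additive matrices, which the tests exploit: random
additive trees (n ≤ 12) must be recovered with their bipartitions and
path lengths intact.  Bootstrap support resamples alignment columns
with replacement; each replicate's RNG stream is derived from the master
seed and the replicate index, so supports are reproducible and
independent of evaluation order.  Two-taxon input yields the unique
trivial tree with a warning.

## Genome context

GFF3 is 1-based inclusive on disk and converted to 0-based half-open
intervals at the I/O boundary; all emitted positions are 1-based again.
Intron positions are reported as bp offsets from the first base of the
8th-Cys codon, measured along the spliced transcript, with negative
values upstream of that codon — the offsets observed in this family lie
in the −9..104 bp band.  Computing offsets in transcript coordinates
makes them invariant under reflecting a locus to the opposite strand,
which the tests check explicitly.

Tandem duplication follows the usual gene-family convention: protein
identity ≥ 50%, same chromosome, separation ≤ 100 kb and ≤ 5 intervening
family genes; clusters are connected components of the tandem relation.
High-identity pairs failing the geometry are reported as *segmental
candidates* — confirming segmental events needs synteny blocks, which is
out of scope.  The synthetic GFF3 writer emits phase 0 for every CDS
segment; phase is not consumed by any reader in this package.

## Promoters

The promoter window is the 1.5 kb immediately upstream of the
*translation* start (ATG anchor), strand-aware and truncated with a
warning at contig edges.  Scanning matches IUPAC-degenerate consensus
strings at every position on both strands; a genomic 'N' matches
nothing; palindromic double-hits with identical footprints collapse to
strand "±"; overlapping hits are all reported and downstream counting
dedups by footprint.  The element catalog
(`data/plantcare.yaml`) follows the public PlantCARE motif collection
and is plain editable YAML — configuration, not an asserted result.

## Expression

2^−ΔΔCt: technical replicates are averaged per biological sample,
ΔCt = Ct(target) − Ct(reference gene), ΔΔCt subtracts the gene's mean
calibrator ΔCt, and the reported fold change is 2^−mean(ΔΔCt) over
biological replicates — subtracting means (not averaging differences)
so the calibrator condition is *exactly* 1.  The standard error is taken
over biological replicates only.  Significance versus the calibrator is
a two-sided Welch t-test on ΔCt values — the source material shows
significance stars without naming a test, so this is a documented
assumption (★★ p<0.01, ★ p<0.05, ns otherwise).  Primer-efficiency
correction is not modelled.  Heatmap display uses log2(x+1), optional
per-row z-scores (zero-variance rows map to 0; output is always finite)
and average-linkage correlation clustering for row order only.  A gene
is "specific" to tissues holding ≥ 50% of its row total; rows entirely
below 1 FPKM are "not expressed".

## Synthetic cohorts

The generator emits candidate proteins, a genome with GFF3 gene models,
promoters and expression tables, cross-referenced by a truth manifest.
Its defaults mirror the published barley family structure: 16/5/11/8
genes of types 1/2/D/G; decoys of 107 cysteine-deficient, 11
signal-less and 2 proline-rich proteins (160 candidates in all); seven
chromosomes with 11 genes on chromosome 2, one on chromosome 6 and one
unplaced gene; six tandem clusters and one segmental pair; introns per
type (1: one at +30 bp; 2: none; D: three carriers at +15 bp; G: two at
−9 and +60 bp, all within the −9..104 band); 1.5 kb promoters with 3–6
planted catalog elements; an FPKM matrix over 16 tissues with one
silent tissue and tissue-specific type 1/2 rows; and qPCR tables at
fold changes 0.25/4.0/2.0 for cold/drought/salt with Gaussian Ct noise
σ = 0.1, 3 biological × 3 technical replicates.

Two divergence scales are modelled.  Members of one type derive from a
per-type ancestral sequence at 0.5 substitutions/site over gap and tail
content, while duplicate copies diverge from their cluster base at only
0.08.  The 0.5 default was chosen by scanning 0.35–0.55 against two
constraints that real families satisfy simultaneously: types must form
clades in the NJ tree (within-type similarity), yet non-duplicate
same-type identity must stay below the 50% duplication cutoff so only
the planted duplication events are called.  At 0.5 both hold with
margin across seeds.

All randomness flows from one master seed through named substreams
(proteins, decoys, genome, promoters, expression, mutation), so adding
a stage never perturbs another stage's output and identical seeds give
byte-identical bundles.

What the generator does **not** emulate: codon usage (back-translation
uses a fixed most-frequent-codon table), GC content (background is
i.i.d. uniform ACGT), UTRs and alternative transcripts, within-signal
sequence families, read-level RNA-seq, or primer effects.  Passing
tests on synthetic data therefore demonstrate the *algorithms'*
correctness and recovery behaviour under the stated noise models, not
performance on real proteomes, where signal-peptide and GPI calls in
particular should come from dedicated predictors via the override
table.

## Problem sizes used in the shipped analyses

The acceptance script analyses the default 160-candidate cohort, 50
random additive trees (n ≤ 12), a 12-taxon 4-type cohort with 1,000
bootstrap replicates, and 200 qPCR trials; the test suite additionally
runs a 500-sequence motif-scanner oracle comparison and a
1,000-cohort funnel-conservation sweep.  These sizes keep the full
suite comfortably fast while exercising every code path at the scale of
the real family.
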