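# Methods

## Scope and data model

plastocomp compares annotated organelle genomes of closely related
species (≥2 species, ≥2 specimens per species) and reports where their
variation lies and which of it is diagnostic.  Internally all
coordinates are 0-based half-open; every report and on-disk format
(GenBank, GFF3, the TSV tables) uses 1-based inclusive coordinates, and
the conversion happens only at the I/O boundary.  Sequences are over
{A,C,G,T,N}; any other ambiguity code is rejected at parse time, because
the downstream scoring rules need a crisp notion of "same allele" and a
silent R or Y would corrupt it.  N is treated as missing data
throughout.

## Quadripartite structure

The plastome's architecture — large single-copy (LSC), inverted repeat
a (IRa), small single-copy (SSC), inverted repeat b (IRb) — is detected
as the longest pair of disjoint intervals whose sequences are exact
reverse complements, with length ≥ `min_ir` (default 1000 bp; plastid
IRs are ~25 kb, and 1000 avoids spurious short repeats).  Matching is
exact by default because repeat homogenization keeps real IR copies
identical; an optional `max_mismatch` budget merges exact runs across
isolated substitutions for degraded assemblies.  The implementation
seeds 24-mer matches between the genome and its reverse complement,
groups them by diagonal, and extends runs — the same result as a
quadratic scan over interval pairs, which the test suite uses as an
oracle on small instances.  The longer of the two arcs between the
repeats is the LSC; IRa is the copy that follows the LSC in circular
order.  Arcs may wrap the sequence origin and are stored with modular
(start, end) semantics.  If no qualifying repeat exists the structure is
flagged `no_ir` with the LSC covering the whole circle — this is how
linear inputs such as the rRNA cluster flow through the same pipeline.

Everything downstream (regions, variation, SSM, SSR) operates on the
single-copy regions plus IRa only; IRb is dropped so duplicated loci
are counted once.

## Regions and homology

Each genome is decomposed into coding regions (CDS/tRNA/rRNA, sequence
reported in annotated strand orientation), introns (derived from the
gaps between a feature's exon parts, numbered in transcription order)
and intergenic spacers (genome orientation, named `left-right` by
ascending coordinate; gaps at the analysed arc's edges use `start`/
`end` as the missing flank).  Abutting genes produce no spacer;
overlapping genes produce no spacer and a logged notice, with the
overlap belonging to both gene regions.  The trans-spliced rps12 gene
is modelled as two independently named sub-regions (`rps12.5p`,
`rps12.3p`) rather than a concatenated virtual CDS, keeping every
region a set of genuine genomic intervals.  Homology across specimens
is by region name only — appropriate for congeneric, collinear
plastomes; rearrangement-aware homology is out of scope.  A region
missing in any specimen is excluded (logged); duplicate names within
one specimen indicate that both IR copies are present and raise an
error instructing IRb removal.

## Alignment

The built-in aligner is deliberately simple and deterministic: global
pairwise Needleman–Wunsch with affine gaps (match +1, mismatch −1, gap
open −4, gap extend −1; the Biopython `PairwiseAligner` kernel),
applied progressively in input order against the majority consensus of
the growing alignment.  For conspecific organelle regions (>98%
identity) this recovers the same events as a production MSA tool; for
anything more divergent, a pre-computed alignment can be imported from
FASTA and is validated against the same contract (equal row lengths, no
all-gap columns, de-gapping reproduces the inputs exactly).

## Variation scoring

Mutation events follow an indel-as-single-character convention:

- **Indel event** — a maximal run of alignment columns sharing one
  gap/non-gap row pattern, with ≥1 gapped row.  One event regardless of
  width; its length is the run width.  Two overlapping gaps of
  different extent in different specimens have different patterns and
  are two events.  This is the most deterministic reading of "indels
  scored as independent single characters".
- **Substitution event** — any column with ≥2 distinct bases among its
  non-gap, non-N rows, including columns inside indel runs (scored
  among the non-gap rows only).

PIC (potentially informative characters) per region = substitutions +
indels.  An event is parsimony-informative when ≥2 allele states each
occur in ≥2 specimens (indels use gap/present as states; N is
missing).  Percent variable characters = 100 × (union of substitution
and indel columns)/aligned length — indel columns are counted
individually, which keeps the quantity a true column percentage in
[0, 100].  The O'Donnell proportion is (NS + ID)/aligned length by
default; the denominator variant is configurable and the choice is
recorded in the run manifest, since the quantity is only used to rank
noncoding regions against each other.  Sliding identity profiles use
100-column windows advanced by 25 (smooth at mVISTA-like scale); gap
columns count as mismatches and the profile has
⌊(L − window)/step⌋ + 1 points.

## Species-specific mutations

An event is an SSM iff exactly two allele states exist, one carried by
all specimens of exactly one species and the other — the consensus —
by all remaining specimens.  Intraspecific variation, three or more
states, a gap row at a substitution site, or an N anywhere in the
column disqualify the event (missing data cannot certify intraspecific
invariance; for the same reason the detector refuses datasets with a
single specimen in any species).  Indel SSMs compare gap-pattern
identity — same columns, same length — which the event definition
already guarantees within one event.  Under this strict two-state rule
the consensus needs no majority vote.  Note that with three species, a
character shared by a two-species clade is indistinguishable from a
character of the third species (the comparison is unrooted), so both
are reported as diagnostic for the species with the rarer state.

Barcode ranking sorts regions by (diagnoses all species, total SSMs,
shorter first) and flags regions over 1000 bp as impractical for
routine single-amplicon assays.  The per-region delimitation table
lists each diagnostic column with every specimen's allele, in input
specimen order.

## CDS effects

CDS region alignments hold spliced coding sequences in reading-frame
orientation.  The reference frame is the per-column majority consensus
(a column with a gap majority is an insertion and has no reference
codon).  A substitution's codon index is its ungapped consensus
position // 3; the alternative codon is read from the carrier
specimen's full row over that codon's columns, so multiple
substitutions hitting one codon in one specimen are evaluated jointly
as one codon change while each SNP event keeps its own record — totals
therefore remain per-SNP comparable.  Translation uses the bacterial/
plastid genetic code (NCBI table 11), the standard for land-plant
plastomes.  Stop gain/loss is reported as a nonsynonymous subtype and
counted within nonsynonymous.  Indels: length ≡ 0 (mod 3) is in-frame
with protein delta ±length/3 (sign from the gap-pattern majority —
gapped majority means the non-gap minority carries an insertion);
otherwise frameshift with no delta.  An indel whose reference footprint
crosses a spliced exon junction, or an insertion landing exactly on
one, is reported `splice_region` with no delta.  Events in pseudogenes
(e.g. the truncated IR copy of ycf1) are `not_applicable`.  RNA editing
is ignored; classification is DNA-level.

## SSR census

Maximal tandem repeats of 1–3 bp primitive motifs at thresholds 10/6/4
repeats (mono/di/tri), the settings commonly used for plastome
microsatellite scans.  A run qualifying at several unit lengths is
reported once at the smallest unit (motifs whose minimal period is
shorter than the nominal unit are skipped); motifs are canonicalized to
their lexicographically minimal rotation; runs are broken at N;
tetra-and-longer motifs are not scanned.  Adjacent different-motif
(compound) repeats are separate loci.  Cross-specimen matching anchors
each locus by its exact 20 bp left and right flanking context, because
indels shift coordinates between specimens; a flank pair matching two
loci in one specimen is ambiguous and excluded with a log entry.  A
locus present in all specimens of exactly one species and absent in
all others — including "present but below threshold", which the
scanner never reports — is species-specific.  The census reports both
per-specimen counts and a per-species deduplicated count, since either
convention is found in the literature.

## Synthetic data generator

The generator is first-class, tested code that emulates the study
design the analysis assumes, with a truth manifest sufficient to score
every detector.

**Ancestor.**  A circular genome assembled from a realistic plastid
gene roster (31 genes: photosystem/polymerase/ribosomal protein genes,
clpP with two introns, trans-spliced rps12 as 5′ and 3′ parts, an IR
block with four rRNAs, ycf2 and a truncated pseudo-ycf1 at the border,
an SSC block ndhF…ycf1).  CDS sequences are clean ORFs (ATG start, no
internal stop, stop codon, length ≡ 0 mod 3; exon lengths are multiples
of 3 so codons never straddle introns).  Spacer lengths fill
compartment targets exactly (LSC 90.3 kb, IR 26.35 kb each, SSC
18.8 kb; ≈162 kb assembled once the planted SSR runs are embedded)
from a gamma-weighted split,
with a few named spacers fixed (ndhD-ccsA at 611 bp, rps4-rps16 at
817 bp, two >1 kb trnV spacers) so the showcase regions have realistic
sizes.  IRb is assembled as the exact reverse complement of IRa with
mirrored features.

**Evolution.**  Species tree ((A,B),C), labels P_patens, P_vernalis,
P_pratensis.  Mutations have two scopes: branch mutations shared by
both specimens of a species (or of the A+B clade) and per-specimen
mutations.  Default per-site substitution rates — A 3.0e-4, B 2.5e-4,
C 1.8e-3, internal AB branch 1.0e-4, specimen 1.5e-5 — emulate an
asymmetric design in which the outgroup species has accumulated
several-fold more diagnostic variation than the sister pair and
conspecific genomes differ at only a handful of sites.  Indels occur in
noncoding sequence at 0.5× the substitution rate with geometric lengths
(mean 2 bp, cap 8); coding indels are only planted explicitly.  Coding
substitutions hit a configured synonymous fraction (0.40) by deciding
the target effect per event and rejection-sampling a compatible site
against the translation oracle.  All mutation footprints are disjoint
(a global per-segment registry with safety margins, and planted SSR
runs reserve their 20 bp anchors), so planted truth is unambiguous and
detector precision/recall can be scored exactly.  IRa mutations are
copy-corrected into IRb, mimicking IR homogenization.

**Planted showcases** (defaults): diagnostic blocks in ndhD-ccsA
(5+2 / 2+0 / 18+9 substitutions+indels for A/B/C), rps4-rps16,
clpP.intron2, rps15.intron1 and trnH-psbA; in-frame insertions of 39 bp
(ndhF), 21 bp (accD) and 6 bp (rpl22) in species C, elongating the
proteins by 13, 7 and 2 amino acids; ten ancestral SSR loci spanning
all three unit lengths plus five species-conditional loci where an
ancestral 9-repeat run crosses the mono threshold only on one branch
via a 1 bp diagnostic insertion.

**rRNA cluster.**  A separate linear 18S-ITS1-5.8S-ITS2-26S genome
with region lengths 1810/200/164/211/3410 (5795 bp); ITS1 and ITS2 are
the spacers between the rRNA genes (region names `18S-5.8S`,
`5.8S-26S`).  The default variation is pure substitution — diagnostic
SNPs (1 in 18S, 2 in ITS1, 4+1+1 in ITS2, 5 in 26S, all but two for
species C) plus four single-specimen singletons, 5.8S monomorphic — so
the cluster length is constant across specimens and only ITS2
discriminates all three species.

**What the generator does not emulate:** sequencing error, assembly
artefacts, heteroplasmy, IR boundary shifts between species, genome
rearrangements, rate heterogeneity along the genome, and multiple hits
at one site (footprints are disjoint).  Passing tests therefore show
the detectors are correct under clean homology and unambiguous truth;
on real data, alignment quality and annotation consistency become the
limiting factors, which is why the aligner is pluggable and homology
is name-based.

## Determinism and problem sizes

All randomness flows from a single seed through one NumPy generator;
identical seed and configuration give byte-identical genomes, manifest
and report tables, and the analysis stages use no randomness at all.
The test suite runs the full default-scale dataset (≈162 kb × 6
specimens, 68 homologous regions) once as a shared fixture and reuses
it; quick unit fixtures are a few hundred bp.  Oracle-equivalence
checks run at the sizes where exhaustive enumeration is honest: the
quadratic IR oracle on ~2 kb circles, the event-caller oracle on ≤8
column × ≤4 row alignments, the regex SSR oracle on 10 kb fixtures.
`scripts/acceptance.py` regenerates everything from scratch at default
scale from the given seed.

## Known limitations

- Region homology is name-based; collinearity is assumed.
- The built-in aligner is not a substitute for MUSCLE/MAFFT on
  divergent sequences; import external alignments there.
- SSM calling is strictly two-state and certifies invariance only at
  the sampled specimens; two specimens per species is the minimum, not
  a statistical guarantee.
- Features spanning the sequence origin of circular records are not
  re-joined in reports; inputs are expected linearized at the
  conventional LSC start (the generator always produces this form).
- The O'Donnell denominator is configurable because the original
  formulation is not uniquely pinned; comparisons across runs should
  use one variant consistently.
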