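# Methods

## The analysis problem

A germline-restricted chromosome (GRC) is present in germ cells and absent
from soma. Sequencing testis and kidney from the same individuals therefore
gives a contrast: GRC-derived reads occur only in the germline libraries,
at reduced depth (one GRC copy per male germ cell, in a subset of cells),
and most GRC sequence is a recent, slightly diverged copy of A-chromosome
sequence. The package turns that contrast into (i) a classifier for
germline reads, (ii) a coverage-based copy-number and size estimator,
(iii) cross-species homology labels, (iv) gene completeness and
pseudogenization scores, and (v) an independent cytological size estimate.

## Identification model (channels a/b/c + barcode expansion)

Channel (a) demands per-base testis depth ≥ 1 and kidney depth = 0 over a
maximal run of ≥ 500 bp ("fully covered" is interpreted as depth ≥ 1 at
every base); reads overlapping such a region by ≥ 10 bp donate their
barcode. Channel (b) calls SNPs with a deliberately naive pileup — a site
is called when ≥ 2 reads in a sample support the same alternative allele,
with no base-quality weighting — keeps sites with ≥ 2 alt reads in *every*
testis sample and 0 alt reads in every kidney sample, builds all 29-bp
windows of the alt-substituted reference containing the site, removes every
k-mer observed (either strand) in the kidney reads, and matches survivors
against the testis reads as exact substrings on both strands. Channel (c)
selects reads aligned to a supplied repeat consensus with ≥ 100 bp and
> 90% identity (repeat discovery itself is out of scope). Finally all
reads sharing a barcode with any flagged read are recruited; barcode-less
reads can trigger channels but recruit nothing.

Design choices worth noting:

* The ≥ 2-alt-read pileup threshold is a stand-in for a production caller;
  at realistic depths the effective gate is the all-testis/no-kidney tissue
  filter, and the threshold is exposed in `RunConfig.min_alt_reads`.
* Variants within k−1 bp of a contig end yield fewer than k k-mers rather
  than being discarded — the diagnostic signal is kept.
* K-mer matching is double-stranded exact substring matching: DNA reads are
  unstranded, so single-strand matching would halve sensitivity.

## Coverage normalisation and copy number

Per sample: `single_copy_grc_depth` is the mode (integer histogram,
binwidth 1, ties toward the smaller depth) of testis depth over GRC bases
with zero kidney coverage; modal A depths are modes over A scaffolds. The
testis ratio `r = single_copy_grc_depth / modal_A_testis` also serves as
the expected GRC fraction of the kidney track, so both tracks are converted
to single-copy-GRC units before subtraction — the only reading under which
the subtraction is dimensionally coherent. Subtraction happens per base,
then windows (default 1 kbp) are averaged and floored at zero; a short
trailing window is kept, flagged, and weighted by its true length in the
size estimate `Σ cn × window length`.

The modal estimator quantises to integer depth, so copy-number estimates
carry a relative bias up to ~0.5/λ at single-copy depth λ — at the ≥ 10x
depths the method assumes this is ≤ 5% and immaterial next to the ±20%
window tolerance; below ~5x the mode becomes unreliable and the
normalisation should not be trusted.

## Homology classes, origin, divergence polarity

Direct cross-GRC alignments (default floor: ≥ 500 bp, ≥ 90% identity —
the alignment acceptance threshold is configurable because no canonical
value exists) mark bases homologous. The remaining bases are potentially
homologous when their A-chromosome footprint — alignments to one shared
reference genome, merged when within 10 kbp — overlaps (≥ 1 bp) the other
species' merged footprint; otherwise species-specific. The three labels
partition each assembly exactly, by construction from per-base label
arrays. Copy-number weighting enters only when proportions are reported.
Origin attribution takes each query's top hit (most matches; ties: longer
block, then lexicographically smaller chromosome) and weights its
contribution by scaffold copy number; expected proportions are chromosome
length over genome length. Divergence polarity is
`d = mismatch_prop(genome 1) − mismatch_prop(genome 2)` from the best
alignment per genome; `d = 0` regions are removed, single-genome regions
excluded and counted.

## Gene content

Hits with e-value ≤ 1e-6 are merged per (scaffold, strand) when they
overlap; each merged region is assigned to the gene of its top-bitscore
hit. Completeness divides the CDS fraction found on the GRC by the fraction
found in the reference genome, floors the denominator at 0.75 (so weak
conservation cannot inflate a fragment), and caps at 1 (a proportion cannot
exceed totality; this also matches the 80%/80% → 100% worked example).
Genes require ≥ 25% completeness in at least one species. The premature-
stop rule considers all three frames on the annotated strand and flags an
exon only when no frame contains a stop-free stretch ≥ 95% of the exon
length; the comparison `20·run ≥ 19·length` is done in integers so the 95%
boundary is exactly inclusive. Expression uses unique-mapping FPKM
(`count / (exon kbp × library millions)`), and the completeness–expression
relation is fitted as OLS of log₂FPKM on completeness over genes with
FPKM > 0 (a log-linear reading of an exponential relation, consistent with
plotting expression on a log₂ axis).

A naive translated scan (six-frame translation, exact 5-mer peptide seeds,
ungapped X-drop extension, identity scoring) is bundled so toy data need no
external tools; it reports raw scores and no e-value statistics and is not
meant for real genomes — supply an external translated-search hit table
(outfmt-6 + frame column) there.

## Cytological size

Within each cell, measured lengths of the 29 largest chromosomes are paired
*by rank* with the 29 largest reference-karyotype sizes — mis-ranking
between similar-sized chromosomes is a known risk that the per-cell R²
(printed with every estimate) partially surfaces. OLS of log(bp) on
log(µm) converts the GRC measurement, divided by 1.5 to undo the apparent
inflation of the unpaired univalent, into base pairs; natural logs are used
but any fixed base gives identical predictions, and the estimate is
invariant to the µm unit. The among-individual test is a one-way ANOVA on
per-cell estimates (10 cells × 3 individuals gives total df 29) with Tukey
HSD on group means; ANOVA is computed from explicit sums of squares and
cross-checked against an independent implementation in the tests.

## Synthetic data: what it emulates, and what it does not

The generator plants, with full truth tables: an A genome; GRC segments
copied from it at 0.1–2% substitution divergence; recent duplications as
byte-identical copies sharing one assembly scaffold (so they collapse, and
surface only as elevated coverage) and older duplications as separately
diverged scaffolds; a GRC-restricted tandem repeat; gene fragments
retaining an exact fraction of their coding length, optionally with one
sense codon converted to TAA mid-exon; and reads drawn per molecule — one
barcode per molecule, molecules confined to one source sequence — with
kidney reads only from A, testis reads from A plus every GRC copy at
`grc_singlecopy_ratio × germline depth` (default ratio 0.2, inside the
~15–25% band seen in real germline libraries).

Deliberate simplifications: substitutions only (no indels or SVs), so
coordinates map 1:1 and mismatch arithmetic is exact; uniform read starts
(no GC bias); no quality-score error model or PCR duplicates; gene exon
lengths must be codon multiples; truth alignments place each read at its
origin, i.e. they emulate a perfectly resolved aligner. Consequently the
tests demonstrate correctness of the *decision rules and arithmetic* under
the stated statistical conditions — not robustness to alignment error,
indel polymorphism or bias, which real data adds on top.

Default scales were chosen to represent the study design at desk size: 3
samples per tissue, germline depth 30x vs somatic 20x for the linked-read
style runs (scaled down ~4x from typical real depths, preserving their
ratio), and 100x unlinked reads (one read per molecule) for the deep
coverage used in copy-number recovery, giving 20x single-copy GRC depth.
Toy genomes are 0.2–2 Mbp with 87–250 kbp copy-weighted GRCs.

## Numerical and degenerate-input policy

Coordinates are 0-based half-open everywhere internally; 1-based inclusive
dialects (hit tables) are converted at the parse boundary. Modes are exact
integer-histogram argmaxes with deterministic ties; all tie-breaks
(mapping placements, origin attribution, pileup alleles) are lexicographic
and documented at the function. Empty zero-kidney base sets, zero modal
depths, singleton ANOVA groups, sub-codon exons, empty repeat consensi and
mismatched track lengths raise immediately with named errors rather than
propagating NaNs. All randomness flows from a single integer seed through
`numpy` generators with fixed stream ids per stage, so identical configs
reproduce outputs byte for byte.
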