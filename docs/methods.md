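# Methods

This note documents the model, the numerical choices, and what the
synthetic-data experiments do and do not demonstrate.

## Coordinates and formats

All genomic coordinates are 0-based half-open internally. BED input/output
is passed through unchanged; GTF (1-based inclusive) is converted on read.
Junction BED records carry two blocks (the exonic anchors, one flank each
side of the intron) and put the evidence count in the score column. Probe
FASTA headers are `>probe_id key=value key=value ...` with `%`, `=`,
whitespace and newlines percent-escaped in values, so annotations
round-trip losslessly. FASTQ qualities are read and discarded: mapping
uses a mismatch budget only.

## Probe geometry

Given read length R and required overhang m, the flank is F = R − m and
the probe length L = 2F. The guarantee is combinatorial: a read contained
in the probe starts at an offset in [0, L − R], and its overlap with the
lesser-covered exon is min(F − offset, offset + R − F), minimized at the
two extreme offsets where it equals m. For the default R = 36, m = 8 there
are exactly L − R + 1 = 21 contained placements and the minimum overlap is
8. Geometries with m > R/2 produce probes shorter than the read (no
placement exists); `solve_geometry` permits them but the mapper then finds
no hits, and `min_overhang_by_enumeration` documents the vacuity.

Probe sequences are taken from the genome adjacent to the intron (last F
bases before, first F after) and reverse-complemented for '−'-strand
events so probes read in transcribed orientation. Supporting transcripts
matter only through the anchor filter: an event is buildable when at least
one supporting transcript has both flanking exons ≥ F; the best-supported
evidence class (refseq > mrna > est > predicted) is recorded in the probe
annotation.

## Catalog filtering

The uniqueness key of an event is (chrom, strand, intron_start,
intron_end, kind). Strand is part of the key even though coordinates alone
nearly always suffice: identical coordinates on opposite strands would
otherwise force contradictory motif annotations. The quality filter keeps
an event if its donor/acceptor pair is canonical — GT–AG plus the minor
spliceosomal GC–AG and AT–AC by default, configurable down to GT–AG only —
or unconditionally if ≥ 2 distinct transcripts support it. Exon–intron
boundary events (intron retention, off by default) carry no complete
intron and are exempt from the motif rule. Introns shorter than 4 bases
cannot carry distinct donor and acceptor dinucleotides and are dropped
with a warning.

## Mapping

A hit is a gapless placement of the read or its reverse complement at a
junction-spanning offset (offset < F and offset + R > F) with Hamming
distance ≤ k; N mismatches everything, including N. The production mapper
indexes all probe substrings of length ⌊R/(k+1)⌋: a read within budget
must contain at least one of its k+1 disjoint chunks exactly (pigeonhole),
so exact chunk lookups nominate candidate placements which are verified
directly. A vectorized prefilter rejects reads none of whose chunks occur
in any probe, which is most reads of a transcript. `oracle_map` is a
deliberately independent brute-force scan of every probe × offset ×
strand; the test suite asserts exact hit-set equality over ≥ 10,000
randomized instances.

Uniqueness is per probe, not per placement: a read with several placements
on one probe is still unique to that probe (the counting unit is the
junction). Reads hitting two probes, or only an ambiguous
(duplicate-sequence) probe, are multimapped; the identity
unique + multimapped + unmapped = total is asserted as an invariant.
Throughput is roughly 50–70k reads/s per core at ~200 probes, adequate for
the simulated studies used here (millions of reads).

## Quantification

Event RPKM uses the probe itself as the exon model (feature length L) and,
by default, the sample's total uniquely probe-mapped reads as library
size — the normalization then reflects exactly the signal the virtual
array observes; callers may supply external library sizes instead. RPKM is
exactly linear in count and inversely linear in length and library size,
and the mega-table column sums equal each sample's unique total.

Gene-level expression, needed only for the confound filter, is estimated
from junction counts: by default the sum over the gene's *constitutive*
junctions (those supported by every transcript of the gene), normalized by
the exon-union length. Constitutive junctions track whole-gene expression
regardless of isoform usage; summing all junctions instead would confound
usage shifts with expression (an isoform switch changes the number and
density of junctions per read). Genes with no constitutive junction fall
back to the all-junction sum and their events can be audited via the
`gene_unknown`/fallback path. A residual bias remains even for
constitutive junctions: isoforms of different lengths yield
junction-spanning reads at different rates, so an extreme usage shift
moves the estimate by ~0.1–0.2 log2 units; this is small relative to the
gene-alpha threshold but is the main known limitation of junction-derived
gene expression.

RPKM itself is not composition-robust: large asymmetric expression changes
shift the library size and attenuate or inflate every other fold change.
This is inherent to the normalization the method prescribes and is visible
in the simulations; modern size-factor normalizations are out of scope.

## Differential splicing

The test is a t test on log2(RPKM + 1): paired across individuals by
default (the design is matched pairs from the same individuals), Welch's
unpaired as an option. The pseudocount ε = 1 RPKM guards zero counts and
is configurable. Fold change is log2((mean_c + ε)/(mean_n + ε)), so
swapping groups negates it exactly and the p-value is symmetric.
Degenerate cases are pinned: both groups all-zero → untestable, p = 1,
FC = 0; zero variance with equal means → p = 1; zero variance with unequal
means → the smallest positive double (p must stay in (0, 1]). Raw p-value
thresholds (10⁻⁴ strict, 10⁻³ loose, |FC| > 1.5 linear) drive the filters;
BH q-values are reported as an extra column but take no part in them.

The confound filter removes a signature event when any of its genes has
gene-level p < 0.01 (same test machinery on gene RPKM); events with no
resolvable gene are kept and flagged.

Clustering is agglomerative on log2(RPKM + 1) sample profiles, correlation
distance, average linkage, via scipy's linkage (deterministic for a given
input; we rely on its fixed merge order for ties rather than imposing a
separate tie-break rule). A constant matrix yields all-zero distances and
is returned flagged degenerate. The tree is rendered as
nested-parenthesis text with branch lengths.

## Synthetic data

The generator emulates the study design: matched tumor/normal pairs per
individual, 36-base reads, multi-isoform genes with exon-skip and
alternative 5'/3' splice-site structures (intron retention optional), and
canonical GT–AG motifs written under every isoform's introns so the
generated catalog survives the quality filter. Reads are sampled uniformly
in transcript coordinates, which makes the expected number of detectable
reads per junction closed-form: n_t · (L − R + 1)/(len_t − R + 1) for each
transcript containing the junction. Gene counts are gamma-Poisson
(negative binomial); the variance is decomposed into a per-gene,
per-individual random effect (default SD 0.4 log2) shared by both members
of a pair — the component the paired test cancels — and a residual
dispersion (default 0.02) between matched tissues. Sequencing error is an
independent per-base substitution (default 0.5%), comfortably inside the
k = 2 budget for 36-mers.

Splicing changes are planted as usage shifts: for linear fold f the
alternative isoform takes usage f/(1+f) versus 1/(1+f), so its unique
junctions change by exactly f and the primary isoform's unique junctions
by 1/f. Expression changes scale a gene's depth with usage untouched.
Ground truth records the analytic per-junction fold changes and expected
detection counts.

What the generator does **not** model: positional coverage bias, GC bias,
indels, quality-correlated errors, paired ends, unannotated junctions, or
isoform structures beyond single-event edits. Passing tests therefore
demonstrate correctness of the pipeline's algebra and calibration of its
statistics under the stated noise model, not robustness to every artifact
of real libraries.

## Validation experiments (problem sizes)

The end-to-end suites run at sizes chosen to keep the statistics
well-posed at five matched pairs (degrees of freedom 4, so the p < 10⁻³
threshold demands |t| > 8.6):

- *Null calibration*: 10,000 no-difference events, mean count 30,
  defaults for dispersion and individual effects; the fraction below α is
  required to sit within 3 binomial SDs of α for α ∈ {0.05, 0.01, 0.001}.
- *Planted recovery*: 30 genes (12 splicing-planted at 4-fold, 8
  expression-planted at 3-fold with read-mass-balanced directions so RPKM
  library composition stays comparable, 10 null), 5–7 exons per gene,
  700k reads per sample across 5 pairs, so minor-isoform junctions retain
  a few hundred reads. Sensitivity ≥ 90% at (α = 10⁻³, FC > 1.5),
  ≥ 90% confound removal, ≥ 90% pure-splicing retention.
- *Clustering depth sensitivity*: signature-like panels of 60 events with
  baseline expression spanning ~1.5 decades and fold changes 1.5–4× (the
  spread matters: correlation distance is meaningless over a flat
  baseline). At the reference depth (typical control-side counts ~4–100)
  the 2-cut separates conditions perfectly in every replicate; at
  one-quarter depth counts become sparse and discrete and purity degrades,
  reproducing the behavior of low-coverage samples in real cohorts.
  Asserted over fixed-seed replicates.

## Known limitations

- Junction-derived gene expression (above) is the weakest link of the
  confound filter; a genome-level read counter would remove its residual
  usage bias.
- RPKM composition bias is inherited from the method.
- The catalog detects only junctions present in the input models;
  discovery requires augmenting the models with predictions.
- Probe collapse treats only exact sequence duplicates as ambiguous;
  near-duplicates are left to the multimapping rule at mapping time.
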