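# Methods

`ssrscan` implements a comparative survey of perfect simple sequence repeats
(SSRs, microsatellites) in coding sequences: detection under a two-tier
length-class scheme, motif canonicalization, per-Mbp density and composition
summaries, amino-acid repeat profiling, and chi-square heterogeneity
comparisons between datasets.  This note records the model, the conventions
chosen where the underlying procedure was ambiguous, and what the synthetic
data generator does and does not emulate.

## Repeat model and detection

A perfect SSR is an uninterrupted tandem repetition of a primitive motif
(one that is not itself a repetition of a shorter unit) with period k in
1..10.  The scanner reports **maximal runs with whole-unit counts**:

- For each period k, positions where `seq[p] == seq[p+k]` are computed in a
  single vectorized pass; maximal stretches of matches are character-level
  runs of period k.
- A run is reported at its **smallest** period only, so `(ATC)4` is one
  trimer run, never also a hexamer run, and no tract is double-counted.
- The repeat count is the floor of the character-maximal extent in whole
  units: a trailing partial unit neither counts toward the repeat number nor
  extends the tract.  The reported start is the character-maximal left end
  (the character immediately left of the tract does not continue the
  period).  This convention is declared, not inferred: published SSR-mining
  tools do not document their overlap semantics, and maximal-run reporting
  is the reproducible choice.  Distinct tracts of different motifs may
  overlap by fewer than k bases; both are reported.
- `N` and IUPAC ambiguity letters are retained in sequences but act as hard
  breaks: no reported tract contains or spans one, so assembly gaps can
  neither create nor extend repeats.

Correctness is established against a brute-force oracle that tests every
(start, period) pair with plain string slicing; the two agree exactly on
hundreds of random sequences, including repeat-dense two- and three-letter
alphabets.

## Class I / class II thresholds

Length classes are operationalized as minimum whole-repeat counts per
period (class I: 20, 10, 7, 5, 4, 4, 3, 3, 3, 2 for periods 1..10; class II:
12, 6, 4, 3, 3, 2, 2, 2, 2 for periods 1..9, no decamer entry).  Class I is
tested first; a run below the class I minimum but at or above the class II
minimum is class II; runs below both are dropped.  The nominal byte
definitions ("class I >= 20 bp, class II 12-19 bp") are descriptive only —
the repeat-count tables are authoritative (they disagree at, e.g.,
octamer x 2 = 16 bp).  Because class II has no decamer entry, decamer loci
are always class I.

## Canonical motif classes

Motifs are clustered under circular permutation and reverse complement
(AC = CA = GT = TG).  The class representative is the lexicographic minimum
over all rotations of the motif and of its reverse complement (A < C < G <
T), which coincides with the first-named motif of conventional pair labels
such as AGG/CCT.  Exhaustive enumeration gives 2 monomer, 4 dimer and 10
trimer primitive classes.  Richness compares A+T against G+C within one
motif copy; ties form an explicit third category, BALANCED, excluded from
both the AT-rich and GC-rich tallies (a forced two-way split would break the
additivity of the richness partition — e.g. ACGT-type motifs belong to
neither side).

## Summaries

Densities are loci per Mbp of **total** dataset length (all genes, not only
SSR-containing ones).  Headline per-class totals — locus counts, density,
tract-length mean/SD (population SD), richness partition, nucleotide
differentials, canonical tables and amino-acid tallies — exclude
mononucleotide loci by default, because monomer runs are difficult to assay
and most comparable surveys drop them; `include_monomers=True` restores
them.  The by-period density table always includes every searched period, so
the monomer row stays visible and the identity

    headline density = sum over periods >= 2 of by-period density

holds by construction.  Nucleotide differentials count one motif copy per
locus (not the whole tract); per class they therefore sum to the sum of
motif periods over loci, a conservation identity the tests assert.

Amino-acid profiles translate, with the standard genetic code, exactly the
codons lying fully inside each tract in the gene's frame anchored at
position 0 of the CDS — the only frame convention that requires no
annotation beyond the CDS itself.  Stop codons are tallied separately and
excluded from the amino-acid map.

## Statistics

The heterogeneity test on k density values is an equal-expectation
goodness-of-fit chi-square: expected value e = mean of the inputs, statistic
`sum (v_i - e)^2 / e`, df = k-1, upper-tail p-value, no continuity
correction.  This is the unique reading that reproduces the published
statistics this package's acceptance script recomputes (a Yates-corrected
2x2 reading does not).  The statistic scales linearly with the inputs, so it
is sensitive to the absolute per-Mbp scale, as intended for count densities.
The tract-length comparison is a two-sided Welch (unequal-variance) t-test;
group sizes and variances differ between datasets, so the pooled-variance
variant was not appropriate.  `compare_datasets` runs the full battery per
class: between-dataset density, within-dataset trimer-vs-hexamer,
AT-rich-vs-GC-rich, (A+T)-vs-(G+C) differential, and the length t-test.  No
multiple-testing correction is applied.

## Synthetic data

The generator emulates gene-model CDS inputs: `n_genes` records with
uniform lengths (default 400-1200 bp), i.i.d. background with a GC knob
(default 0.5), and planted perfect tracts of known motif, count and
position.  Planting mutates up to one flanking base per side so the tract is
not extendable (the left guard may not equal the motif's last base, the
right guard its first), and the dataset is reconciled against the detector:
background that happens to contain a thresholded repeat is resampled
locally, genes whose planted tracts were disturbed are rebuilt, until the
detected locus set equals the planted truth exactly.  Recovery scoring is
exact-interval matching on (seq_id, start, end, period), so precision =
recall = 1.0 on generator output is a property of the construction — and a
regression alarm for the detector, not evidence about real data.

The background has no codon structure, no GC heterogeneity along genes, no
imperfect or compound repeats, and no evolutionary relatedness between
datasets.  Passing tests therefore demonstrate the correctness of
detection, classification, aggregation and testing machinery under the
declared repeat model; they say nothing about gene-model quality, assembly
artifacts, or repeat-calling choices in real genomes.

## Problem sizes and numerical choices

- The oracle-equivalence checks use hundreds of random sequences up to
  500 bp; the brute-force oracle is quadratic and sets the runtime.
- The end-to-end power study plants the published class II density contrast
  (1768 vs 1542 loci per Mbp) into two 1 Mbp datasets (500 genes of
  2000 bp) per seed, 100 seeds in the test suite.  Because the generator
  plants exact counts, the detected densities are exact and the rejection
  rate at alpha = 0.01 measures end-to-end recovery, not count noise.
- Background rejection-sampling is bounded (60 rounds by default) and raises
  rather than looping forever on pathological configurations; the GC
  fraction must be strictly inside (0, 1).
- `chi_square_heterogeneity` rejects all-zero and negative input;
  `welch_t_test` requires two values per group and returns statistic 0 with
  p = 1 for identical degenerate groups.
- Empty FASTA input yields an empty dataset (with a warning), not an error,
  so pipelines compose; duplicate record IDs are an error.

## Known limitations

- Imperfect and compound SSRs are out of scope; only perfect tracts are
  detected.
- CDS are single-strand objects taken as given in frame 0; there is no
  reverse-strand scan (reverse-complement equivalence is handled at
  canonicalization) and no GFF/annotation parsing.
- The per-Mbp denominator is the total length of the provided records;
  whether a published survey filtered its gene set before normalizing cannot
  be reconstructed from summary tables alone.
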