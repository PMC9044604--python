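# Methods

## Model and procedure

`sexscan` treats sex-linkage detection as a genome-wide outlier scan of
two window statistics contrasted between the heterogametic and
homogametic sexes, on a reference assumed to come from the homogametic
sex (so X/Z is present in two copies in the reference individual and
Y/W is absent).

1. **Read filtering.** Every alignment record must be mapped, primary,
   non-supplementary, non-duplicate and have MAPQ ≥ 20.  On top of
   these gates, three mismatch stringencies are scanned using the NM
   tag (edit distance, indel bases included): strict (NM = 0),
   intermediate (NM ≤ 2) and unfiltered (no NM gate).  The MAPQ floor
   applies to the "unfiltered" setting too — "unfiltered" refers only
   to mismatches; without the floor, multi-mappers would flatten the
   X/Z coverage contrast.  Records lacking NM are excluded from bounded
   settings and counted; above 1% a run-level warning is raised.
2. **Window coverage.** Mean per-base depth per 5 kb unit window,
   computed from CIGAR aligned blocks (deletions and clips contribute
   nothing); a read spanning a boundary contributes to each window
   proportionally to overlap, which is exactly a per-base pileup (the
   test suite asserts bitwise agreement with one).
3. **Masking.** A window is masked when any sample's unfiltered depth
   exceeds `mask_factor` (default 10) times that sample's genome-wide
   median unfiltered depth — collapsed repeats would otherwise dominate
   the normalization means.  The mask applies to all settings.
4. **Normalization.** Per sample and setting, depths are divided by the
   mean over unmasked windows, making samples of different sequencing
   depth directly comparable (mean, not median, so the genome-wide
   expectation is exactly 1; a median option exists via the band
   method's robustness rather than the scaling).
5. **Heterozygosity.** From a multi-sample VCF called on the unfiltered
   alignments: biallelic SNVs with QUAL ≥ 30 are kept; genotypes with
   GQ < 20 or DP < 3 are set missing.  Per window and sample the
   statistic is het genotypes / window length.  The denominator is the
   full window length rather than callable sites: it is the same
   convention for every sample, so sex *differences* are unbiased;
   callable-site correction is future work.  The genome-wide
   heterozygosity percentage is reported per sample, with a caution at
   ≥ 1% where background diversity can drown the sex signal.
6. **Sex contrast.** Unweighted role means per window, then
   d = heterogametic − homogametic for heterozygosity and for coverage
   at each setting.  The same sign convention serves XY and ZW systems:
   degeneration gives d(coverage) < 0, low differentiation gives
   d(het) > 0.
7. **Aggregation.** Unit windows are averaged into report windows
   (default 1 Mb; simulation presets use smaller sizes, below) by
   midpoint binning; masked units and trailing units shorter than half
   the unit size are excluded, and report windows with fewer than 5
   contributing units are set missing (suppresses liftover-sparse
   noise).
8. **95% band and outliers.** The "95% confidence interval" is the
   empirical 2.5th/97.5th percentile band of the genome-wide
   distribution of d per metric and setting — an outlier threshold, not
   a standard-error interval (an SE-of-mean band would flag nearly
   every window in a genome-sized sample).  A mean ± 1.96·SD variant is
   available (`band_method: stddev`).  The band needs ≥ 20 non-missing
   report windows; below that it is omitted with a warning.  By
   construction the quantile band flags ≈ 5% of windows on null data;
   it can resolve a sex-linked fraction only up to ~2.5% of report
   windows per tail, which matches the biological regime (sex-linked
   sequence is a small fraction of a genome).
9. **Liftover (optional).** Co-linear blocks are read from PSL
   (expanded exactly per block, never interpolated across alignment
   gaps; minus-strand query starts converted to forward coordinates) or
   a 7-column TSV.  A unit window anchors when blocks agreeing on one
   target scaffold cover ≥ 50% of it (`anchor_min_overlap`); the window
   midpoint is projected through the best-overlapping block (ties:
   larger block, then lexicographic target name — determinism).  The
   anchoring rate (anchored / all unit windows) is reported.  With an
   identity map the synteny branch reproduces the study branch
   byte-identically up to scaffold renaming, which the tests assert.

## Synthetic data generator

The simulator writes already-aligned BAM records with synthetic NM tags
rather than running an aligner: it exercises exactly the filter path
the pipeline applies to real alignments while keeping the package
self-contained.  Per sample, read starts are Poisson-uniform at the
configured depth (default 10×, read length 100); reads carry a
background NM ~ Poisson(0.15), 3% duplicate flags, 2% MAPQ-0 records
and 0.2% NM-less records.  In sex-linked regions the heterogametic
sample's depth splits into an X/Z-derived half (background NM) and a
Y/W-derived half scaled by (1 − degeneration) carrying
NM ~ Poisson(divergence · read length / 100) extra mismatches.  The VCF
gives every sample a background het rate of 0.001/bp via population
SNPs (each sample het with probability 0.5 at a site density of
2 × rate); gametolog divergence adds heterogametic-only het sites at
rate divergence/100 · 0.5 · (1 − degeneration); fully degenerate
regions make the heterogametic samples hemizygous (never het).  ~2.5%
junk records (indels, multiallelics, low QUAL) exercise the variant
filter; 3% of genotypes get GQ 10 and DP ~ Poisson(sample depth), so
the realized callable fraction is analytically known and used by the
recovery tests.

Presets (chosen once as desk-scale study conditions; a full run takes
well under five minutes on one CPU):

* `fig1d` / `fig1c`: four 2.4 Mb autosomes + a 400 kb scaffold with a
  200 kb high-differentiation region (divergence 8/100 bp;
  degeneration 1.0 or 0.3) and a 200 kb pseudoautosomal region; 2
  samples per sex at 9–11×; 5 kb units, 100 kb report windows (100
  report windows, 2 of them truly sex-linked ≈ 2% — within the band's
  resolving regime).
* `fig1b`: four 2.4 Mb autosomes + three fully low-differentiation
  80 kb scaffolds (divergence 3/100 bp, no degeneration).
* `null`: five 1 Mb autosomes, 1 sample per sex, 25 kb report windows
  (200 windows) for band calibration.

The report-window sizes are scaled below the 1 Mb default so that the
band's ≥ 20-window precondition and its percentile granularity are
satisfied at desk scale; all rates and effect sizes are held at the
values above regardless of test outcomes.

What the simulator does *not* model — sequencing error beyond the NM
burden, indels, GC bias, mappability structure, linked selection,
structural variation other than degeneration — bounds what passing
tests show: they validate the statistics, filters, coordinate
arithmetic and end-to-end recovery of the canonical signatures, not
robustness to every artefact of real libraries.

## Numerical and design choices

* Coordinates are 0-based half-open internally; tables print 1-based
  inclusive with a README describing every column.
* Aggregation-then-mean equals the n-weighted unit mean exactly
  (asserted); normalization is invariant to scaling a sample's depths.
* Degenerate cases: a scaffold with one non-missing report window gets
  SD 0 with n = 1 recorded; an all-masked input is a hard error; an
  empty synteny map yields anchoring rate 0 and no synteny branch.
* Stage caching is keyed by content digests (never timestamps) of the
  BAMs/VCF/map plus the relevant configuration, so re-running with only
  plotting options changed re-renders without re-scanning, and
  `sexscan render` touches no tables at all.
* The variant branch always uses the unfiltered alignments; the
  consensus-genome option substitutes a base only where alternate
  alleles outnumber reference alleles across all genotypes (ties keep
  the reference), preserving scaffold names and lengths.

## Known limitations

* Heterozygosity uses a fixed-length denominator (no callable-site
  correction), so absolute het levels are underestimated where coverage
  is thin; sex differences are unaffected to first order.
* The outlier band is descriptive, not a significance test; no
  multiple-testing control is attempted, by design.
* Anchoring projects window midpoints; sub-window rearrangements within
  a block are invisible at unit-window resolution.
* Very small fully sex-linked regions (below the report window) and
  systems with ≥ 1% background heterozygosity are expected failure
  modes, flagged in the report rather than solved.
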