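# sexscan

Detection and visualization of sex-linked genomic regions from
whole-genome sequencing data of males and females.

## The problem

In species with genetic sex determination, one sex is heterogametic (XY
males, or ZW females).  The non-recombining part of a sex chromosome
leaves two genomic signatures when WGS reads from both sexes are aligned
to a reference genome built from the *homogametic* sex:

* **Coverage.** Y/W degeneration removes sequence from the sex-limited
  chromosome, so the heterogametic sex drops towards half coverage on
  X/Z-linked regions.  In young, weakly differentiated systems the Y/W
  reads still align — but they carry mismatches, so the deficit appears
  only when reads are filtered by edit distance (NM tag).
* **Heterozygosity.** In weakly differentiated regions the aligned
  gametolog reads make the heterogametic sex look excessively
  heterozygous; in fully degenerate regions the X/Z is hemizygous there
  and heterozygosity falls *below* the homogametic background.

`sexscan` scans both signatures in windows (5 kb units, aggregated into
larger report windows), under three mismatch stringencies — strict
(NM = 0), intermediate (NM ≤ 2) and unfiltered — and flags report
windows whose sex difference

&nbsp;&nbsp;&nbsp;&nbsp;*d*(w) = mean(heterogametic) − mean(homogametic)

falls outside the empirical 95% band (2.5th–97.5th percentiles) of the
genome-wide distribution of *d*.  An optional liftover anchors windows
onto a second species' assembly through a whole-genome-alignment block
map (PSL or 7-column TSV), pooling fragmented scaffolds into contiguous
chromosome coordinates and reporting the anchoring rate.

Inputs are coordinate-sorted, duplicate-marked BAMs (≥ 1 sample per
sex), a multi-sample VCF called from the unfiltered alignments, the
reference FASTA, and a YAML run configuration.  A bundled simulator
fabricates all of these, so the whole pipeline is testable offline.

## Worked example

Simulate the fully degenerate scenario (four 2.4 Mb autosomes plus a
400 kb scaffold whose first half is sex-linked with a completely
degenerate Y copy, 2 samples per sex at ~10×) and run the scan:

```
sexscan simulate --preset fig1d --out demo --seed 1 --synteny-mode identity
sexscan run --config demo/config.yaml
```

which prints

```
tables: demo/results/tables
report: demo/results/report.html
anchoring rate: 100.0%
```

The strict-filtering coverage outlier table
(`tables/study_outliers_window100000_coverage_0mm.tsv`, 1-based
coordinates) recovers exactly the simulated sex-linked windows as low
outliers, at half coverage in the heterogametic sex:

```
scaffold  start    end      n   heterogametic  homogametic  diff     outlier
scafZ     1        100000   20  0.504          1.011        -0.507   low
scafZ     100001   200000   20  0.489          1.014        -0.524   low
...
```

(the handful of autosomal `high`/`low` rows are the ~5% expected by
construction of the 95% band), and the per-scaffold summary shows the
scaffold-level coverage deficit of ≈ −0.25 (half the scaffold is
sex-linked at −0.5, half is pseudoautosomal at 0) at every mismatch
setting — the setting-independence that distinguishes full degeneration
from a young sex chromosome.  `report.html` bundles the five plot types
(genome scan, per-sex scan, per-scaffold scatter, per-chromosome
mean ± SD scatter, per-sample profiles), the outlier tables, per-sample
mean depth and genome-wide heterozygosity (with a caution above 1%),
assembly statistics (N50), and the anchoring rate.

`sexscan render --config ...` re-renders plots (e.g. with
`--chromosomes` or `--highlight`) from cached tables without touching
the analysis.

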