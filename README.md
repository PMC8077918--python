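# wgscohort

Cohort comparison of tumor/normal whole-genome sequencing data. The package
implements the bespoke computational steps of a tumor-cohort comparison study
as a tested, reusable pipeline: read-depth copy-number segmentation with
sliding-median smoothing, 1-Mb binned gain/loss frequency comparison between
cohorts with a label-randomization null, loss-of-heterozygosity (LOH)
calling from paired genotypes, clonal-architecture statistics (MATH score,
clone-count estimation, evolutionary-tree topology), mutation-spectrum and
signature-weight fitting, and parsimonious taxonomic assignment of non-host
reads. A synthetic-data module generates every input with planted ground
truth, so the whole pipeline is exercised and validated without any external
or controlled-access dataset.

It is written for researchers comparing somatic landscapes between two
tumor cohorts (for example a rare phenotype against matched conventional
cases) who need transparent, testable implementations of these steps rather
than a monolithic caller.

## The methods in brief

**CNV segmentation.** From paired binned read-depth profiles RDt and RDn,
the normal is scaled to the tumor's total signal,
RD̂n(i) = RDn(i) · ΣRDt / ΣRDn, both are aggregated into 3000-bp bins, and
the log ratio LR(b) = log2(Σ RDt / Σ RD̂n) is computed per bin. The LR track
is smoothed with a sliding median over a 1001-bin window (half-window
l_win = 500), maximal constant runs of the smoothed track become segments,
each segment's LR is recomputed from the raw binned totals, and segments
longer than 100 kb are called gains (LR > 0.2) or losses (LR < −0.2). Note
that a median filter of half-window w erases isolated events shorter than
w + 1 bins, so the default window resolves events of roughly 1.5 Mb and
larger; pass a smaller `half_window` to target smaller events.

**Cohort comparison.** Per-sample calls are mapped onto 1-Mb genome bins
(a sample counts in every bin one of its events overlaps by ≥ 1 bp), and
each bin/event-type is tested between cohorts with a two-sided Fisher exact
test. The number of significant peaks is calibrated against a null obtained
by shuffling cohort labels (group sizes preserved) and re-running the whole
map-and-test comparison, 1000 times by default.

**LOH.** A site is an LOH event when it is heterozygous in the normal and
the tumor alternate-allele fraction is ≤ af_tol or ≥ 1 − af_tol at depth
≥ 10 (defaults af_tol = 0.02).

**Clonal architecture.** MATH = 100 · 1.4826 · MAD(VAF) / median(VAF).
Clone counts come from binomial-mixture model fits (EM, 10 restarts) on
(alt, depth) pairs for k = 1…5, selected by BIC, after removing SNVs with
VAF > 0.6 or depth < 14. Clone trees (parent vectors) are classified linear
(every node ≤ 1 child) or branching.

**Spectra and signatures.** Mutations are tabulated in the 6 or 96
pyrimidine-centered classes; a 96-class spectrum s is decomposed against a
reference matrix R by minimizing ‖Rw − s‖² with w ≥ 0, Σw ≤ 1, zeroing
weights below 0.06 and re-fitting.

**Exogenous reads.** Reads with a credible host alignment (≤ 5 mismatches
per 100 bp), reads overlapping host repeats, and host multi-mapped reads
are removed; each surviving read is assigned to the lowest common ancestor
of the taxonomy leaves its zero-mismatch exogenous hits cover, and taxon
counts (rolled up to ancestors) are compared between cohorts.

## Worked example

```python
from wgscohort import (GenomeSpec, PlantedCNV, gen_rd_profiles,
                       segment_sample, segment_recovery)

genome = GenomeSpec((("chr1", 25_000_000), ("chr2", 25_000_000)), bin_size=3000)
events = [PlantedCNV("chr1", 3_000_000, 5_100_000, 1.0),
          PlantedCNV("chr2", 8_000_000, 10_000_000, -0.6)]
tumor, normal, truth = gen_rd_profiles(genome, events, base_depth=100,
                                       noise_sd=0.0, seed=1)
segments = segment_sample(tumor, normal)
for s in segments:
    if s.call != "neutral":
        print(s.chrom, s.start, s.end, round(s.lr, 3), s.call)
print(segment_recovery(truth, segments, genome))
```

prints

```
chr1 3000000 5100000 0.96 gain
chr2 8001000 9999000 -0.64 loss
(1.0, 1.0)
```

Both planted events are recovered at bin resolution (boundaries snap to the
3-kb grid of bins whose midpoints the event covers), and
precision = recall = 1.0 against the planted truth. The recovered log
ratios (0.96, −0.64) differ slightly from the planted 1.0/−0.6 because
total-signal normalization shifts the genome-wide baseline by the net
event load — an inherent property of the normalization, not noise.

The same stages are available from a shell:

```bash
wgscohort simulate rd --events chr1:3000000-5100000:1.0 --noise-sd 0 \
    --seed 1 --out-dir sim/
wgscohort cnv segment --tumor sim/tumor.bedgraph --normal sim/normal.bedgraph \
    --out sim/segments.bed
```

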