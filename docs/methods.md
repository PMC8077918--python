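# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generators emulate, the
numerical choices, and known limitations.

## CNV segmentation from read depth

The pipeline assumes copy-number change manifests as a multiplicative shift
in binned tumor read depth relative to the matched normal, with no
GC/mappability correction (out of scope) and a diploid-dominant genome so
that total-signal normalization approximates the neutral baseline.

Steps, with parameters (all configurable):

1. **Normalization.** The normal profile is multiplied by
   ΣRDt / ΣRDn so its total signal equals the tumor's. This conserves total
   signal exactly, but means the assigned log ratios are measured against a
   baseline shifted by log2 of the sample's net event load: a genome that is
   mostly amplified will see its neutral regions pushed slightly negative.
   With gain/loss thresholds at ±0.2 this matters only for heavily
   rearranged genomes.
2. **Binning.** Both profiles are aggregated into `bin_size = 3000` bp bins
   and LR(b) = log2(tumor/normal) per bin. Bins where either total is zero
   are masked (the log ratio is undefined); masked bins are excluded from
   smoothing windows and split segments. Input tracks may be at base or any
   finer resolution dividing 3000 bp; a trailing partial bin per chromosome
   is kept.
3. **Median smoothing.** Each bin is replaced by the median of the window
   [b − l_win, b + l_win] with `half_window` l_win = 500 bins (a 1001-bin,
   ≈ 3 Mb window), truncated at chromosome ends. The window is centered, so
   a stated total width of 1000 bins becomes 2·500 + 1 = 1001; a window
   wider than the chromosome truncates to the whole chromosome with a
   logged warning.

   **Detection limit.** A sliding median of half-window w is a root-signal
   operator: it reproduces constant blocks of length ≥ w + 1 bins exactly
   (including their boundaries) and removes isolated blocks of ≤ w bins
   entirely. At the defaults this puts the resolution floor at
   501 × 3 kb ≈ 1.5 Mb: smaller events cannot survive smoothing no matter
   how clean the data. Users targeting 100-kb-scale events should lower
   `half_window` to well below the expected event length in bins (e.g.
   `half_window = 20` resolves 150-kb events cleanly; see the tests).
4. **Segmentation.** Maximal runs of constant smoothed LR become segments;
   a run extends while each value is within `tol = 1e-9` of the run's first
   value. On noiseless input the smoothed track is piecewise bit-constant
   and `tol` only guards float noise. Each segment's log ratio is
   recomputed from the raw binned totals, log2(Σ tumor / Σ normal) over the
   segment's bins, not from the smoothed values.
5. **Classification.** gain iff lr > 0.2 and length > 100 kb; loss iff
   lr < −0.2 and length > 100 kb; strict inequalities, so a value exactly
   at a threshold is neutral.

Under bin-level noise the smoothed track is no longer piecewise constant:
the median stays bit-constant exactly where the window covers the entire
event (the median is then a fixed order statistic of the event's values),
which is the plateau the segmenter picks up. The called event therefore
shrinks toward the event center — a plateau of 2w + 2 − L bins for an
event of L bins — and events longer than 2w + 1 bins fragment. In noisy
data the practical detection band at the default window is roughly
1.5–2.9 Mb; boundary-exact recovery should only be expected of noiseless
input. The per-segment log ratio remains accurate because it is recomputed
from raw totals. An `intersect_with_caller` helper optionally intersects
these calls with an external caller's segments (same sign, ≥ 1 bp overlap)
when the pipeline is used as a filter on another caller's output.

## Cohort frequency maps and the randomization null

Per-sample gain/loss calls are mapped onto 1-Mb bins; a sample counts in a
bin when at least one same-type segment overlaps it by ≥ 1 bp (no minimum
overlap fraction — a segment straddling a boundary counts in both bins).
Each (bin, type) is tested with a two-sided Fisher exact test on
samples-with-event vs without across cohorts. Significance defaults to raw
p < 0.05; Bonferroni adjustment over all bin/type tests is available as a
config option (`adjust="bonferroni"`), since both conventions are in
circulation for this kind of genome-wide peak counting and the choice is
deliberately exposed rather than hard-coded.

The randomization null preserves group sizes: samples are pooled and
re-split into groups of the original sizes, the full frequency-map +
per-bin-Fisher path is re-run per iteration on the fixed per-sample calls,
and the number of significant peaks recorded (default 1000 iterations).
Per-sample calls are fixed across iterations because the shuffle acts on
cohort labels, not on the underlying segmentations. Fisher p-values are
memoized by exact table within a run; this is a pure cache of a
deterministic function and cannot drift from the primary path.

## LOH calling

Criteria: heterozygous in the normal, and tumor alternate-allele fraction
≤ af_tol or ≥ 1 − af_tol at tumor depth ≥ `min_tumor_depth`. The germline
criterion is the genotype call rather than a literal allele-frequency
equality (observed frequencies are never exactly 0.5); defaults
`af_tol = 0.02`, `min_tumor_depth = 10` absorb residual non-tumor reads and
low-coverage noise. Both tolerances are inclusive (≤/≥).

## Clonal architecture

* **MATH score** = 100 · 1.4826 · median(|VAF − median VAF|) / median(VAF);
  the 1.4826 factor is the normal-consistency scaling of the MAD. Requires
  ≥ 2 VAFs and a positive median; scale-invariant.
* **Input filters**: SNVs with VAF > 0.6 are removed before clustering
  (likely copy-number affected under the diploid-heterozygous convention
  where a fully clonal mutation sits at VAF 0.5) together with SNVs of
  depth < 14; before tree analysis, SNVs are removed only when their
  overlapping CNV segment has |lr| > 0.2 AND segment p < 0.01 (conjunction;
  unannotated records are kept).
* **Clone count**: binomial mixtures on (alt, depth) for k = 1…5, EM with
  10 restarts initialized from VAF quantiles with small seeded jitter,
  selected by BIC with 2k − 1 free parameters. This is a deliberate,
  transparent stand-in for heavier variational VAF-clustering tools; it
  recovers planted k reliably when clone VAF modes are separated by ≥ 0.15
  at depth ≈ 100 with ≥ 150–200 SNVs per clone, and degrades for closer
  modes or shallower coverage, as any 1-D mixture must.
* **Topology**: a parent-vector tree is linear iff every node has at most
  one child; a single node is linear (vacuously). Tree inference itself is
  out of scope — trees are consumed, not built.
* **Cohort comparison**: binary per-sample summaries (k = 1; tree linear)
  are compared with the Fisher exact test. A sample is "clonal" exactly
  when the estimator returns k = 1.

## Mutation spectra and signature fitting

Spectra use the pyrimidine-centered convention; purine-reference mutations
are reverse-complemented (the context string is reversed and complemented,
so the 5' flank of the purine strand becomes the 3' flank). Weights w
minimize ‖Rw − s‖² subject to w ≥ 0 and Σw ≤ 1 (solved with a bounded
SLSQP quadratic program; the single-signature case has a closed form);
weights below `trim = 0.06` — the customary default of signature-refitting
tools — are zeroed and the surviving set re-fit, with the trim re-applied
after the re-fit. No reference matrix is bundled: references are
user-supplied TSVs, and tests use a synthetic 96×4 Dirichlet reference
generated at run time.

## Exogenous reads

`filter_host` removes: reads overlapping host repeats; reads with a host
hit at ≤ 5 mismatches per 100 bp (a credible host alignment at any hit
count); and host multi-mapped reads (≥ 2 host locations), up to and —
conservatively, by default — beyond the 200-location search cap
(`remove_beyond_cap=False` retains reads exceeding the cap). A *unique*
host hit with a high mismatch rate does not remove a read. Surviving reads
with zero-mismatch exogenous hits are assigned to the lowest common
ancestor of the hit leaves, computed by depth-aligned parent walking (and
cross-checked in tests against explicit path intersection). Taxon
summaries roll counts up to ancestors, so the root count equals the number
of assigned reads, and per-taxon cohort enrichment uses Fisher tests on
per-sample presence/absence.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (parameters, seed); a single global
seed fans out to labeled sub-streams via SHA-256 hashing (`derive_seed`),
and planted truth is always returned alongside the data.

* **Read-depth profiles**: expected depth `base_depth = 100` reads per 3-kb
  bin (the scale of ~60× tumor WGS after binning), multiplied by 2^lr
  inside planted events (an event affects every bin whose midpoint it
  covers, making truth exact at bin resolution). Noise is Gaussian on bin
  totals with sd = noise_sd · sqrt(base_depth), matching Poisson-like
  dispersion at far lower cost; a per-bin Poisson mode exists behind
  `noise_model="poisson"`. Not emulated: GC and mappability waves,
  replication-timing trends, tumor purity and subclonal CNVs — so passing
  recovery tests demonstrate the signal-processing chain is correct, not
  that it is robust to real-genome covariates.
* **Genotype tables**: exactly round(n·het_fraction) het sites, of which
  round(·loh_fraction) are planted LOH; noisy mode draws depth from
  Poisson(depth ≥ 1) and alt counts binomially, with a residual
  alternate-allele rate of 0.01 at LOH sites standing in for tumor-purity
  leakage. Noiseless mode emits exact expected counts.
* **VAF tables**: a clone of cellular fraction f contributes mutations at
  expected VAF f/2 (diploid heterozygous); alt ~ Binomial(depth, f/2),
  depth ~ Poisson(mean) truncated at 1. No purity correction or subclonal
  copy number.
* **Taxonomies**: random trees of configurable depth/leaf count; read truth
  is the LCA of its hit pattern, computed in the generator by explicit
  root-path intersection (independent of the assignment code it is used to
  test).
* **Cohort features**: Bernoulli per-sample binary features with per-cohort
  probabilities.

## Problem sizes used in tests and the acceptance script

Recovery experiments use genomes of 12–50 Mb at 3-kb bins, cohorts of
20 + 23 samples (the study-scale cohort split), 1000-iteration
randomization nulls with 10–20 replicate experiments, 10,000-site LOH
tables, 200 SNVs per planted clone at depth 100, and 10,000 sampled
mutations for the signature round trip. These sizes are chosen so every
experiment is comfortably reproducible on a laptop while keeping the
statistical checks well-powered.

## Known limitations

* The median-smoothing detection floor (half_window + 1 bins) means the
  default configuration cannot detect events between the 100-kb call
  threshold and ~1.5 Mb; resolving them requires a smaller window, with
  correspondingly less noise suppression.
* Constant-run segmentation with a bit-level tolerance fragments the
  interiors of events much longer than the smoothing window under noise;
  such events are still detected via their edge plateaus only when shorter
  than twice the window. A larger `tol` trades boundary sharpness for
  robustness.
* The clone-count estimator ignores purity and copy number; its k is a
  lower bound when clones overlap in VAF space.
* Host filtering consumes alignment summaries; its correctness is relative
  to the upstream aligner's reporting (hit counts capped at the search
  limit, NM tags).
* The Wilcoxon implementation switches to the exact permutation
  distribution only for combined n ≤ 12 without ties; cohort-scale
  comparisons use the tie-corrected normal approximation with continuity
  correction.
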