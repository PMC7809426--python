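# Methods

This note records the models, conventions and numerical choices behind
`meliflora`, and what the synthetic-data experiments do and do not show.

## Synthetic data model

**Reference library.** Sequences are built top-down along the taxonomy:
independent random sequences per clade, then per-rank mutation at
declared substitution rates (family 8 %, genus 5 %, species 2 % by
default).  This guarantees the identity ordering within-genus >
within-family > within-clade that top-hit consensus assignment relies
on; the defaults put sister species at ~96 % identity and congeneric
genera at ~86 %, comfortably separated relative to the simulated
sequencing error.  Both markers share one taxonomy but have independent
sequences of equal length (marker length polymorphism is out of scope).

**Communities.** Each sample has a month (April–October, the honey
season) and a composition drawn from a symmetric Dirichlet scaled by
seasonal weights: taxon *t* has weight `base_t · exp(−(m − peak_t)² /
(2 width_t²))`, and the sample is Dirichlet(concentration · normalised
weights).  The Gaussian month kernel reproduces season-structured
composition with two parameters per taxon; the Dirichlet is the simplest
simplex-valued noise family and gives the analytic mean used by the
parameter-recovery tests (E[pᵢ] = wᵢ/Σw).  Default concentration 30
yields realistic sample-to-sample spread (a handful of dominant taxa,
many minor ones); the sparse regimes used in some tests and examples
lower it deliberately so that occurrence frequencies vary.

**Reads.** Per marker, reads per taxon are multinomial on proportions ×
per-taxon amplification bias, renormalised — metabarcoding is
semi-quantitative, and bias is the mechanism.  Forward and reverse reads
cover the two ends of the reference amplicon (default 300 bp reads on a
500 bp amplicon, 100 bp true overlap), with i.i.d. substitutions
(default 0.5 %) and a two-level quality model: Q35 at correct positions,
Q15 at substituted ones.  That is the simplest profile that exercises
quality-aware trimming and overlap consensus; real degradation gradients,
chimeras and index hopping are not modelled, so passing tests say nothing
about those failure modes.

**Pollen counts.** The historical protocol is emulated as a multinomial
of ~200 grains on the composition collapsed to an identification rank
(genus by default — microscopy rarely separates congeners), with classes
derived from grain proportions by the same quantizer as read proportions.

**Landscape.** A planar km grid; habitat labels fill exact quotas
(largest-remainder rounding, seeded shuffle — spatially unstructured),
crops flag cells inside declared circular fields.  Geographic lat/lon
metadata is projected with an equirectangular approximation; at UK scale
(< 1000 km, mid-latitudes) the distance error is well under 1 %, which is
negligible against 2 km radii and kNN neighbourhoods.

All generators take a seed and are byte-deterministic given identical
arguments.

## Read processing conventions

* **Trimming**: the retained read is the longest prefix containing no
  complete window (default 4 bp) whose mean Phred quality is below the
  threshold (default 20); a remainder shorter than one window must pass
  the mean check on its own.  This is a declared rule, not a
  reimplementation of any specific trimmer.
* **Merging**: candidate overlaps between the forward 3′ end and the
  reverse-complement 5′ end are scanned from the longest length down;
  the first whose mismatch fraction is ≤ 0.1 (default) wins, the
  higher-quality base is taken at overlap mismatches (ties keep the
  forward base), and merged sequences shorter than 450 bp are discarded.
  Equal-length overlap ties cannot arise in this suffix–prefix scheme.
* **Clustering** keys on exact string equality ("100 % identity" taken
  literally); singletons are removed after cross-sample clustering, so a
  sequence seen once in each of two samples survives.
* Every discard carries a reason code (`too_short_after_trim`,
  `no_overlap`, `merged_too_short`) and counts are conserved:
  merged + discarded = input pairs at every stage.

## Assignment conventions

The built-in aligner uses edlib's edit-distance-optimal global alignment,
rescored with match +2 / mismatch −3 / gap −5 and converted to bits via
`(λS − ln K)/ln 2` with λ = 0.625, K = 0.41.  For the high-identity
hits that decide assignments, the edit-distance-optimal path is also
score-optimal; imported BLAST tabular hits bypass the aligner entirely
and are the fidelity path for real data.  Raw scores ≤ 0 are dropped.

The 1st-percentile bit-score exclusion is computed over per-query *best*
scores, globally per marker per run (the percentile scope is
configurable); the threshold is the linear-interpolated quantile, and
exclusion is strict (`best < threshold`), so an all-equal run excludes
nothing.  "Top hits" are exact ties at the query maximum by default; a
tolerance window (`top_bits_tolerance`) exposes the alternative.  Any
tie spanning multiple families is excluded, whether or not the families
share a clade — the clade rank is retained for reporting.  Manual
botanical-veracity checks of the kind applied to real surveys are not
automated; an allow/deny list can be applied to assignment tables
downstream.

## Abundance classes

Boundaries (proportion *p* of reads or grains within one sample):
predominant (0.45, 1], secondary [0.15, 0.45], important minor
[0.01, 0.15), minor (0, 0.01).  "> 45 %" is strict as printed in the
melissopalynology convention; the closed/open choices at 0.15 and 0.01
leave no gaps and are configurable in spirit — they matter only for
proportions exactly on a boundary.  Proportions are computed on the
combined (rbcL + ITS2) layer.  Seasonal summaries exclude months with
fewer than 10 samples.  Rarefaction subsamples without replacement
(multivariate hypergeometric) to an exact depth, dropping shallower
samples with a log entry.

## Comparison statistics

Harmonization matches taxa whose lineages nest, at the coarser of the
two recorded ranks, summing within-sample proportions before
re-deriving classes; non-nesting names are reported unmatched.  Kendall
τ-b is used because occurrence frequencies tie heavily; for n ≤ 8 the
p-value enumerates all n! orderings (ties included), otherwise the
normal approximation is used.  χ² tests are Pearson, Yates correction
off by default (a flag enables it); expected counts below 1 set a
warning flag.  Degenerate 2×2 tables with an empty margin (a taxon major
in all samples of both surveys, or in none) return statistic 0 by
convention.  Bonferroni is min(1, m·p).  The major-change screen keeps
taxa whose major frequency exceeds 1 % in both surveys, mirroring the
survey-comparison design it emulates.  A multivariate
presence/absence-by-county model is out of scope; the harmonized table
is the input such a model would consume.

## Spatial statistics

Moran's I uses row-standardized kNN weights (default k = 8, capped at
n − 1 for small surveys; inverse-distance weights available).  The
permutation test permutes values over sites; p = two-sided by doubling
the smaller tail, each tail (1 + #extreme)/(1 + n_perm), so p has
resolution 1/(n_perm + 1) and can never reach 0.  A direct consequence:
with 199 permutations the smallest two-sided p is 0.01, so a
Bonferroni-corrected screen over 150 taxa cannot flag anything — screens
that need family-wise significance must use more permutations (the
planted-signal experiment uses 9999).  Within one screen the permutation
index matrix is drawn once and shared across taxa, which turns the whole
screen into one matrix product; each per-taxon test remains valid.  The
neighbour-graph conventions of other spatial packages are not
reproduced, so results are framework-comparable rather than
value-comparable with analyses built on, e.g., Moran eigenvector maps.

## Validation experiments and their scope

`meliflora.experiments` (run by the test suite and
`scripts/acceptance.py`) measures:

* end-to-end abundance-class recovery at 50 samples × 20 taxa ×
  2 markers × 2000 read pairs, 0.5 % error — recovery is evaluated for
  taxa with true proportion ≥ 15 %.  Residual failures are dominated by
  true proportions within ~1 percentage point of the 0.15 class
  boundary, where a multinomial estimate at this depth legitimately
  falls on either side; the recovery rate therefore fluctuates by a few
  points across seeds with no systematic bias (mean recovered-minus-true
  proportion ≈ 0).
* consensus assignment vs a brute-force tied-top-set taxonomy walk;
* χ² vs the 2×2 product formula, τ-b vs O(n²) pair enumeration,
  Bonferroni vs min(1, m·p);
* type-I error and power of the change test at the historical/modern
  sample sizes (855 / 441), with null major frequencies spread over
  5–70 %;
* Moran screen null calibration (150 taxa, 200 sites, 199 permutations)
  and planted-cluster recovery;
* rarefaction class concordance at depth 5000, excluding cells within
  0.5 percentage points of a class boundary.

These experiments validate the pipeline's internal consistency and
statistical calibration on data matching the generator's assumptions.
They do not establish accuracy on real honey data, where reference-library
gaps, chimeras, length variation between markers and PCR bias structure
the errors differently.
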