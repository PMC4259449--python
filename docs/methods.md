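# Methods

This note documents the models and procedures implemented in `dtcsig`,
the assumptions behind them, the tunable parameters with their defaults,
and what the synthetic-data generator does and does not emulate.

## Data model

The central object is a probe/gene × cell matrix of two-color microarray
measurements: `M = log2(sample / reference)` per probe and cell, paired
with `A`, the mean channel fluorescence intensity (arbitrary units).
Missing measurements are first-class (NaN) and are distinguished from
zero everywhere: a missing value never counts as a signature call, never
enters a mean or variance, and survives normalization untouched. Cell
metadata carries patient, clinical group (NED = no evidence of disease,
ADV = advanced), EpCAM staining grade (2–4), and the pipeline status of
each cell.

## Normalization

**Within-array loess.** Two-color arrays show intensity-dependent dye
bias, so per cell the M values are replaced by residuals of a locally
weighted regression of M on log2 A (tricube weights, span 0.4, two
robustness iterations via `statsmodels`' lowess). Cells with fewer than
20 usable (M, A) pairs are passed through with a warning rather than
fitted — a 20-point loess is noise. Span 0.4 and two robustness passes
are the conventional M-A defaults; nothing downstream is sensitive to
the span at the 0.3–0.5 level on the synthetic data.

**Among-array quantile normalization.** Every cell is mapped onto the
across-cell mean quantile profile. With complete data this is the classic
sort / row-mean / unsort algorithm (and the implementation reproduces it
exactly; see the oracle test). With missing values, ranks are computed on
each cell's non-missing entries (ties averaged) and the target profile is
linearly interpolated at the cell's normalized rank positions — gaps in
one cell must not shift the values of another. The operation is
idempotent on complete data to 1e-12; with missing data the interpolation
makes a second pass agree only approximately, which is why the
idempotence property is asserted on complete matrices.

## Quality filters

- Cells: removed when **strictly more than 25 %** of probes are missing
  (a cell at exactly 25 % is retained), or when the median intensity over
  non-missing probes falls below a signal floor. "Poor hybridization
  signal" is not a number anywhere upstream, so the floor defaults to the
  5th percentile of all cells' median intensities and is configurable;
  pass `min_median_signal=0` to disable it.
- Probes: removed when the across-cell mean intensity (non-missing
  entries only) is **strictly below 300** units; a probe at exactly 300
  is retained. The filter applies to raw intensities before
  normalization — intensity is a property of the measurement, not of the
  normalized ratio.

All filters report counts that reconcile exactly with the input/output
shapes; the pipeline asserts this conservation at run time.

## Probe collapsing

Agilent 4x44K probes map many-to-one onto gene symbols. The default rule
keeps, per symbol, the probe with the largest inter-quartile range across
cells (`max_iqr`) — the conventional choice that preserves dynamic range;
`mean` averaging is available. Ties break lexicographically by probe id
so results are order-independent. Symbols are matched case-insensitively
after whitespace stripping, because GMT and annotation sources disagree
on case.

## GSVA scoring

The per-cell, per-gene-set enrichment score follows the published GSVA
recipe for continuous data:

1. Per gene `i`, a Gaussian-kernel empirical CDF across cells:
   `z_ij = (1/n) Σ_k Φ((x_ij − x_ik)/h_i)` with bandwidth
   `h_i = sd_i / 4` (the published default). Constant genes and missing
   entries receive the neutral level 0.5; missing entries are excluded
   from the CDF sample.
2. Per cell `j`, genes are ranked by decreasing `z_ij` (ties broken by
   gene position, deterministically) and the rank is folded into the
   symmetric statistic `|p/2 − r_ij|`.
3. A weighted random walk down the ranked list: set genes increment by
   their folded rank to the power τ (default 1), normalized over the
   set; non-set genes decrement uniformly by `1/(p − m)`. The score is
   the maximum positive deviation plus the maximum negative deviation,
   bounded in [−1, 1].

Because the kernel bandwidth scales with the data, the score is exactly
invariant to increasing affine transforms of the matrix, and equivariant
under cell permutations. It is **not** invariant under arbitrary
monotone transforms of a single cell's values: the kernel CDF step pools
information across cells by design. For genes with strongly bimodal
distributions (exactly the erythroid/prostate markers in a mixed
population), cells in the low mode get mid-range levels rather than
extreme ones, so scores of true-negative cells hover near zero rather
than at −1; the classification thresholds sit at 0 for this reason.

## Cell classification

A QC-passing cell is classified with the dual criterion, erythroid
exclusion first (so the two excluded classes are disjoint and the three
statuses partition the cells):

1. erythroid GSVA score > θ_e (default 0) → `excluded_erythroid`;
2. else prostate GSVA score < θ_p (default 0), or NKX3-1 log-ratio not
   above 0 where NKX3-1 was measured → `excluded_low_prostate`;
3. else `retained_dtc`.

A **missing** NKX3-1 measurement is not evidence of low expression; the
NKX3-1 requirement applies only where the gene was observed. Without
this rule, every retained-quality cell with a dropout at one probe would
be discarded on a technicality.

## Differential expression

**SAM.** `d_i = (x̄_i1 − x̄_i2)/(s_i + s₀)` with `s_i` the pooled standard
error. `s₀ = "auto"` picks, among the 5-percentile grid of `s`, the value
minimizing the coefficient of variation of the windowed median absolute
deviation of `d` (20 quantile windows of `s`) — the standard
variance-stabilizing calibration. With `s₀ = 0` and equal group variances
`d` is the pooled two-sample t statistic to machine precision (asserted
against a hand-coded oracle). q-values: the observed `|d|` are compared
with a pooled permutation null of the group labels (default 1000 seeded
splits; all distinct splits enumerated when fewer exist), giving
empirical p-values that are then Benjamini–Hochberg adjusted. The null
partitions are drawn on a canonical cell-id-sorted column order with the
smaller group size, which makes q exactly invariant under swapping the
two group labels while `d` negates.

**t-tests.** Per-gene unpaired Welch tests (scipy) with BH q-values;
degenerate genes (zero variance in both groups with equal means) get
t = 0, p = 1. Genes with fewer than two observations in either group are
dropped from both procedures — single-cell arrays are gappy and a
one-point variance is meaningless.

**Selection.** The NED-vs-ADV signature is the top and bottom 50 genes by
SAM `d` (ties by symbol, so selection is stable); global clustering uses
the 5000 genes with the largest across-cell IQR (capped at the gene count
when the matrix is smaller, as with the synthetic default of 2000 genes).

## Clustering and ADV subgroups

Cells are clustered Eisen-style: distance = 1 − Pearson correlation over
pairwise-complete entries (Euclidean available), average linkage
(complete and Ward available) via scipy. Cells enter in identifier-sorted
order, so the tree is invariant to input order. A cell with zero variance
under correlation distance is an error naming the cell.

ADV subgrouping cuts the dendrogram of the retained ADV cells — computed
on the top/bottom-50 signature genes — at k = 2. The cluster whose
centroid (gene-wise mean, missing ignored) lies closer in Euclidean
distance to the NED centroid is labeled ADV_2 (NED-like), the other
ADV_1. Exact ties go to the larger cluster, then to the cluster holding
the lexicographically smallest cell id, with a log message. NED retained
cells all carry subgroup NED; {ADV_1, ADV_2} partitions the retained ADV
cells.

Clustering quality depends on normalization: on raw simulated data the
per-patient intercepts and unequal value distributions let average
linkage chain off tiny outlier clusters, while after loess + quantile
normalization the planted split is recovered exactly (see
`examples/04`). This is the reason the pipeline normalizes before any
distance computation.

## Preranked GSEA

Given a gene → score ranking (descending; ties by symbol), the enrichment
score is the extremum of the running sum where hits add `|score|^p`
normalized over the set (p = 1 default) and misses subtract `1/(n − m)`.
The null permutes gene labels — random same-size sets, the only null
available in preranked mode — with one-sided p on the sign of the
observed ES and an FDR from pooling normalized ES (NES) over all sets and
permutations. Sets overlapping the ranking by fewer than two genes are
skipped with a warning. Fixed seed gives bit-identical p and FDR.

## Dormancy coverage

For a cell and an UP signature, `coverage_up` is the percentage of the
signature's matrix-present genes whose value is strictly above `τ_up`;
`coverage_down` analogous with strictly below `τ_down`. Defaults
`τ_up = τ_down = 0`: on loess/quantile-normalized log-ratios, zero is the
pooled-reference level, so "induced" means above reference. Missing
values never count as calls; genes absent from the matrix shrink the
recorded denominator and nothing else; a gene in both the UP and DOWN
sets is a configuration error. `coverage_up` is monotone non-decreasing
as `τ_up` decreases (property-tested).

Group comparison regresses coverage on a 0/1 group indicator. The
coefficient is algebraically the difference of group means (asserted to
1e-12 and cross-checked against statsmodels OLS), and its two-sided
t-test is the equal-variance two-sample t-test, evaluated in closed
form. Group means ± SD (unbiased, n−1) are reported alongside.

The dormancy gene sets bundled in `dtcsig.signatures` are **synthetic
placeholders** (`DORMUP_SYN01…26`, `DORMDN_SYN01…21`): the real p38-linked
dormancy signature is not redistributable from this package (part of it
was never published), and the coverage statistic is signature-agnostic.
The placeholder sets are size-matched (26 UP, 21 DOWN) so that worked
examples and the generator exercise the same shapes; analyses of real
data must supply their own GMT files.

## Synthetic data generator

The generator emulates the study design the analysis assumes, at a scale
where the whole pipeline runs in seconds:

| parameter | default | meaning |
|---|---|---|
| patients | 4 NED + 6 ADV | clinical groups |
| cells/patient | 10 (or a range) | ~100 cells total |
| contaminant fraction | 0.4 | erythroid-like cells among sorted cells |
| ADV dormant fraction | 0.4 | latent NED-like (ADV_2) state |
| effect size Δ | 2.0 log2 | signature shifts |
| patient SD | 0.3 log2 | additive random intercept per patient |
| noise SD | 0.5 log2 | i.i.d. Gaussian on log-ratios |
| missing rate | 0.05 | plus optional planted 40 %-missing cells |
| genes | 2000 | 63 signature + background |
| intensities | log-normal, median ≈ 1000 | 15 % of background probes planted below the 300 filter |

Log-ratios are baseline 0 + patient intercept + class shifts + noise.
Erythroid contaminants carry the erythroid panel at +Δ and the prostate
panel at −Δ; DTC the reverse (an epithelial cell is depleted of
hemoglobin transcripts relative to a pooled reference); dormant DTC
additionally carry the dormancy UP set at +Δ and the DOWN set at −Δ,
while active DTC leave the dormancy genes at baseline (hence ~50 %
coverage, the chance level at τ = 0). All NED DTC are dormant-like; the
ADV dormant fraction creates the ADV_1/ADV_2 structure. Planted
low-intensity probes come only from the background genes and all other
base intensities are kept above the filter floor, so planted counts are
exact and signature genes never vanish in the probe filter. Contaminants
are mostly EpCAM grade 2, DTC grade 3–4. Fixed seed ⇒ bit-identical
output, and planted fractions are deterministic counts, not Bernoulli
draws.

What the generator does **not** emulate: intensity-dependent dye bias
(M is independent of A, so loess is exercised as a near-no-op),
correlated gene modules beyond the planted signatures, heavy-tailed or
batch-structured noise, dropout that depends on expression level, and
probe-level redundancy (it emits gene-level rows). Passing the recovery
tests therefore shows the statistics recover structure of the assumed
form at realistic effect sizes — not that they are robust to every
artifact of real arrays.

## Pipeline and reproducibility

`run_pipeline` executes the stages in fixed order from a validated flat
YAML config (unknown keys rejected with a did-you-mean suggestion;
defaults echoed), writes TSV/GMT/JSON outputs, and asserts cell-count
conservation: profiled = QC-failed + (excluded_erythroid +
excluded_low_prostate + retained), retained = NED + ADV_1 + ADV_2. One
master seed drives SAM permutations (seed) and GSEA permutations
(seed + 1); reports carry no timestamps, so reruns are byte-identical.
The default synthetic run (2000 genes × 100 cells, 1000 SAM and GSEA
permutations) completes in well under a minute on one CPU.

## Known limitations

- GSVA scores for small sets (8 genes) on bimodal markers cluster near 0
  for the negative class; thresholds other than 0 may suit other marker
  panels.
- The SAM q-value uses a pooled-null + BH construction, not the original
  "median number of falsely called genes" plateau estimate; the two agree
  in ordering but not necessarily in value.
- Preranked GSEA FDR with very few gene sets is coarse (pooling has
  little to pool).
- Exact reproduction of any specific published heatmap/leaf order is not
  claimed: distance and linkage choices upstream of such figures are
  rarely reported, and the defaults here (correlation, average) are field
  convention.
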