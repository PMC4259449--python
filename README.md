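# dtcsig

Single-cell transcriptomic analysis of **disseminated tumor cells (DTC)**
from bone marrow: normalization and QC of two-color microarray profiles,
signature-based separation of genuine tumor cells from hematopoietic
contaminants, differential-expression signatures between clinical groups,
subgroup discovery, and a per-cell **dormancy-signature coverage**
statistic.

## The problem

In prostate cancer, tumor cells that disseminate to the bone marrow can
persist for years without clinical recurrence. Profiling single
EpCAM+/CD45− cells sorted from bone-marrow aspirates raises three analysis
problems this package addresses:

1. **Contamination.** Immature erythroid progenitors transiently express
   EpCAM, so the sorted population mixes real DTC with erythroid-like
   cells. Cells are scored per-sample against an 8-gene erythroid panel
   (AHSP, CA1, HBA1, HBA2, HBB, HBD, LMO2, MYB) and an 8-gene prostate
   epithelial panel (AR, CD63, FOLH1, HOXB13, ID1, NKX3-1, RELB, XAGE1A)
   and classified by a dual criterion: low erythroid score **and** high
   prostate score including elevated NKX3-1.
2. **Heterogeneity.** DTC from patients with advanced disease (ADV) split
   into two states: ADV_1 (distinct from the no-evidence-of-disease, NED,
   profile) and ADV_2 (NED-like), found by hierarchical clustering on the
   top/bottom-50 NED-vs-ADV signature.
3. **Dormancy.** Each cell is scored for the fraction of a
   dormancy-associated gene signature it expresses in the right direction
   (the *coverage* statistic), and group means are compared.

## Methods at a glance

- **Normalization** — per-cell loess of M on A (log-ratio on log
  intensity, tricube weights), then quantile normalization among cells
  with missing-value-aware rank interpolation.
- **QC filters** — cells with > 25 % missing probes or poor hybridization
  signal removed; probes with mean intensity below 300 removed.
- **GSVA scores** — per gene, a Gaussian-kernel empirical CDF across cells
  (bandwidth `sd/4`); per cell, genes ranked by that level and folded into
  `|p/2 − r|`; a weighted Kolmogorov–Smirnov-like random walk gives the
  enrichment score `ES = max⁺(walk) + min⁻(walk) ∈ [−1, 1]`.
- **SAM** — `d_i = (x̄₁ − x̄₂) / (s_i + s₀)` with pooled standard error
  `s_i` and the fudge factor `s₀` calibrated to stabilize the coefficient
  of variation of `|d|` across windows of `s_i`; q-values from a pooled
  label-permutation null (seeded, exhaustive when few distinct splits).
- **Preranked GSEA** — weighted running-sum enrichment score with a
  gene-label permutation null and NES-pooled FDR.
- **Coverage** — `coverage_up = 100 · |{g ∈ UP ∩ matrix : x_g > τ_up}| /
  |UP ∩ matrix|`, analogously for DOWN with `x_g < τ_down`; group contrast
  via indicator regression (coefficient = difference of group means)
  with a two-sided t-test.

## Worked example

```bash
python examples/06_full_pipeline.py
```

simulates the default study — 100 cells from 10 patients (4 NED, 6 ADV),
40 % planted erythroid contaminants, a latent dormant/active split in the
ADV group, signature effect size 2.0 log2, noise SD 0.5 — and runs the
whole pipeline. Output:

```
cells_profiled        100
cells_qc_failed       7
cells_qc_passed       93
excluded_erythroid    37
excluded_low_prostate 0
retained_dtc          56
subgroup_NED          19
subgroup_ADV_1        22
subgroup_ADV_2        15

  statistic group_a group_b  n_a  n_b  mean_a  sd_a  mean_b   sd_b  difference       t     p
coverage_up     NED     ADV   19   37  94.939 4.632  67.879 23.504      27.060   4.948 0.000
coverage_up     NED   ADV_1   19   22  94.939 4.632  49.825  9.678      45.114  18.545 0.000
coverage_up     NED   ADV_2   19   15  94.939 4.632  94.359  4.077       0.580   0.382 0.705
coverage_up   ADV_1   ADV_2   22   15  49.825 9.678  94.359  4.077     -44.534 -16.777 0.000
```

Reading the numbers: of 100 profiled cells, 7 fail QC, 37 are excluded as
erythroid-like and 56 are retained as DTC. Retained ADV cells split into
ADV_1 and a NED-like ADV_2. NED cells call ~95 % of the dormancy UP
signature induced versus ~50 % in ADV_1 (difference 45.1 points,
p ≈ 6·10⁻²¹), while NED and ADV_2 are indistinguishable (p = 0.705) —
exactly the pattern planted by the generator.

The other examples (`examples/01…05`) run each stage on its own:
simulation, normalization + QC, classification, differential expression +
subgrouping, and coverage.

The `dtcsig` command exposes the same pipeline from the shell
(`dtcsig simulate`, `dtcsig run --config config.yaml`, `dtcsig score`,
`dtcsig coverage`).

## Layout

```
src/dtcsig/      io, preprocess, score, differential, cluster,
                 enrichment, coverage, simulate, pipeline, cli
examples/        one narrative script per capability
tests/           unit, property and acceptance tests (pytest)
docs/methods.md  models, assumptions, parameter choices, limitations
```
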