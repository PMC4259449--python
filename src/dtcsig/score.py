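"""Single-sample gene-set enrichment (GSVA) and dual-signature cell
classification.

The GSVA statistic summarizes, per cell, how concentrated a gene set's
members are at the top (or bottom) of that cell's expression profile after
a rank transformation that normalizes each gene across cells:

1. per gene, a kernel-smoothed empirical CDF across cells (Gaussian kernel,
   bandwidth = per-gene SD / 4) turns each value into a relative expression
   level z in (0, 1);
2. per cell, genes are ranked by decreasing z and the rank r is folded into
   the symmetric statistic |p/2 - r| (p = number of genes);
3. a weighted Kolmogorov-Smirnov-like random walk down the ranked list
   accumulates the folded-rank weights at set genes and a uniform decrement
   at non-set genes; the score is the maximum positive deviation plus the
   maximum negative deviation of the walk, bounded in [-1, 1].

Cells are then classified by the dual criterion used for EpCAM+/CD45-
bone-marrow cells: high erythroid progenitor-like score excludes a cell as
a hematopoietic contaminant; low prostate epithelial score (or absent
NKX3-1 expression) excludes it as non-prostate; the remainder are retained
as disseminated tumor cells (DTC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import CellRecord, CellStatus, ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)


@dataclass
class ClassificationRule:
    """Thresholds for the dual erythroid/prostate criterion.

    Scores are on the GSVA scale (positive = enriched). A cell is excluded
    as erythroid-like when its erythroid score exceeds ``erythroid_threshold``;
    otherwise excluded as low-prostate when its prostate score falls below
    ``prostate_threshold`` or (if ``require_nkx31``) its NKX3-1 log-ratio is
    not above ``nkx31_min``.
    """

    erythroid_threshold: float = 0.0
    prostate_threshold: float = 0.0
    nkx31_min: float = 0.0
    require_nkx31: bool = True
    erythroid_set: str = "ERYTHROID_PROGENITOR"
    prostate_set: str = "PROSTATE_EPITHELIAL"
    nkx31_symbol: str = "NKX3-1"

    def __post_init__(self) -> None:
        for v in (self.erythroid_threshold, self.prostate_threshold, self.nkx31_min):
            if not np.isfinite(v):
                raise ValueError("classification thresholds must be finite")


def _kernel_cdf_levels(X: np.ndarray) -> np.ndarray:
    """Gaussian-kernel ECDF statistic per gene across cells.

    z[i, j] = mean_k Phi((x[i, j] - x[i, k]) / h_i) with h_i = SD_i / 4.
    Missing entries receive the neutral level 0.5 and are excluded from the
    ECDF sample. Constant genes get 0.5 everywhere.
    """
    p, n = X.shape
    z = np.full((p, n), 0.5)
    chunk = max(1, int(2**22 // max(n * n, 1)))
    for start in range(0, p, chunk):
        rows = X[start:start + chunk]  # (c, n)
        mask = np.isfinite(rows)
        counts = mask.sum(axis=1)
        filled = np.where(mask, rows, 0.0)
        mean = filled.sum(axis=1) / np.maximum(counts, 1)
        var = (np.where(mask, (rows - mean[:, None]) ** 2, 0.0).sum(axis=1)
               / np.maximum(counts - 1, 1))
        h = np.sqrt(var) / 4.0
        diffs = rows[:, :, None] - rows[:, None, :]  # (c, n, n): x_ij - x_ik
        with np.errstate(invalid="ignore", divide="ignore"):
            cdf = norm.cdf(diffs / h[:, None, None])
        valid_k = mask[:, None, :]
        cdf = np.where(valid_k, cdf, 0.0)
        denom = counts[:, None]
        zi = cdf.sum(axis=2) / np.maximum(denom, 1)
        usable = mask & (h[:, None] > 0) & (counts[:, None] > 0)
        z[start:start + chunk][usable] = zi[usable]
    return z


def gsva_score(m: ExpressionMatrix, sets: list[GeneSet], tau: float = 1.0) -> pd.DataFrame:
    """Compute GSVA enrichment scores (cells x gene sets).

    ``m`` must be gene-level (rows keyed by symbol). Set genes absent from
    the matrix are ignored with a logged count; a set with no matched gene
    raises. Requires at least 3 cells.
    """
    if m.n_cells < 3:
        raise ValueError("GSVA requires >= 3 cells")
    genes = [str(g) for g in m.probe_ids]
    gene_lower = [g.strip().lower() for g in genes]
    index_of = {}
    for i, g in enumerate(gene_lower):
        index_of.setdefault(g, i)

    member_idx: dict[str, np.ndarray] = {}
    for s in sets:
        idx = sorted({index_of[g.strip().lower()] for g in s.genes
                      if g.strip().lower() in index_of})
        n_absent = len(s.genes) - len(idx)
        if not idx:
            raise ValueError(f"gene set {s.name!r} has no genes in the matrix")
        if n_absent:
            logger.info("gsva_score: %d/%d genes of %s absent from matrix",
                        n_absent, len(s.genes), s.name)
        member_idx[s.name] = np.asarray(idx)

    X = m.values.to_numpy(dtype=float)
    p, n = X.shape
    z = _kernel_cdf_levels(X)

    scores = pd.DataFrame(index=pd.Index(m.cell_ids, name="cell_id"),
                          columns=[s.name for s in sets], dtype=float)
    gene_order_key = np.arange(p)
    for j in range(n):
        # rank genes by decreasing z; ties broken by gene position for determinism
        order = np.lexsort((gene_order_key, -z[:, j]))
        r = np.empty(p, dtype=float)
        r[order] = np.arange(1, p + 1)
        folded = np.abs(p / 2.0 - r) ** tau
        for s in sets:
            idx = member_idx[s.name]
            msize = idx.size
            hit = np.zeros(p, dtype=bool)
            hit[idx] = True
            hit_ord = hit[order]
            w = folded[order] * hit_ord
            wsum = w.sum()
            if wsum == 0:
                scores.iloc[j, scores.columns.get_loc(s.name)] = 0.0
                continue
            step = w / wsum - (~hit_ord) / float(p - msize)
            walk = np.cumsum(step)
            es = max(walk.max(), 0.0) + min(walk.min(), 0.0)
            scores.iloc[j, scores.columns.get_loc(s.name)] = es
    return scores


def classify_cells(scores: pd.DataFrame, m: ExpressionMatrix,
                   records: list[CellRecord],
                   rule: ClassificationRule | None = None) -> list[CellRecord]:
    """Apply the dual erythroid/prostate criterion to QC-passing cells.

    Precedence: erythroid exclusion is evaluated first, so the two excluded
    classes are disjoint. Returns new CellRecords; cells already marked
    qc_failed are untouched.
    """
    rule = rule or ClassificationRule()
    nkx_row = None
    if rule.require_nkx31:
        target = rule.nkx31_symbol.strip().lower()
        matches = [g for g in m.probe_ids if str(g).strip().lower() == target]
        if not matches:
            raise ValueError(f"{rule.nkx31_symbol} absent from matrix but require_nkx31 is set")
        nkx_row = m.values.loc[matches[0]]

    out: list[CellRecord] = []
    for rec in records:
        if rec.status == CellStatus.QC_FAILED or rec.cell_id not in scores.index:
            out.append(rec)
            continue
        e = scores.at[rec.cell_id, rule.erythroid_set]
        pscore = scores.at[rec.cell_id, rule.prostate_set]
        # a missing NKX3-1 measurement is not evidence of low expression:
        # the NKX3-1 criterion only applies where the gene was observed
        nkx_low = False
        if nkx_row is not None:
            v = nkx_row[rec.cell_id]
            nkx_low = bool(np.isfinite(v) and v <= rule.nkx31_min)
        if e > rule.erythroid_threshold:
            status = CellStatus.EXCLUDED_ERYTHROID
        elif pscore < rule.prostate_threshold or nkx_low:
            status = CellStatus.EXCLUDED_LOW_PROSTATE
        else:
            status = CellStatus.RETAINED_DTC
        out.append(replace(rec, status=status))
    n = pd.Series([r.status.value for r in out]).value_counts().to_dict()
    logger.info("classify_cells: %s", n)
    return out
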