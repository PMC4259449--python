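"""Within-array loess and among-array quantile normalization, plus the
cell- and probe-level quality filters applied before any analysis.

The normalization model is the standard two-color M-A correction: per cell,
the log-ratio M is regressed on mean intensity A with a locally weighted
(loess) fit and replaced by its residual, removing intensity-dependent dye
bias; the cells are then quantile normalized among arrays so each shares a
common value distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

MIN_LOESS_POINTS = 20


@dataclass
class QcReport:
    """Bookkeeping for the QC filters; counts reconcile exactly with the
    input/output matrix shapes."""

    cells_in: int = 0
    cells_removed_missing: int = 0
    cells_removed_signal: int = 0
    probes_in: int = 0
    probes_removed_low_intensity: int = 0
    thresholds: dict = field(default_factory=dict)
    removed_cells: list[str] = field(default_factory=list)
    removed_probes: list[str] = field(default_factory=list)

    @property
    def cells_retained(self) -> int:
        return self.cells_in - self.cells_removed_missing - self.cells_removed_signal

    @property
    def probes_retained(self) -> int:
        return self.probes_in - self.probes_removed_low_intensity

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("cells_in", self.cells_in),
            ("cells_removed_missing", self.cells_removed_missing),
            ("cells_removed_signal", self.cells_removed_signal),
            ("cells_retained", self.cells_retained),
            ("probes_in", self.probes_in),
            ("probes_removed_low_intensity", self.probes_removed_low_intensity),
            ("probes_retained", self.probes_retained),
        ]
        return pd.DataFrame(rows, columns=["metric", "count"])


def loess_normalize_within(m: ExpressionMatrix, span: float = 0.4,
                           iterations: int = 2) -> ExpressionMatrix:
    """Replace each cell's M by the residual of a loess fit of M on A.

    Tricube-weighted local linear regression with ``iterations`` robustness
    reweightings. Cells with fewer than 20 non-missing (M, A) pairs are
    passed through unchanged with a warning. A values and the missing mask
    are untouched.
    """
    if m.intensities is None:
        raise ValueError("loess normalization requires intensities (A values)")
    out = m.values.copy()
    A = np.log2(m.intensities.to_numpy(dtype=float))
    M = m.values.to_numpy(dtype=float)
    for j, cell in enumerate(m.cell_ids):
        ok = np.isfinite(M[:, j]) & np.isfinite(A[:, j])
        n = int(ok.sum())
        if n < MIN_LOESS_POINTS:
            logger.warning("cell %s has only %d usable (M, A) pairs; loess skipped", cell, n)
            continue
        mj, aj = M[ok, j], A[ok, j]
        if np.ptp(aj) == 0:  # degenerate: constant intensity, fit is the mean
            fitted = np.full(n, mj.mean())
        else:
            fitted = lowess(mj, aj, frac=span, it=iterations, return_sorted=False)
        resid = mj - fitted
        col = out[cell].to_numpy(dtype=float)
        col[ok] = resid
        out[cell] = col
    return ExpressionMatrix(out, m.intensities)


def quantile_normalize_across(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile normalize cells so each shares the mean quantile profile.

    Ranks are computed per cell on non-missing entries (ties averaged); the
    target profile is the across-cell mean of the per-cell quantile
    functions evaluated on a common grid, with linear interpolation for
    cells whose non-missing count differs from the grid size. Complete,
    equal-length columns reproduce classic sort/mean/unsort quantile
    normalization exactly.
    """
    if m.n_cells < 2:
        raise ValueError("quantile normalization needs >= 2 cells")
    X = m.values.to_numpy(dtype=float)
    n_rows = X.shape[0]
    grid = np.linspace(0.0, 1.0, n_rows)

    profiles = np.empty((n_rows, X.shape[1]))
    for j in range(X.shape[1]):
        col = X[:, j]
        vals = np.sort(col[np.isfinite(col)])
        if vals.size == 0:
            raise ValueError(f"cell {m.cell_ids[j]!r} has no non-missing values")
        if vals.size == 1:
            profiles[:, j] = vals[0]
        else:
            own_grid = np.linspace(0.0, 1.0, vals.size)
            profiles[:, j] = np.interp(grid, own_grid, vals)
    target = profiles.mean(axis=1)

    out = np.full_like(X, np.nan)
    for j in range(X.shape[1]):
        col = X[:, j]
        ok = np.isfinite(col)
        k = int(ok.sum())
        ranks = pd.Series(col[ok]).rank(method="average").to_numpy()  # 1..k
        q = np.zeros(k) if k == 1 else (ranks - 1.0) / (k - 1.0)
        out[ok, j] = np.interp(q, grid, target)
    df = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(df, m.intensities)


def filter_cells(m: ExpressionMatrix, max_missing_fraction: float = 0.25,
                 min_median_signal: float | None = None) -> tuple[ExpressionMatrix, QcReport]:
    """Remove cells with too many missing probes or poor hybridization signal.

    A cell is removed when its fraction of missing values is strictly
    greater than ``max_missing_fraction`` (default 0.25: a cell missing
    exactly 25% of probes is retained), or when its median intensity over
    non-missing probes falls below ``min_median_signal``. When
    ``min_median_signal`` is None it defaults to the 5th percentile of all
    cells' median intensities (a relative floor for "poor signal").
    """
    if m.n_cells == 0:
        raise ValueError("empty matrix")
    report = QcReport(cells_in=m.n_cells, probes_in=m.n_probes)
    frac_missing = m.values.isna().mean(axis=0)

    medians = None
    if m.intensities is not None:
        medians = m.intensities.median(axis=0, skipna=True)
        if min_median_signal is None:
            min_median_signal = float(np.percentile(medians.to_numpy(), 5))
    report.thresholds = {"max_missing_fraction": max_missing_fraction,
                         "min_median_signal": min_median_signal}

    keep: list[str] = []
    for cell in m.cell_ids:
        if frac_missing[cell] > max_missing_fraction:
            report.cells_removed_missing += 1
            report.removed_cells.append(cell)
        elif medians is not None and min_median_signal is not None and (
                medians[cell] < min_median_signal):
            report.cells_removed_signal += 1
            report.removed_cells.append(cell)
        else:
            keep.append(cell)
    if not keep:
        raise ValueError("no cells survive QC")
    logger.info("filter_cells: %d -> %d cells (%d missing, %d signal)", m.n_cells,
                len(keep), report.cells_removed_missing, report.cells_removed_signal)
    return m.subset_cells(keep), report


def filter_probes(m: ExpressionMatrix, min_mean_intensity: float = 300.0) -> tuple[ExpressionMatrix, QcReport]:
    """Remove probes whose across-cell mean signal intensity is strictly
    below ``min_mean_intensity`` (default 300, computed on non-missing
    entries; a probe at exactly 300 is retained)."""
    if m.intensities is None:
        raise ValueError("probe filtering requires intensities")
    report = QcReport(cells_in=m.n_cells, probes_in=m.n_probes,
                      thresholds={"min_mean_intensity": min_mean_intensity})
    means = m.intensities.mean(axis=1, skipna=True)
    keep = [p for p in m.probe_ids if means[p] >= min_mean_intensity]
    report.probes_removed_low_intensity = m.n_probes - len(keep)
    report.removed_probes = [p for p in m.probe_ids if p not in set(keep)]
    if not keep:
        raise ValueError("no probes survive the intensity filter")
    logger.info("filter_probes: %d -> %d probes", m.n_probes, len(keep))
    return m.subset_probes(keep), report
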