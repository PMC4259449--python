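"""Per-cell dormancy-signature "percent coverage" and group comparisons.

Coverage asks, for each cell, what percentage of a signature's genes the
cell actually calls in the signature's direction: coverage_up is the
percent of the UP set's matrix-present genes whose normalized log-ratio
exceeds the up-cutoff in that cell, and coverage_down the percent of the
DOWN set's genes falling below the down-cutoff. A cell exceeding the
up-cutoff for all genes of the UP signature scores 100%. Group differences
in mean coverage are estimated by regressing coverage on a group indicator,
whose coefficient is exactly the difference of group means, with a
two-sided t-test of that coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSet


@dataclass
class CoverageCutoffs:
    """Log-ratio cutoffs: a gene counts as up in a cell when its value is
    strictly above tau_up, down when strictly below tau_down. The defaults
    (0, 0) are the natural centre of loess/quantile-normalized log-ratios:
    up means above the pooled reference channel."""

    tau_up: float = 0.0
    tau_down: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_up < self.tau_down:
            raise ValueError("tau_up must be >= tau_down")


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    difference: float  # mean_a - mean_b, the indicator-regression coefficient
    t: float
    p: float
    n_a: int
    n_b: int


def coverage(m: ExpressionMatrix, up_set: GeneSet, down_set: GeneSet,
             cutoffs: CoverageCutoffs | None = None,
             cells: Sequence[str] | None = None,
             groups: pd.Series | dict | None = None) -> pd.DataFrame:
    """Compute per-cell percent coverage of UP and DOWN signature genes.

    Returns a DataFrame indexed by cell with columns coverage_up,
    coverage_down, n_up_genes, n_down_genes (the matrix-present denominators)
    and, if ``groups`` is given, a group column. Missing values never count
    as exceeding a cutoff. Genes shared by both sets are a configuration
    error.
    """
    cutoffs = cutoffs or CoverageCutoffs()
    shared = {g.lower() for g in up_set.genes} & {g.lower() for g in down_set.genes}
    if shared:
        raise ValueError(f"genes in both UP and DOWN sets: {sorted(shared)}")
    cells = list(cells) if cells is not None else m.cell_ids

    up_genes = up_set.intersect(m.probe_ids)
    down_genes = down_set.intersect(m.probe_ids)
    if not up_genes:
        raise ValueError(f"UP set {up_set.name!r} has no genes in the matrix")
    if not down_genes:
        raise ValueError(f"DOWN set {down_set.name!r} has no genes in the matrix")

    up_vals = m.values.loc[up_genes, cells].to_numpy(dtype=float)
    down_vals = m.values.loc[down_genes, cells].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        up_calls = np.where(np.isfinite(up_vals), up_vals > cutoffs.tau_up, False)
        down_calls = np.where(np.isfinite(down_vals), down_vals < cutoffs.tau_down, False)
    table = pd.DataFrame(
        {
            "coverage_up": 100.0 * up_calls.sum(axis=0) / len(up_genes),
            "coverage_down": 100.0 * down_calls.sum(axis=0) / len(down_genes),
            "n_up_genes": len(up_genes),
            "n_down_genes": len(down_genes),
        },
        index=pd.Index(cells, name="cell_id"),
    )
    if groups is not None:
        table["group"] = pd.Series(groups).reindex(cells).to_numpy()
    return table


def compare_groups(cov: pd.DataFrame, contrast: tuple[str, str],
                   column: str = "coverage_up",
                   group_column: str = "group") -> GroupComparison:
    """Compare mean coverage between two groups.

    The model is an ordinary least-squares regression of coverage on a 0/1
    group indicator; the coefficient equals mean(group_a) - mean(group_b)
    exactly and its two-sided t-test is the equal-variance two-sample
    t-test, evaluated here in closed form. Group SDs use the unbiased
    (n-1) estimator, matching the mean +/- SD presentation.
    """
    a_name, b_name = contrast
    ga = cov.loc[cov[group_column] == a_name, column].to_numpy(dtype=float)
    gb = cov.loc[cov[group_column] == b_name, column].to_numpy(dtype=float)
    if ga.size < 2 or gb.size < 2:
        raise ValueError(f"each group needs >= 2 cells (got {ga.size} {a_name!r}, "
                         f"{gb.size} {b_name!r})")
    diff = float(ga.mean() - gb.mean())
    na, nb = ga.size, gb.size
    pooled_var = ((na - 1) * ga.var(ddof=1) + (nb - 1) * gb.var(ddof=1)) / (na + nb - 2)
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    if se == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        t = diff / se
        p = 2.0 * stats.t.sf(abs(t), df=na + nb - 2)
    return GroupComparison(a_name, b_name, float(ga.mean()), float(gb.mean()),
                           float(ga.std(ddof=1)), float(gb.std(ddof=1)),
                           diff, float(t), float(p), na, nb)


def compare_all(cov: pd.DataFrame, contrasts: list[tuple[str, str]],
                column: str = "coverage_up") -> pd.DataFrame:
    """One comparison row per contrast (e.g. NED vs ADV, NED vs ADV_1, ...)."""
    rows = []
    for contrast in contrasts:
        c = compare_groups(cov, contrast, column=column)
        rows.append({
            "group_a": c.group_a, "group_b": c.group_b, "n_a": c.n_a, "n_b": c.n_b,
            "mean_a": c.mean_a, "sd_a": c.sd_a, "mean_b": c.mean_b, "sd_b": c.sd_b,
            "difference": c.difference, "t": c.t, "p": c.p,
        })
    return pd.DataFrame(rows)
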