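"""Two-group differential expression: the SAM moderated statistic with a
permutation false-discovery estimate, plain unpaired t-tests with BH
q-values, and the selection helpers used downstream (top/bottom-K signature
extraction and IQR-based variable-gene selection).

The SAM statistic for gene i is

    d_i = (mean_1 - mean_2) / (s_i + s0)

with s_i the pooled standard error of the mean difference and s0 a small
positive offset ("fudge factor") that damps the statistic for genes whose
variance estimate is near zero. With s0 = 0 and equal group variances d_i
is exactly the pooled two-sample t statistic. When s0="auto" the offset is
chosen to minimize the coefficient of variation of the median absolute d
across quantile windows of s_i (the standard calibration). q-values come
from a pooled permutation null of the group labels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import Direction, ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)


@dataclass
class SamConfig:
    s0: float | str = "auto"
    n_permutations: int = 1000
    seed: int = 17

    def __post_init__(self) -> None:
        if isinstance(self.s0, str):
            if self.s0 != "auto":
                raise ValueError("s0 must be a non-negative number or 'auto'")
        elif self.s0 < 0:
            raise ValueError("s0 must be >= 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def _group_arrays(m: ExpressionMatrix, groups: pd.Series | dict) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    groups = pd.Series(groups)
    groups = groups.reindex(m.cell_ids).dropna()
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    cells1 = [c for c in m.cell_ids if c in groups.index and groups[c] == levels[0]]
    cells2 = [c for c in m.cell_ids if c in groups.index and groups[c] == levels[1]]
    if len(cells1) < 2 or len(cells2) < 2:
        raise ValueError("each group needs >= 2 cells")
    X1 = m.values[cells1].to_numpy(dtype=float)
    X2 = m.values[cells2].to_numpy(dtype=float)
    return X1, X2, levels, [*cells1, *cells2]


def _nan_mean_var(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row mean, unbiased variance and count over non-missing entries."""
    mask = np.isfinite(X)
    n = mask.sum(axis=1)
    filled = np.where(mask, X, 0.0)
    mean = filled.sum(axis=1) / np.maximum(n, 1)
    ss = np.where(mask, (X - mean[:, None]) ** 2, 0.0).sum(axis=1)
    var = ss / np.maximum(n - 1, 1)
    return mean, var, n


def _sam_d(X: np.ndarray, idx1: np.ndarray, idx2: np.ndarray, s0: float) -> tuple[np.ndarray, np.ndarray]:
    """SAM d and pooled standard error s for a split of columns of X."""
    m1, v1, n1 = _nan_mean_var(X[:, idx1])
    m2, v2, n2 = _nan_mean_var(X[:, idx2])
    dof = np.maximum(n1 + n2 - 2, 1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / dof
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.sqrt(pooled * (1.0 / np.maximum(n1, 1) + 1.0 / np.maximum(n2, 1)))
        d = (m1 - m2) / (s + s0)
    d = np.where((s + s0) == 0, 0.0, d)
    return d, s


def _auto_s0(d_num: np.ndarray, s: np.ndarray) -> float:
    """Tusher-style s0: the percentile of s minimizing the coefficient of
    variation of the windowed median absolute deviation of d."""
    ok = np.isfinite(s) & np.isfinite(d_num)
    s_ok, num_ok = s[ok], d_num[ok]
    if s_ok.size < 20:
        return 0.0
    percentiles = np.arange(0, 101, 5)
    candidates = np.unique(np.percentile(s_ok, percentiles))
    edges = np.percentile(s_ok, np.linspace(0, 100, 21))
    which = np.clip(np.searchsorted(edges, s_ok, side="right") - 1, 0, 19)
    best, best_cv = 0.0, np.inf
    for s0 in candidates:
        d = num_ok / (s_ok + s0)
        mads = []
        for b in range(20):
            sel = which == b
            if sel.sum() >= 3:
                db = d[sel]
                mads.append(np.median(np.abs(db - np.median(db))) * 1.4826)
        mads = np.asarray(mads)
        if mads.size < 2 or mads.mean() == 0:
            continue
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best_cv:
            best_cv, best = cv, float(s0)
    return best


def _label_splits(n1: int, n: int, n_perm: int, seed: int) -> list[np.ndarray]:
    """Permuted assignments of which columns belong to group 1."""
    total = math.comb(n, n1)
    if total <= n_perm:
        logger.warning("only %d distinct permutations available (< %d requested); "
                       "using all", total, n_perm)
        return [np.asarray(c) for c in combinations(range(n), n1)]
    rng = np.random.default_rng(seed)
    return [rng.permutation(n)[:n1] for _ in range(n_perm)]


def sam_statistic(m: ExpressionMatrix, groups: pd.Series | dict,
                  cfg: SamConfig | None = None) -> pd.DataFrame:
    """SAM differential expression between two groups of cells.

    Returns a DataFrame indexed by gene with columns d, t, s, p, q, rank.
    Group 1 is the lexicographically smaller label; positive d means higher
    in group 1. Genes with fewer than 2 observations in either group are
    dropped with a log message. q-values are Benjamini-Hochberg adjusted
    empirical p-values from the pooled permutation null of the labels.
    """
    cfg = cfg or SamConfig()
    X1, X2, levels, _ = _group_arrays(m, groups)
    genes = np.asarray(m.probe_ids)

    ok = (np.isfinite(X1).sum(axis=1) >= 2) & (np.isfinite(X2).sum(axis=1) >= 2)
    if not ok.all():
        logger.info("sam_statistic: dropping %d genes with <2 observations in a group",
                    int((~ok).sum()))
    X1, X2, genes = X1[ok], X2[ok], genes[ok]

    X = np.concatenate([X1, X2], axis=1)
    n1, n = X1.shape[1], X1.shape[1] + X2.shape[1]
    idx1, idx2 = np.arange(n1), np.arange(n1, n)

    m1, _, _ = _nan_mean_var(X1)
    m2, _, _ = _nan_mean_var(X2)
    _, s = _sam_d(X, idx1, idx2, 0.0)
    s0 = _auto_s0(m1 - m2, s) if cfg.s0 == "auto" else float(cfg.s0)
    d, _ = _sam_d(X, idx1, idx2, s0)
    t, _ = _sam_d(X, idx1, idx2, 0.0)

    # pooled permutation null of |d|: partitions are drawn on a canonical
    # (cell-id-sorted) column order with the smaller group size, so the
    # null -- and hence q -- is invariant under swapping the group labels
    groups_ser = pd.Series(groups)
    cells1 = [c for c in m.cell_ids if c in groups_ser.index and groups_ser[c] == levels[0]]
    cells2 = [c for c in m.cell_ids if c in groups_ser.index and groups_ser[c] == levels[1]]
    col_of = {c: i for i, c in enumerate(cells1 + cells2)}
    canon = np.asarray([col_of[c] for c in sorted(col_of)])
    Xc = X[:, canon]
    m_small = min(n1, n - n1)
    null_abs = []
    for split in _label_splits(m_small, n, cfg.n_permutations, cfg.seed):
        g1 = np.asarray(split)
        g2 = np.setdiff1d(np.arange(n), g1, assume_unique=True)
        d_null, _ = _sam_d(Xc, g1, g2, s0)
        null_abs.append(np.abs(d_null[np.isfinite(d_null)]))
    pool = np.sort(np.concatenate(null_abs))
    p = (pool.size - np.searchsorted(pool, np.abs(d), side="left") + 1) / (pool.size + 1)
    q = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame({"d": d, "t": t, "s": s, "p": p, "q": q},
                         index=pd.Index(genes, name="gene"))
    table.attrs["s0"] = s0
    table.attrs["groups"] = levels
    table["rank"] = _signed_ranks(table)
    return table


def _signed_ranks(table: pd.DataFrame) -> np.ndarray:
    """Unique signed ranks: +1 = largest d, -1 = smallest; sign follows d.

    Zero-d genes get positive ranks after all nonzero ones; ties broken by
    gene symbol for determinism.
    """
    df = table.reset_index()
    desc = df.sort_values(["d", "gene"], ascending=[False, True], kind="mergesort")
    pos = pd.Series(np.arange(1, len(df) + 1), index=desc.index)
    signed = np.where(df["d"].to_numpy() < 0,
                      -(len(df) - pos.loc[df.index].to_numpy() + 1),
                      pos.loc[df.index].to_numpy())
    return signed


def welch_tests(m: ExpressionMatrix, groups: pd.Series | dict,
                fdr_method: str = "fdr_bh") -> pd.DataFrame:
    """Per-gene unpaired two-sample t-tests (Welch) with adjusted q-values.

    A gene with identical values in both groups gets t = 0, p = 1.
    """
    X1, X2, levels, _ = _group_arrays(m, groups)
    genes = np.asarray(m.probe_ids)
    ok = (np.isfinite(X1).sum(axis=1) >= 2) & (np.isfinite(X2).sum(axis=1) >= 2)
    X1, X2, genes = X1[ok], X2[ok], genes[ok]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(X1, X2, axis=1, equal_var=False, nan_policy="omit")
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    q = multipletests(p, method=fdr_method)[1]
    table = pd.DataFrame({"d": t, "t": t, "p": p, "q": q},
                         index=pd.Index(genes, name="gene"))
    table.attrs["groups"] = levels
    table["rank"] = _signed_ranks(table)
    return table


def top_bottom_k(diff: pd.DataFrame, k: int = 50,
                 name_prefix: str = "SIGNATURE") -> tuple[GeneSet, GeneSet]:
    """Extract the k most up- and k most down-ranked genes as GeneSets.

    Ranking is by the d column; ties are broken by gene symbol so the
    selection is stable across runs.
    """
    if len(diff) < 2 * k:
        raise ValueError(f"need >= {2 * k} genes for top/bottom-{k}, have {len(diff)}")
    df = diff.reset_index().sort_values(["d", "gene"], ascending=[False, True],
                                        kind="mergesort")
    up = df.head(k)["gene"].tolist()
    down = df.tail(k)["gene"].tolist()
    return (GeneSet(f"{name_prefix}_UP", frozenset(up), Direction.UP),
            GeneSet(f"{name_prefix}_DOWN", frozenset(down), Direction.DOWN))


def top_variable_genes(m: ExpressionMatrix, k: int = 5000) -> list[str]:
    """The k genes with largest across-cell inter-quartile range (IQR),
    computed over non-missing entries; ties broken by gene symbol."""
    if k > m.n_probes:
        raise ValueError(f"k={k} exceeds gene count {m.n_probes}")
    iqr = m.values.quantile(0.75, axis=1) - m.values.quantile(0.25, axis=1)
    order = pd.DataFrame({"gene": iqr.index.astype(str), "iqr": iqr.to_numpy()})
    order = order.sort_values(["iqr", "gene"], ascending=[False, True], kind="mergesort")
    return order.head(k)["gene"].tolist()
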