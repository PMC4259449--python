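"""Hierarchical clustering of cells and ADV subgroup assignment.

Cells are clustered Eisen-style: 1 - Pearson correlation distance over
pairwise-complete entries, average linkage by default. The ADV subgrouping
cuts the dendrogram of ADV cells (restricted to the NED-vs-ADV signature
genes) into two clusters; the cluster whose centroid lies closer to the NED
centroid in signature space is the "NED-like" ADV_2 group, the other ADV_1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .io import CellRecord, CellStatus, ExpressionMatrix, Subgroup

logger = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray          # scipy (n-1) x 4 linkage
    cell_ids: list[str]                 # order matching linkage leaf indices
    leaf_order: list[str]               # dendrogram left-to-right order
    distance: str
    linkage_method: str

    def cut(self, k: int) -> pd.Series:
        """Assign every cell to one of k clusters (labels 1..k)."""
        labels = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.cell_ids, name="cluster")


def _pairwise_distance(X: np.ndarray, cell_ids: list[str], distance: str) -> np.ndarray:
    """Condensed distance over cells (columns of X), pairwise-complete."""
    n = X.shape[1]
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            xa, xb = X[:, a], X[:, b]
            ok = np.isfinite(xa) & np.isfinite(xb)
            if ok.sum() < 2:
                raise ValueError(
                    f"cells {cell_ids[a]!r} and {cell_ids[b]!r} share <2 observed genes")
            ya, yb = xa[ok], xb[ok]
            if distance == "euclidean":
                dist = float(np.sqrt(((ya - yb) ** 2).sum()))
            else:
                sa, sb = ya.std(), yb.std()
                if sa == 0:
                    raise ValueError(f"cell {cell_ids[a]!r} has zero variance; "
                                     "correlation distance undefined")
                if sb == 0:
                    raise ValueError(f"cell {cell_ids[b]!r} has zero variance; "
                                     "correlation distance undefined")
                r = float(np.corrcoef(ya, yb)[0, 1])
                dist = 1.0 - r
            D[a, b] = D[b, a] = dist
    return squareform(D, checks=False)


def hcluster_cells(m: ExpressionMatrix, gene_list: list[str] | None = None,
                   distance: str = "correlation",
                   linkage_method: str = "average") -> ClusterResult:
    """Hierarchically cluster cells on (a gene subset of) the matrix.

    Cells are processed in identifier-sorted order so the tree is invariant
    to the input column order.
    """
    if distance not in ("correlation", "euclidean"):
        raise ValueError(f"unknown distance {distance!r}")
    if linkage_method not in ("average", "complete", "ward"):
        raise ValueError(f"unknown linkage {linkage_method!r}")
    if m.n_cells < 2:
        raise ValueError("clustering needs >= 2 cells")
    sub = m
    if gene_list is not None:
        present = [g for g in gene_list if g in set(m.probe_ids)]
        if not present:
            raise ValueError("none of the requested genes are in the matrix")
        sub = m.subset_probes(present)
    cell_ids = sorted(sub.cell_ids)
    X = sub.values[cell_ids].to_numpy(dtype=float)
    condensed = _pairwise_distance(X, cell_ids, distance)
    Z = linkage(condensed, method=linkage_method)
    order = [cell_ids[i] for i in leaves_list(Z)]
    return ClusterResult(Z, cell_ids, order, distance, linkage_method)


def assign_adv_subgroups(records: list[CellRecord], signature_matrix: ExpressionMatrix,
                         distance: str = "correlation",
                         linkage_method: str = "average") -> tuple[list[CellRecord], ClusterResult]:
    """Split retained ADV DTC into ADV_1 / ADV_2 by clustering on the
    NED-vs-ADV signature genes.

    ``signature_matrix`` must already be restricted to the signature genes
    (e.g. the top/bottom-50 differential genes). The ADV-only dendrogram is
    cut at k = 2; the cluster whose centroid (gene-wise mean, missing
    ignored) is closer in Euclidean distance to the NED centroid becomes
    ADV_2 (NED-like). Ties go to the larger cluster, then to the cluster
    containing the lexicographically smallest cell id. Retained NED cells
    receive subgroup NED.
    """
    retained = {r.cell_id: r for r in records if r.status == CellStatus.RETAINED_DTC}
    ned_cells = sorted(c for c, r in retained.items() if r.clinical_group == "NED")
    adv_cells = sorted(c for c, r in retained.items() if r.clinical_group == "ADV")
    if len(adv_cells) < 2:
        raise ValueError("need >= 2 retained ADV cells to form subgroups")
    if not ned_cells:
        raise ValueError("need >= 1 retained NED cell for the NED-likeness reference")

    adv_m = signature_matrix.subset_cells(adv_cells)
    result = hcluster_cells(adv_m, distance=distance, linkage_method=linkage_method)
    labels = result.cut(2)
    if labels.nunique() < 2:
        raise ValueError("ADV cells form a single indivisible cluster at this cut; "
                         "try a different linkage or distance")

    V = signature_matrix.values
    ned_centroid = V[ned_cells].mean(axis=1, skipna=True).to_numpy()
    dists, sizes, min_ids = {}, {}, {}
    for lab in (1, 2):
        members = sorted(labels.index[labels == lab])
        centroid = V[members].mean(axis=1, skipna=True).to_numpy()
        ok = np.isfinite(centroid) & np.isfinite(ned_centroid)
        dists[lab] = float(np.sqrt(((centroid[ok] - ned_centroid[ok]) ** 2).sum()))
        sizes[lab] = len(members)
        min_ids[lab] = members[0]

    if dists[1] != dists[2]:
        ned_like = 1 if dists[1] < dists[2] else 2
    elif sizes[1] != sizes[2]:
        ned_like = 1 if sizes[1] > sizes[2] else 2
        logger.info("centroid-distance tie broken by cluster size")
    else:
        ned_like = 1 if min_ids[1] < min_ids[2] else 2
        logger.info("centroid-distance tie broken by cell identifier")

    out: list[CellRecord] = []
    for rec in records:
        if rec.status != CellStatus.RETAINED_DTC:
            out.append(rec)
        elif rec.clinical_group == "NED":
            out.append(replace(rec, subgroup=Subgroup.NED))
        else:
            sg = Subgroup.ADV_2 if labels[rec.cell_id] == ned_like else Subgroup.ADV_1
            out.append(replace(rec, subgroup=sg))
    n1 = sum(1 for r in out if r.subgroup == Subgroup.ADV_1)
    n2 = sum(1 for r in out if r.subgroup == Subgroup.ADV_2)
    logger.info("ADV subgroups: %d ADV_1, %d ADV_2 (NED-like)", n1, n2)
    return out, result
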