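"""Reading and writing expression matrices, cell metadata and gene sets.

The on-disk formats are the plain-text conventions of two-color microarray
work: tab-delimited probe x cell matrices of log2(sample/reference) ratios
(M values) with a parallel matrix of mean channel intensities (A values),
GMT gene-set files, and a TSV of per-cell metadata.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tokens accepted as missing values in matrix files (case-insensitive)
MISSING_TOKENS = {"", "na", "nan"}


class CellStatus(str, Enum):
    PENDING = "pending"
    QC_FAILED = "qc_failed"
    EXCLUDED_ERYTHROID = "excluded_erythroid"
    EXCLUDED_LOW_PROSTATE = "excluded_low_prostate"
    RETAINED_DTC = "retained_dtc"


class Subgroup(str, Enum):
    NONE = "none"
    NED = "NED"
    ADV_1 = "ADV_1"
    ADV_2 = "ADV_2"


class Direction(str, Enum):
    UP = "UP"
    DOWN = "DOWN"
    UNSIGNED = "UNSIGNED"


@dataclass
class ExpressionMatrix:
    """Probe/gene x cell matrix of log-ratios with paired intensities.

    ``values`` holds M (log2 sample/reference ratios) and ``intensities``
    holds A (mean channel signal, arbitrary fluorescence units). Both are
    pandas DataFrames indexed by probe/gene identifier with cell identifiers
    as columns; NaN marks a missing measurement. ``intensities`` may be None
    for gene-level matrices downstream of probe collapsing.
    """

    values: pd.DataFrame
    intensities: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate probe id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate cell id: {dup!r}")
        if self.intensities is not None:
            if self.intensities.shape != self.values.shape:
                raise ValueError(
                    "values and intensities must have identical shape, got "
                    f"{self.values.shape} vs {self.intensities.shape}"
                )
            if not self.intensities.index.equals(self.values.index) or not (
                self.intensities.columns.equals(self.values.columns)
            ):
                raise ValueError("values/intensities row or column ordering differs")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, cell_ids: Sequence[str]) -> "ExpressionMatrix":
        inten = None if self.intensities is None else self.intensities[list(cell_ids)]
        return ExpressionMatrix(self.values[list(cell_ids)], inten)

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        inten = None if self.intensities is None else self.intensities.loc[list(probe_ids)]
        return ExpressionMatrix(self.values.loc[list(probe_ids)], inten)


@dataclass
class CellRecord:
    """Per-cell metadata: provenance, clinical group and pipeline status."""

    cell_id: str
    patient_id: str
    clinical_group: str  # "NED" or "ADV"
    epcam_grade: int = 3  # staining intensity, ordinal 2..4
    status: CellStatus = CellStatus.PENDING
    subgroup: Subgroup = Subgroup.NONE

    def __post_init__(self) -> None:
        if self.clinical_group not in ("NED", "ADV"):
            raise ValueError(f"clinical_group must be NED or ADV, got {self.clinical_group!r}")
        if self.subgroup != Subgroup.NONE and self.status != CellStatus.RETAINED_DTC:
            raise ValueError("subgroup may only be set on retained DTC")
        if self.clinical_group == "NED" and self.subgroup in (Subgroup.ADV_1, Subgroup.ADV_2):
            raise ValueError("NED cells cannot carry an ADV subgroup")


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols with an optional direction tag."""

    name: str
    genes: frozenset[str]
    direction: Direction = Direction.UNSIGNED

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def intersect(self, symbols: Iterable[str]) -> list[str]:
        """Members present in ``symbols``, matched case-insensitively, in
        the order they appear in ``symbols``."""
        lower = {g.lower() for g in self.genes}
        return [s for s in symbols if str(s).strip().lower() in lower]


@dataclass
class ProbeAnnotation:
    """probe_id -> gene_symbol mapping; many probes may share a symbol."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.mapping, dict):
            self.mapping = dict(self.mapping)

    def __len__(self) -> int:
        return len(self.mapping)


def _clean_symbol(s: str) -> str:
    return str(s).strip()


def read_matrix(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a tab-delimited probe x cell matrix of M values.

    The first column holds probe identifiers; the header row holds cell
    identifiers. Empty fields, ``NA`` and ``NaN`` (any case) parse as
    missing. ``dialect='geo_series_matrix'`` additionally skips ``!``-prefixed
    header/footer lines and strips quotes, as in GEO series-matrix exports.
    """
    path = Path(path)
    if dialect not in ("tsv", "geo_series_matrix"):
        raise ValueError(f"unknown dialect {dialect!r}")
    kwargs: dict = dict(sep="\t", index_col=0, na_values=["NA", "na", "NaN", "nan", "Na"],
                        keep_default_na=False)
    if dialect == "geo_series_matrix":
        kwargs["comment"] = "!"
        kwargs["quotechar"] = '"'
    try:
        df = pd.read_csv(path, **kwargs)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed matrix file {path}: {exc}") from exc
    if df.columns.has_duplicates or df.columns.isnull().any():
        raise ValueError(f"malformed header in {path}: duplicate or empty cell ids")
    df.index = df.index.map(_clean_symbol)
    df.columns = [str(c).strip().strip('"') for c in df.columns]
    df = df.apply(pd.to_numeric, errors="coerce")
    logger.info("read %d probes x %d cells from %s", *df.shape, path)
    return ExpressionMatrix(df)


def write_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write M values as TSV; missing entries become 'NA'."""
    m.values.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id")


def read_intensities(path: str | Path) -> pd.DataFrame:
    """Read an intensity (A-value) matrix laid out like the M matrix."""
    return read_matrix(path).values


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT gene-set file: name TAB description TAB symbol...

    Duplicate symbols within a line are deduplicated with a warning. A name
    suffix of ``_UP`` / ``_DOWN`` sets the direction tag.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields, got {len(fields)}")
            name = fields[0].strip()
            symbols = [_clean_symbol(f) for f in fields[2:] if f.strip()]
            unique = list(dict.fromkeys(symbols))
            if len(unique) < len(symbols):
                warnings.warn(f"{path}:{lineno}: {len(symbols) - len(unique)} duplicate "
                              f"symbol(s) in set {name!r} dropped")
            direction = Direction.UNSIGNED
            upper = name.upper()
            if upper.endswith("_UP"):
                direction = Direction.UP
            elif upper.endswith("_DOWN") or upper.endswith("_DN"):
                direction = Direction.DOWN
            sets.append(GeneSet(name, frozenset(unique), direction))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path, description: str = "dtcsig") -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description, *sorted(s.genes)]) + "\n")


def read_metadata(path: str | Path) -> list[CellRecord]:
    """Read cell metadata TSV with columns cell_id, patient_id,
    clinical_group, epcam_grade (and optionally status, subgroup)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cell_id", "patient_id", "clinical_group", "epcam_grade"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata file {path} lacks columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(CellRecord(
            cell_id=row["cell_id"],
            patient_id=row["patient_id"],
            clinical_group=row["clinical_group"],
            epcam_grade=int(row["epcam_grade"]),
            status=CellStatus(row["status"]) if "status" in df.columns else CellStatus.PENDING,
            subgroup=Subgroup(row["subgroup"]) if "subgroup" in df.columns else Subgroup.NONE,
        ))
    ids = [r.cell_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate cell_id in {path}")
    return records


def write_metadata(records: Sequence[CellRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "patient_id": [r.patient_id for r in records],
            "clinical_group": [r.clinical_group for r in records],
            "epcam_grade": [r.epcam_grade for r in records],
            "status": [r.status.value for r in records],
            "subgroup": [r.subgroup.value for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def collapse_probes(m: ExpressionMatrix, ann: ProbeAnnotation, rule: str = "max_iqr") -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene symbol.

    ``rule='max_iqr'`` keeps, for each symbol, the probe with the largest
    inter-quartile range of M across cells (the conventional choice for
    Agilent arrays); ``rule='mean'`` averages probes elementwise, ignoring
    missing values. Unmapped probes are dropped with a logged count.
    """
    if not ann.mapping:
        raise ValueError("empty probe annotation")
    if rule not in ("max_iqr", "mean"):
        raise ValueError(f"unknown collapse rule {rule!r}")
    mapped = [p for p in m.probe_ids if p in ann.mapping]
    if not mapped:
        raise ValueError("no probe in the matrix maps to a gene symbol")
    n_dropped = m.n_probes - len(mapped)
    if n_dropped:
        logger.info("collapse_probes: dropping %d unmapped probes", n_dropped)

    symbols = pd.Series({p: _clean_symbol(ann.mapping[p]) for p in mapped})
    vals = m.values.loc[mapped]
    inten = None if m.intensities is None else m.intensities.loc[mapped]

    if rule == "mean":
        out_vals = vals.groupby(symbols).mean()
        out_inten = None if inten is None else inten.groupby(symbols).mean()
    else:
        iqr = vals.quantile(0.75, axis=1) - vals.quantile(0.25, axis=1)
        # deterministic: on IQR ties keep the lexicographically first probe id
        order = pd.DataFrame({"sym": symbols, "iqr": iqr.loc[mapped]})
        order = order.sort_values(["sym", "iqr"], ascending=[True, False], kind="mergesort")
        keep = order.groupby("sym", sort=True).head(1).index
        out_vals = vals.loc[keep].set_axis(symbols.loc[keep], axis=0).sort_index()
        out_inten = None
        if inten is not None:
            out_inten = inten.loc[keep].set_axis(symbols.loc[keep], axis=0).sort_index()
    out_vals.index.name = "gene"
    return ExpressionMatrix(out_vals, out_inten)
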