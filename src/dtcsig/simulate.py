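"""Synthetic single-cell two-color expression data generator.

The generator emulates the statistical structure of a bone-marrow
disseminated-tumor-cell (DTC) study: ~100 EpCAM+/CD45- cells from ~10
patients in two clinical groups (NED = no evidence of disease, ADV =
advanced), where a fraction of sorted cells are erythroid progenitor-like
contaminants (erythroid marker genes up, prostate markers down), genuine
DTC express the prostate epithelial panel including NKX3-1, and the ADV
group hides a latent dormant/active split: dormant cells carry the dormancy
UP signature induced and the DOWN signature repressed, exactly the
structure the classification, subgrouping and coverage statistics are meant
to recover. NED DTC are all dormant-like.

Log-ratios are baseline 0 plus an additive per-patient random intercept,
class-specific signature shifts of configurable effect size, and Gaussian
noise; intensities are log-normal with a configurable fraction of probes
planted below the 300-unit mean-intensity filter; entries go missing at a
configurable rate, with optional planted QC-failure cells at 40% missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import signatures as sig
from .io import (CellRecord, Direction, ExpressionMatrix, GeneSet,
                 write_gmt, write_matrix, write_metadata)

CLASS_ERYTHROID = "erythroid"
CLASS_DORMANT = "dtc_dormant"
CLASS_ACTIVE = "dtc_active"

INTENSITY_FILTER = 300.0  # the probe-level mean-intensity floor the data must span


@dataclass
class SimConfig:
    n_patients_ned: int = 4
    n_patients_adv: int = 6
    cells_per_patient: int | tuple[int, int] = 10
    frac_erythroid_contaminant: float = 0.4
    frac_adv_dormant: float = 0.4
    n_genes: int = 2000
    effect_size: float = 2.0          # log2 units for erythroid/prostate shifts
    dormancy_effect_size: float | None = None  # defaults to effect_size
    patient_sd: float = 0.3
    noise_sd: float = 0.5
    missing_rate: float = 0.05
    intensity_meanlog: float = float(np.log(1000.0))
    intensity_sdlog: float = 0.6
    frac_low_intensity: float = 0.15  # fraction of background probes planted < 300
    n_qc_fail_cells: int = 0          # extra cells with ~40% missing values
    seed: int = 17

    def __post_init__(self) -> None:
        for f in (self.frac_erythroid_contaminant, self.frac_adv_dormant,
                  self.missing_rate, self.frac_low_intensity):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for s in (self.patient_sd, self.noise_sd):
            if s < 0:
                raise ValueError("SDs must be >= 0")
        n_signature = (len(sig.ERYTHROID_GENES) + len(sig.PROSTATE_GENES)
                       + len(sig.DORMANCY_UP_GENES) + len(sig.DORMANCY_DOWN_GENES))
        if self.n_genes < n_signature:
            raise ValueError(f"n_genes={self.n_genes} is smaller than the union of "
                             f"signature genes ({n_signature})")

    @property
    def delta_dormancy(self) -> float:
        return self.effect_size if self.dormancy_effect_size is None else self.dormancy_effect_size


@dataclass
class GroundTruth:
    """Planted labels, used only by tests; never written into the
    expression files themselves."""

    cell_class: dict[str, str]          # cell_id -> planted class
    cell_patient: dict[str, str]
    gene_signature: dict[str, str]      # gene -> signature name ("" = background)
    qc_fail_cells: list[str] = field(default_factory=list)
    low_intensity_genes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cells = sorted(self.cell_class)
        return pd.DataFrame({
            "cell_id": cells,
            "planted_class": [self.cell_class[c] for c in cells],
            "patient_id": [self.cell_patient[c] for c in cells],
            "planted_qc_fail": [c in set(self.qc_fail_cells) for c in cells],
        })


def default_gene_sets() -> dict[str, GeneSet]:
    return {
        "erythroid": sig.erythroid_signature(),
        "prostate": sig.prostate_signature(),
        "dormancy_up": sig.dormancy_up_signature(),
        "dormancy_down": sig.dormancy_down_signature(),
    }


def simulate(cfg: SimConfig | None = None) -> tuple[ExpressionMatrix, list[CellRecord], dict[str, GeneSet], GroundTruth]:
    """Generate a synthetic dataset with planted ground truth.

    Fixed seed gives bit-identical output. Returns the expression matrix
    (gene-level M values with paired intensities), cell metadata, the four
    gene sets used for planting, and the GroundTruth.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    gene_names = (list(sig.ERYTHROID_GENES) + list(sig.PROSTATE_GENES)
                  + list(sig.DORMANCY_UP_GENES) + list(sig.DORMANCY_DOWN_GENES))
    n_background = cfg.n_genes - len(gene_names)
    background = [f"GENE{i:05d}" for i in range(1, n_background + 1)]
    genes = gene_names + background
    gene_signature = {g: "erythroid" for g in sig.ERYTHROID_GENES}
    gene_signature.update({g: "prostate" for g in sig.PROSTATE_GENES})
    gene_signature.update({g: "dormancy_up" for g in sig.DORMANCY_UP_GENES})
    gene_signature.update({g: "dormancy_down" for g in sig.DORMANCY_DOWN_GENES})
    gene_signature.update({g: "" for g in background})

    # patients and cells
    patients = ([f"P{i:02d}_NED" for i in range(1, cfg.n_patients_ned + 1)]
                + [f"P{i:02d}_ADV" for i in range(cfg.n_patients_ned + 1,
                                                  cfg.n_patients_ned + cfg.n_patients_adv + 1)])
    groups = (["NED"] * cfg.n_patients_ned + ["ADV"] * cfg.n_patients_adv)
    cell_ids, cell_patient, cell_group = [], {}, {}
    for pat, grp in zip(patients, groups):
        if isinstance(cfg.cells_per_patient, tuple):
            lo, hi = cfg.cells_per_patient
            n_cells = int(rng.integers(lo, hi + 1))
        else:
            n_cells = cfg.cells_per_patient
        for k in range(1, n_cells + 1):
            cid = f"{pat}_c{k:02d}"
            cell_ids.append(cid)
            cell_patient[cid] = pat
            cell_group[cid] = grp
    n_total = len(cell_ids)

    # planted classes: exact contaminant count, exact dormant count among ADV DTC
    n_contaminant = int(round(cfg.frac_erythroid_contaminant * n_total))
    contaminants = set(rng.choice(n_total, size=n_contaminant, replace=False).tolist())
    cell_class = {}
    adv_dtc = []
    for i, cid in enumerate(cell_ids):
        if i in contaminants:
            cell_class[cid] = CLASS_ERYTHROID
        elif cell_group[cid] == "NED":
            cell_class[cid] = CLASS_DORMANT
        else:
            adv_dtc.append(cid)
    n_adv_dormant = int(round(cfg.frac_adv_dormant * len(adv_dtc)))
    dormant_idx = set(rng.choice(len(adv_dtc), size=n_adv_dormant, replace=False).tolist()) if adv_dtc else set()
    for i, cid in enumerate(adv_dtc):
        cell_class[cid] = CLASS_DORMANT if i in dormant_idx else CLASS_ACTIVE

    # expression: baseline 0 + patient intercept + class shifts + noise
    patient_effect = {p: rng.normal(0.0, cfg.patient_sd) for p in patients}
    shift = np.zeros((cfg.n_genes, n_total))
    gene_idx = {g: i for i, g in enumerate(genes)}
    ery = [gene_idx[g] for g in sig.ERYTHROID_GENES]
    pro = [gene_idx[g] for g in sig.PROSTATE_GENES]
    dup = [gene_idx[g] for g in sig.DORMANCY_UP_GENES]
    ddn = [gene_idx[g] for g in sig.DORMANCY_DOWN_GENES]
    d, dd = cfg.effect_size, cfg.delta_dormancy
    for j, cid in enumerate(cell_ids):
        cls = cell_class[cid]
        if cls == CLASS_ERYTHROID:
            shift[ery, j] += d
            shift[pro, j] -= d
        else:
            shift[pro, j] += d
            shift[ery, j] -= d
            if cls == CLASS_DORMANT:
                shift[dup, j] += dd
                shift[ddn, j] -= dd
    M = shift + np.array([patient_effect[cell_patient[c]] for c in cell_ids])[None, :]
    M = M + rng.normal(0.0, cfg.noise_sd, size=M.shape)

    # intensities: per-probe log-normal base x per-cell jitter; a planted
    # fraction of background probes sits below the 300 mean-intensity floor,
    # everything else is kept above it so planted counts are exact
    n_low = int(round(cfg.frac_low_intensity * len(background)))
    low_genes = list(rng.choice(background, size=n_low, replace=False)) if n_low else []
    low_set = set(low_genes)
    base = np.exp(rng.normal(cfg.intensity_meanlog, cfg.intensity_sdlog, size=cfg.n_genes))
    base = np.maximum(base, 1.2 * INTENSITY_FILTER)
    for g in low_genes:
        base[gene_idx[g]] = np.exp(rng.normal(np.log(150.0), 0.2))
    jitter = np.exp(rng.normal(0.0, 0.2, size=(cfg.n_genes, n_total)))
    A = base[:, None] * jitter

    # missing values; planted QC-failure cells get ~40% missing
    missing = rng.random(M.shape) < cfg.missing_rate
    qc_fail = []
    if cfg.n_qc_fail_cells:
        if cfg.n_qc_fail_cells > n_total:
            raise ValueError("n_qc_fail_cells exceeds the number of cells")
        fail_idx = rng.choice(n_total, size=cfg.n_qc_fail_cells, replace=False)
        for j in fail_idx:
            missing[:, j] = rng.random(cfg.n_genes) < 0.4
            qc_fail.append(cell_ids[j])
    M = np.where(missing, np.nan, M)

    values = pd.DataFrame(M, index=pd.Index(genes, name="gene"), columns=cell_ids)
    intensities = pd.DataFrame(A, index=pd.Index(genes, name="gene"), columns=cell_ids)
    matrix = ExpressionMatrix(values, intensities)

    records = []
    for cid in cell_ids:
        if cell_class[cid] == CLASS_ERYTHROID:
            grade = 2 if rng.random() < 0.9 else 4
        else:
            grade = int(rng.choice([3, 4]))
        records.append(CellRecord(cell_id=cid, patient_id=cell_patient[cid],
                                  clinical_group=cell_group[cid], epcam_grade=grade))

    truth = GroundTruth(cell_class=cell_class, cell_patient=cell_patient,
                        gene_signature=gene_signature, qc_fail_cells=qc_fail,
                        low_intensity_genes=sorted(low_set))
    return matrix, records, default_gene_sets(), truth


def write_dataset(outdir: str | Path, m: ExpressionMatrix, records: list[CellRecord],
                  sets: dict[str, GeneSet], truth: GroundTruth | None = None) -> dict[str, Path]:
    """Write a simulated dataset in the formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.tsv",
        "intensities": outdir / "intensities.tsv",
        "metadata": outdir / "metadata.tsv",
        "gene_sets": outdir / "signatures.gmt",
    }
    write_matrix(m, paths["matrix"])
    if m.intensities is not None:
        ExpressionMatrix(m.intensities).values.to_csv(
            paths["intensities"], sep="\t", na_rep="NA", index_label="probe_id")
    write_metadata(records, paths["metadata"])
    write_gmt(list(sets.values()), paths["gene_sets"])
    if truth is not None:
        paths["truth"] = outdir / "truth.tsv"
        truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths
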