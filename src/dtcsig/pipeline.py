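"""End-to-end analysis pipeline driven by a single YAML config.

Stages, in fixed order: load -> cell QC -> probe intensity filter -> loess
within-array normalization -> quantile normalization among arrays ->
(optional probe collapsing) -> GSVA signature scoring -> dual-criterion
cell classification -> global variable-gene clustering -> SAM differential
expression (NED vs ADV) -> top/bottom-K signature extraction -> ADV
subgroup clustering -> t-tests + preranked GSEA -> dormancy coverage and
group comparisons. A run report reconciles cell counts at every stage.
"""

from __future__ import annotations

import difflib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import __version__ as _version
from .cluster import assign_adv_subgroups, hcluster_cells
from .coverage import CoverageCutoffs, compare_groups, coverage
from .differential import SamConfig, sam_statistic, top_bottom_k, top_variable_genes, welch_tests
from .enrichment import preranked_gsea, results_frame
from .io import (CellStatus, ExpressionMatrix, GeneSet, ProbeAnnotation, Subgroup,
                 collapse_probes, read_gmt, read_matrix, read_metadata,
                 write_gmt, write_matrix, write_metadata)
from .preprocess import filter_cells, filter_probes, loess_normalize_within, quantile_normalize_across
from .score import ClassificationRule, classify_cells, gsva_score

logger = logging.getLogger(__name__)

DEFAULTS: dict[str, dict] = {
    "input": {
        "matrix": None,          # required
        "intensities": None,     # required
        "metadata": None,        # required
        "gene_sets": None,       # required (GMT)
        "annotation": None,      # optional probe -> symbol TSV
        "collapse_rule": "max_iqr",
    },
    "preprocess": {
        "span": 0.4,
        "max_missing_fraction": 0.25,
        "min_median_signal": None,   # null -> 5th percentile of cell medians
        "min_mean_intensity": 300,
    },
    "classify": {
        "erythroid_threshold": 0.0,
        "prostate_threshold": 0.0,
        "nkx31_min": 0.0,
        "require_nkx31": True,
        "erythroid_set": "ERYTHROID_PROGENITOR",
        "prostate_set": "PROSTATE_EPITHELIAL",
    },
    "differential": {
        "s0": "auto",
        "n_permutations": 1000,
        "k_top": 50,
        "n_variable": 5000,
    },
    "clustering": {
        "distance": "correlation",
        "linkage": "average",
    },
    "enrichment": {
        "n_perm": 1000,
        "weight": 1.0,
    },
    "coverage": {
        "tau_up": 0.0,
        "tau_down": 0.0,
        "up_set": None,    # required: name of the UP set in the GMT
        "down_set": None,  # required
    },
}
TOP_LEVEL_SCALARS = {"seed": 17, "outdir": None}
REQUIRED = [("input", "matrix"), ("input", "intensities"), ("input", "metadata"),
            ("input", "gene_sets"), ("coverage", "up_set"), ("coverage", "down_set")]


@dataclass
class RunConfig:
    sections: dict = field(default_factory=dict)
    seed: int = 17
    outdir: str | None = None

    def __getitem__(self, key: str) -> dict:
        return self.sections[key]


class ConfigError(ValueError):
    """Aggregated configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid config:\n  " + "\n  ".join(errors))


def _suggest(key: str, known: list[str]) -> str:
    close = difflib.get_close_matches(key, known, n=1)
    return f" (did you mean {close[0]!r}?)" if close else ""


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML pipeline config; unknown keys are rejected
    with a suggestion, defaults are filled in and echoed in the result."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])
    errors: list[str] = []
    sections = {name: dict(defaults) for name, defaults in DEFAULTS.items()}
    scalars = dict(TOP_LEVEL_SCALARS)

    for key, value in raw.items():
        if key in TOP_LEVEL_SCALARS:
            scalars[key] = value
        elif key in DEFAULTS:
            if not isinstance(value, dict):
                errors.append(f"section {key!r} must be a mapping")
                continue
            for sub, v in value.items():
                if sub not in DEFAULTS[key]:
                    errors.append(f"unknown key {key}.{sub!r}"
                                  f"{_suggest(sub, list(DEFAULTS[key]))}")
                else:
                    sections[key][sub] = v
        else:
            known = list(DEFAULTS) + list(TOP_LEVEL_SCALARS)
            errors.append(f"unknown key {key!r}{_suggest(key, known)}")

    for sec, key in REQUIRED:
        if sections[sec][key] is None:
            errors.append(f"missing required key {sec}.{key}")
    for sec, key in [("input", "matrix"), ("input", "intensities"),
                     ("input", "metadata"), ("input", "gene_sets")]:
        p = sections[sec][key]
        if p is not None and not Path(p).exists():
            errors.append(f"{sec}.{key}: file not found: {p}")
    if sections["differential"]["n_permutations"] < 1:
        errors.append("differential.n_permutations must be >= 1")
    if sections["enrichment"]["n_perm"] < 1:
        errors.append("enrichment.n_perm must be >= 1")
    if not 0 <= sections["preprocess"]["max_missing_fraction"] <= 1:
        errors.append("preprocess.max_missing_fraction must be in [0, 1]")
    if errors:
        raise ConfigError(errors)
    return RunConfig(sections=sections, seed=int(scalars["seed"]), outdir=scalars["outdir"])


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full analysis and return the run report dict.

    Outputs (TSV/GMT/JSON) are written under ``outdir`` (or cfg.outdir).
    Any stage failure raises StageError naming the stage.
    """
    outdir = Path(outdir or cfg.outdir or "dtcsig_run")
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": _version, "seed": cfg.seed, "stages": {}, "counts": {}}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return deco

    @stage("load")
    def _load():
        m = read_matrix(cfg["input"]["matrix"])
        inten = read_matrix(cfg["input"]["intensities"]).values
        records = read_metadata(cfg["input"]["metadata"])
        sets = {s.name: s for s in read_gmt(cfg["input"]["gene_sets"])}
        return ExpressionMatrix(m.values, inten.loc[m.values.index, m.values.columns]), records, sets
    matrix, records, gene_sets = _load
    report["counts"]["cells_profiled"] = matrix.n_cells
    report["counts"]["probes_profiled"] = matrix.n_probes

    @stage("cell_qc")
    def _cell_qc():
        pp = cfg["preprocess"]
        return filter_cells(matrix, max_missing_fraction=pp["max_missing_fraction"],
                            min_median_signal=pp["min_median_signal"])
    matrix_qc, cell_report = _cell_qc
    failed = set(cell_report.removed_cells)
    records = [r if r.cell_id not in failed else replace(r, status=CellStatus.QC_FAILED)
               for r in records]
    report["stages"]["cell_qc"] = {
        "cells_removed_missing": cell_report.cells_removed_missing,
        "cells_removed_signal": cell_report.cells_removed_signal,
        "thresholds": cell_report.thresholds,
    }
    report["counts"]["cells_qc_passed"] = matrix_qc.n_cells

    @stage("probe_filter")
    def _probe_filter():
        return filter_probes(matrix_qc, min_mean_intensity=cfg["preprocess"]["min_mean_intensity"])
    matrix_f, probe_report = _probe_filter
    report["stages"]["probe_filter"] = {
        "probes_removed_low_intensity": probe_report.probes_removed_low_intensity}
    report["counts"]["probes_passing_filters"] = matrix_f.n_probes
    pd.concat([cell_report.to_frame(), probe_report.to_frame()]).to_csv(
        outdir / "qc_report.tsv", sep="\t", index=False)

    @stage("normalize")
    def _normalize():
        m = loess_normalize_within(matrix_f, span=cfg["preprocess"]["span"])
        return quantile_normalize_across(m)
    norm = _normalize

    if cfg["input"]["annotation"]:
        @stage("collapse_probes")
        def _collapse():
            ann_df = pd.read_csv(cfg["input"]["annotation"], sep="\t", dtype=str)
            ann = ProbeAnnotation(dict(zip(ann_df.iloc[:, 0], ann_df.iloc[:, 1])))
            return collapse_probes(norm, ann, rule=cfg["input"]["collapse_rule"])
        norm = _collapse
        report["counts"]["genes_after_collapse"] = norm.n_probes

    @stage("signature_scores")
    def _scores():
        cl = cfg["classify"]
        wanted = [cl["erythroid_set"], cl["prostate_set"]]
        missing = [w for w in wanted if w not in gene_sets]
        if missing:
            raise ValueError(f"gene set(s) {missing} not in {cfg['input']['gene_sets']}")
        return gsva_score(norm, [gene_sets[w] for w in wanted])
    scores = _scores
    scores.to_csv(outdir / "signature_scores.tsv", sep="\t")

    @stage("classify")
    def _classify():
        cl = cfg["classify"]
        rule = ClassificationRule(
            erythroid_threshold=cl["erythroid_threshold"],
            prostate_threshold=cl["prostate_threshold"],
            nkx31_min=cl["nkx31_min"], require_nkx31=cl["require_nkx31"],
            erythroid_set=cl["erythroid_set"], prostate_set=cl["prostate_set"])
        return classify_cells(scores, norm, records, rule)
    records = _classify
    by_status = pd.Series([r.status.value for r in records]).value_counts().to_dict()
    report["counts"]["excluded_erythroid"] = by_status.get("excluded_erythroid", 0)
    report["counts"]["excluded_low_prostate"] = by_status.get("excluded_low_prostate", 0)
    report["counts"]["retained_dtc"] = by_status.get("retained_dtc", 0)

    retained = [r for r in records if r.status == CellStatus.RETAINED_DTC]
    retained_ids = [r.cell_id for r in retained]
    dtc = norm.subset_cells(retained_ids)
    groups = pd.Series({r.cell_id: r.clinical_group for r in retained})

    @stage("global_clustering")
    def _global():
        n_var = min(cfg["differential"]["n_variable"], dtc.n_probes)
        if n_var < cfg["differential"]["n_variable"]:
            logger.info("n_variable capped at gene count %d", n_var)
        var_genes = top_variable_genes(dtc, k=n_var)
        res = hcluster_cells(dtc, gene_list=var_genes,
                             distance=cfg["clustering"]["distance"],
                             linkage_method=cfg["clustering"]["linkage"])
        return res
    global_cluster = _global
    pd.Series(global_cluster.leaf_order, name="cell_id").to_csv(
        outdir / "global_leaf_order.tsv", sep="\t", index=False)

    @stage("sam")
    def _sam():
        d = cfg["differential"]
        return sam_statistic(dtc, groups, SamConfig(s0=d["s0"],
                                                    n_permutations=d["n_permutations"],
                                                    seed=cfg.seed))
    sam = _sam
    sam.to_csv(outdir / "diff_sam.tsv", sep="\t")

    @stage("top_bottom_k")
    def _topk():
        return top_bottom_k(sam, k=cfg["differential"]["k_top"], name_prefix="NED_VS_ADV")
    up_set, down_set = _topk
    write_gmt([up_set, down_set], outdir / "ned_vs_adv_signature.gmt")

    @stage("adv_subgroups")
    def _subgroups():
        sig_genes = sorted(up_set.genes | down_set.genes)
        sig_matrix = dtc.subset_probes([g for g in dtc.probe_ids if g in set(sig_genes)])
        return assign_adv_subgroups(records, sig_matrix,
                                    distance=cfg["clustering"]["distance"],
                                    linkage_method=cfg["clustering"]["linkage"])
    records, adv_cluster = _subgroups
    write_metadata(records, outdir / "metadata_classified.tsv")
    by_subgroup = pd.Series([r.subgroup.value for r in records]).value_counts().to_dict()
    report["counts"]["subgroup_NED"] = by_subgroup.get("NED", 0)
    report["counts"]["subgroup_ADV_1"] = by_subgroup.get("ADV_1", 0)
    report["counts"]["subgroup_ADV_2"] = by_subgroup.get("ADV_2", 0)

    @stage("t_tests")
    def _ttests():
        return welch_tests(dtc, groups)
    tt = _ttests
    tt.to_csv(outdir / "diff_t.tsv", sep="\t")

    @stage("gsea")
    def _gsea():
        ranking = tt["t"]
        res = preranked_gsea(ranking, list(gene_sets.values()),
                             weight=cfg["enrichment"]["weight"],
                             n_perm=cfg["enrichment"]["n_perm"], seed=cfg.seed + 1)
        return results_frame(res)
    gsea = _gsea
    gsea.to_csv(outdir / "gsea.tsv", sep="\t", index=False)

    @stage("coverage")
    def _coverage():
        cv = cfg["coverage"]
        for key in ("up_set", "down_set"):
            if cv[key] not in gene_sets:
                raise ValueError(f"coverage.{key} {cv[key]!r} not in the GMT")
        subgroup_of = pd.Series({r.cell_id: r.subgroup.value for r in records
                                 if r.status == CellStatus.RETAINED_DTC})
        tab = coverage(dtc, gene_sets[cv["up_set"]], gene_sets[cv["down_set"]],
                       CoverageCutoffs(cv["tau_up"], cv["tau_down"]),
                       cells=retained_ids, groups=subgroup_of)
        tab["clinical_group"] = groups.reindex(tab.index).to_numpy()
        rows = []
        contrasts = [("NED", "ADV", "clinical_group"), ("NED", "ADV_1", "group"),
                     ("NED", "ADV_2", "group"), ("ADV_1", "ADV_2", "group")]
        for col in ("coverage_up", "coverage_down"):
            for a, b, gcol in contrasts:
                try:
                    c = compare_groups(tab, (a, b), column=col, group_column=gcol)
                except ValueError as exc:
                    logger.warning("contrast %s vs %s skipped: %s", a, b, exc)
                    continue
                rows.append({"statistic": col, "group_a": a, "group_b": b,
                             "n_a": c.n_a, "n_b": c.n_b, "mean_a": c.mean_a,
                             "sd_a": c.sd_a, "mean_b": c.mean_b, "sd_b": c.sd_b,
                             "difference": c.difference, "t": c.t, "p": c.p})
        return tab, pd.DataFrame(rows)

    cov_table, comparisons = _coverage
    cov_table.to_csv(outdir / "coverage.tsv", sep="\t")
    comparisons.to_csv(outdir / "coverage_comparisons.tsv", sep="\t", index=False)
    write_matrix(dtc, outdir / "normalized_dtc_matrix.tsv")

    # cell-count conservation across stages
    profiled = report["counts"]["cells_profiled"]
    qc_failed = profiled - report["counts"]["cells_qc_passed"]
    classified = (report["counts"]["excluded_erythroid"]
                  + report["counts"]["excluded_low_prostate"]
                  + report["counts"]["retained_dtc"])
    assert profiled == qc_failed + classified, "cell counts do not reconcile"
    assert report["counts"]["retained_dtc"] == (report["counts"]["subgroup_NED"]
                                                + report["counts"]["subgroup_ADV_1"]
                                                + report["counts"]["subgroup_ADV_2"])
    report["counts"]["cells_qc_failed"] = qc_failed
    report["conservation_ok"] = True

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    metrics = pd.DataFrame(sorted(report["counts"].items()), columns=["metric", "count"])
    metrics.to_csv(outdir / "stage_metrics.tsv", sep="\t", index=False)
    return report
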