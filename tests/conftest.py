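import numpy as np
import pandas as pd
import pytest
import yaml

from dtcsig import ExpressionMatrix
from dtcsig.pipeline import run_pipeline, validate_config
from dtcsig.simulate import SimConfig, simulate, write_dataset


@pytest.fixture(scope="session")
def default_sim():
    """The default-scale synthetic study: ~100 cells, 10 patients, planted
    erythroid contaminants and a latent dormant/active ADV split."""
    return simulate(SimConfig(n_qc_fail_cells=2))


@pytest.fixture(scope="session")
def pipeline_run(default_sim, tmp_path_factory):
    """One full pipeline run on the default synthetic dataset, shared by
    the end-to-end tests."""
    m, records, sets, truth = default_sim
    base = tmp_path_factory.mktemp("pipeline")
    paths = write_dataset(base / "data", m, records, sets, truth)
    cfg_path = base / "config.yaml"
    yaml.safe_dump(
        {
            "input": {k: str(paths[k]) for k in ("matrix", "intensities", "metadata", "gene_sets")},
            "coverage": {"up_set": "DORMANCY_SYN_UP", "down_set": "DORMANCY_SYN_DOWN"},
            "seed": 17,
        },
        cfg_path.open("w"),
    )
    cfg = validate_config(cfg_path)
    outdir = base / "run"
    report = run_pipeline(cfg, outdir=outdir)
    return {"report": report, "outdir": outdir, "truth": truth, "config_path": cfg_path}


@pytest.fixture()
def toy_matrix():
    """10 genes x 6 cells, continuous, no missing values."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.normal(0, 1, size=(10, 6)),
        index=[f"G{i}" for i in range(10)],
        columns=[f"c{j}" for j in range(6)],
    )
    return ExpressionMatrix(values)


def make_matrix(values, genes=None, cells=None, intensities=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=cells)
    inten = None
    if intensities is not None:
        inten = pd.DataFrame(np.asarray(intensities, dtype=float), index=genes, columns=cells)
    return ExpressionMatrix(df, inten)
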