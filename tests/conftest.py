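import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from sctme import ExpressionMatrix, SyntheticSpec, generate_dataset, normalize_log, run_qc

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*did not converge.*")


def toy_matrix(counts, mito_flags=None, tissues=None, chromosomes=None, positions=None):
    """Small dense-counts ExpressionMatrix for hand-worked examples."""
    counts = np.asarray(counts)
    ng, nc = counts.shape
    gene_meta = pd.DataFrame(
        {
            "symbol": [f"g{i + 1}" for i in range(ng)],
            "chromosome": chromosomes if chromosomes is not None else ["chr1"] * ng,
            "position": positions if positions is not None else list(range(ng)),
            "mito": mito_flags if mito_flags is not None else [False] * ng,
        }
    )
    cell_meta = pd.DataFrame(
        {
            "barcode": [f"c{i + 1}" for i in range(nc)],
            "patient": "P1",
            "tissue": tissues if tissues is not None else ["tumor"] * nc,
        }
    )
    return ExpressionMatrix(sp.csr_matrix(counts), gene_meta, cell_meta)


def four_type_spec(seed, cells_per_type_per_tissue=100, **overrides):
    """Four planted populations, 4-fold markers, no CNV/trajectory/network."""
    kwargs = dict(
        n_cells_per_type={
            t: {"tumor": cells_per_type_per_tissue, "normal": cells_per_type_per_tissue}
            for t in ["epithelial", "CD14+ monocyte", "M2 macrophage", "T cell"]
        },
        seed=seed,
        lowq_cells={"count": 0},
        cnv={"regions": [], "malignant_fraction": 0.0},
        trajectory=None,
        grn=None,
    )
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


def trajectory_spec(seed, n_branches=1, **overrides):
    """Monocyte-to-macrophage trajectory, normal-enriched root."""
    types = (
        ("CD14+ monocyte", "M2 macrophage")
        if n_branches == 1
        else ("CD14+ monocyte", "M2 macrophage", "CD1c+ DC")
    )
    ncpt = {
        "CD14+ monocyte": {"tumor": 100, "normal": 150},
        "M2 macrophage": {"tumor": 150, "normal": 30},
    }
    if n_branches == 2:
        ncpt["CD1c+ DC"] = {"tumor": 80, "normal": 20}
    kwargs = dict(
        n_cells_per_type=ncpt,
        seed=seed,
        lowq_cells={"count": 0},
        cnv={"regions": [], "malignant_fraction": 0.0},
        grn=None,
        lr_channels=[],
        trajectory={"types": types, "n_branches": n_branches},
    )
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


def prepared(spec):
    """Generate, QC and normalize a synthetic dataset; returns (matrix, truth).

    QC keeps every non-planted-low-quality cell under the default spec
    conditions, so ground-truth rows align with matrix cells.
    """
    matrix, truth = generate_dataset(spec)
    matrix, _ = run_qc(matrix)
    normalize_log(matrix)
    truth.cells = truth.cells[~truth.cells["lowq"]].reset_index(drop=True)
    assert len(truth.cells) == matrix.n_cells
    return matrix, truth


@pytest.fixture(scope="session")
def small_typed_dataset():
    """Session-scoped 4-type dataset used by several module tests."""
    return prepared(four_type_spec(seed=11))


@pytest.fixture(scope="session")
def linear_trajectory_dataset():
    return prepared(trajectory_spec(seed=11))
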