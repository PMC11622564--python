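import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from spatialtme import io, qc, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-patient, 8-FOV cohort with a small panel; session-cached, copy before mutating."""
    cfg = synthetic.SimConfig(
        n_patients={"io_naive_nonsarc": 2, "io_naive_sarc": 0, "io_exposed": 2},
        n_cells_range=(220, 360),
        panel=synthetic.default_panel(120),
        seed=11,
    )
    adata, truth_cells, truth_fovs = synthetic.simulate_cohort(cfg)
    return adata, truth_cells, truth_fovs, cfg


@pytest.fixture
def qc_cohort(small_cohort):
    """QC'd + normalized copy of the small cohort with truth phenotypes attached."""
    adata, truth_cells, truth_fovs, cfg = small_cohort
    adata, _, _ = qc.run_qc(adata.copy())
    truth = truth_cells.set_index("cell_id").loc[adata.obs_names]
    adata.obs["phenotype"] = truth["true_phenotype"].to_numpy()
    return adata, truth, truth_fovs, cfg


def make_dataset(cells: pd.DataFrame, counts, genes):
    """Shortcut: build an AnnData from a plain cell table and dense counts."""
    return io.build_dataset(cells, sp.csr_matrix(np.asarray(counts)), list(genes))


def toy_cells(n, fov="F1", compartment="tumor", cohort="io_naive_nonsarc", rng=None, **over):
    rng = rng or np.random.default_rng(0)
    base = dict(
        cell_id=[f"{fov}_c{i}" for i in range(n)],
        fov_id=fov,
        sample_id=f"{fov}_S",
        patient_id=f"{fov}_P",
        compartment=compartment,
        cohort=cohort,
        x=rng.uniform(0, 900, n),
        y=rng.uniform(0, 700, n),
        area=rng.lognormal(np.log(120), 0.3, n),
    )
    base.update(over)
    return pd.DataFrame(base)
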