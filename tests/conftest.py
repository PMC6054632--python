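import numpy as np
import pytest

from bruchase.quantify import FilterConfig, apply_filters, compute_rpkm
from bruchase.simulate import GroupSpec, SimulationConfig, simulate_experiment
from bruchase.stability import stability_analysis


def small_config(**kw) -> SimulationConfig:
    """A fast two-group pulse-chase design used across tests."""
    defaults = dict(
        n_genes=400,
        groups=[
            GroupSpec("control", 3),
            GroupSpec("case", 3, k_multipliers={"planted": 2.0}),
        ],
        depth_pulse=1e6,
        depth_chase=1e6,
        dispersion=0.02,
        gene_sets={"planted": 40, "decoy": 40},
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_experiment(small_config(), seed=11)


@pytest.fixture(scope="session")
def small_stability(small_dataset):
    ds = small_dataset
    expr = compute_rpkm(ds.counts, ds.gene_models)
    pulse = ds.sample_sheet.loc[ds.sample_sheet["assay"] == "pulse", "library_id"]
    kept = apply_filters(expr, ds.gene_models, FilterConfig(), list(pulse))
    return stability_analysis(expr.loc[kept], ds.sample_sheet, "case", "control")


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
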