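"""Shared fixtures: benchmark systems, noisy datasets, trained hybrid models.

The expensive end-to-end fixtures (trained hybrid models plus their ranked
stage-2 reports) are session-scoped and shared between the module tests and
the acceptance tests, so each training run happens exactly once.
"""

import warnings

import numpy as np
import pytest

from hybridsindy import (
    HybridODERegressor,
    KnownPart,
    NoiseSpec,
    SimulationGrid,
    get_preset,
    lotka_volterra,
    make_dataset,
    repressilator,
    select_models,
    simulate,
)

LV_PARAMS = {"alpha": 1.3, "beta": 0.9, "gamma": 0.8, "delta": 1.8}
LV_X0 = np.array([0.4425, 4.6281])


@pytest.fixture(scope="session")
def lv_system():
    return lotka_volterra(LV_PARAMS)


@pytest.fixture(scope="session")
def lv_known():
    return KnownPart.linear([LV_PARAMS["alpha"], -LV_PARAMS["delta"]], name="lv_known")


@pytest.fixture(scope="session")
def lv_truth(lv_system):
    return simulate(lv_system, LV_X0, SimulationGrid(0.0, 4.0, 0.1))


@pytest.fixture(scope="session")
def lv_noisefree_dataset(lv_system):
    """Noise-free data: 1 training sample, 50 (identical) validation samples."""
    return make_dataset(
        lv_system, LV_X0, SimulationGrid(0.0, 4.0, 0.1), SimulationGrid(0.0, 20.0, 0.1),
        NoiseSpec("additive", 0.0), n_train=1, n_val=50, n_test=1, seed=0,
    )


@pytest.fixture(scope="session")
def lv_hybrid_runs(lv_system, lv_known):
    """Three seeded end-to-end runs at 0.1% additive noise, 50 training samples.

    Each entry is (dataset, fitted hybrid, ranked stage-2 report) with the
    full published stage-2 grid.
    """
    grid = get_preset("lotka_volterra").selection_grid
    runs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in range(3):
            ds = make_dataset(
                lv_system, LV_X0, SimulationGrid(0.0, 4.0, 0.1),
                SimulationGrid(0.0, 20.0, 0.1), NoiseSpec("additive", 0.001),
                n_train=50, n_val=50, n_test=5, seed=100 + s,
            )
            model = HybridODERegressor(
                known=lv_known, window=5, batch_size=5, lr=0.01, epochs=10,
                init_seed=s, shuffle_seed=s,
            ).fit(ds)
            report = select_models(model, ds, grid, truth=lv_system)
            runs.append((ds, model, report))
    return runs


@pytest.fixture(scope="session")
def repressilator_run():
    """Scaled repressilator end-to-end run at 0.1% additive noise.

    100 training samples, one NN configuration (w=5, b=10, lr=0.01,
    10 epochs), full published stage-2 grid.
    """
    system = repressilator()
    known = KnownPart.linear([-1.0, -1.0, -1.0], name="degradation")
    ds = make_dataset(
        system, [1.0, 1.0, 1.2], SimulationGrid(0.0, 10.0, 0.2),
        SimulationGrid(0.0, 30.0, 0.2), NoiseSpec("additive", 0.001),
        n_train=100, n_val=50, n_test=5, seed=201,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = HybridODERegressor(
            known=known, hidden_layers=(8, 8), window=5, batch_size=10,
            lr=0.01, epochs=10, init_seed=0, shuffle_seed=0,
        ).fit(ds)
        report = select_models(model, ds, get_preset("repressilator").selection_grid,
                               truth=system)
    return ds, model, report
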