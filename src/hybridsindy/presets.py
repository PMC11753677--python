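"""Named study presets: systems, grids, and model-selection configurations.

Each preset bundles a benchmark system with its published study conditions:
initial conditions, training/test spans and step sizes, the known part used
in the hybrid formulation, the stage-1 (w, b, lr) grid and the stage-2
(step size, library, alpha) grid with the STLSQ threshold.

Two alternative Lotka-Volterra parameterizations are exposed
(``lotka_volterra_alt_x0`` and ``lotka_volterra_alt_params``); published
descriptions of the alternative study disagree on which was used, so both
are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .model_selection import SelectionGrid
from .ode_models import ODESystem, SimulationGrid, ValidationError, lotka_volterra, repressilator

__all__ = ["SystemPreset", "PRESETS", "get_preset"]

_STAGE1_GRID = {"w": [5, 10], "b": [5, 10, 20], "lr": [0.001, 0.01, 0.1]}

_LV_SELECTION = SelectionGrid(
    dt_values=(0.05, 0.1),
    library_names=("poly_max_2", "poly_2_3"),
    alpha_values=(0.05, 0.1, 0.5, 1.0, 5.0, 10.0),
    threshold=0.1,
)

_REP_SELECTION = SelectionGrid(
    dt_values=(0.1, 0.2),
    library_names=("hill_1", "hill_2", "hill_3", "hill_max_3"),
    alpha_values=(0.05, 0.1, 0.5, 1.0, 5.0, 10.0),
    threshold=1.0,
)


@dataclass(frozen=True)
class SystemPreset:
    """A benchmark system together with its study conditions."""

    name: str
    make_system: Callable[[], ODESystem]
    x0: tuple[float, ...]
    train_grid: SimulationGrid
    test_grid: SimulationGrid
    known_coeffs: tuple[float, ...]  # diagonal linear known part g_i = c_i x_i
    hidden_layers: tuple[int, ...]
    stage1_grid: dict = field(default_factory=lambda: dict(_STAGE1_GRID))
    selection_grid: SelectionGrid = _LV_SELECTION


_LV_PARAMS = {"alpha": 1.3, "beta": 0.9, "gamma": 0.8, "delta": 1.8}
_LV_ALT_PARAMS = {"alpha": 2.1, "beta": 1.2, "gamma": 0.7, "delta": 1.1}

PRESETS: dict[str, SystemPreset] = {
    "lotka_volterra": SystemPreset(
        name="lotka_volterra",
        make_system=lambda: lotka_volterra(_LV_PARAMS),
        x0=(0.4425, 4.6281),
        train_grid=SimulationGrid(0.0, 4.0, 0.1),
        test_grid=SimulationGrid(0.0, 20.0, 0.1),
        known_coeffs=(_LV_PARAMS["alpha"], -_LV_PARAMS["delta"]),
        hidden_layers=(8,),
        selection_grid=_LV_SELECTION,
    ),
    "lotka_volterra_alt_x0": SystemPreset(
        name="lotka_volterra_alt_x0",
        make_system=lambda: lotka_volterra(_LV_PARAMS),
        x0=(2.5, 0.7),
        train_grid=SimulationGrid(0.0, 4.0, 0.1),
        test_grid=SimulationGrid(0.0, 20.0, 0.1),
        known_coeffs=(_LV_PARAMS["alpha"], -_LV_PARAMS["delta"]),
        hidden_layers=(8,),
        selection_grid=_LV_SELECTION,
    ),
    "lotka_volterra_alt_params": SystemPreset(
        name="lotka_volterra_alt_params",
        make_system=lambda: lotka_volterra(_LV_ALT_PARAMS),
        x0=(2.5, 0.7),
        train_grid=SimulationGrid(0.0, 4.0, 0.1),
        test_grid=SimulationGrid(0.0, 20.0, 0.1),
        known_coeffs=(_LV_ALT_PARAMS["alpha"], -_LV_ALT_PARAMS["delta"]),
        hidden_layers=(8,),
        selection_grid=_LV_SELECTION,
    ),
    "repressilator": SystemPreset(
        name="repressilator",
        make_system=lambda: repressilator(beta=10.0, n=3, gamma=1.0),
        x0=(1.0, 1.0, 1.2),
        train_grid=SimulationGrid(0.0, 10.0, 0.2),
        test_grid=SimulationGrid(0.0, 30.0, 0.2),
        known_coeffs=(-1.0, -1.0, -1.0),
        hidden_layers=(8, 8),
        selection_grid=_REP_SELECTION,
    ),
    "repressilator_asym": SystemPreset(
        name="repressilator_asym",
        make_system=lambda: repressilator(beta=(7.0, 6.0, 8.0), n=2, gamma=1.0),
        x0=(1.0, 1.0, 1.2),
        train_grid=SimulationGrid(0.0, 10.0, 0.2),
        test_grid=SimulationGrid(0.0, 30.0, 0.2),
        known_coeffs=(-1.0, -1.0, -1.0),
        hidden_layers=(8, 8),
        selection_grid=SelectionGrid(
            dt_values=(0.1, 0.2),
            library_names=("hill_1", "hill_2", "hill_3", "hill_max_3"),
            alpha_values=(0.05, 0.1, 0.5, 1.0, 5.0, 10.0),
            threshold=1.0,
        ),
    ),
}


def get_preset(name: str) -> SystemPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown system preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
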