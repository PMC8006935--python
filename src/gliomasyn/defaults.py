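"""Default parameter sets, loaded from the packaged YAML config.

All numeric defaults (growth kinetics, pharmacodynamics, initial state,
dose-grid ranges, horizons) live in ``data/default_params.yaml`` so they are
version-controlled data rather than code. The growth set was calibrated once
so that the resistant subclone dominates the sensitive one at steady state
and all compartments settle well inside the 300 h simulation window; the
per-drug ``emax`` values were calibrated once so the simulated 72-h
monotherapy dose-response of the targeted compartment crosses 50% close to
the configured IC50.
"""

from __future__ import annotations

import functools
from importlib import resources

import yaml

from .model_core import CellState, DrugEffectParams, GrowthParams

__all__ = [
    "load_default_config",
    "default_growth_params",
    "default_drug_params",
    "default_initial_state",
    "default_grid_range",
    "default_horizons",
]


@functools.lru_cache(maxsize=1)
def load_default_config() -> dict:
    """Parsed contents of the packaged default-parameter file."""
    text = (resources.files("gliomasyn.data") / "default_params.yaml").read_text()
    return yaml.safe_load(text)


def default_growth_params() -> GrowthParams:
    return GrowthParams.from_dict(load_default_config()["growth"])


def default_drug_params(acridone: str = "AC26") -> DrugEffectParams:
    cfg = load_default_config()
    tmz = cfg["drugs"]["TMZ"]
    acr = cfg["drugs"][acridone]
    return DrugEffectParams(
        d1_r=_triplet(tmz["r"]), d1_s=_triplet(tmz["s"]),
        d2_r=_triplet(acr["r"]), d2_s=_triplet(acr["s"]),
        acridone=acridone,
    )


def _triplet(d):
    from .model_core import HillTriplet
    return HillTriplet.from_dict(d)


def default_initial_state() -> CellState:
    s = load_default_config()["initial_state"]
    return CellState(n=s["N"], c=s["C"], c_r=s["C_R"], c_s=s["C_S"])


def default_grid_range(drug: str) -> tuple[float, float]:
    lo, hi = load_default_config()["grid_ranges"][drug]
    return float(lo), float(hi)


def default_horizons() -> dict:
    return dict(load_default_config()["horizons"])
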