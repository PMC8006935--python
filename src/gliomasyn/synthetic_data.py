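"""Synthetic inputs for the pipeline: noisy 96-h growth curves and
Hill-shaped dose-response readouts.

The growth generator emulates time-course viability data for glioma cell
lines (one observation per compartment per time point, Gaussian noise
truncated at zero); the dose-response generator emulates triplicate-style
viability percentages along a dose ladder. Both record the generating truth
so inference and curve-fitting stages can be tested for recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import CellState, GrowthParams
from .simulate import integrate

__all__ = [
    "SyntheticGrowthDataset",
    "generate_growth_data",
    "generate_dose_response_data",
    "DEFAULT_OBSERVED",
]

#: Compartments observed by default (undifferentiated pool as the total-
#: cancer proxy plus the two subclones).
DEFAULT_OBSERVED = ("C", "C_R", "C_S")

_COL = {"N": 0, "C": 1, "C_R": 2, "C_S": 3}


@dataclass
class SyntheticGrowthDataset:
    """Noisy growth-curve observations plus the generating truth."""

    true_params: GrowthParams
    initial_state: CellState
    times: np.ndarray
    observed_compartments: tuple
    observations: dict          # compartment -> array over times
    truth: dict                 # compartment -> noise-free trajectory
    noise_sd: dict              # compartment -> Gaussian sd used
    seed: Optional[int]

    def to_frame(self) -> pd.DataFrame:
        data = {"time_h": self.times}
        for comp in self.observed_compartments:
            data[comp] = self.observations[comp]
        return pd.DataFrame(data)

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write observations as tidy CSV plus a JSON sidecar recording the
        seed, noise levels and generating parameters."""
        self.to_frame().to_csv(path, index=False, float_format="%.12g")
        if sidecar:
            meta = {
                "seed": self.seed,
                "noise_sd": self.noise_sd,
                "observed_compartments": list(self.observed_compartments),
                "true_params": self.true_params.to_dict(),
                "initial_state": list(self.initial_state.to_array()),
            }
            with open(f"{path}.meta.json", "w") as fh:
                json.dump(meta, fh, indent=1, sort_keys=True)


def generate_growth_data(
    true_params: GrowthParams,
    initial_state: Optional[CellState] = None,
    times: Optional[Sequence[float]] = None,
    observed_compartments: Sequence[str] = DEFAULT_OBSERVED,
    noise_sd=None,
    seed: Optional[int] = 0,
) -> SyntheticGrowthDataset:
    """Simulate the drug-free model and add truncated Gaussian noise.

    ``times`` defaults to 0-96 h every 4 h. ``noise_sd`` may be a scalar,
    a per-compartment mapping, or None for the default of 5% of each
    compartment's trajectory mean. Observations are clipped at zero.
    """
    if initial_state is None:
        from .defaults import default_initial_state
        initial_state = default_initial_state()
    times = np.arange(0.0, 96.0 + 1e-9, 4.0) if times is None \
        else np.asarray(times, dtype=float)
    for comp in observed_compartments:
        if comp not in _COL:
            raise ValueError(f"unknown compartment {comp!r}")

    tc = integrate(initial_state, true_params, t_end=float(times[-1]),
                   sample_dt=min(0.5, float(np.min(np.diff(times)))))
    truth = {}
    for comp in observed_compartments:
        truth[comp] = np.interp(times, tc.times, tc.compartment(comp))

    if noise_sd is None:
        sd = {c: 0.05 * float(np.mean(truth[c])) for c in observed_compartments}
    elif np.isscalar(noise_sd):
        if noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        sd = {c: float(noise_sd) for c in observed_compartments}
    else:
        sd = {c: float(noise_sd[c]) for c in observed_compartments}

    rng = np.random.default_rng(seed)
    observations = {
        c: np.clip(truth[c] + rng.normal(0.0, sd[c], size=times.size), 0.0, None)
        for c in observed_compartments
    }
    return SyntheticGrowthDataset(
        true_params=true_params, initial_state=initial_state, times=times,
        observed_compartments=tuple(observed_compartments),
        observations=observations, truth=truth, noise_sd=sd, seed=seed)


def generate_dose_response_data(
    ic50: float, eta: float, doses: Sequence[float],
    noise_sd_pct: float = 5.0, seed: Optional[int] = 0,
) -> pd.DataFrame:
    """Hill-shaped relative-growth observations along a dose ladder.

    Relative growth is ``100 * (1 - d^eta / (ic50^eta + d^eta))`` plus
    Gaussian noise (percentage points), clipped to
    ``[0, 100 + 3 * noise_sd_pct]``.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0")
    if ic50 <= 0 or eta <= 0:
        raise ValueError("ic50 and eta must be > 0")
    if noise_sd_pct < 0:
        raise ValueError("noise_sd_pct must be >= 0")
    # overflow in (ic50/d)^eta for d -> 0 saturates to inf, giving frac 0
    with np.errstate(divide="ignore", over="ignore"):
        frac = np.where(doses > 0,
                        1.0 / (1.0 + (ic50 / np.maximum(doses, 1e-300)) ** eta),
                        0.0)
    growth = 100.0 * (1.0 - frac)
    rng = np.random.default_rng(seed)
    noisy = growth + rng.normal(0.0, noise_sd_pct, size=doses.size)
    noisy = np.clip(noisy, 0.0, 100.0 + 3.0 * noise_sd_pct)
    return pd.DataFrame({"dose_uM": doses, "relative_growth_pct": noisy})
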