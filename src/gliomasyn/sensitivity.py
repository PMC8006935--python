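"""Global sensitivity analysis: Latin hypercube sampling with partial rank
correlation coefficients (LHS-PRCC).

Each LHS row is a full model configuration (growth parameters, the twelve
pharmacodynamic parameters and the two doses); the model is simulated to the
readout horizon and the PRCC of every varied parameter against each
compartment's abundance is computed, with a t-based p-value. Because
``gamma_R + omega_S = 1`` is a hard model constraint, ``omega_S`` is derived
from ``gamma_R`` rather than sampled independently (sampling both would make
the rank-regression design singular), so 28 independent quantities are
varied by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .model_core import (
    CellState,
    DosePair,
    DrugEffectParams,
    GrowthParams,
    HillTriplet,
)
from .simulate import IntegrationError, fast_endpoint

__all__ = [
    "PrccResult",
    "lhs_sample",
    "prcc",
    "run_sensitivity",
    "default_sensitivity_ranges",
    "SENSITIVITY_OUTPUTS",
]

logger = logging.getLogger(__name__)

SENSITIVITY_OUTPUTS = ("N", "C", "C_R", "C_S")

#: Growth parameters varied by default (omega_S derived from gamma_R).
_GROWTH_VARIED = ("alpha_N", "delta_N", "rho", "K", "mu", "alpha_C",
                  "delta_C", "gamma_R", "alpha_CR", "delta_R",
                  "omega_S_tilde", "alpha_CS", "delta_S", "gamma_R_tilde")
_DRUG_VARIED = tuple(f"{f}_{slot}" for slot in ("d1_r", "d1_s", "d2_r", "d2_s")
                     for f in ("emax", "eta", "ic50"))
_DOSES = ("d1", "d2")


@dataclass
class PrccResult:
    """PRCC values and p-values, one row per (parameter, output)."""

    table: pd.DataFrame          # columns: parameter, output, prcc, p_value
    n_samples: int
    ranges: dict

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_value"] < alpha]

    def lookup(self, parameter: str, output: str) -> tuple[float, float]:
        row = self.table[(self.table["parameter"] == parameter)
                         & (self.table["output"] == output)]
        if row.empty:
            raise KeyError((parameter, output))
        return float(row["prcc"].iloc[0]), float(row["p_value"].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.12g")


def lhs_sample(ranges: Sequence[Sequence[float]], n: int,
               seed: Optional[int] = None) -> np.ndarray:
    """Latin hypercube sample: one draw per equal-probability stratum per
    parameter, uniform within each stratum, strata independently permuted
    across parameters. Returns an (n, k) matrix."""
    ranges = np.asarray(ranges, dtype=float)
    k = ranges.shape[0]
    if n < k + 2:
        raise ValueError(f"need n >= k+2 samples (k={k})")
    if np.any(ranges[:, 0] >= ranges[:, 1]):
        raise ValueError("each range must satisfy lo < hi")
    sampler = qmc.LatinHypercube(d=k, seed=np.random.default_rng(seed))
    unit = sampler.random(n)
    return qmc.scale(unit, ranges[:, 0], ranges[:, 1])


def prcc(samples: np.ndarray, outputs: np.ndarray,
         names: Optional[Sequence[str]] = None,
         output_name: str = "y") -> PrccResult:
    """Partial rank correlation of each parameter column with the output.

    All columns are rank-transformed (average ranks on ties); parameter j's
    PRCC is the Pearson correlation of the residuals of rank(x_j) and
    rank(y) after linear regression on the other k-1 rank-transformed
    parameters. p-values use the t statistic with ``n - 2 - (k - 1)``
    degrees of freedom.
    """
    samples = np.asarray(samples, dtype=float)
    outputs = np.asarray(outputs, dtype=float)
    n, k = samples.shape
    if outputs.shape != (n,):
        raise ValueError("outputs must be an n-vector")
    if n <= k + 2:
        raise ValueError(f"insufficient samples: need n > k+2 (n={n}, k={k})")
    if np.any(np.ptp(samples, axis=0) == 0):
        raise ValueError("constant parameter column(s) present")
    names = list(names) if names is not None else [f"x{j}" for j in range(k)]

    rx = np.column_stack([stats.rankdata(samples[:, j]) for j in range(k)])
    ry = stats.rankdata(outputs)
    dof = n - 2 - (k - 1)
    rows = []
    for j in range(k):
        others = np.delete(rx, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        res_x = rx[:, j] - design @ np.linalg.lstsq(design, rx[:, j], rcond=None)[0]
        res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
        denom = np.linalg.norm(res_x) * np.linalg.norm(res_y)
        r = float(res_x @ res_y / denom) if denom > 0 else 0.0
        r = float(np.clip(r, -1.0, 1.0))
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt(dof / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), dof))
        rows.append((names[j], output_name, r, p))
    table = pd.DataFrame(rows, columns=["parameter", "output", "prcc", "p_value"])
    return PrccResult(table=table, n_samples=n, ranges={})


def default_sensitivity_ranges(width: float = 0.5) -> dict:
    """+/-50% ranges around the default parameter set.

    Probabilities are clipped to [0, 1]; the acridone (drug 2) ranges span
    the values of all three derivatives; doses span the default grids.
    """
    from .defaults import (default_drug_params, default_growth_params,
                           default_grid_range)
    g = default_growth_params().to_dict()
    ranges = {}
    for name in _GROWTH_VARIED:
        v = g[name]
        lo, hi = v * (1 - width), v * (1 + width)
        if name in ("rho", "gamma_R", "omega_S_tilde", "gamma_R_tilde"):
            lo, hi = max(lo, 0.0), min(hi, 1.0)
        ranges[name] = (lo, hi)
    d1 = default_drug_params("AC26")
    for slot, trip in (("d1_r", d1.d1_r), ("d1_s", d1.d1_s)):
        for f in ("emax", "eta", "ic50"):
            v = getattr(trip, f)
            ranges[f"{f}_{slot}"] = (v * (1 - width), v * (1 + width))
    for slot, attr in (("d2_r", "d2_r"), ("d2_s", "d2_s")):
        for f in ("emax", "eta", "ic50"):
            vals = [getattr(getattr(default_drug_params(a), attr), f)
                    for a in ("AC2", "AC7", "AC26")]
            ranges[f"{f}_{slot}"] = (min(vals) * (1 - width),
                                     max(vals) * (1 + width))
    ranges["d1"] = default_grid_range("TMZ")
    ranges["d2"] = default_grid_range("AC26")
    return ranges


def _row_to_model(row: Mapping[str, float], base: GrowthParams):
    g = base.to_dict()
    for name in _GROWTH_VARIED:
        if name in row:
            g[name] = row[name]
    g["omega_S"] = 1.0 - g["gamma_R"]
    p = GrowthParams.from_dict(g)
    trips = {}
    for slot in ("d1_r", "d1_s", "d2_r", "d2_s"):
        trips[slot] = HillTriplet(
            emax=row.get(f"emax_{slot}", 0.0),
            eta=row.get(f"eta_{slot}", 1.0),
            ic50=row.get(f"ic50_{slot}", 1.0))
    dp = DrugEffectParams(**trips)
    doses = DosePair(row.get("d1", 0.0), row.get("d2", 0.0))
    return p, dp, doses


def run_sensitivity(ranges: Optional[Mapping[str, Sequence[float]]] = None,
                    n: int = 500, seed: Optional[int] = 0,
                    horizon_h: float = 300.0,
                    initial: Optional[CellState] = None,
                    outputs: Sequence[str] = SENSITIVITY_OUTPUTS,
                    max_dropped_frac: float = 0.1) -> dict:
    """LHS-PRCC of all varied parameters against each compartment.

    Zero-width ranges pin a parameter at that value and exclude it from the
    PRCC design. Rows whose simulation blows up are dropped with a logged
    count; more than ``max_dropped_frac`` dropped is an error. Returns a
    mapping output name -> :class:`PrccResult`.
    """
    from .defaults import default_growth_params, default_initial_state
    if ranges is None:
        ranges = default_sensitivity_ranges()
    if initial is None:
        initial = default_initial_state()
    base = default_growth_params()

    fixed = {k: v[0] for k, v in ranges.items() if v[0] == v[1]}
    varied = [k for k in ranges if k not in fixed]
    bounds = [ranges[k] for k in varied]
    samples = lhs_sample(bounds, n, seed=seed)

    results = np.empty((n, 4))
    ok_mask = np.ones(n, dtype=bool)
    for i in range(n):
        row = dict(zip(varied, samples[i]))
        row.update(fixed)
        try:
            p, dp, doses = _row_to_model(row, base)
            results[i] = fast_endpoint(p, dp, doses, initial, horizon_h)
        except (IntegrationError, ValueError):
            ok_mask[i] = False
    dropped = int((~ok_mask).sum())
    if dropped:
        logger.warning("dropped %d/%d failed simulations", dropped, n)
        if dropped > max_dropped_frac * n:
            raise IntegrationError(
                f"{dropped}/{n} sensitivity simulations failed")
    samples, results = samples[ok_mask], results[ok_mask]

    out = {}
    idx = {"N": 0, "C": 1, "C_R": 2, "C_S": 3}
    for name in outputs:
        res = prcc(samples, results[:, idx[name]], names=varied,
                   output_name=name)
        res.ranges = {k: tuple(ranges[k]) for k in varied}
        out[name] = res
    return out
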