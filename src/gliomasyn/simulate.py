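"""Numerical integration, steady-state detection and relative-growth readouts."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _fast
from .model_core import (
    CellState,
    DosePair,
    DrugEffectParams,
    GrowthParams,
    growth_rhs,
)

__all__ = [
    "TimeCourse",
    "IntegrationError",
    "SteadyStateWarning",
    "integrate",
    "steady_state",
    "relative_growth",
    "fast_endpoint",
]

logger = logging.getLogger(__name__)

COMPARTMENTS = ("N", "C", "C_R", "C_S")

#: Accepted compartment selectors for growth readouts.
_READOUTS = {"N": (0,), "C": (1,), "C_R": (2,), "C_S": (3,),
             "total_cancer": (1, 2, 3)}


class IntegrationError(RuntimeError):
    pass


class SteadyStateWarning(UserWarning):
    """Raised when the relative-derivative criterion is not met by t_max."""


@dataclass
class TimeCourse:
    """A solved trajectory sampled on a dense grid.

    ``states`` has one row per time and columns (N, C, C_R, C_S).
    """

    times: np.ndarray
    states: np.ndarray
    params_used: GrowthParams
    drug_params: Optional[DrugEffectParams] = None
    doses: Optional[DosePair] = None
    clipped_points: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, 4):
            raise ValueError("states must be (len(times), 4)")
        if self.times.size and self.times[0] < 0:
            raise ValueError("first time must be >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def compartment(self, name: str) -> np.ndarray:
        idx = _READOUTS[name]
        return self.states[:, idx].sum(axis=1)

    def final_state(self) -> CellState:
        return CellState.from_array(self.states[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_h": self.times,
             "N": self.states[:, 0], "C": self.states[:, 1],
             "C_R": self.states[:, 2], "C_S": self.states[:, 3]})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def read_csv(cls, path, params: GrowthParams) -> "TimeCourse":
        df = pd.read_csv(path)
        return cls(times=df["time_h"].to_numpy(),
                   states=df[["N", "C", "C_R", "C_S"]].to_numpy(),
                   params_used=params)


def _make_rhs(p: GrowthParams, dp, doses):
    theta = p.to_array()
    if dp is not None and doses is not None:
        k_r, k_s = dp.kill_rates(doses)
    else:
        k_r = k_s = 0.0
    out = np.empty(4)

    def rhs(t, y):
        _fast._rhs4(y, theta, k_r, k_s, out)
        return out.copy()

    return rhs


def integrate(initial: CellState, p: GrowthParams,
              dp: Optional[DrugEffectParams] = None,
              doses: Optional[DosePair] = None,
              t_end: float = 300.0, rtol: float = 1e-7, atol: float = 1e-9,
              sample_dt: float = 0.5) -> TimeCourse:
    """Solve the model with an adaptive Dormand-Prince RK45 integrator.

    ``dp``/``doses`` add the Emax/Hill kill terms; omit both for the
    drug-free system. Tiny negative excursions in the sampled solution are
    clipped to zero and counted in ``TimeCourse.clipped_points``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be > 0")
    if (dp is None) != (doses is None):
        raise ValueError("drug params and doses must be given together")
    times = np.arange(0.0, t_end + 0.5 * sample_dt, sample_dt)
    times[-1] = min(times[-1], t_end)
    sol = solve_ivp(_make_rhs(p, dp, doses), (0.0, t_end),
                    initial.to_array(), method="RK45",
                    t_eval=times, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(
            f"integration failed ({sol.message}) for params {p.to_dict()}")
    states = sol.y.T
    neg = states < 0
    clipped = int(neg.sum())
    if clipped:
        logger.info("clipped %d negative sample(s) to zero", clipped)
        states = np.where(neg, 0.0, states)
    return TimeCourse(times=sol.t, states=states, params_used=p,
                      drug_params=dp, doses=doses, clipped_points=clipped)


def steady_state(initial: CellState, p: GrowthParams,
                 dp: Optional[DrugEffectParams] = None,
                 doses: Optional[DosePair] = None,
                 t_max: float = 300.0, tol: float = 1e-6,
                 sample_dt: float = 0.5) -> CellState:
    """State at the first sampled time where every compartment's relative
    derivative ``|dX/dt| / (X + mu)`` falls below ``tol`` (per hour).

    Falls back to the ``t_max`` state with a :class:`SteadyStateWarning`
    when the criterion is never met.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    tc = integrate(initial, p, dp, doses, t_end=t_max, sample_dt=sample_dt)
    theta = p.to_array()
    if dp is not None and doses is not None:
        k_r, k_s = dp.kill_rates(doses)
    else:
        k_r = k_s = 0.0
    deriv = np.empty(4)
    for i, row in enumerate(tc.states):
        _fast._rhs4(row, theta, k_r, k_s, deriv)
        if np.max(np.abs(deriv) / (row + p.mu)) < tol:
            return CellState.from_array(tc.states[i])
    warnings.warn(
        f"steady state not reached by t={t_max} h (tol={tol}); "
        "returning the final state", SteadyStateWarning)
    return tc.final_state()


class UndefinedBaselineError(ZeroDivisionError):
    """Untreated reference abundance is zero at the requested horizon."""


def _horizon_state(initial, p, dp, doses, horizon, t_max, tol):
    mode, value = _parse_horizon(horizon, t_max)
    if mode == "fixed":
        return integrate(initial, p, dp, doses, t_end=value).final_state()
    return steady_state(initial, p, dp, doses, t_max=value, tol=tol)


def _parse_horizon(horizon, t_max):
    if horizon == "steady_state":
        return "steady_state", t_max
    if isinstance(horizon, (int, float)):
        return "fixed", float(horizon)
    if isinstance(horizon, tuple) and horizon[0] in ("fixed", "steady_state"):
        return horizon[0], float(horizon[1])
    raise ValueError(f"unrecognized horizon {horizon!r}")


def relative_growth(p: GrowthParams, dp: DrugEffectParams, doses: DosePair,
                    compartment: str = "C_R",
                    horizon="steady_state",
                    initial: Optional[CellState] = None,
                    t_max: float = 300.0, tol: float = 1e-6) -> float:
    """Treated abundance as a percentage of the untreated control.

    ``horizon`` is either a fixed time in hours (e.g. ``72.0``, matching a
    72-h drug exposure) or ``"steady_state"``. The control run shares the
    initial state and growth parameters with doses (0, 0).
    """
    if compartment not in _READOUTS:
        raise ValueError(f"compartment must be one of {sorted(_READOUTS)}")
    if initial is None:
        from .defaults import default_initial_state
        initial = default_initial_state()
    treated = _horizon_state(initial, p, dp, doses, horizon, t_max, tol)
    control = _horizon_state(initial, p, dp, DosePair(0.0, 0.0),
                             horizon, t_max, tol)
    idx = _READOUTS[compartment]
    num = sum(treated.to_array()[list(idx)])
    den = sum(control.to_array()[list(idx)])
    if den == 0:
        raise UndefinedBaselineError(
            f"untreated {compartment} abundance is zero at horizon {horizon!r}")
    return 100.0 * num / den


def fast_endpoint(p: GrowthParams, dp: Optional[DrugEffectParams],
                  doses: Optional[DosePair], initial: CellState,
                  t_end: float, h: float = _fast.DEFAULT_STEP_H) -> np.ndarray:
    """Endpoint state via the compiled fixed-step RK4 kernel.

    Used by the dose-grid and sensitivity sweeps; raises
    :class:`IntegrationError` on numerical blow-up.
    """
    if dp is not None and doses is not None:
        k_r, k_s = dp.kill_rates(doses)
    else:
        k_r = k_s = 0.0
    ok, y = _fast.rk4_endpoint(p.to_array(), k_r, k_s,
                               initial.to_array(), t_end, h)
    if not ok:
        raise IntegrationError(f"trajectory blew up for params {p.to_dict()}")
    return y
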