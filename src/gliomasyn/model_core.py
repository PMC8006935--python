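"""Core tumor-growth model: state, parameters and ODE right-hand sides.

The model tracks four cell populations of a developing glioma:

* ``N``   non-cancerous precursor cells, growing logistically and mutating
  into cancer cells with probability ``rho``;
* ``C``   undifferentiated cancer cells, growing by Gompertz kinetics and
  differentiating into resistant/sensitive subclones;
* ``C_R`` drug-resistant cancer cells;
* ``C_S`` drug-sensitive cancer cells.

Resistant and sensitive clones interconvert (``gamma_R_tilde`` forward,
``omega_S_tilde`` backward) and share a common carrying capacity ``K``.
Drug action (temozolomide, ``D1``; an acridone derivative, ``D2``) enters
the resistant and sensitive equations only, as saturating Emax/Hill kill
terms with constant concentration over the integration window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "CellState",
    "GrowthParams",
    "HillTriplet",
    "DrugEffectParams",
    "DosePair",
    "gompertz_term",
    "hill_kill_term",
    "growth_rhs",
    "treated_rhs",
    "TOXICITY_LIMIT_TMZ_UM",
    "TOXICITY_LIMIT_ACRIDONE_UM",
    "ACRIDONE_LABELS",
]

#: Doses above these raise toxicity flags (uM).
TOXICITY_LIMIT_TMZ_UM = 250.0
TOXICITY_LIMIT_ACRIDONE_UM = 100.0

ACRIDONE_LABELS = ("AC2", "AC7", "AC26")

_PROB_TOL = 1e-12


class ParameterDomainError(ValueError):
    """A parameter value lies outside its admissible domain."""


def _check_unknown(data: Mapping, allowed: Iterable[str], what: str) -> None:
    unknown = set(data) - set(allowed)
    if unknown:
        raise ParameterDomainError(f"unknown {what} field(s): {sorted(unknown)}")


@dataclass(frozen=True)
class CellState:
    """Abundances of the four populations at one instant (all >= 0)."""

    n: float
    c: float
    c_r: float
    c_s: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ParameterDomainError(f"CellState.{f.name} must be finite")
            if v < 0:
                raise ParameterDomainError(f"CellState.{f.name} must be >= 0, got {v}")

    def to_array(self) -> np.ndarray:
        return np.array([self.n, self.c, self.c_r, self.c_s], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "CellState":
        n, c, c_r, c_s = (float(x) for x in arr)
        return cls(n, c, c_r, c_s)


#: Canonical parameter ordering shared with the compiled integrator.
GROWTH_PARAM_ORDER = (
    "alpha_N", "delta_N", "rho", "K", "mu",
    "alpha_C", "delta_C", "gamma_R", "omega_S",
    "alpha_CR", "delta_R", "omega_S_tilde",
    "alpha_CS", "delta_S", "gamma_R_tilde",
)


@dataclass(frozen=True)
class GrowthParams:
    """The 15 drug-free model parameters.

    Rates are per hour, probabilities unitless, ``K``/``mu`` in cell units.
    ``gamma_R + omega_S = 1`` is enforced at construction: a dividing cancer
    cell commits to exactly one of the two subclones.
    """

    alpha_N: float
    delta_N: float
    rho: float
    K: float
    mu: float
    alpha_C: float
    delta_C: float
    gamma_R: float
    omega_S: float
    alpha_CR: float
    delta_R: float
    omega_S_tilde: float
    alpha_CS: float
    delta_S: float
    gamma_R_tilde: float

    def __post_init__(self) -> None:
        rates = ("alpha_N", "delta_N", "alpha_C", "delta_C",
                 "alpha_CR", "delta_R", "alpha_CS", "delta_S")
        for name in rates:
            if getattr(self, name) < 0:
                raise ParameterDomainError(f"{name} must be >= 0")
        if self.K <= 0:
            raise ParameterDomainError("K must be > 0")
        if self.mu <= 0:
            raise ParameterDomainError("mu must be > 0")
        if not 0.0 <= self.rho <= 1.0:
            raise ParameterDomainError("rho must lie in [0, 1]")
        for name in ("gamma_R", "omega_S", "gamma_R_tilde", "omega_S_tilde"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ParameterDomainError(f"{name} must lie in [0, 1]")
        if abs(self.gamma_R + self.omega_S - 1.0) > _PROB_TOL:
            raise ParameterDomainError(
                "gamma_R + omega_S must equal 1 "
                f"(got {self.gamma_R + self.omega_S!r})")

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "GrowthParams":
        _check_unknown(data, GROWTH_PARAM_ORDER, "GrowthParams")
        return cls(**{k: float(data[k]) for k in GROWTH_PARAM_ORDER})

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in GROWTH_PARAM_ORDER}

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in GROWTH_PARAM_ORDER], dtype=float)

    def with_updates(self, **kwargs) -> "GrowthParams":
        """Return a copy with fields replaced; setting ``gamma_R`` without
        ``omega_S`` (or vice versa) rebalances the pair to sum to 1."""
        if "gamma_R" in kwargs and "omega_S" not in kwargs:
            kwargs["omega_S"] = 1.0 - kwargs["gamma_R"]
        elif "omega_S" in kwargs and "gamma_R" not in kwargs:
            kwargs["gamma_R"] = 1.0 - kwargs["omega_S"]
        return replace(self, **kwargs)


_HILL_FIELDS = ("emax", "eta", "ic50")


@dataclass(frozen=True)
class HillTriplet:
    """One Emax/Hill/IC50 triplet: maximal kill rate (per hour), Hill
    exponent (unitless, > 0) and half-maximal concentration (uM, > 0)."""

    emax: float
    eta: float
    ic50: float

    def __post_init__(self) -> None:
        if self.emax < 0:
            raise ParameterDomainError("emax must be >= 0")
        if self.eta <= 0:
            raise ParameterDomainError("eta must be > 0")
        if self.ic50 <= 0:
            raise ParameterDomainError("ic50 must be > 0")

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "HillTriplet":
        _check_unknown(data, _HILL_FIELDS, "HillTriplet")
        return cls(**{k: float(data[k]) for k in _HILL_FIELDS})

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in _HILL_FIELDS}


@dataclass(frozen=True)
class DrugEffectParams:
    """Per-drug, per-subpopulation pharmacodynamic parameters.

    Drug 1 is temozolomide; drug 2 is the acridone derivative named by
    ``acridone`` (one of AC2/AC7/AC26). ``r`` = resistant cells,
    ``s`` = sensitive cells; twelve parameters in total, the two doses
    living in :class:`DosePair`.
    """

    d1_r: HillTriplet
    d1_s: HillTriplet
    d2_r: HillTriplet
    d2_s: HillTriplet
    acridone: str = "AC26"

    def __post_init__(self) -> None:
        if self.acridone not in ACRIDONE_LABELS:
            raise ParameterDomainError(
                f"acridone must be one of {ACRIDONE_LABELS}, got {self.acridone!r}")

    @classmethod
    def from_dict(cls, data: Mapping) -> "DrugEffectParams":
        _check_unknown(data, ("d1_r", "d1_s", "d2_r", "d2_s", "acridone"),
                       "DrugEffectParams")
        kw = {k: HillTriplet.from_dict(data[k])
              for k in ("d1_r", "d1_s", "d2_r", "d2_s")}
        if "acridone" in data:
            kw["acridone"] = data["acridone"]
        return cls(**kw)

    def to_dict(self) -> dict:
        return {"d1_r": self.d1_r.to_dict(), "d1_s": self.d1_s.to_dict(),
                "d2_r": self.d2_r.to_dict(), "d2_s": self.d2_s.to_dict(),
                "acridone": self.acridone}

    def kill_rates(self, doses: "DosePair") -> tuple[float, float]:
        """Total per-capita kill rates (k_r, k_s) at constant doses."""
        k_r = (hill_kill_term(self.d1_r.emax, doses.d1, self.d1_r.ic50, self.d1_r.eta)
               + hill_kill_term(self.d2_r.emax, doses.d2, self.d2_r.ic50, self.d2_r.eta))
        k_s = (hill_kill_term(self.d1_s.emax, doses.d1, self.d1_s.ic50, self.d1_s.eta)
               + hill_kill_term(self.d2_s.emax, doses.d2, self.d2_s.ic50, self.d2_s.eta))
        return k_r, k_s


@dataclass(frozen=True)
class DosePair:
    """Constant concentrations of TMZ (``d1``) and acridone (``d2``), uM."""

    d1: float = 0.0
    d2: float = 0.0

    def __post_init__(self) -> None:
        if self.d1 < 0 or self.d2 < 0:
            raise ParameterDomainError("doses must be >= 0")

    @property
    def toxicity_flags(self) -> tuple[bool, bool]:
        """(TMZ above 250 uM, acridone above 100 uM)."""
        return (self.d1 > TOXICITY_LIMIT_TMZ_UM,
                self.d2 > TOXICITY_LIMIT_ACRIDONE_UM)


def gompertz_term(alpha: float, x: float, k: float, mu: float) -> float:
    """Gompertz growth contribution ``alpha * x * log(K / (x + mu))``.

    The offset ``mu > 0`` regularizes the classical Gompertz law, which is
    singular at ``x = 0``; with it the term vanishes at zero abundance and
    changes sign where ``x + mu`` crosses ``K``.
    """
    if k <= 0:
        raise ParameterDomainError("carrying capacity K must be > 0")
    if mu <= 0:
        raise ParameterDomainError("mu must be > 0")
    if alpha < 0:
        raise ParameterDomainError("alpha must be >= 0")
    if x < 0:
        raise ParameterDomainError("abundance must be >= 0")
    return alpha * x * math.log(k / (x + mu))


def hill_kill_term(emax: float, dose: float, ic50: float, eta: float) -> float:
    """Saturating Emax/Hill kill rate ``emax * D^eta / (IC50^eta + D^eta)``.

    Monotone non-decreasing in dose, zero at zero dose, equal to ``emax/2``
    at ``dose == ic50`` for any Hill exponent, and bounded above by ``emax``.
    """
    if dose < 0:
        raise ParameterDomainError("dose must be >= 0")
    if ic50 <= 0:
        raise ParameterDomainError("ic50 must be > 0")
    if eta <= 0:
        raise ParameterDomainError("eta must be > 0")
    if emax < 0:
        raise ParameterDomainError("emax must be >= 0")
    if dose == 0.0:
        return 0.0
    # work on the log scale to dodge overflow for extreme dose/IC50 ratios
    log_r = eta * (math.log(ic50) - math.log(dose))
    if log_r > 700.0:
        return 0.0
    return emax / (1.0 + math.exp(log_r))


def growth_rhs(state, p: GrowthParams) -> np.ndarray:
    """Drug-free time derivatives (per hour) of (N, C, C_R, C_S).

    ``state`` may be a :class:`CellState` or a length-4 array.
    """
    if isinstance(state, CellState):
        n, c, c_r, c_s = state.n, state.c, state.c_r, state.c_s
    else:
        n, c, c_r, c_s = (float(v) for v in state)
    dn = (p.alpha_N * n * (1.0 - p.rho) * (1.0 - n / p.K)
          - p.delta_N * n
          - p.alpha_N * n * p.rho)
    dc = (p.alpha_N * p.rho * n
          + gompertz_term(p.alpha_C, c, p.K, p.mu)
          - p.gamma_R * p.alpha_C * c
          - p.omega_S * p.alpha_C * c
          - p.delta_C * c)
    dcr = (p.gamma_R * p.alpha_C * c
           + p.gamma_R_tilde * p.alpha_CS * c_s
           + gompertz_term(p.alpha_CR, c_r, p.K, p.mu)
           - p.delta_R * c_r
           - p.omega_S_tilde * p.alpha_CR * c_r)
    dcs = (p.omega_S_tilde * p.alpha_CR * c_r
           + p.omega_S * p.alpha_C * c
           + gompertz_term(p.alpha_CS, c_s, p.K, p.mu)
           - p.delta_S * c_s
           - p.gamma_R_tilde * p.alpha_CS * c_s)
    return np.array([dn, dc, dcr, dcs])


def treated_rhs(state, p: GrowthParams, dp: DrugEffectParams,
                doses: DosePair) -> np.ndarray:
    """Drug-treated derivatives: :func:`growth_rhs` minus Emax/Hill kill
    terms on C_R and C_S. N and C equations are unchanged — the drugs act
    only on the differentiated subclones."""
    if isinstance(state, CellState):
        c_r, c_s = state.c_r, state.c_s
    else:
        c_r, c_s = float(state[2]), float(state[3])
    out = growth_rhs(state, p)
    k_r, k_s = dp.kill_rates(doses)
    out[2] -= k_r * c_r
    out[3] -= k_s * c_s
    return out
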