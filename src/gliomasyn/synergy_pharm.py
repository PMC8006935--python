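"""Dose-grid simulation, Bliss-independence synergy surfaces and the
pharmacology summary statistics (IC50 extraction, selectivity index,
combination index, fold change, growth/inhibition conversions).

Sign convention for synergy scores: scores are differences on the growth
(viability) scale, ``observed - Bliss-expected`` relative growth in
percentage points, so **negative scores mean synergy** (more kill than the
independence expectation) and positive scores antagonism. This is the
opposite of the common inhibition-scale convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .model_core import (
    CellState,
    DosePair,
    DrugEffectParams,
    GrowthParams,
    TOXICITY_LIMIT_ACRIDONE_UM,
    TOXICITY_LIMIT_TMZ_UM,
    hill_kill_term,
)
from .simulate import IntegrationError, _parse_horizon, fast_endpoint

__all__ = [
    "DoseGrid",
    "DoseResponseMatrix",
    "SynergySurface",
    "PharmacologySummary",
    "growth_to_inhibition",
    "dose_response_matrix",
    "bliss_expected",
    "synergy_surface",
    "ic50_from_curve",
    "selectivity_index",
    "fold_change",
    "combination_index",
    "Ic50NotReachedError",
]


@dataclass(frozen=True)
class DoseGrid:
    """Dose levels for the two drugs; each axis includes 0 and stays within
    the toxicity bounds (TMZ <= 250 uM, acridone <= 100 uM)."""

    d1_levels: np.ndarray
    d2_levels: np.ndarray
    spacing: str = "linear"

    def __post_init__(self) -> None:
        object.__setattr__(self, "d1_levels",
                           np.asarray(self.d1_levels, dtype=float))
        object.__setattr__(self, "d2_levels",
                           np.asarray(self.d2_levels, dtype=float))
        for name, lv, cap in (("d1", self.d1_levels, TOXICITY_LIMIT_TMZ_UM),
                              ("d2", self.d2_levels, TOXICITY_LIMIT_ACRIDONE_UM)):
            if lv[0] != 0.0:
                raise ValueError(f"{name} levels must start at 0")
            if np.any(np.diff(lv) <= 0):
                raise ValueError(f"{name} levels must be strictly increasing")
            if lv[-1] > cap:
                raise ValueError(f"{name} levels exceed the toxicity bound {cap}")

    @property
    def shape(self) -> tuple:
        return self.d1_levels.size, self.d2_levels.size

    @classmethod
    def default(cls, acridone: str = "AC26", n: int = 100) -> "DoseGrid":
        """100 linearly spaced levels per drug, including 0 (TMZ 0-200 uM,
        acridone range per compound)."""
        from .defaults import default_grid_range
        lo1, hi1 = default_grid_range("TMZ")
        lo2, hi2 = default_grid_range(acridone)
        return cls(np.linspace(lo1, hi1, n), np.linspace(lo2, hi2, n))


def _matrix_frame(grid: DoseGrid, values: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(values, index=grid.d1_levels, columns=grid.d2_levels)
    df.index.name = "d1_uM"
    df.columns.name = "d2_uM"
    return df


@dataclass
class DoseResponseMatrix:
    """Relative growth (%) of one compartment over a 2-D dose grid;
    rows follow d1 (TMZ), columns d2 (acridone); entry (0, 0) is 100."""

    grid: DoseGrid
    values: np.ndarray
    compartment: str
    acridone: str

    def to_csv(self, path) -> None:
        _matrix_frame(self.grid, self.values).to_csv(path, float_format="%.12g")

    @classmethod
    def read_csv(cls, path, compartment: str = "C_R",
                 acridone: str = "AC26") -> "DoseResponseMatrix":
        df = pd.read_csv(path, index_col=0)
        grid = DoseGrid(df.index.to_numpy(dtype=float),
                        df.columns.to_numpy(dtype=float))
        return cls(grid=grid, values=df.to_numpy(dtype=float),
                   compartment=compartment, acridone=acridone)


@dataclass
class SynergySurface:
    """Bliss synergy scores (percentage points; negative = synergy)."""

    grid: DoseGrid
    scores: np.ndarray
    compartment: str
    acridone: str

    def to_csv(self, path) -> None:
        _matrix_frame(self.grid, self.scores).to_csv(path, float_format="%.12g")

    def mean_interior_score(self) -> float:
        """Mean score over cells where both doses are positive."""
        return float(self.scores[1:, 1:].mean())


@dataclass(frozen=True)
class PharmacologySummary:
    ic50: Optional[float] = None
    cc50: Optional[float] = None
    selectivity_index: Optional[float] = None
    combination_index: Optional[float] = None
    fold_change: Optional[float] = None
    pct_fold_change: Optional[float] = None


def growth_to_inhibition(growth_pct):
    """Percent growth inhibition: ``100 - % cell growth``."""
    return 100.0 - np.asarray(growth_pct) if np.ndim(growth_pct) \
        else 100.0 - growth_pct


def dose_response_matrix(p: GrowthParams, dp: DrugEffectParams,
                         grid: DoseGrid, compartment: str = "C_R",
                         horizon="steady_state",
                         initial: Optional[CellState] = None,
                         t_max: float = 300.0) -> DoseResponseMatrix:
    """Relative growth (%) at every dose pair of the grid.

    The untreated control is the grid's own (0, 0) corner, so that entry is
    exactly 100. ``horizon`` is a fixed time in hours or ``"steady_state"``
    (integrated to the ``t_max`` cap; under default parameters the system
    settles well before it).
    """
    comp_idx = {"C_R": 2, "C_S": 3}.get(compartment)
    if comp_idx is None:
        raise ValueError("compartment must be 'C_R' or 'C_S'")
    if initial is None:
        from .defaults import default_initial_state
        initial = default_initial_state()
    mode, t_end = _parse_horizon(horizon, t_max)
    if mode == "steady_state":
        t_end = t_max

    n1, n2 = grid.shape
    values = np.empty((n1, n2))
    for i, d1 in enumerate(grid.d1_levels):
        for j, d2 in enumerate(grid.d2_levels):
            try:
                y = fast_endpoint(p, dp, DosePair(d1, d2), initial, t_end)
            except IntegrationError as err:
                raise IntegrationError(
                    f"dose pair (d1={d1}, d2={d2}) failed: {err}") from err
            values[i, j] = y[comp_idx]
    baseline = values[0, 0]
    if baseline <= 0:
        raise ZeroDivisionError("untreated baseline abundance is zero")
    # divide before scaling so the control corner is exactly 100.0
    values = 100.0 * (values / baseline)
    return DoseResponseMatrix(grid=grid, values=values,
                              compartment=compartment, acridone=dp.acridone)


def bliss_expected(y_a: float, y_b: float):
    """Bliss-independence expected fractional inhibition
    ``yA + yB - yA*yB`` for two non-interacting drugs."""
    y_a = np.asarray(y_a, dtype=float)
    y_b = np.asarray(y_b, dtype=float)
    if np.any(y_a < 0) or np.any(y_a > 1) or np.any(y_b < 0) or np.any(y_b > 1):
        raise ValueError("fractional inhibitions must lie in [0, 1]")
    out = y_a + y_b - y_a * y_b
    return float(out) if out.ndim == 0 else out


def synergy_surface(matrix: DoseResponseMatrix) -> SynergySurface:
    """Bliss synergy scores from a dose-response matrix.

    Monotherapy inhibitions come from the matrix margins (first column for
    drug 1, first row for drug 2); the score in each cell is observed
    relative growth minus the Bliss-expected growth, so any zero-dose margin
    scores exactly 0 and negative values mean synergy.
    """
    vals = matrix.values
    if vals[0, 0] != 100.0:
        raise ValueError("matrix must carry monotherapy margins "
                         "(entry (0,0) must be 100)")
    y_a = np.clip((100.0 - vals[:, 0]) / 100.0, 0.0, 1.0)
    y_b = np.clip((100.0 - vals[0, :]) / 100.0, 0.0, 1.0)
    expected_growth = 100.0 * (1.0 - bliss_expected(y_a[:, None], y_b[None, :]))
    scores = vals - expected_growth
    scores[0, :] = 0.0
    scores[:, 0] = 0.0
    return SynergySurface(grid=matrix.grid, scores=scores,
                          compartment=matrix.compartment,
                          acridone=matrix.acridone)


class Ic50NotReachedError(ValueError):
    """The growth curve never crosses 50%."""

    def __init__(self, max_inhibition: float):
        self.max_inhibition = max_inhibition
        super().__init__(
            f"response never reaches 50% growth inhibition "
            f"(max inhibition {max_inhibition:.3g}%)")


def ic50_from_curve(doses, growth_pct) -> float:
    """IC50 by log-dose linear interpolation at the growth = 50% crossing.

    Zero doses are excluded from the log axis; the first bracketing pair of
    adjacent points is used. Raises :class:`Ic50NotReachedError`, carrying
    the maximal observed inhibition, when the curve never crosses 50%.
    """
    doses = np.asarray(doses, dtype=float)
    growth = np.asarray(growth_pct, dtype=float)
    if doses.shape != growth.shape:
        raise ValueError("doses and growth_pct must have equal length")
    pos = doses > 0
    d, g = doses[pos], growth[pos]
    order = np.argsort(d)
    d, g = d[order], g[order]
    if d.size < 2:
        raise ValueError("need at least two positive doses")
    for i in range(d.size - 1):
        g0, g1 = g[i] - 50.0, g[i + 1] - 50.0
        if g0 == 0.0:
            return float(d[i])
        if g0 * g1 < 0:
            frac = g0 / (g0 - g1)
            return float(math.exp(
                math.log(d[i]) + frac * (math.log(d[i + 1]) - math.log(d[i]))))
    if g[-1] == 50.0:
        return float(d[-1])
    raise Ic50NotReachedError(float(np.max(100.0 - growth)))


def selectivity_index(cc50_vero: float, ic50_cancer: float) -> float:
    """Selectivity index ``CC50(normal) / IC50(cancer)``, reported to two
    decimals (round-half-even); higher means a wider therapeutic window."""
    if cc50_vero <= 0 or ic50_cancer <= 0:
        raise ValueError("CC50 and IC50 must be > 0")
    return round(cc50_vero / ic50_cancer, 2)


def fold_change(initial_ic50: float, final_ic50: float) -> tuple[float, float]:
    """(ratio, percent) change of an IC50 between monotherapy and
    combination: ratio ``final/initial``, percent ``|final - initial| /
    initial * 100`` (magnitude), both to two decimals."""
    if initial_ic50 <= 0 or final_ic50 <= 0:
        raise ValueError("IC50 values must be > 0")
    ratio = final_ic50 / initial_ic50
    pct = abs(final_ic50 - initial_ic50) / initial_ic50 * 100.0
    return round(ratio, 2), round(pct, 2)


#: Interpretation bands for the combination index.
CI_BANDS = ((0.8, "synergism"), (1.2, "additive"), (math.inf, "antagonism"))


def combination_index(d1_combo: float, d2_combo: float,
                      ic50_d1_alone: float, ic50_d2_alone: float
                      ) -> tuple[float, str]:
    """Combination index ``d1/IC50_1 + d2/IC50_2`` with its interpretation
    band (< 0.8 synergism, 0.8-1.2 additive, > 1.2 antagonism).

    Uses the mutually-nonexclusive Chou-Talalay form without the interaction
    term. A zero dose on one axis is permitted (single-agent degenerate
    case); the label then reflects the single drug's dose ratio.
    """
    if ic50_d1_alone <= 0 or ic50_d2_alone <= 0:
        raise ValueError("monotherapy IC50s must be > 0")
    if d1_combo < 0 or d2_combo < 0:
        raise ValueError("doses must be >= 0")
    ci = d1_combo / ic50_d1_alone + d2_combo / ic50_d2_alone
    for upper, label in CI_BANDS:
        if ci < upper or (label == "additive" and ci == upper):
            return ci, label
    return ci, "antagonism"  # pragma: no cover
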