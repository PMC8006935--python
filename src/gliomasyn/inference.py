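"""Bayesian estimation of growth parameters by DRAM MCMC.

The sampler is a single-chain Delayed-Rejection Adaptive-Metropolis:
a Gaussian random-walk Metropolis whose proposal covariance is adapted from
the chain history (scaled empirical covariance, ``2.38^2/d``, plus a small
jitter), with one delayed-rejection stage that retries a rejected move from
a shrunk proposal using the standard two-stage acceptance ratio. The
likelihood is Gaussian around the deterministic model trajectory with known
observation noise; priors are independent truncated normals over
biologically feasible ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import _fast
from .model_core import GrowthParams
from .synthetic_data import SyntheticGrowthDataset

__all__ = [
    "PriorSpec",
    "McmcChain",
    "log_likelihood",
    "make_log_posterior",
    "dram_sample",
    "run_dram",
    "chain_diagnostics",
    "posterior_predictive",
    "default_priors",
    "DEFAULT_FREE_PARAMS",
]

#: Parameters estimated by default: growth/death rates and transition
#: probabilities; K, mu and rho are held fixed. ``gamma_R`` implies
#: ``omega_S = 1 - gamma_R``.
DEFAULT_FREE_PARAMS = (
    "alpha_N", "delta_N", "alpha_C", "delta_C", "alpha_CR", "delta_R",
    "alpha_CS", "delta_S", "gamma_R", "gamma_R_tilde", "omega_S_tilde",
)

_COMP_IDX = {"N": 0, "C": 1, "C_R": 2, "C_S": 3}


@dataclass(frozen=True)
class PriorSpec:
    """Independent truncated-normal priors: per free parameter a (mean, sd)
    pair and hard [lo, hi] feasibility bounds."""

    names: tuple
    means: np.ndarray
    sds: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        d = len(self.names)
        for arr_name in ("means", "sds", "lower", "upper"):
            arr = np.asarray(getattr(self, arr_name), dtype=float)
            object.__setattr__(self, arr_name, arr)
            if arr.shape != (d,):
                raise ValueError(f"{arr_name} must have length {d}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{arr_name} must be finite")
        if np.any(self.sds <= 0):
            raise ValueError("prior sds must be > 0")
        if np.any(self.lower >= self.upper):
            raise ValueError("bounds must satisfy lo < hi")

    @classmethod
    def from_dict(cls, spec: Mapping[str, Mapping[str, float]]) -> "PriorSpec":
        names = tuple(spec)
        return cls(
            names=names,
            means=np.array([spec[n]["mean"] for n in names]),
            sds=np.array([spec[n]["sd"] for n in names]),
            lower=np.array([spec[n]["lo"] for n in names]),
            upper=np.array([spec[n]["hi"] for n in names]),
        )

    def log_density(self, theta: np.ndarray) -> float:
        if np.any(theta < self.lower) or np.any(theta > self.upper):
            return -math.inf
        z = (theta - self.means) / self.sds
        return float(-0.5 * np.sum(z * z))


def default_priors(free_params: Sequence[str] = DEFAULT_FREE_PARAMS,
                   base: Optional[GrowthParams] = None,
                   rel_sd: float = 0.25) -> PriorSpec:
    """Normal priors centred at the default parameter set with sd equal to
    ``rel_sd`` of the value, bounded to [0.2x, 5x] (probabilities capped
    at 1)."""
    if base is None:
        from .defaults import default_growth_params
        base = default_growth_params()
    g = base.to_dict()
    probs = {"gamma_R", "gamma_R_tilde", "omega_S_tilde", "rho", "omega_S"}
    means, sds, lo, hi = [], [], [], []
    for name in free_params:
        v = g[name]
        means.append(v)
        sds.append(rel_sd * v)
        lo.append(0.2 * v)
        hi.append(min(5.0 * v, 1.0) if name in probs else 5.0 * v)
    return PriorSpec(tuple(free_params), np.array(means), np.array(sds),
                     np.array(lo), np.array(hi))


def _theta_to_params(theta, free_names, base: GrowthParams) -> np.ndarray:
    """Full 15-vector in canonical order from a free-parameter vector."""
    from .model_core import GROWTH_PARAM_ORDER
    full = base.to_array()
    pos = {n: i for i, n in enumerate(GROWTH_PARAM_ORDER)}
    for name, v in zip(free_names, theta):
        full[pos[name]] = v
    if "gamma_R" in free_names and "omega_S" not in free_names:
        full[pos["omega_S"]] = 1.0 - full[pos["gamma_R"]]
    return full


def log_likelihood(theta, dataset: SyntheticGrowthDataset,
                   noise_sd=None,
                   free_names: Sequence[str] = DEFAULT_FREE_PARAMS,
                   base: Optional[GrowthParams] = None,
                   step_h: float = _fast.DEFAULT_STEP_H) -> float:
    """Gaussian log-likelihood of the observations given the trajectory at
    the observation times; ``-inf`` when the solver blows up (rejection
    signal for the sampler).

    ``noise_sd`` defaults to the dataset's recorded noise levels.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (len(free_names),):
        raise ValueError("theta length does not match free_names")
    base = base if base is not None else dataset.true_params
    full = _theta_to_params(theta, free_names, base)
    if np.any(~np.isfinite(full)):
        return -math.inf
    ok, traj = _fast.rk4_trajectory(
        full, 0.0, 0.0, dataset.initial_state.to_array(),
        np.ascontiguousarray(dataset.times, dtype=float), step_h)
    if not ok:
        return -math.inf
    if noise_sd is None:
        noise_sd = dataset.noise_sd
    total = 0.0
    for comp in dataset.observed_compartments:
        sd = noise_sd[comp] if isinstance(noise_sd, Mapping) else float(noise_sd)
        resid = dataset.observations[comp] - traj[:, _COMP_IDX[comp]]
        total += (-0.5 * np.sum((resid / sd) ** 2)
                  - resid.size * math.log(sd)
                  - 0.5 * resid.size * math.log(2.0 * math.pi))
    return float(total) if math.isfinite(total) else -math.inf


def make_log_posterior(dataset: SyntheticGrowthDataset, priors: PriorSpec,
                       noise_sd=None,
                       base: Optional[GrowthParams] = None) -> Callable:
    """Bind dataset and priors into a log-posterior callable; parameter
    vectors outside the prior bounds (which subsume parameter-validity
    constraints) score ``-inf`` without a solver call."""

    def log_post(theta):
        lp = priors.log_density(np.asarray(theta, dtype=float))
        if not math.isfinite(lp):
            return -math.inf
        return lp + log_likelihood(theta, dataset, noise_sd=noise_sd,
                                   free_names=priors.names, base=base)

    return log_post


@dataclass
class McmcChain:
    """Post-run chain: one sampled parameter vector per iteration."""

    samples: np.ndarray          # (n_iter, d)
    log_posterior: np.ndarray    # (n_iter,)
    acceptance_rate: float
    seed: Optional[int]
    n_iter: int
    param_names: tuple = ()

    def burned(self, frac: float = 0.25) -> np.ndarray:
        return self.samples[int(self.n_iter * frac):]

    def to_csv(self, path) -> None:
        cols = list(self.param_names) or [f"x{j}"
                                          for j in range(self.samples.shape[1])]
        df = pd.DataFrame(self.samples, columns=cols)
        df["log_posterior"] = self.log_posterior
        df.to_csv(path, index=False, float_format="%.12g")


def dram_sample(log_post: Callable, x0: np.ndarray, cov0: np.ndarray,
                n_iter: int, seed: Optional[int] = 0,
                adapt_start: int = 1000, adapt_interval: int = 100,
                dr_scale: float = 0.2, jitter: float = 1e-10,
                adapt: bool = True, delayed_rejection: bool = True,
                param_names: Sequence[str] = ()) -> McmcChain:
    """Core DRAM sampler over an arbitrary log-posterior.

    After ``adapt_start`` iterations the proposal covariance is refreshed
    every ``adapt_interval`` steps as ``2.38^2/d * cov(history) + jitter*I``.
    A first-stage rejection triggers one delayed-rejection stage proposing
    from the covariance shrunk by ``dr_scale`` with the two-stage acceptance
    ratio that preserves detailed balance. Bit-reproducible given ``seed``.
    """
    if n_iter < 1000:
        raise ValueError("n_iter must be >= 1000")
    x = np.asarray(x0, dtype=float).copy()
    d = x.size
    lp = float(log_post(x))
    if not math.isfinite(lp):
        raise ValueError("initial point has non-finite posterior")
    cov0 = np.asarray(cov0, dtype=float)
    chol = np.linalg.cholesky(cov0)
    inv = np.linalg.inv(cov0)
    rng = np.random.default_rng(seed)
    sd_opt = 2.38 ** 2 / d

    samples = np.empty((n_iter, d))
    logps = np.empty(n_iter)
    accepted = 0

    for i in range(n_iter):
        y1 = x + chol @ rng.standard_normal(d)
        lp1 = float(log_post(y1))
        log_a1 = min(0.0, lp1 - lp)
        if math.log(rng.random()) < log_a1:
            x, lp = y1, lp1
            accepted += 1
        elif delayed_rejection:
            y2 = x + dr_scale * (chol @ rng.standard_normal(d))
            lp2 = float(log_post(y2))
            if math.isfinite(lp2):
                # two-stage acceptance (symmetric stage-1 proposal):
                # a2 = [pi(y2) q1(y2->y1) (1-a1(y2,y1))] /
                #      [pi(x)  q1(x ->y1) (1-a1(x, y1))]
                d21 = y1 - y2
                d01 = y1 - x
                log_a1_rev = min(0.0, lp1 - lp2)
                num = lp2 - 0.5 * float(d21 @ inv @ d21) + _log1mexp(log_a1_rev)
                den = lp - 0.5 * float(d01 @ inv @ d01) + _log1mexp(log_a1)
                if math.log(rng.random()) < num - den:
                    x, lp = y2, lp2
                    accepted += 1
        samples[i] = x
        logps[i] = lp
        if adapt and i + 1 >= adapt_start and (i + 1) % adapt_interval == 0:
            emp = np.cov(samples[: i + 1].T)
            emp = np.atleast_2d(emp)
            prop = sd_opt * emp + jitter * np.eye(d)
            try:
                chol = np.linalg.cholesky(prop)
                inv = np.linalg.inv(prop)
            except np.linalg.LinAlgError:
                pass  # keep the previous proposal on a degenerate history
    rate = accepted / n_iter
    return McmcChain(samples=samples, log_posterior=logps,
                     acceptance_rate=rate, seed=seed, n_iter=n_iter,
                     param_names=tuple(param_names))


def _log1mexp(log_a: float) -> float:
    """log(1 - exp(log_a)) for log_a <= 0; -inf when log_a == 0."""
    if log_a >= 0.0:
        return -math.inf
    if log_a > -math.log(2.0):
        return math.log(-math.expm1(log_a))
    return math.log1p(-math.exp(log_a))


def run_dram(dataset: SyntheticGrowthDataset, priors: PriorSpec,
             n_iter: int = 20000, seed: Optional[int] = 0,
             adapt_start: int = 1000, adapt_interval: int = 100,
             dr_scale: float = 0.2, noise_sd=None,
             x0: Optional[np.ndarray] = None,
             base: Optional[GrowthParams] = None) -> McmcChain:
    """Fit the growth model to a growth-curve dataset with DRAM.

    Starts at the prior means by default with an initial proposal sd of a
    tenth of the prior sd per coordinate.
    """
    log_post = make_log_posterior(dataset, priors, noise_sd=noise_sd, base=base)
    x0 = priors.means.copy() if x0 is None else np.asarray(x0, dtype=float)
    cov0 = np.diag((0.1 * priors.sds) ** 2)
    return dram_sample(log_post, x0, cov0, n_iter=n_iter, seed=seed,
                       adapt_start=adapt_start, adapt_interval=adapt_interval,
                       dr_scale=dr_scale, param_names=priors.names)


def effective_sample_size(x: np.ndarray) -> float:
    """Univariate ESS via Geyer's initial positive sequence of autocovariance
    pair sums; returns NaN for a degenerate (constant) chain."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.ptp(x) == 0:
        return float("nan")
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1:] / n
    if acov[0] <= 0:
        return float("nan")
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n // 2):
        pair = rho[2 * k - 1] + rho[2 * k]
        if pair < 0:
            break
        s += pair
    tau = 1.0 + 2.0 * s
    return n / max(tau, 1.0)


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing the means of the first and last
    chain segments, with ESS-corrected variances."""
    x = np.asarray(x, dtype=float)
    a = x[: int(first * x.size)]
    b = x[-int(last * x.size):]
    va = np.var(a, ddof=1) / max(effective_sample_size(a), 1.0)
    vb = np.var(b, ddof=1) / max(effective_sample_size(b), 1.0)
    if not (math.isfinite(va) and math.isfinite(vb)) or va + vb == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / math.sqrt(va + vb))


def chain_diagnostics(chain: McmcChain) -> pd.DataFrame:
    """Per-parameter summary: mean, sd, 2.5/50/97.5 percentiles, ESS,
    Geweke z and a degeneracy flag (constant chain)."""
    if chain.samples.size == 0:
        raise ValueError("chain is empty")
    names = list(chain.param_names) or [f"x{j}"
                                        for j in range(chain.samples.shape[1])]
    rows = []
    for j, name in enumerate(names):
        x = chain.samples[:, j]
        ess = effective_sample_size(x)
        rows.append({
            "parameter": name,
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)),
            "q2.5": float(np.percentile(x, 2.5)),
            "q50": float(np.percentile(x, 50)),
            "q97.5": float(np.percentile(x, 97.5)),
            "ess": ess,
            "geweke_z": geweke_z(x),
            "degenerate": bool(not math.isfinite(ess)),
        })
    return pd.DataFrame(rows)


def posterior_predictive(chain: McmcChain, dataset: SyntheticGrowthDataset,
                         n_draws: int = 200,
                         base: Optional[GrowthParams] = None,
                         burn_frac: float = 0.25,
                         include_observation_noise: bool = True,
                         seed: Optional[int] = 0,
                         step_h: float = _fast.DEFAULT_STEP_H) -> dict:
    """Pointwise 2.5-97.5% predictive envelopes per observed compartment.

    Thins ``n_draws`` evenly from the post-burn-in chain, re-simulates each
    draw (adding Gaussian observation noise at the dataset's recorded level,
    so the envelope is predictive for data points, not just for the mean
    trajectory) and returns ``{compartment: (lo, median, hi)}`` arrays over
    the dataset's observation times.
    """
    kept = chain.burned(burn_frac)
    if n_draws > chain.n_iter:
        raise ValueError("n_draws exceeds chain length")
    idx = np.linspace(0, kept.shape[0] - 1, n_draws).astype(int)
    base = base if base is not None else dataset.true_params
    times = np.ascontiguousarray(dataset.times, dtype=float)
    y0 = dataset.initial_state.to_array()
    rng = np.random.default_rng(seed)
    trajs = {c: [] for c in dataset.observed_compartments}
    for theta in kept[idx]:
        full = _theta_to_params(theta, chain.param_names, base)
        ok, traj = _fast.rk4_trajectory(full, 0.0, 0.0, y0, times, step_h)
        if not ok:
            continue
        for c in dataset.observed_compartments:
            y = traj[:, _COMP_IDX[c]]
            if include_observation_noise:
                y = y + rng.normal(0.0, dataset.noise_sd[c], size=y.size)
            trajs[c].append(y)
    out = {}
    for c, rows in trajs.items():
        arr = np.asarray(rows)
        out[c] = (np.percentile(arr, 2.5, axis=0),
                  np.percentile(arr, 50, axis=0),
                  np.percentile(arr, 97.5, axis=0))
    return out
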