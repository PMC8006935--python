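"""Compiled fixed-step RK4 integrator for hot paths.

MCMC likelihood evaluations, LHS-PRCC sensitivity sweeps and 100x100 dose
grids each need thousands to hundreds of thousands of trajectory solves, so
those paths use this numba-jitted classical RK4 with a fixed sub-step
(default 0.1 h). Because the drugs are modelled as constant concentrations,
a treated system is the drug-free system plus constant per-capita kill
rates (k_r, k_s) on the two differentiated compartments, which keeps the
compiled kernel a single function. Accuracy against the adaptive reference
integrator is covered by the test suite.

Falls back to a pure-python implementation when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

#: Default sub-step for the fixed-step integrator (hours).
DEFAULT_STEP_H = 0.1

_OVERFLOW = 1e15


@njit(cache=True)
def _rhs4(y, th, k_r, k_s, out):
    n = y[0] if y[0] > 0.0 else 0.0
    c = y[1] if y[1] > 0.0 else 0.0
    cr = y[2] if y[2] > 0.0 else 0.0
    cs = y[3] if y[3] > 0.0 else 0.0
    a_n, d_n, rho, K, mu = th[0], th[1], th[2], th[3], th[4]
    a_c, d_c, g_r, w_s = th[5], th[6], th[7], th[8]
    a_cr, d_r, w_st = th[9], th[10], th[11]
    a_cs, d_s, g_rt = th[12], th[13], th[14]

    out[0] = a_n * n * (1.0 - rho) * (1.0 - n / K) - d_n * n - a_n * n * rho
    out[1] = (a_n * rho * n + a_c * c * np.log(K / (c + mu))
              - g_r * a_c * c - w_s * a_c * c - d_c * c)
    out[2] = (g_r * a_c * c + g_rt * a_cs * cs
              + a_cr * cr * np.log(K / (cr + mu))
              - d_r * cr - w_st * a_cr * cr - k_r * cr)
    out[3] = (w_st * a_cr * cr + w_s * a_c * c
              + a_cs * cs * np.log(K / (cs + mu))
              - d_s * cs - g_rt * a_cs * cs - k_s * cs)


@njit(cache=True)
def rk4_trajectory(theta, k_r, k_s, y0, t_obs, h_max):
    """Integrate the 4-compartment system through the times ``t_obs``.

    Parameters are the canonical 15-vector (``GROWTH_PARAM_ORDER``),
    ``k_r``/``k_s`` the constant per-capita kill rates on C_R/C_S.
    Returns ``(ok, out)`` where ``out[i]`` is the state at ``t_obs[i]``
    (``out[0] = y0``); ``ok`` is False on numerical blow-up.
    """
    m = t_obs.shape[0]
    out = np.empty((m, 4))
    y = y0.copy()
    k1 = np.empty(4)
    k2 = np.empty(4)
    k3 = np.empty(4)
    k4 = np.empty(4)
    ytmp = np.empty(4)
    out[0] = y
    for i in range(1, m):
        span = t_obs[i] - t_obs[i - 1]
        nsub = int(np.ceil(span / h_max))
        if nsub < 1:
            nsub = 1
        h = span / nsub
        for _ in range(nsub):
            _rhs4(y, theta, k_r, k_s, k1)
            for j in range(4):
                ytmp[j] = y[j] + 0.5 * h * k1[j]
            _rhs4(ytmp, theta, k_r, k_s, k2)
            for j in range(4):
                ytmp[j] = y[j] + 0.5 * h * k2[j]
            _rhs4(ytmp, theta, k_r, k_s, k3)
            for j in range(4):
                ytmp[j] = y[j] + h * k3[j]
            _rhs4(ytmp, theta, k_r, k_s, k4)
            for j in range(4):
                y[j] += h / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
                if y[j] < 0.0:
                    y[j] = 0.0
            for j in range(4):
                if not np.isfinite(y[j]) or y[j] > _OVERFLOW:
                    return False, out
        out[i] = y
    return True, out


@njit(cache=True)
def rk4_endpoint(theta, k_r, k_s, y0, t_end, h_max):
    """State at ``t_end`` starting from ``y0`` at t=0; ``(ok, y)``."""
    t_obs = np.empty(2)
    t_obs[0] = 0.0
    t_obs[1] = t_end
    ok, out = rk4_trajectory(theta, k_r, k_s, y0, t_obs, h_max)
    return ok, out[1]
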