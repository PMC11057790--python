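"""Variance-based global sensitivity analysis of the post-treatment model.

Total-effect Sobol indices S_T are estimated with the Saltelli sampling
scheme (two quasi-random base matrices A, B plus the k column-swapped
matrices AB_i) and the Jansen estimator

    S_Ti = E[(f(A) - f(AB_i))^2] / (2 Var f),

giving k + 2 model evaluations per base sample.  The default base size of
625 with the six post-treatment parameters (gs, fs, gd, kd, gamma_d, theta)
yields 625 * 8 = 5000 model evaluations.

The quantity of interest is the terminal total cell count of a spatially
uniform well (all parameters global and uniform, which makes diffusion
inert under no-flux boundaries, so the well reduces to the exact scalar
forward-Euler recurrence and thousands of evaluations are cheap).

This screening stage is what justifies treating gs as the only local
parameter: gs and the carrying capacity theta dominate the output variance.
Because theta's admissible calibration range is deliberately narrow, the
screening explores a widened theta range by default (``wide_theta=True``);
with the narrow range, theta's index collapses, which is precisely why the
narrow range is safe to use in calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc

from .calibration import ParameterBounds
from .model_core import DomainError

POST_PARAM_NAMES = ("gs", "fs", "gd", "kd", "gamma_d", "theta")

#: theta range used for the screening stage (wide, before the decision to
#: restrict it for calibration).
WIDE_THETA_RANGE = (9000.0, 90000.0)


@dataclass
class SensitivityResult:
    total_effect: dict[str, float]
    n_evaluations: int
    output_definition: str
    n_base: int
    wide_ci: bool = False

    def ranking(self) -> list[str]:
        """Parameter names sorted by decreasing total-effect index."""
        return sorted(self.total_effect, key=self.total_effect.get, reverse=True)


def _uniform_well_terminal_count(
    params: np.ndarray,
    n0_well: float = 7500.0,
    t_dox: float = 48.0,
    t_end: float = 963.0,
    dt: float = 1.0,
) -> np.ndarray:
    """Terminal total count of a spatially uniform well, vectorized over
    parameter sets (rows: gs, fs, gd, kd, gamma_d, theta)."""
    gs, fs, gd, kd, gamma_d, theta = (params[:, i] for i in range(6))
    ns = fs * n0_well
    nd = (1.0 - fs) * n0_well
    n_steps = int(round((t_end - t_dox) / dt))
    for k in range(n_steps):
        t = t_dox + k * dt
        crowding = 1.0 - (ns + nd) / theta
        rate_d = gd + kd * np.exp(-gamma_d * (t - t_dox)) - kd
        ns = np.maximum(ns + dt * gs * ns * crowding, 0.0)
        nd = np.maximum(nd + dt * rate_d * nd * crowding, 0.0)
    return ns + nd


def jansen_total_effect(
    func,
    lower: np.ndarray,
    upper: np.ndarray,
    n_base: int,
    rng_seed: int = 0,
) -> tuple[np.ndarray, int]:
    """Saltelli-sampled Jansen total-effect estimates for a vectorized model.

    ``func`` maps an (n, k) parameter matrix to an (n,) output vector.
    Returns (S_T per factor, total evaluation count).
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    k = len(lower)
    sampler = qmc.Sobol(d=2 * k, scramble=True, seed=rng_seed)
    with warnings.catch_warnings():
        # scrambled Sobol tolerates non-power-of-2 sizes; the budget is fixed
        # by the evaluation count, not by balance properties
        warnings.simplefilter("ignore", UserWarning)
        base = sampler.random(n_base)
    a = lower + base[:, :k] * (upper - lower)
    b = lower + base[:, k:] * (upper - lower)
    blocks = [a, b]
    for i in range(k):
        ab = a.copy()
        ab[:, i] = b[:, i]
        blocks.append(ab)
    f_all = func(np.vstack(blocks))
    f_a = f_all[:n_base]
    f_b = f_all[n_base : 2 * n_base]
    var = np.var(np.concatenate([f_a, f_b]))
    st = np.empty(k)
    for i in range(k):
        f_ab = f_all[(2 + i) * n_base : (3 + i) * n_base]
        st[i] = np.mean((f_a - f_ab) ** 2) / (2.0 * var) if var > 0 else 0.0
    return st, n_base * (k + 2)


def total_effect_indices(
    bounds: ParameterBounds | None = None,
    n_base: int = 625,
    rng_seed: int = 0,
    wide_theta: bool = True,
    t_end: float = 963.0,
    theta_range: tuple[float, float] | None = None,
) -> SensitivityResult:
    """Total-effect Sobol indices of the post-treatment parameters.

    All parameters are set global and spatially uniform and sampled within
    their admissible ranges; the scalar output is the terminal total well
    count at ``t_end``.  ``wide_theta`` widens theta's range for the
    screening stage (see module docstring); an explicit ``theta_range``
    overrides both.
    """
    if n_base < 64:
        raise DomainError("n_base must be >= 64")
    bounds = bounds or ParameterBounds()
    if theta_range is None:
        theta_range = WIDE_THETA_RANGE if wide_theta else bounds.theta
    lower = np.array([
        bounds.gs[0], bounds.fs[0], bounds.gd[0],
        bounds.kd[0], bounds.gamma_d[0], theta_range[0],
    ])
    upper = np.array([
        bounds.gs[1], bounds.fs[1], bounds.gd[1],
        bounds.kd[1], bounds.gamma_d[1], theta_range[1],
    ])
    st, n_eval = jansen_total_effect(
        lambda p: _uniform_well_terminal_count(p, t_end=t_end),
        lower, upper, n_base, rng_seed,
    )
    return SensitivityResult(
        total_effect=dict(zip(POST_PARAM_NAMES, (float(v) for v in st))),
        n_evaluations=n_eval,
        output_definition=f"terminal total well cell count at t={t_end} h",
        n_base=n_base,
        wide_ci=n_base < 256,
    )
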