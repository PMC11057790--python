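"""Model calibration: bounded least squares plus residual bootstrap.

The fit proceeds in two stages, mirroring the experiment's two phases:

1. Pre-treatment: the global exponential growth rate g0 and diffusion
   coefficient D0 are fitted jointly to all pixel time courses before the
   treatment time.  D0 is then frozen for the post-treatment phase (all cell
   classes are assumed to diffuse alike).
2. Post-treatment: the surviving proliferation rate gs is local (one value
   per pixel, the only local parameter) while fs, kd, gd, gamma_d and theta
   are global; theta is restricted to a narrow admissible range.  The
   objective is the concatenated (model - data) misfit of the observable
   total density Ntot over every pixel and post-treatment timepoint, solved
   with scipy's trust-region reflective bounded least squares on variables
   rescaled to the unit cube.

Calibration precision is quantified by a residual bootstrap: the pooled
residual standard deviation defines a Gaussian noise model, synthetic
datasets are drawn around the fitted model curve and refitted, and the
resulting parameter distributions are summarized by mean, interquartile
range and normalized standard deviation (NSD = sd/mean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .model_core import (
    DensityMap,
    DomainError,
    GridSpec,
    PretreatmentParams,
    SolverConfig,
    TreatmentParams,
    integrate_post,
    integrate_pre,
)
from .metrics_io import FitMetrics, ccc_pixel
from .synthetic_data import WellSeries

GLOBAL_PARAM_NAMES = ("fs", "kd", "gd", "gamma_d", "theta")


@dataclass(frozen=True)
class ParameterBounds:
    """Admissible parameter ranges (lower, upper)."""

    g0: tuple[float, float] = (0.02, 0.035)
    d0: tuple[float, float] = (0.0, 0.005)
    gs: tuple[float, float] = (0.0001, 0.035)
    fs: tuple[float, float] = (0.0, 1.0)
    kd: tuple[float, float] = (0.0001, 0.01)
    gd: tuple[float, float] = (0.001, 0.05)
    gamma_d: tuple[float, float] = (1.0 / 120.0, 1.0 / 10.0)
    theta: tuple[float, float] = (88000.0, 90000.0)

    def __post_init__(self) -> None:
        for name in ("g0", "d0", "gs", "fs", "kd", "gd", "gamma_d", "theta"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise DomainError(f"bounds for {name}: lower must be < upper")

    def clip(self, name: str, value):
        lo, hi = getattr(self, name)
        return np.clip(value, lo, hi)


class InsufficientDataError(ValueError):
    """Too few timepoints for the requested calibration stage."""


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass
class PretreatmentFit:
    params: PretreatmentParams
    residuals: np.ndarray
    converged: bool
    n_iter: int
    at_bounds: bool = False


@dataclass
class CalibrationResult:
    """Fitted parameters, misfit and agreement metrics for one well."""

    pre: PretreatmentParams
    post: TreatmentParams
    residuals: np.ndarray
    ccc_well: float
    ccc_pixel: float
    converged: bool
    n_iter: int
    cost: float = 0.0
    gs_fixed_mask: np.ndarray | None = None
    times: np.ndarray | None = None          # post-treatment data times used
    model_stack: np.ndarray | None = None    # fitted Ntot at those times
    data_stack: np.ndarray | None = None
    ic_map: DensityMap | None = None
    bounds: ParameterBounds | None = None
    cfg: SolverConfig | None = None


@dataclass
class BootstrapDistribution:
    """Bootstrap parameter samples and their summary statistics.

    ``samples['gs']`` holds full gs grids of shape (n_boot, n_rows, n_cols);
    scalar summaries of gs use the per-sample pixel mean.
    """

    samples: dict[str, np.ndarray]
    n_boot: int

    def _scalar(self, name: str) -> np.ndarray:
        s = self.samples[name]
        return s.reshape(s.shape[0], -1).mean(axis=1) if s.ndim > 1 else s

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(self.samples)

    def mean(self) -> dict[str, float]:
        return {k: float(self._scalar(k).mean()) for k in self.samples}

    def iqr(self) -> dict[str, float]:
        return {
            k: float(np.subtract(*np.percentile(self._scalar(k), [75, 25])))
            for k in self.samples
        }

    def nsd(self) -> dict[str, float]:
        """Normalized standard deviation (sd/mean) per parameter."""
        out = {}
        for k in self.samples:
            s = self._scalar(k)
            m = s.mean()
            out[k] = float(s.std() / abs(m)) if m != 0 else math.inf
        return out


# ---------------------------------------------------------------------------
# Parameter vector packing (natural units)
# ---------------------------------------------------------------------------


def pack_treatment(post: TreatmentParams, grid: GridSpec) -> np.ndarray:
    """Flatten to [gs (row-major, n_pixels), fs, kd, gd, gamma_d, theta]."""
    gs = np.broadcast_to(np.asarray(post.gs, dtype=float), grid.shape).ravel()
    tail = [float(np.mean(getattr(post, n))) for n in GLOBAL_PARAM_NAMES]
    return np.concatenate([gs, tail])


def unpack_treatment(
    flat: np.ndarray, grid: GridSpec, d0: float
) -> TreatmentParams:
    n_px = grid.n_pixels
    if len(flat) != n_px + len(GLOBAL_PARAM_NAMES):
        raise DomainError(f"parameter vector length {len(flat)} != {n_px + 5}")
    gs = np.asarray(flat[:n_px], dtype=float).reshape(grid.shape)
    fs, kd, gd, gamma_d, theta = (float(v) for v in flat[n_px:])
    return TreatmentParams(
        gs=gs, fs=fs, kd=kd, gd=gd, gamma_d=gamma_d, theta=theta, ds=d0, dd=d0
    )


# ---------------------------------------------------------------------------
# Pre-treatment calibration
# ---------------------------------------------------------------------------


def _pre_maps(series: WellSeries) -> list[DensityMap]:
    return [m for m in series.maps if m.time <= series.t_dox + 1e-9]


def calibrate_pretreatment(
    series: WellSeries,
    bounds: ParameterBounds | None = None,
    cfg: SolverConfig | None = None,
) -> PretreatmentFit:
    """Fit (g0, D0) to all pre-treatment pixel time courses jointly."""
    bounds = bounds or ParameterBounds()
    cfg = cfg or SolverConfig(t_dox=series.t_dox)
    pre_maps = _pre_maps(series)
    if len(pre_maps) < 3:
        raise InsufficientDataError(
            f"pre-treatment calibration needs >= 3 timepoints, got {len(pre_maps)}"
        )
    grid = series.grid
    ic = pre_maps[0]
    times = [m.time for m in pre_maps[1:]]
    data = np.stack([m.values for m in pre_maps[1:]])
    lo = np.array([bounds.g0[0], bounds.d0[0]])
    hi = np.array([bounds.g0[1], bounds.d0[1]])

    def residuals_z(z: np.ndarray) -> np.ndarray:
        g0, d0 = lo + z * (hi - lo)
        p = PretreatmentParams(g0=g0, d0=d0)
        _, stack = integrate_pre(ic.values, p, cfg, grid, ic.time, times)
        return (stack - data).ravel()

    res = least_squares(
        residuals_z, np.array([0.5, 0.5]), bounds=(0.0, 1.0),
        method="trf", ftol=1e-10, xtol=1e-10, gtol=1e-10, diff_step=1e-6,
    )
    g0, d0 = lo + res.x * (hi - lo)
    at_bounds = bool(np.any(res.x < 1e-6) or np.any(res.x > 1 - 1e-6))
    return PretreatmentFit(
        params=PretreatmentParams(g0=float(g0), d0=float(d0)),
        residuals=res.fun,
        converged=res.status > 0,
        n_iter=res.nfev,
        at_bounds=at_bounds,
    )


# ---------------------------------------------------------------------------
# Post-treatment objective and calibration
# ---------------------------------------------------------------------------


def _post_window(
    series: WellSeries, t_max: float | None
) -> tuple[DensityMap, np.ndarray, np.ndarray]:
    """Initial-condition map (at t_dox) and the post-treatment data window."""
    t_dox = series.t_dox
    times_all = series.times
    i_dox = int(np.argmin(np.abs(times_all - t_dox)))
    ic = series.maps[i_dox]
    sel = times_all > times_all[i_dox]
    if t_max is not None:
        sel &= times_all <= t_max + 1e-9
    idx = np.flatnonzero(sel)
    if len(idx) == 0:
        raise InsufficientDataError("no post-treatment timepoints in window")
    times = times_all[idx]
    data = np.stack([series.maps[i].values for i in idx])
    return ic, times, data


def objective_residuals(
    params_flat: np.ndarray,
    series: WellSeries,
    frozen: PretreatmentParams,
    cfg: SolverConfig | None = None,
    t_max: float | None = None,
) -> np.ndarray:
    """Concatenated (model - data) over every pixel and post-treatment time.

    ``params_flat`` is the natural-units vector of
    :func:`pack_treatment`; diffusion is frozen at the pre-treatment D0.
    """
    cfg = cfg or SolverConfig(t_dox=series.t_dox)
    grid = series.grid
    post = unpack_treatment(np.asarray(params_flat, dtype=float), grid, frozen.d0)
    ic, times, data = _post_window(series, t_max)
    fs = np.asarray(post.fs, dtype=float)
    ns0 = fs * ic.values
    nd0 = ic.values - ns0
    _, ns, nd = integrate_post(ns0, nd0, post, cfg, grid, ic.time, times)
    return ((ns + nd) - data).ravel()


def calibrate_posttreatment(
    series: WellSeries,
    bounds: ParameterBounds | None = None,
    frozen: PretreatmentParams | None = None,
    cfg: SolverConfig | None = None,
    t_max: float | None = None,
    x0: TreatmentParams | None = None,
    max_nfev: int | None = None,
) -> CalibrationResult:
    """Bounded least squares over local gs plus global (fs, kd, gd,
    gamma_d, theta).

    Pixels whose data course is identically zero get gs fixed at its lower
    bound and are excluded from the optimization (and later from CCC_pixel
    averaging, where their score is undefined anyway).
    """
    bounds = bounds or ParameterBounds()
    if frozen is None:
        frozen = calibrate_pretreatment(series, bounds).params
    cfg = cfg or SolverConfig(t_dox=series.t_dox)
    grid = series.grid
    n_px = grid.n_pixels
    ic, times, data = _post_window(series, t_max)

    zero_mask = np.all(data == 0, axis=0) & (ic.values == 0)  # (r, c)
    free_px = np.flatnonzero(~zero_mask.ravel())

    # natural-unit bounds per vector entry
    lo_full = np.concatenate([
        np.full(n_px, bounds.gs[0]),
        [getattr(bounds, n)[0] for n in GLOBAL_PARAM_NAMES],
    ])
    hi_full = np.concatenate([
        np.full(n_px, bounds.gs[1]),
        [getattr(bounds, n)[1] for n in GLOBAL_PARAM_NAMES],
    ])
    free_idx = np.concatenate([free_px, n_px + np.arange(len(GLOBAL_PARAM_NAMES))])

    # initial guess: pre-treatment g0 for gs, bound midpoints for globals
    if x0 is not None:
        full0 = pack_treatment(x0, grid)
    else:
        full0 = np.concatenate([
            np.full(n_px, np.clip(frozen.g0, *bounds.gs)),
            [(getattr(bounds, n)[0] + getattr(bounds, n)[1]) / 2 for n in GLOBAL_PARAM_NAMES],
        ])
    full0 = np.clip(full0, lo_full, hi_full)

    base = np.array(full0)
    base[:n_px][zero_mask.ravel()] = bounds.gs[0]
    lo, hi = lo_full[free_idx], hi_full[free_idx]
    span = hi - lo

    def residuals_z(z: np.ndarray) -> np.ndarray:
        flat = base.copy()
        flat[free_idx] = lo + z * span
        return objective_residuals(flat, series, frozen, cfg, t_max)

    z0 = np.clip((full0[free_idx] - lo) / span, 0.0, 1.0)
    res = least_squares(
        residuals_z, z0, bounds=(0.0, 1.0), method="trf",
        ftol=1e-8, xtol=1e-8, gtol=1e-8, diff_step=1e-6,
        max_nfev=max_nfev,
    )
    flat = base.copy()
    flat[free_idx] = lo + res.x * span
    post = unpack_treatment(flat, grid, frozen.d0)

    fs = float(np.mean(post.fs))
    ns0 = fs * ic.values
    nd0 = ic.values - ns0
    _, ns, nd = integrate_post(ns0, nd0, post, cfg, grid, ic.time, times)
    model_stack = ns + nd

    model_series = WellSeries(
        maps=[DensityMap(model_stack[i], float(times[i]), grid) for i in range(len(times))],
        dose=series.dose, t_dox=series.t_dox, replicate_id=series.replicate_id,
    )
    data_series = WellSeries(
        maps=[DensityMap(data[i], float(times[i]), grid) for i in range(len(times))],
        dose=series.dose, t_dox=series.t_dox, replicate_id=series.replicate_id,
    )
    metrics: FitMetrics = ccc_pixel(model_series, data_series)

    return CalibrationResult(
        pre=frozen,
        post=post,
        residuals=res.fun,
        ccc_well=metrics.ccc_well,
        ccc_pixel=metrics.ccc_pixel,
        converged=res.status > 0,
        n_iter=res.nfev,
        cost=float(res.cost),
        gs_fixed_mask=zero_mask,
        times=times,
        model_stack=model_stack,
        data_stack=data,
        ic_map=ic,
        bounds=bounds,
        cfg=cfg,
    )


# ---------------------------------------------------------------------------
# Residual bootstrap
# ---------------------------------------------------------------------------


def bootstrap_calibration(
    series: WellSeries,
    result: CalibrationResult,
    n_boot: int = 100,
    rng_seed: int | np.random.Generator = 0,
    max_nfev: int | None = 60,
    warm_start: bool = False,
) -> BootstrapDistribution:
    """Residual-resampling bootstrap around a converged calibration.

    The pooled residual sd defines an i.i.d. Gaussian noise model; each
    bootstrap dataset is the fitted model curve plus fresh noise, refitted
    with the same initial guesses as the original calibration (so weakly
    identified parameters express their full spread; ``warm_start`` instead
    restarts from the fitted point, faster but spread-collapsing).
    """
    if n_boot < 2:
        raise DomainError("n_boot must be >= 2")
    if not result.converged:
        raise DomainError("bootstrap requires a converged calibration")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    grid = series.grid
    sigma = float(np.std(result.residuals))
    times = result.times
    samples: dict[str, list] = {n: [] for n in ("gs",) + GLOBAL_PARAM_NAMES}

    for _ in range(n_boot):
        if sigma == 0.0:
            fit_post = result.post
        else:
            noisy = np.maximum(
                result.model_stack + rng.normal(0.0, sigma, result.model_stack.shape),
                0.0,
            )
            boot_maps = [result.ic_map] + [
                DensityMap(noisy[i], float(times[i]), grid) for i in range(len(times))
            ]
            boot_series = WellSeries(
                maps=boot_maps, dose=series.dose, t_dox=series.t_dox,
                replicate_id=series.replicate_id,
            )
            fit = calibrate_posttreatment(
                boot_series, result.bounds, result.pre, result.cfg,
                x0=result.post if warm_start else None, max_nfev=max_nfev,
            )
            fit_post = fit.post
        samples["gs"].append(np.broadcast_to(np.asarray(fit_post.gs, float), grid.shape).copy())
        for n in GLOBAL_PARAM_NAMES:
            samples[n].append(float(np.mean(getattr(fit_post, n))))

    return BootstrapDistribution(
        samples={k: np.asarray(v) for k, v in samples.items()},
        n_boot=n_boot,
    )
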