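"""Two-phenotype reaction-diffusion model of treated cell colonies.

Pre-treatment, the colony grows exponentially with diffusion:

    dN/dt = D0 * Laplacian(N) + g0 * N

At the treatment time ``t_dox`` the population is split into a surviving
fraction ``fs`` and an irreversibly damaged fraction ``1 - fs``.  Afterwards
the two subpopulations obey logistic reaction-diffusion dynamics,

    dNs/dt = D * Laplacian(Ns) + gs * Ns * (1 - Ntot / theta)
    dNd/dt = D * Laplacian(Nd)
             + [gd + kd * exp(-gamma_d * (t - t_dox)) - kd]
               * Nd * (1 - Ntot / theta)

with ``Ntot = Ns + Nd``.  The damaged net per-capita rate starts at ``gd``
(brief post-treatment growth) and decays with rate ``gamma_d`` towards
``gd - kd`` (drug-induced death).  All three cell classes share one diffusion
coefficient, fixed from the pre-treatment phase.

The PDEs are solved on the density-map pixel grid with a fully explicit
forward-Euler scheme (default step 1 h), 5-point central differences and
zero-flux (mirrored ghost node) boundaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger("tumorcast")

# CFL limit for the 2D explicit diffusion stencil.
CFL_LIMIT = 0.25

MM_PER_UM = 1e-3


class StabilityError(RuntimeError):
    """Explicit-scheme CFL condition violated."""


class DomainError(ValueError):
    """Argument outside its physical/model domain."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the density-map pixel grid.

    Defaults: a 6450 um field of view binned at 430 um, i.e. 15 x 15 pixels.
    """

    n_rows: int = 15
    n_cols: int = 15
    pixel_size_um: float = 430.0
    field_of_view_um: float = 6450.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise DomainError("grid must have at least one pixel per side")
        if self.pixel_size_um <= 0:
            raise DomainError("pixel_size_um must be positive")
        if abs(self.n_rows * self.pixel_size_um - self.field_of_view_um) > 0.5 * self.pixel_size_um:
            raise DomainError(
                f"n_rows*pixel_size ({self.n_rows * self.pixel_size_um}) does not "
                f"match field_of_view ({self.field_of_view_um})"
            )

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def pixel_size_mm(self) -> float:
        return self.pixel_size_um * MM_PER_UM

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)


@dataclass
class DensityMap:
    """Cell counts per pixel at one timepoint (row-major, origin top-left)."""

    values: np.ndarray
    time: float
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise DomainError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise DomainError("density map contains non-finite values")
        if np.any(self.values < 0):
            raise DomainError("density map contains negative counts")

    @property
    def total(self) -> float:
        """Total cell count over the well."""
        return float(self.values.sum())


@dataclass
class PretreatmentParams:
    """Exponential growth rate g0 (1/h) and diffusion D0 (mm^2/h)."""

    g0: float = 0.0275
    d0: float = 0.003


@dataclass
class TreatmentParams:
    """Post-treatment parameters.

    ``gs`` may be a scalar or an (n_rows, n_cols) field; the remaining
    parameters are scalar during calibration but may also be per-pixel fields
    during prediction (the forecasting stage lets all six vary pixelwise).
    ``theta`` is the well-level carrying capacity (cells per well).
    Diffusion ``ds``/``dd`` default to the pre-treatment D0.
    """

    gs: float | np.ndarray = 0.02
    fs: float | np.ndarray = 0.5
    gd: float | np.ndarray = 0.02
    kd: float | np.ndarray = 0.005
    gamma_d: float | np.ndarray = 0.03
    theta: float | np.ndarray = 89000.0
    ds: float = 0.003
    dd: float = 0.003


@dataclass
class TwoPopState:
    """Surviving and damaged density maps at one time."""

    ns: DensityMap
    nd: DensityMap
    time: float

    @property
    def ntot(self) -> np.ndarray:
        """Total density map values, Ns + Nd elementwise."""
        return self.ns.values + self.nd.values

    @property
    def total(self) -> float:
        return float(self.ntot.sum())


@dataclass
class SolverConfig:
    """Explicit solver settings.

    theta_scope: "well" divides theta by the pixel count so the logistic
    crowding term acts per pixel against a well-level capacity; "pixel" uses
    theta directly in every pixel.
    """

    dt: float = 1.0
    t_dox: float = 48.0
    clip_negative: bool = True
    theta_scope: str = "well"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise DomainError("dt must be positive")
        if self.theta_scope not in ("well", "pixel"):
            raise DomainError("theta_scope must be 'well' or 'pixel'")


@dataclass(frozen=True)
class StabilityDiagnostic:
    cfl: float
    ok: bool
    limit: float = CFL_LIMIT


# ---------------------------------------------------------------------------
# Spatial operator
# ---------------------------------------------------------------------------


def laplacian_noflux(values: np.ndarray, pixel_size: float) -> np.ndarray:
    """5-point discrete Laplacian with zero-flux (mirrored ghost) boundaries.

    ``pixel_size`` sets the length unit of the result (counts / length^2).
    The operator conserves mass: the returned grid sums to zero.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise DomainError("non-finite input to laplacian")
    if pixel_size <= 0:
        raise DomainError("pixel_size must be positive")
    padded = np.pad(values, 1, mode="edge")
    lap = (
        padded[:-2, 1:-1]
        + padded[2:, 1:-1]
        + padded[1:-1, :-2]
        + padded[1:-1, 2:]
        - 4.0 * values
    )
    return lap / (pixel_size * pixel_size)


def check_stability(
    diffusion: float, cfg: SolverConfig, grid: GridSpec
) -> StabilityDiagnostic:
    """CFL number D*dt/dx^2 for the explicit scheme, checked against 0.25."""
    dx = grid.pixel_size_mm
    cfl = float(diffusion) * cfg.dt / (dx * dx)
    return StabilityDiagnostic(cfl=cfl, ok=cfl <= CFL_LIMIT)


def _require_stable(diffusion: float, cfg: SolverConfig, grid: GridSpec) -> None:
    diag = check_stability(diffusion, cfg, grid)
    if not diag.ok:
        raise StabilityError(
            f"CFL number {diag.cfl:.4g} exceeds {CFL_LIMIT} "
            f"(D={diffusion}, dt={cfg.dt}, dx={grid.pixel_size_mm} mm)"
        )


# ---------------------------------------------------------------------------
# Time stepping
# ---------------------------------------------------------------------------


def _clip(values: np.ndarray, cfg: SolverConfig) -> np.ndarray:
    if cfg.clip_negative:
        neg = values < 0
        if np.any(neg):
            logger.debug("clipping %d negative pixels to 0", int(neg.sum()))
            values = np.where(neg, 0.0, values)
    return values


def step_pretreatment(
    n: DensityMap, p: PretreatmentParams, cfg: SolverConfig
) -> DensityMap:
    """One forward-Euler step of the pre-treatment exponential model."""
    _require_stable(p.d0, cfg, n.grid)
    lap = laplacian_noflux(n.values, n.grid.pixel_size_mm)
    new = n.values + cfg.dt * (p.d0 * lap + p.g0 * n.values)
    return DensityMap(_clip(new, cfg), n.time + cfg.dt, n.grid)


def split_population(n: DensityMap, fs: float | np.ndarray) -> TwoPopState:
    """Split the total population into surviving/damaged at treatment time."""
    fs_arr = np.asarray(fs, dtype=float)
    if np.any(fs_arr < 0) or np.any(fs_arr > 1):
        raise DomainError(f"fs={fs} outside [0, 1]")
    # compute the larger share by multiplication and the smaller one as the
    # complement: the subtraction is then exact (Sterbenz), so Ns + Nd == N
    # holds bitwise for every fs
    ns_direct = fs_arr * n.values
    nd_direct = (1.0 - fs_arr) * n.values
    big_is_ns = fs_arr >= 0.5
    ns = np.where(big_is_ns, ns_direct, n.values - nd_direct)
    nd = np.where(big_is_ns, n.values - ns_direct, nd_direct)
    return TwoPopState(
        ns=DensityMap(ns, n.time, n.grid),
        nd=DensityMap(nd, n.time, n.grid),
        time=n.time,
    )


def damaged_net_rate(
    t: float, p: TreatmentParams, t_dox: float
) -> float | np.ndarray:
    """Net per-capita rate of the damaged population at time t.

    gd + kd*exp(-gamma_d*(t - t_dox)) - kd: equals gd at t_dox and decays
    towards gd - kd, the delayed drug-induced death.
    """
    if t < t_dox:
        raise DomainError(f"t={t} before treatment time {t_dox}")
    rate = p.gd + p.kd * np.exp(-p.gamma_d * (t - t_dox)) - p.kd
    return rate if isinstance(rate, np.ndarray) else float(rate)


def _theta_pixel(p: TreatmentParams, cfg: SolverConfig, grid: GridSpec):
    if cfg.theta_scope == "well":
        return np.asarray(p.theta, dtype=float) / grid.n_pixels
    return np.asarray(p.theta, dtype=float)


def step_posttreatment(
    s: TwoPopState, p: TreatmentParams, cfg: SolverConfig
) -> TwoPopState:
    """One forward-Euler step of the coupled surviving/damaged system."""
    grid = s.ns.grid
    _require_stable(max(float(np.max(p.ds)), float(np.max(p.dd))), cfg, grid)
    if s.time < cfg.t_dox:
        raise DomainError(f"post-treatment step at t={s.time} < t_dox={cfg.t_dox}")
    ns, nd = s.ns.values, s.nd.values
    ntot = ns + nd
    crowding = 1.0 - ntot / _theta_pixel(p, cfg, grid)
    dx = grid.pixel_size_mm
    rate_d = damaged_net_rate(s.time, p, cfg.t_dox)
    ns_new = ns + cfg.dt * (p.ds * laplacian_noflux(ns, dx) + p.gs * ns * crowding)
    nd_new = nd + cfg.dt * (p.dd * laplacian_noflux(nd, dx) + rate_d * nd * crowding)
    t_new = s.time + cfg.dt
    return TwoPopState(
        ns=DensityMap(_clip(ns_new, cfg), t_new, grid),
        nd=DensityMap(_clip(nd_new, cfg), t_new, grid),
        time=t_new,
    )


# ---------------------------------------------------------------------------
# Full-well simulation
# ---------------------------------------------------------------------------


def snap_to_step(t: float, dt: float) -> int:
    """Index of the internal Euler step nearest to time t."""
    return int(round(t / dt))


try:  # numba accelerates the inner Euler loops; a numpy path covers its absence
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f
        return deco(args[0]) if args and callable(args[0]) else deco


@_njit(cache=True)
def _pre_kernel(n, g0, d0, dx2, dt, k0, record_steps, clip, out):  # pragma: no cover
    nr, nc = n.shape
    n_rec = record_steps.size
    k_end = k0
    for i in range(n_rec):
        if record_steps[i] > k_end:
            k_end = record_steps[i]
        if record_steps[i] == k0:
            out[i] = n
    work = n.copy()
    for k in range(k0, k_end):
        new = np.empty_like(work)
        for i in range(nr):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < nr - 1 else nr - 1
            for j in range(nc):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < nc - 1 else nc - 1
                lap = (
                    work[im, j] + work[ip, j] + work[i, jm] + work[i, jp]
                    - 4.0 * work[i, j]
                ) / dx2
                v = work[i, j] + dt * (d0 * lap + g0 * work[i, j])
                if clip and v < 0.0:
                    v = 0.0
                new[i, j] = v
        work = new
        for r in range(n_rec):
            if record_steps[r] == k + 1:
                out[r] = work


@_njit(cache=True)
def _post_kernel(
    ns, nd, gs, gd, kd, gamma_d, theta_px, ds, dd, dx2, dt, t_dox, k0,
    record_steps, clip, ns_out, nd_out,
):  # pragma: no cover
    nr, nc = ns.shape
    n_rec = record_steps.size
    k_end = k0
    for i in range(n_rec):
        if record_steps[i] > k_end:
            k_end = record_steps[i]
        if record_steps[i] == k0:
            ns_out[i] = ns
            nd_out[i] = nd
    ws = ns.copy()
    wd = nd.copy()
    for k in range(k0, k_end):
        t = k * dt
        new_s = np.empty_like(ws)
        new_d = np.empty_like(wd)
        for i in range(nr):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < nr - 1 else nr - 1
            for j in range(nc):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < nc - 1 else nc - 1
                lap_s = (
                    ws[im, j] + ws[ip, j] + ws[i, jm] + ws[i, jp]
                    - 4.0 * ws[i, j]
                ) / dx2
                lap_d = (
                    wd[im, j] + wd[ip, j] + wd[i, jm] + wd[i, jp]
                    - 4.0 * wd[i, j]
                ) / dx2
                crowding = 1.0 - (ws[i, j] + wd[i, j]) / theta_px[i, j]
                rate_d = (
                    gd[i, j]
                    + kd[i, j] * math.exp(-gamma_d[i, j] * (t - t_dox))
                    - kd[i, j]
                )
                vs = ws[i, j] + dt * (ds * lap_s + gs[i, j] * ws[i, j] * crowding)
                vd = wd[i, j] + dt * (dd * lap_d + rate_d * wd[i, j] * crowding)
                if clip:
                    if vs < 0.0:
                        vs = 0.0
                    if vd < 0.0:
                        vd = 0.0
                new_s[i, j] = vs
                new_d[i, j] = vd
        ws = new_s
        wd = new_d
        for r in range(n_rec):
            if record_steps[r] == k + 1:
                ns_out[r] = ws
                nd_out[r] = wd


def _as_field(value, grid: GridSpec) -> np.ndarray:
    return np.ascontiguousarray(
        np.broadcast_to(np.asarray(value, dtype=float), grid.shape)
    )


def integrate_pre(
    n0: np.ndarray,
    p: PretreatmentParams,
    cfg: SolverConfig,
    grid: GridSpec,
    t0: float,
    record_times: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Fast raw-array pre-treatment integration (exponential growth +
    diffusion).  Returns (times, stack) at the snapped record times."""
    _require_stable(p.d0, cfg, grid)
    dt = cfg.dt
    k0 = snap_to_step(t0, dt)
    record_steps = np.array([snap_to_step(t, dt) for t in record_times], dtype=np.int64)
    if np.any(record_steps < k0):
        raise DomainError("record_times precede the initial state")
    out = np.empty((len(record_steps),) + grid.shape)
    times = record_steps * dt
    _pre_kernel(
        np.ascontiguousarray(n0, dtype=float), float(p.g0), float(p.d0),
        grid.pixel_size_mm**2, dt, k0, record_steps, cfg.clip_negative, out,
    )
    return times, out


def integrate_post(
    ns0: np.ndarray,
    nd0: np.ndarray,
    p: TreatmentParams,
    cfg: SolverConfig,
    grid: GridSpec,
    t0: float,
    record_times: Sequence[float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fast raw-array post-treatment integration.

    Runs the same explicit update as :func:`step_posttreatment` without
    per-step object construction.  Returns (times, Ns_stack, Nd_stack) with
    stacks of shape (n_record, n_rows, n_cols), record times snapped to the
    step grid.  Used by calibration and forecasting, where the post phase is
    integrated thousands of times.
    """
    _require_stable(max(float(np.max(p.ds)), float(np.max(p.dd))), cfg, grid)
    if t0 < cfg.t_dox - 0.5 * cfg.dt:
        raise DomainError(f"post-phase start t0={t0} before t_dox={cfg.t_dox}")
    dt = cfg.dt
    k0 = snap_to_step(t0, dt)
    record_steps = np.array([snap_to_step(t, dt) for t in record_times], dtype=np.int64)
    if np.any(record_steps < k0):
        raise DomainError("record_times precede the initial state")

    n_rec = len(record_steps)
    ns_out = np.empty((n_rec,) + grid.shape)
    nd_out = np.empty((n_rec,) + grid.shape)
    times = record_steps * dt

    theta_px = _as_field(_theta_pixel(p, cfg, grid), grid)
    _post_kernel(
        np.ascontiguousarray(ns0, dtype=float),
        np.ascontiguousarray(nd0, dtype=float),
        _as_field(p.gs, grid), _as_field(p.gd, grid), _as_field(p.kd, grid),
        _as_field(p.gamma_d, grid), theta_px,
        float(np.max(p.ds)), float(np.max(p.dd)),
        grid.pixel_size_mm**2, dt, cfg.t_dox, k0, record_steps,
        cfg.clip_negative, ns_out, nd_out,
    )
    return times, ns_out, nd_out


def simulate_well(
    n0: DensityMap,
    pre: PretreatmentParams,
    post: TreatmentParams,
    cfg: SolverConfig,
    t_end: float,
    sample_times: Sequence[float],
) -> list[TwoPopState]:
    """Run the full two-phase model and return states at the sample times.

    Pre-treatment states carry the convention Ns = Ntot, Nd = 0.  Sample
    times are snapped to the nearest internal step, never interpolated.
    """
    sample_times = list(sample_times)
    if any(b < a for a, b in zip(sample_times, sample_times[1:])):
        raise DomainError("sample_times must be sorted ascending")
    if sample_times and (sample_times[0] < 0 or sample_times[-1] > t_end + 0.5 * cfg.dt):
        raise DomainError("sample_times must lie within [0, t_end]")
    if not (0 <= cfg.t_dox <= t_end):
        raise DomainError(f"t_dox={cfg.t_dox} outside [0, {t_end}]")

    dt = cfg.dt
    k_dox = snap_to_step(cfg.t_dox, dt)
    k_end = snap_to_step(t_end, dt)
    sample_steps = [snap_to_step(t, dt) for t in sample_times]
    wanted = {}
    for k in sample_steps:
        wanted.setdefault(k, 0)
        wanted[k] += 1

    out: list[TwoPopState] = []
    grid = n0.grid

    def emit_pre(m: DensityMap, k: int) -> None:
        if k in wanted:
            zero = DensityMap(np.zeros(grid.shape), m.time, grid)
            st = TwoPopState(ns=m, nd=zero, time=m.time)
            out.extend([st] * wanted[k])

    current = DensityMap(n0.values.copy(), 0.0, grid)
    if k_dox > 0:
        emit_pre(current, 0)
    for k in range(k_dox):
        current = step_pretreatment(current, pre, cfg)
        if k + 1 < k_dox:
            emit_pre(current, k + 1)

    # ensure post parameters use the frozen pre-treatment diffusion setup
    state = split_population(current, post.fs)
    if k_dox in wanted:
        out.extend([state] * wanted[k_dox])
    for k in range(k_dox, k_end):
        state = step_posttreatment(state, post, cfg)
        if k + 1 in wanted:
            out.extend([state] * wanted[k + 1])
    return out
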