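"""Leave-one-out weekly data assimilation and forecasting.

For the six replicates of one dose, five form a training set and one is held
out.  The pipeline alternates measurement and prediction in weekly (168 h)
segments:

* Week 0 -> 1: the training replicates are fully calibrated, their parameter
  sets averaged pixelwise into a prior grid P_training, and the model is run
  forward from the held-out replicate's density map at the treatment time.
* Each later week w: the model is recalibrated to the held-out replicate's
  data from the treatment time through week w (P_measure).  Every test pixel
  is then compared, by the concordance correlation coefficient of its raw
  cell-count time course, against all training pixels; the top 25% most
  similar training pixels contribute their calibrated parameter sets in a
  CCC-weighted average (P_training,p).  The refreshed prior is blended with
  P_measure by the scheduled weight

      omega(t_hat) = 0.6 t_hat^2 - 1.2 t_hat + 1.0,

  t_hat being the segment start time normalized by the longest experiment
  (963 h), and the blended per-pixel parameter grid drives the next week's
  forecast, initialized at the last measured map split by the blended
  surviving fraction.

Forecast uncertainty propagates the bootstrap parameter distributions of the
training and weekly calibrations through the same blending, summarizing many
forward runs by their mean and interquartile band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calibration import (
    BootstrapDistribution,
    CalibrationResult,
    ParameterBounds,
    bootstrap_calibration,
    calibrate_posttreatment,
    calibrate_pretreatment,
)
from .metrics_io import ccc_many, ccc_pixel
from .model_core import (
    DensityMap,
    DomainError,
    GridSpec,
    SolverConfig,
    TreatmentParams,
    integrate_post,
)
from .synthetic_data import WellSeries

PARAM_NAMES = ("gs", "fs", "gd", "kd", "gamma_d", "theta")
N_PARAMS = len(PARAM_NAMES)

DEFAULT_WEEK_H = 168.0
DEFAULT_T_REF_H = 963.0
SELECTION_FRACTION = 0.25


# ---------------------------------------------------------------------------
# Parameter grids
# ---------------------------------------------------------------------------


@dataclass
class TreatmentParameterGrid:
    """Per-pixel 6-vectors (gs, fs, gd, kd, gamma_d, theta) over the grid."""

    values: np.ndarray  # (n_rows, n_cols, 6)
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape + (N_PARAMS,):
            raise DomainError(
                f"parameter grid shape {self.values.shape} != "
                f"{self.grid.shape + (N_PARAMS,)}"
            )

    def param(self, name: str) -> np.ndarray:
        return self.values[..., PARAM_NAMES.index(name)]

    def to_treatment_params(self, d0: float) -> TreatmentParams:
        return TreatmentParams(
            gs=self.param("gs"), fs=self.param("fs"), gd=self.param("gd"),
            kd=self.param("kd"), gamma_d=self.param("gamma_d"),
            theta=self.param("theta"), ds=d0, dd=d0,
        )

    @classmethod
    def from_calibration(cls, result: CalibrationResult) -> "TreatmentParameterGrid":
        return cls.from_treatment_params(result.post, result.ic_map.grid)

    @classmethod
    def from_treatment_params(
        cls, post: TreatmentParams, grid: GridSpec
    ) -> "TreatmentParameterGrid":
        stacked = np.stack(
            [
                np.broadcast_to(np.asarray(getattr(post, n), dtype=float), grid.shape)
                for n in PARAM_NAMES
            ],
            axis=-1,
        )
        return cls(stacked.copy(), grid)


def build_training_prior(
    calibrations: Sequence[CalibrationResult],
) -> TreatmentParameterGrid:
    """Pixelwise arithmetic mean of the training calibrations' parameters."""
    if not calibrations:
        raise DomainError("at least one training calibration required")
    grids = [TreatmentParameterGrid.from_calibration(c) for c in calibrations]
    shapes = {g.grid.shape for g in grids}
    if len(shapes) > 1:
        raise DomainError(f"training calibrations on mismatched grids: {shapes}")
    mean = np.mean([g.values for g in grids], axis=0)
    return TreatmentParameterGrid(mean, grids[0].grid)


# ---------------------------------------------------------------------------
# Similarity ranking and parameter transfer
# ---------------------------------------------------------------------------


@dataclass
class SimilarityRanking:
    """Training pixels ranked by CCC similarity to one test pixel."""

    order: np.ndarray          # training pixel ids, best first
    scores: np.ndarray         # CCC per id, same order
    selected: np.ndarray       # the ceil(25%) most similar ids
    weights: np.ndarray        # alpha_k over the selection, sums to 1
    degenerate: bool = False


def selection_size(n_training_pixels: int, fraction: float = SELECTION_FRACTION) -> int:
    """Number of training pixels retained: ceil(fraction * K)."""
    return int(math.ceil(fraction * n_training_pixels))


def rank_similar_pixels(
    test_course: np.ndarray,
    training_courses: np.ndarray,
    fraction: float = SELECTION_FRACTION,
) -> SimilarityRanking:
    """Rank all training pixel time courses against one test pixel course.

    ``training_courses`` has shape (K, n_times) of raw cell counts over the
    common window.  Stable sort by (CCC descending, pixel id); weights are
    CCC_k / sum CCC over the selection, falling back to uniform weights when
    the test course has zero variance or the selected CCC sum is <= 0.
    """
    test_course = np.asarray(test_course, dtype=float)
    training_courses = np.asarray(training_courses, dtype=float)
    if training_courses.ndim != 2 or len(test_course) != training_courses.shape[1]:
        raise DomainError("training_courses must be (K, n_times) matching test course")
    if len(test_course) < 2:
        raise DomainError("need >= 2 common timepoints for similarity ranking")
    k_total = training_courses.shape[0]
    n_sel = selection_size(k_total, fraction)

    degenerate = bool(np.var(test_course) == 0.0)
    scores = ccc_many(training_courses, test_course)
    scores = np.where(np.isnan(scores), -np.inf, scores)
    order = np.lexsort((np.arange(k_total), -scores))
    sorted_scores = scores[order]
    selected = order[:n_sel]
    sel_scores = sorted_scores[:n_sel]

    finite = np.isfinite(sel_scores)
    total = sel_scores[finite].sum() if np.any(finite) else 0.0
    if degenerate or total <= 0:
        weights = np.full(n_sel, 1.0 / n_sel)
        degenerate = True
    else:
        weights = np.where(finite, sel_scores, 0.0) / total
    return SimilarityRanking(
        order=order, scores=sorted_scores, selected=selected,
        weights=weights, degenerate=degenerate,
    )


def transfer_parameters(
    rankings: Sequence[SimilarityRanking],
    training_params: np.ndarray,
    grid: GridSpec,
) -> TreatmentParameterGrid:
    """CCC-weighted average of the selected training parameter sets per pixel.

    ``training_params`` has shape (K, 6) in PARAM_NAMES order; ``rankings``
    lists one ranking per test pixel in row-major order.
    """
    training_params = np.asarray(training_params, dtype=float)
    if len(rankings) != grid.n_pixels:
        raise DomainError("one ranking per test pixel required")
    out = np.empty((grid.n_pixels, N_PARAMS))
    for i, r in enumerate(rankings):
        if len(r.selected) == 0:
            raise DomainError(f"empty selection for test pixel {i}")
        out[i] = r.weights @ training_params[r.selected]
    return TreatmentParameterGrid(out.reshape(grid.shape + (N_PARAMS,)), grid)


# ---------------------------------------------------------------------------
# Blending schedule
# ---------------------------------------------------------------------------


def omega(t_hat: float) -> float:
    """Prior-vs-replicate blending weight, 0.6 t^2 - 1.2 t + 1.0 on [0, 1].

    Decreasing from 1 (trust the training prior) to 0.4 (mostly trust the
    replicate-specific calibration)."""
    if not 0.0 <= t_hat <= 1.0:
        raise DomainError(f"t_hat={t_hat} outside [0, 1]")
    return 0.6 * t_hat * t_hat - 1.2 * t_hat + 1.0


def blend_parameters(
    p_training: TreatmentParameterGrid,
    p_measure: TreatmentParameterGrid,
    t_hat: float,
) -> TreatmentParameterGrid:
    """Elementwise convex combination omega*P_training + (1-omega)*P_measure."""
    if p_training.values.shape != p_measure.values.shape:
        raise DomainError("parameter grids have mismatched shapes")
    w = omega(t_hat)
    return TreatmentParameterGrid(
        w * p_training.values + (1.0 - w) * p_measure.values, p_training.grid
    )


# ---------------------------------------------------------------------------
# Forward prediction
# ---------------------------------------------------------------------------


def predict_week(
    initial: DensityMap,
    params: TreatmentParameterGrid,
    cfg: SolverConfig,
    d0: float,
    sample_times: Sequence[float],
    split_fs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward simulation with per-pixel parameters from a measured map.

    The map is split into surviving/damaged by ``split_fs`` (default: the
    grid's own fs field).  Returns (times, Ns_stack, Nd_stack).
    """
    fs = params.param("fs") if split_fs is None else np.asarray(split_fs, float)
    ns0 = fs * initial.values
    nd0 = initial.values - ns0
    post = params.to_treatment_params(d0)
    return integrate_post(ns0, nd0, post, cfg, initial.grid, initial.time, sample_times)


def propagated_surviving_share(
    params: TreatmentParameterGrid,
    t_dox_map: DensityMap,
    cfg: SolverConfig,
    d0: float,
    t_at: float,
) -> np.ndarray:
    """Per-pixel surviving share Ns/Ntot at time ``t_at``, obtained by
    running the model from the measured treatment-time map (split there by
    the grid's fs).

    The surviving fraction fs is defined at the treatment time; a measured
    map at a later weekly boundary must be split by the composition the model
    itself predicts there.  Pixels the model empties fall back to fs.
    """
    if t_at <= t_dox_map.time + 1e-9:
        return np.array(params.param("fs"))
    _, ns, nd = predict_week(t_dox_map, params, cfg, d0, [t_at])
    tot = ns[0] + nd[0]
    fs0 = params.param("fs")
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(tot > 0, ns[0] / np.where(tot > 0, tot, 1.0), fs0)
    return share


@dataclass
class PredictionBand:
    """Mean and interquartile band over sampled forward runs."""

    mean: np.ndarray   # (n_times, n_rows, n_cols)
    lower: np.ndarray  # 25th percentile
    upper: np.ndarray  # 75th percentile
    n_samples: int


def sample_prediction_band(
    training_samples: np.ndarray,
    measure_samples: np.ndarray | None,
    t_hat: float,
    initial: DensityMap,
    cfg: SolverConfig,
    d0: float,
    sample_times: Sequence[float],
    n_samples: int = 1000,
    rng_seed: int | np.random.Generator = 0,
    t_dox_map: DensityMap | None = None,
) -> PredictionBand:
    """Propagate bootstrap parameter-grid samples through the blend and the
    forward model.

    ``training_samples`` / ``measure_samples`` are (B, n_rows, n_cols, 6)
    stacks of parameter grids; each draw pairs one sample from each,
    blends with omega(t_hat), and runs the model forward.
    """
    if n_samples < 4:
        raise DomainError("n_samples must be >= 4")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    grid = initial.grid
    w = omega(t_hat)
    b_train = training_samples.shape[0]
    runs = np.empty((n_samples, len(sample_times)) + grid.shape)
    for s in range(n_samples):
        pt = training_samples[rng.integers(b_train)]
        if measure_samples is None:
            blended = pt
        else:
            pm = measure_samples[rng.integers(measure_samples.shape[0])]
            blended = w * pt + (1.0 - w) * pm
        pgrid = TreatmentParameterGrid(blended, grid)
        split = (
            propagated_surviving_share(pgrid, t_dox_map, cfg, d0, initial.time)
            if t_dox_map is not None
            else None
        )
        _, ns, nd = predict_week(initial, pgrid, cfg, d0, sample_times, split_fs=split)
        runs[s] = ns + nd
    return PredictionBand(
        mean=runs.mean(axis=0),
        lower=np.percentile(runs, 25, axis=0),
        upper=np.percentile(runs, 75, axis=0),
        n_samples=n_samples,
    )


# ---------------------------------------------------------------------------
# The leave-one-out pipeline
# ---------------------------------------------------------------------------


@dataclass
class PredictionSegment:
    """One weekly forecast segment of the held-out replicate."""

    week: int
    t_start: float
    times: np.ndarray
    ntot: np.ndarray           # point forecast (n_times, n_rows, n_cols)
    ns: np.ndarray
    nd: np.ndarray
    params: TreatmentParameterGrid
    omega_used: float
    ccc_well: float
    ccc_pixel: float
    band: PredictionBand | None = None


@dataclass
class PredictionTrace:
    segments: list[PredictionSegment]

    @property
    def ccc_well_by_week(self) -> np.ndarray:
        return np.array([s.ccc_well for s in self.segments])


@dataclass
class PipelineResult:
    trace: PredictionTrace
    training_calibrations: list[CalibrationResult]
    weekly_calibrations: list[CalibrationResult]
    prior: TreatmentParameterGrid
    test_index: int


def _post_courses(series: WellSeries, t_lo: float, t_hi: float) -> tuple[np.ndarray, np.ndarray]:
    """(times, (n_pixels, n_times) pixel courses) within (t_lo, t_hi]."""
    times = series.times
    sel = (times > t_lo + 1e-9) & (times <= t_hi + 1e-9)
    idx = np.flatnonzero(sel)
    stack = np.stack([series.maps[i].values for i in idx])
    return times[idx], stack.reshape(len(idx), -1).T


def _grid_samples_from_bootstrap(
    dist: BootstrapDistribution, grid: GridSpec
) -> np.ndarray:
    """(n_boot, n_rows, n_cols, 6) parameter-grid stack from a bootstrap."""
    n_boot = dist.n_boot
    out = np.empty((n_boot,) + grid.shape + (N_PARAMS,))
    out[..., 0] = dist.samples["gs"]
    for j, name in enumerate(PARAM_NAMES[1:], start=1):
        out[..., j] = dist.samples[name][:, None, None]
    return out


def _segment_metrics(
    test: WellSeries, times: np.ndarray, pred_ntot: np.ndarray
) -> tuple[float, float]:
    sel = np.isin(np.round(test.times, 6), np.round(times, 6))
    idx = np.flatnonzero(sel)
    data_maps = [test.maps[i] for i in idx]
    grid = test.grid
    model = WellSeries(
        maps=[DensityMap(pred_ntot[i], float(times[i]), grid) for i in range(len(times))],
        dose=test.dose, t_dox=test.t_dox, replicate_id=test.replicate_id,
    )
    data = WellSeries(
        maps=data_maps, dose=test.dose, t_dox=test.t_dox,
        replicate_id=test.replicate_id,
    )
    m = ccc_pixel(model, data)
    return m.ccc_well, m.ccc_pixel


def run_pipeline(
    replicates: Sequence[WellSeries],
    test_index: int,
    rng_seed: int = 0,
    bounds: ParameterBounds | None = None,
    cfg: SolverConfig | None = None,
    n_boot: int = 0,
    n_band_samples: int = 200,
    week_length: float = DEFAULT_WEEK_H,
    t_ref: float = DEFAULT_T_REF_H,
    max_nfev: int | None = None,
) -> PipelineResult:
    """Leave-one-out weekly assimilation-prediction for one dose group.

    ``n_boot`` = 0 skips the bootstrap/uncertainty propagation (point
    forecasts only); with ``n_boot`` > 0 every segment carries an
    interquartile prediction band from ``n_band_samples`` forward runs.
    """
    if len(replicates) != 6:
        raise DomainError(f"pipeline requires 6 replicates, got {len(replicates)}")
    if not 0 <= test_index < 6:
        raise DomainError("test_index must be in [0, 6)")
    bounds = bounds or ParameterBounds()
    test = replicates[test_index]
    training = [r for i, r in enumerate(replicates) if i != test_index]
    cfg = cfg or SolverConfig(t_dox=test.t_dox)
    grid = test.grid
    rng = np.random.default_rng(rng_seed)
    t_dox = test.t_dox

    # --- full-course calibration of the training replicates -----------------
    training_cals: list[CalibrationResult] = []
    training_boot_grids: list[np.ndarray] = []
    for r in training:
        pre = calibrate_pretreatment(r, bounds, cfg).params
        cal = calibrate_posttreatment(r, bounds, pre, cfg, max_nfev=max_nfev)
        training_cals.append(cal)
        if n_boot > 0:
            dist = bootstrap_calibration(
                r, cal, n_boot=n_boot, rng_seed=np.random.default_rng(rng.integers(2**31))
            )
            training_boot_grids.append(_grid_samples_from_bootstrap(dist, grid))
    prior = build_training_prior(training_cals)

    # calibrated per-pixel parameter sets of all training pixels, (K, 6)
    training_param_sets = np.concatenate(
        [TreatmentParameterGrid.from_calibration(c).values.reshape(-1, N_PARAMS)
         for c in training_cals]
    )
    if training_boot_grids:
        # (n_boot, K, 6): sample-matched pixel sets across replicates
        boot_param_sets = np.concatenate(
            [g.reshape(n_boot, -1, N_PARAMS) for g in training_boot_grids], axis=1
        )
        prior_samples = np.mean(
            np.stack(training_boot_grids), axis=0
        )  # (n_boot, r, c, 6)
    else:
        boot_param_sets = None
        prior_samples = None

    t_end = float(test.times[-1])
    test_times = test.times

    def measured_map_at(t: float) -> DensityMap:
        idx = np.flatnonzero(test_times <= t + 1e-9)
        return test.maps[int(idx[-1])]

    segments: list[PredictionSegment] = []
    weekly_cals: list[CalibrationResult] = []
    week = 0
    warm: TreatmentParams | None = None
    t_now = t_dox
    current_grid = prior
    current_train_samples = prior_samples
    current_measure_samples = None
    t_hat_now = 0.0

    while t_now < t_end - 1e-9:
        t_next = min(t_now + week_length, t_end)
        seg_sel = (test_times > t_now + 1e-9) & (test_times <= t_next + 1e-9)
        seg_times = test_times[np.flatnonzero(seg_sel)]
        if len(seg_times) == 0:
            break
        ic = measured_map_at(t_now)
        d0 = training_cals[0].pre.d0
        split = propagated_surviving_share(
            current_grid, measured_map_at(t_dox), cfg, d0, t_now
        )
        times_out, ns, nd = predict_week(
            ic, current_grid, cfg, d0, seg_times, split_fs=split,
        )
        ntot = ns + nd
        w_used = omega(t_hat_now)
        cw, cp = _segment_metrics(test, seg_times, ntot)
        band = None
        if n_boot > 0 and current_train_samples is not None:
            band = sample_prediction_band(
                current_train_samples, current_measure_samples, t_hat_now,
                ic, cfg, d0, seg_times,
                n_samples=n_band_samples,
                rng_seed=np.random.default_rng(rng.integers(2**31)),
                t_dox_map=measured_map_at(t_dox),
            )
        segments.append(PredictionSegment(
            week=week, t_start=t_now, times=times_out, ntot=ntot,
            ns=ns, nd=nd, params=current_grid, omega_used=w_used,
            ccc_well=cw, ccc_pixel=cp, band=band,
        ))

        # --- assimilate the newly measured week, prepare the next segment ---
        t_now = t_next
        week += 1
        if t_now >= t_end - 1e-9:
            break
        pre_test = calibrate_pretreatment(test, bounds, cfg).params
        cal = calibrate_posttreatment(
            test, bounds, pre_test, cfg, t_max=t_now, x0=warm, max_nfev=max_nfev
        )
        weekly_cals.append(cal)
        warm = cal.post
        p_measure = TreatmentParameterGrid.from_calibration(cal)

        _, test_courses = _post_courses(test, t_dox, t_now)
        train_courses = np.concatenate(
            [_post_courses(r, t_dox, t_now)[1] for r in training]
        )
        rankings = [
            rank_similar_pixels(test_courses[p], train_courses)
            for p in range(grid.n_pixels)
        ]
        p_training = transfer_parameters(rankings, training_param_sets, grid)
        t_hat_now = min(t_now / t_ref, 1.0)
        current_grid = blend_parameters(p_training, p_measure, t_hat_now)

        if n_boot > 0:
            mdist = bootstrap_calibration(
                test, cal, n_boot=n_boot,
                rng_seed=np.random.default_rng(rng.integers(2**31)),
            )
            current_measure_samples = _grid_samples_from_bootstrap(mdist, grid)
            # transfer each bootstrap draw's training pixel sets with the
            # same similarity weights
            n_b = boot_param_sets.shape[0]
            ts = np.empty((n_b,) + grid.shape + (N_PARAMS,))
            flat = ts.reshape(n_b, grid.n_pixels, N_PARAMS)
            for p, r in enumerate(rankings):
                flat[:, p, :] = np.einsum(
                    "k,bkj->bj", r.weights, boot_param_sets[:, r.selected]
                )
            current_train_samples = ts

    return PipelineResult(
        trace=PredictionTrace(segments=segments),
        training_calibrations=training_cals,
        weekly_calibrations=weekly_cals,
        prior=prior,
        test_index=test_index,
    )
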