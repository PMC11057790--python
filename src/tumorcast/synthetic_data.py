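"""Synthetic well experiments emulating time-lapse density-map data.

The generator reproduces the structure of the in-vitro study the model was
built for: 9 doxorubicin doses (10-300 nM) x 6 replicates plus 6 untreated
controls, 2000 cells seeded per well, a single 24-h drug exposure starting at
t = 48 h, imaging every 4 h, centroid tables binned at 430 um into a 15 x 15
density grid, and series truncated at confluence.  Dose regimes follow the
observed qualitative behaviour: low doses grow almost unperturbed, medium
doses (50-150 nM) decline and then relapse from localized clusters of
fast-proliferating survivors, and high doses decay homogeneously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model_core import (
    DensityMap,
    DomainError,
    GridSpec,
    PretreatmentParams,
    SolverConfig,
    TreatmentParams,
    simulate_well,
)

DEFAULT_DOSES_NM = (10.0, 20.0, 35.0, 50.0, 75.0, 100.0, 125.0, 150.0, 300.0)

#: Experiment durations anchor points: 277 h at 10 nM up to 963 h at 300 nM.
_T_END_MIN, _T_END_MAX = 277.0, 963.0
_MEDIUM_DOSE_RANGE = (50.0, 150.0)


def default_t_end(dose: float) -> float:
    """Experiment length for a dose, log-interpolated between 277 h (10 nM)
    and 963 h (300 nM); controls use the shortest duration."""
    if dose <= 10.0:
        return _T_END_MIN
    if dose >= 300.0:
        return _T_END_MAX
    frac = math.log(dose / 10.0) / math.log(300.0 / 10.0)
    return _T_END_MIN + (_T_END_MAX - _T_END_MIN) * frac


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExperimentDesign:
    """Layout of the synthetic experiment (defaults mirror the real study)."""

    doses_nM: tuple[float, ...] = DEFAULT_DOSES_NM
    replicates_per_dose: int = 6
    n_controls: int = 6
    seed_cells: int = 2000
    t_dox: float = 48.0
    imaging_interval: float = 4.0
    grid: GridSpec = field(default_factory=GridSpec)

    def t_end(self, dose: float) -> float:
        return default_t_end(dose)


@dataclass
class ClusterSpec:
    """High-proliferation foci on the gs field (relapse clusters)."""

    n_clusters: int = 0
    radius_px: float = 1.5
    gs_peak: float = 0.03


@dataclass
class GroundTruth:
    """Generating parameters for one synthetic well.

    Pixel noise is additive Gaussian with sd = max(noise_rel * count,
    noise_floor); set both to 0 for noiseless data.
    """

    pre: PretreatmentParams
    post: TreatmentParams
    noise_rel: float = 0.05
    noise_floor: float = 1.0
    cluster_spec: ClusterSpec = field(default_factory=ClusterSpec)


@dataclass
class CentroidTable:
    """Cell centroid positions (um) with their imaging times (h)."""

    time_h: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if not (len(self.time_h) == len(self.x_um) == len(self.y_um)):
            raise DomainError("centroid columns must have equal length")

    def __len__(self) -> int:
        return len(self.time_h)


@dataclass
class WellSeries:
    """One replicate's record: density maps over time plus metadata."""

    maps: list[DensityMap]
    dose: float
    t_dox: float
    replicate_id: int = 0
    truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        times = self.times
        if np.any(np.diff(times) <= 0):
            raise DomainError("map times must be strictly increasing")
        grids = {m.grid.shape for m in self.maps}
        if len(grids) > 1:
            raise DomainError("all maps must share one grid")

    @property
    def times(self) -> np.ndarray:
        return np.array([m.time for m in self.maps])

    @property
    def grid(self) -> GridSpec:
        return self.maps[0].grid

    def stack(self) -> np.ndarray:
        """(n_times, n_rows, n_cols) array of the density maps."""
        return np.stack([m.values for m in self.maps])

    @property
    def totals(self) -> np.ndarray:
        """Total well count per timepoint."""
        return np.array([m.total for m in self.maps])


# ---------------------------------------------------------------------------
# Ground-truth sampling
# ---------------------------------------------------------------------------


def _dose_fs(dose: float) -> float:
    """Surviving fraction, decreasing in dose (1 for controls)."""
    if dose <= 0:
        return 1.0
    return float(np.exp(-dose / 40.0))


def _dose_kd(dose: float) -> float:
    """Drug-induced death rate, increasing in dose within [1e-4, 1e-2].

    At every treated dose kd clearly exceeds the damaged proliferation rate
    (0.002), so the damaged pool visibly declines after the death delay --
    the defining treatment effect of this two-phenotype model.
    """
    if dose <= 0:
        return 1e-4
    return 0.002 + 0.008 * (min(dose, 300.0) / 300.0) ** 0.4


def is_medium_dose(dose: float) -> bool:
    return _MEDIUM_DOSE_RANGE[0] <= dose <= _MEDIUM_DOSE_RANGE[1]


def _gs_field(dose: float, grid: GridSpec, rng: np.random.Generator) -> tuple[np.ndarray, ClusterSpec]:
    """Surviving-proliferation field: uniform except for medium-dose foci."""
    if dose <= 0:
        return np.full(grid.shape, 0.0275), ClusterSpec(0)
    if dose < _MEDIUM_DOSE_RANGE[0]:
        return np.full(grid.shape, 0.025), ClusterSpec(0)
    if dose > _MEDIUM_DOSE_RANGE[1]:
        return np.full(grid.shape, 0.002), ClusterSpec(0)
    # relapse clusters become identifiable ~2 weeks post-treatment and reach
    # confluence only near the experiment end: effective regrowth ~0.015/h
    base, peak = 0.005, 0.015
    n_clusters = int(rng.integers(2, 6))
    radius = float(rng.uniform(1.2, 2.0)) * grid.n_rows / 15.0
    spec = ClusterSpec(n_clusters=n_clusters, radius_px=radius, gs_peak=peak)
    gs = np.full(grid.shape, base)
    rows = np.arange(grid.n_rows)[:, None]
    cols = np.arange(grid.n_cols)[None, :]
    for _ in range(n_clusters):
        r0 = rng.uniform(1, grid.n_rows - 2)
        c0 = rng.uniform(1, grid.n_cols - 2)
        bump = np.exp(-((rows - r0) ** 2 + (cols - c0) ** 2) / (2 * radius**2))
        gs = np.maximum(gs, base + (peak - base) * bump)
    return gs, spec


def sample_dose_truth(
    dose: float, rng_seed: int | np.random.Generator = 0
) -> GroundTruth:
    """Ground-truth parameters for one well at the given dose.

    Encodes the dose regimes: surviving fraction decreases with dose, the
    death rate increases, and only medium doses carry spatial gs clusters.
    All values stay within the model's admissible parameter ranges.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    grid = GridSpec()
    gs, cluster_spec = _gs_field(dose, grid, rng)
    pre = PretreatmentParams(g0=0.0275, d0=0.003)
    post = TreatmentParams(
        gs=gs,
        fs=_dose_fs(dose),
        # interior of the decay-compatible gd sub-range [.001, .01): damaged
        # cells proliferate briefly, then kd > gd drives the decline
        gd=0.005,
        kd=_dose_kd(dose),
        gamma_d=0.03,
        theta=89000.0,
        ds=pre.d0,
        dd=pre.d0,
    )
    return GroundTruth(pre=pre, post=post, cluster_spec=cluster_spec)


def regrid_truth(truth: GroundTruth, grid: GridSpec, rng_seed: int = 0) -> GroundTruth:
    """Resample the gs field of a truth onto a different grid (for the
    miniature test configurations)."""
    rng = np.random.default_rng(rng_seed)
    gs_old = np.asarray(truth.post.gs)
    if gs_old.shape == grid.shape:
        return truth
    if truth.cluster_spec.n_clusters == 0:
        gs = np.full(grid.shape, float(gs_old.flat[0]))
    else:
        base = float(np.min(gs_old))
        peak = truth.cluster_spec.gs_peak
        radius = truth.cluster_spec.radius_px * grid.n_rows / 15.0
        gs = np.full(grid.shape, base)
        rows = np.arange(grid.n_rows)[:, None]
        cols = np.arange(grid.n_cols)[None, :]
        for _ in range(truth.cluster_spec.n_clusters):
            r0 = rng.uniform(0.5, grid.n_rows - 1.5)
            c0 = rng.uniform(0.5, grid.n_cols - 1.5)
            bump = np.exp(-((rows - r0) ** 2 + (cols - c0) ** 2) / (2 * radius**2))
            gs = np.maximum(gs, base + (peak - base) * bump)
    post = TreatmentParams(
        gs=gs, fs=truth.post.fs, gd=truth.post.gd, kd=truth.post.kd,
        gamma_d=truth.post.gamma_d, theta=truth.post.theta,
        ds=truth.post.ds, dd=truth.post.dd,
    )
    return GroundTruth(
        pre=truth.pre, post=post, noise_rel=truth.noise_rel,
        noise_floor=truth.noise_floor, cluster_spec=truth.cluster_spec,
    )


# ---------------------------------------------------------------------------
# Forward simulation of a well
# ---------------------------------------------------------------------------


def seed_initial_map(
    design: ExperimentDesign, rng: np.random.Generator
) -> DensityMap:
    """Multinomial scatter of the seeded cells over the grid (homogeneous
    seeding in expectation)."""
    grid = design.grid
    probs = np.full(grid.n_pixels, 1.0 / grid.n_pixels)
    counts = rng.multinomial(design.seed_cells, probs).reshape(grid.shape)
    return DensityMap(counts.astype(float), 0.0, grid)


def imaging_times(design: ExperimentDesign, dose: float) -> np.ndarray:
    t_end = design.t_end(dose)
    return np.arange(0.0, t_end + 1e-9, design.imaging_interval)


def simulate_truth_series(
    truth: GroundTruth,
    design: ExperimentDesign,
    dose: float,
    rng_seed: int | np.random.Generator = 0,
    replicate_id: int = 0,
) -> WellSeries:
    """Forward-simulate one well and add measurement noise.

    Noiseless solver states are taken at the imaging times, then each pixel
    receives additive Gaussian noise with sd = max(noise_rel*count,
    noise_floor), clipped at zero.  The generating truth is retained.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    grid = design.grid
    truth = regrid_truth(truth, grid, rng_seed=int(rng.integers(2**31)))
    cfg = SolverConfig(t_dox=design.t_dox)
    n0 = seed_initial_map(design, rng)
    times = imaging_times(design, dose)
    states = simulate_well(n0, truth.pre, truth.post, cfg, float(times[-1]), times)
    maps = []
    for st in states:
        values = st.ntot
        if truth.noise_rel > 0 or truth.noise_floor > 0:
            sd = np.maximum(truth.noise_rel * values, truth.noise_floor)
            values = np.maximum(values + rng.normal(0.0, 1.0, grid.shape) * sd, 0.0)
        maps.append(DensityMap(values, st.time, grid))
    return WellSeries(
        maps=maps, dose=dose, t_dox=design.t_dox,
        replicate_id=replicate_id, truth=truth,
    )


def generate_dose_replicates(
    dose: float,
    design: ExperimentDesign | None = None,
    master_seed: int = 0,
    n_replicates: int | None = None,
    shared_truth: bool = False,
    noise_rel: float | None = None,
    noise_floor: float | None = None,
) -> list[WellSeries]:
    """All replicates of one dose, each with its own deterministic RNG stream.

    ``shared_truth`` makes every replicate use the first replicate's truth
    (identical-truth designs for self-consistency experiments).
    """
    design = design or ExperimentDesign()
    n_rep = n_replicates if n_replicates is not None else design.replicates_per_dose
    wells = []
    truth0 = None
    for rep in range(n_rep):
        ss = np.random.SeedSequence([master_seed, int(round(dose * 10)), rep])
        rng = np.random.default_rng(ss)
        if shared_truth and truth0 is not None:
            truth = truth0
        else:
            truth = regrid_truth(
                sample_dose_truth(dose, rng), design.grid,
                rng_seed=int(rng.integers(2**31)),
            )
        if truth0 is None:
            truth0 = truth
        if noise_rel is not None or noise_floor is not None:
            truth = GroundTruth(
                pre=truth.pre, post=truth.post,
                noise_rel=truth.noise_rel if noise_rel is None else noise_rel,
                noise_floor=truth.noise_floor if noise_floor is None else noise_floor,
                cluster_spec=truth.cluster_spec,
            )
        wells.append(
            simulate_truth_series(truth, design, dose, rng, replicate_id=rep)
        )
    return wells


# ---------------------------------------------------------------------------
# Centroid tables and binning
# ---------------------------------------------------------------------------


def scatter_centroids(
    density: DensityMap, rng_seed: int | np.random.Generator = 0
) -> CentroidTable:
    """Emit round(count) centroids per pixel, uniform within the pixel."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    grid = density.grid
    counts = np.rint(density.values).astype(int)
    xs, ys = [], []
    px = grid.pixel_size_um
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            n = counts[r, c]
            if n <= 0:
                continue
            xs.append(c * px + rng.uniform(0, px, n))
            ys.append(r * px + rng.uniform(0, px, n))
    if xs:
        x = np.concatenate(xs)
        y = np.concatenate(ys)
    else:
        x = np.empty(0)
        y = np.empty(0)
    t = np.full(len(x), density.time)
    return CentroidTable(time_h=t, x_um=x, y_um=y)


def bin_centroids_to_density(
    table: CentroidTable, grid: GridSpec, time: float
) -> DensityMap:
    """Count centroids at the given time into half-open 430-um pixel cells."""
    sel = np.isclose(table.time_h, time)
    x, y = table.x_um[sel], table.y_um[sel]
    fov_x = grid.n_cols * grid.pixel_size_um
    fov_y = grid.n_rows * grid.pixel_size_um
    bad = (x < 0) | (x >= fov_x) | (y < 0) | (y >= fov_y)
    if np.any(bad):
        idx = int(np.flatnonzero(sel)[np.argmax(bad)])
        raise DomainError(f"centroid record {idx} outside the field of view")
    cols = np.floor(x / grid.pixel_size_um).astype(int)
    rows = np.floor(y / grid.pixel_size_um).astype(int)
    values = np.zeros(grid.shape)
    np.add.at(values, (rows, cols), 1.0)
    return DensityMap(values, time, grid)


def truncate_at_confluence(
    series: WellSeries, threshold_fraction: float = 0.95, theta: float | None = None
) -> WellSeries:
    """Drop timepoints after the first where the total count reaches
    threshold_fraction * theta (confluence)."""
    if not (0 < threshold_fraction <= 1):
        raise DomainError("threshold_fraction must be in (0, 1]")
    if theta is None:
        if series.truth is None:
            raise DomainError("theta required when the series carries no truth")
        theta = float(np.mean(series.truth.post.theta))
    totals = series.totals
    crossing = np.flatnonzero(totals >= threshold_fraction * theta)
    if len(crossing) == 0:
        return series
    k = int(crossing[0])
    return WellSeries(
        maps=series.maps[: k + 1], dose=series.dose, t_dox=series.t_dox,
        replicate_id=series.replicate_id, truth=series.truth,
    )
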