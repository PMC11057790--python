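"""Concordance correlation coefficient (CCC) metrics and serialization.

Lin's CCC measures agreement between two series,

    CCC = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)

with population (1/n) moments.  ``ccc_well`` applies it to the two
whole-well total-count time courses; ``ccc_pixel`` averages per-pixel CCCs
over the pixels where the score is defined (constant-vs-constant courses are
excluded, and the exclusion count reported).

Well series are serialized to an HDF5 container (one group per well holding
``times`` and ``Ntot``/``Ns``/``Nd`` stacks with dose/treatment metadata) or,
as a plain-text fallback, to a directory of per-timepoint TSV matrices with a
JSON manifest.  Centroid tables are delimited text with header
``time_h,x_um,y_um``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .model_core import DensityMap, DomainError, GridSpec
from .synthetic_data import CentroidTable, WellSeries

SCHEMA_VERSION = "1.0"


class SchemaError(ValueError):
    """Serialized container does not follow the documented schema."""


# ---------------------------------------------------------------------------
# CCC
# ---------------------------------------------------------------------------


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments).

    Returns NaN (flagged not-a-score) when both series are constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("ccc requires two equal-length 1-D series")
    if len(x) < 2:
        raise DomainError("ccc requires at least 2 observations")
    mx, my = x.mean(), y.mean()
    vx = np.mean((x - mx) ** 2)
    vy = np.mean((y - my) ** 2)
    if vx == 0.0 and vy == 0.0:
        return math.nan
    cov = np.mean((x - mx) * (y - my))
    return float(2.0 * cov / (vx + vy + (mx - my) ** 2))


def ccc_many(courses: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """CCC of each row of ``courses`` (K, n) against one reference series.

    Vectorized version of :func:`ccc`; rows where both the row and the
    reference are constant yield NaN.
    """
    courses = np.asarray(courses, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mx = courses.mean(axis=1)
    my = reference.mean()
    dx = courses - mx[:, None]
    dy = reference - my
    vx = np.mean(dx * dx, axis=1)
    vy = np.mean(dy * dy)
    cov = dx @ dy / courses.shape[1]
    denom = vx + vy + (mx - my) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, 2.0 * cov / np.where(denom > 0, denom, 1.0), np.nan)
    return out


@dataclass(frozen=True)
class FitMetrics:
    """Well- and pixel-level agreement between model and data."""

    ccc_well: float
    ccc_pixel: float
    n_pixels_included: int
    n_pixels_excluded: int


def _aligned_stacks(model: WellSeries, data: WellSeries) -> tuple[np.ndarray, np.ndarray]:
    tm, td = model.times, data.times
    if len(tm) != len(td) or np.max(np.abs(tm - td)) > 1e-6:
        raise DomainError("model and data series times are not aligned")
    return model.stack(), data.stack()


def ccc_well(model: WellSeries, data: WellSeries) -> float:
    """CCC between the two whole-well total-count time courses."""
    sm, sd = _aligned_stacks(model, data)
    return ccc(sm.sum(axis=(1, 2)), sd.sum(axis=(1, 2)))


def ccc_pixel(model: WellSeries, data: WellSeries) -> FitMetrics:
    """Mean per-pixel CCC over pixels with a defined score."""
    sm, sd = _aligned_stacks(model, data)
    n_t = sm.shape[0]
    flat_m = sm.reshape(n_t, -1).T
    flat_d = sd.reshape(n_t, -1).T
    scores = np.array([ccc(m, d) for m, d in zip(flat_m, flat_d)])
    defined = ~np.isnan(scores)
    n_inc = int(defined.sum())
    n_exc = int(len(scores) - n_inc)
    pixel_score = float(scores[defined].mean()) if n_inc else math.nan
    return FitMetrics(
        ccc_well=ccc_well(model, data),
        ccc_pixel=pixel_score,
        n_pixels_included=n_inc,
        n_pixels_excluded=n_exc,
    )


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------


def write_well_series(
    series: WellSeries,
    path: str | Path,
    ns_stack: np.ndarray | None = None,
    nd_stack: np.ndarray | None = None,
) -> None:
    """Write one well to the hierarchical container (group /well_<id>)."""
    path = Path(path)
    with h5py.File(path, "a") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        name = f"well_{series.replicate_id}"
        if name in f:
            del f[name]
        g = f.create_group(name)
        g.create_dataset("times", data=series.times)
        g.create_dataset("Ntot", data=series.stack())
        if ns_stack is not None:
            g.create_dataset("Ns", data=ns_stack)
        if nd_stack is not None:
            g.create_dataset("Nd", data=nd_stack)
        g.attrs["dose_nM"] = series.dose
        g.attrs["t_dox_h"] = series.t_dox
        g.attrs["pixel_size_um"] = series.grid.pixel_size_um
        g.attrs["field_of_view_um"] = series.grid.field_of_view_um


def read_well_series(path: str | Path, replicate_id: int = 0) -> WellSeries:
    """Read one well back from the hierarchical container."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        name = f"well_{replicate_id}"
        if name not in f:
            raise SchemaError(f"missing group '{name}' in {path}")
        g = f[name]
        for key in ("times", "Ntot"):
            if key not in g:
                raise SchemaError(f"group '{name}' missing dataset '{key}'")
        for attr in ("dose_nM", "t_dox_h", "pixel_size_um"):
            if attr not in g.attrs:
                raise SchemaError(f"group '{name}' missing attribute '{attr}'")
        times = np.asarray(g["times"])
        stack = np.asarray(g["Ntot"])
        px = float(g.attrs["pixel_size_um"])
        n_rows, n_cols = stack.shape[1], stack.shape[2]
        grid = GridSpec(
            n_rows=n_rows, n_cols=n_cols, pixel_size_um=px,
            field_of_view_um=float(g.attrs.get("field_of_view_um", n_rows * px)),
        )
        maps = [DensityMap(stack[i], float(times[i]), grid) for i in range(len(times))]
        return WellSeries(
            maps=maps,
            dose=float(g.attrs["dose_nM"]),
            t_dox=float(g.attrs["t_dox_h"]),
            replicate_id=replicate_id,
        )


# ---------------------------------------------------------------------------
# Plain-text fallback
# ---------------------------------------------------------------------------


def write_well_series_text(series: WellSeries, directory: str | Path) -> None:
    """Per-timepoint TSV matrices plus a JSON manifest (lossless for
    integer-valued maps; floats written at full repr precision)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "dose_nM": series.dose,
        "t_dox_h": series.t_dox,
        "replicate_id": series.replicate_id,
        "pixel_size_um": series.grid.pixel_size_um,
        "field_of_view_um": series.grid.field_of_view_um,
        "times_h": [float(t) for t in series.times],
        "n_rows": series.grid.n_rows,
        "n_cols": series.grid.n_cols,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for i, m in enumerate(series.maps):
        np.savetxt(directory / f"map_{i:04d}.tsv", m.values, delimiter="\t", fmt="%.17g")


def read_well_series_text(directory: str | Path) -> WellSeries:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise SchemaError(f"missing manifest.json in {directory}")
    meta = json.loads(manifest_path.read_text())
    for key in ("dose_nM", "t_dox_h", "times_h", "pixel_size_um"):
        if key not in meta:
            raise SchemaError(f"manifest missing key '{key}'")
    grid = GridSpec(
        n_rows=meta["n_rows"], n_cols=meta["n_cols"],
        pixel_size_um=meta["pixel_size_um"],
        field_of_view_um=meta.get(
            "field_of_view_um", meta["n_rows"] * meta["pixel_size_um"]
        ),
    )
    maps = []
    for i, t in enumerate(meta["times_h"]):
        values = np.loadtxt(directory / f"map_{i:04d}.tsv", delimiter="\t", ndmin=2)
        maps.append(DensityMap(values, float(t), grid))
    return WellSeries(
        maps=maps, dose=float(meta["dose_nM"]), t_dox=float(meta["t_dox_h"]),
        replicate_id=int(meta.get("replicate_id", 0)),
    )


def write_centroid_table(table: CentroidTable, path: str | Path) -> None:
    """Delimited text with header time_h,x_um,y_um."""
    data = np.column_stack([table.time_h, table.x_um, table.y_um])
    np.savetxt(
        path, data, delimiter=",", header="time_h,x_um,y_um",
        comments="", fmt="%.10g",
    )


def read_centroid_table(path: str | Path) -> CentroidTable:
    path = Path(path)
    header = path.read_text().splitlines()[0].strip()
    if header != "time_h,x_um,y_um":
        raise SchemaError(f"unexpected centroid header: {header!r}")
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.size == 0:
        return CentroidTable(np.empty(0), np.empty(0), np.empty(0))
    return CentroidTable(data[:, 0], data[:, 1], data[:, 2])
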