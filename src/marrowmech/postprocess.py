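"""Surface-stress statistics: grid sampling, histograms, front tracking.

The biological readouts of the simulations are statistics of the surface
von Mises stress sigma_S on the outer vessel wall: its distribution on a
10 µm x 10 µm sampling grid of the unwrapped cylindrical surface, a
Gaussian fit to the area-weighted histogram, the fraction of surface area
above the 10 kPa osteogenic threshold, and the axial propagation speed
v_S of the travelling stress peak sigma_Smax during a stretch pulse.

Stresses enter in the solver unit (MPa) and are reported in kPa.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import MeshError, PostprocessError
from .geometry import VesselMesh
from .units import KPA_PER_MPA

__all__ = [
    "SurfaceStressSample",
    "StressSummary",
    "FrontTrace",
    "grid_sample",
    "fit_gaussian",
    "fraction_above",
    "track_front",
    "summarize",
]

DEFAULT_CELL = 10.0       # µm, sampling-grid cell edge
DEFAULT_BIN_WIDTH = 1.0   # kPa, histogram bin width
DEFAULT_THRESHOLD = 10.0  # kPa, osteogenic stress threshold


@dataclass
class SurfaceStressSample:
    """Per-cell sigma_S (kPa) on the unwrapped (z, arc) surface grid.

    ``values``/``areas`` are (n_axial_cells, n_circ_cells); empty cells
    carry zero area and are excluded from all statistics.
    """

    values: np.ndarray
    areas: np.ndarray
    cell_size: float
    z_edges: np.ndarray
    s_edges: np.ndarray
    mean_radius: float
    surface: str

    def __post_init__(self):
        if np.any(self.values[self.areas > 0] < 0):
            raise PostprocessError("surface stress values must be >= 0")

    @property
    def cell_values(self) -> np.ndarray:
        """Values of the populated cells, flattened."""
        return self.values[self.areas > 0]

    @property
    def cell_areas(self) -> np.ndarray:
        return self.areas[self.areas > 0]

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())


@dataclass
class StressSummary:
    """Histogram, Gaussian fit and threshold statistics of one sample.

    ``frequencies`` are area-weighted and sum to 1; ``mode``/``width`` are
    the fitted Gaussian (mu, sigma) in kPa, falling back to the empirical
    mode with ``fit_converged=False``.  ``degenerate`` marks a zero-spread
    field where no fit is meaningful.
    """

    bin_edges: np.ndarray
    frequencies: np.ndarray
    mode: float
    width: float
    amplitude: float
    fraction_above_threshold: float
    sigma_smax: float
    threshold: float = DEFAULT_THRESHOLD
    fit_converged: bool = True
    good_fit: bool = True
    r_squared: float = 1.0
    degenerate: bool = False
    front: Optional["FrontTrace"] = None

    def to_frame(self) -> pd.DataFrame:
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return pd.DataFrame({"bin_center_kPa": centers,
                             "frequency": self.frequencies})


@dataclass
class FrontTrace:
    """Axial position of the travelling sigma_Smax peak over time."""

    times: np.ndarray              # µs
    positions: np.ndarray          # µm, axial coordinate of the peak
    peak_values: np.ndarray        # kPa, sigma_Smax(t)
    velocity: float                # µm/µs, (last - first) / elapsed
    interval_velocities: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_us": self.times,
                             "position_um": self.positions,
                             "sigma_smax_kPa": self.peak_values})


def _surface_facet_data(mesh: VesselMesh, surface: str):
    """Triangles, centroids and areas of a surface facet set."""
    if surface not in mesh.surface_sets:
        raise MeshError(f"unknown surface set {surface!r}")
    facets = mesh.surface_sets[surface]
    tri = mesh.facet_triangles(surface)
    x = mesh.nodes[tri]
    centroids = x.mean(axis=1)
    areas = 0.5 * np.linalg.norm(
        np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]), axis=1)
    return facets[:, 0], centroids, areas


def _facet_values_kpa(values_mpa: np.ndarray, parent_tets: np.ndarray) -> np.ndarray:
    values_mpa = np.asarray(values_mpa, dtype=float)
    if values_mpa.ndim != 1:
        raise PostprocessError("expected one value per element")
    return KPA_PER_MPA * values_mpa[parent_tets]


def grid_sample(values_mpa: np.ndarray, mesh: VesselMesh,
                surface: str = "outer_wall",
                cell: float = DEFAULT_CELL) -> SurfaceStressSample:
    """Area-average a per-element field onto the unwrapped surface grid.

    ``values_mpa`` is indexed by global tet id (MPa, as produced by the
    solvers); each surface facet takes its parent element's value and is
    binned by its centroid into cells of size ``cell`` on the (axial z,
    circumferential arc s = r_mean * angle) plane.  Output values are kPa.

    Raises :class:`PostprocessError` if the surface is not topologically
    cylindrical around the z axis (unwrap would fold); facet-level
    statistics on ``values_mpa`` directly are the fallback in that case.
    """
    if cell <= 0:
        raise PostprocessError("cell size must be positive")
    parents, centroids, areas = _surface_facet_data(mesh, surface)
    radii = np.linalg.norm(centroids[:, :2], axis=1)
    r_mean = float(np.average(radii, weights=areas))
    if r_mean <= 0 or np.any(radii < 0.2 * r_mean) or radii.max() > 3.0 * r_mean:
        raise PostprocessError(
            f"surface {surface!r} is not cylindrical about the z axis; "
            "unwrapping is ill-defined — compute facet-level statistics "
            "on the raw element values instead")
    z = centroids[:, 2]
    z0, z1 = float(z.min()), float(z.max())
    if z1 - z0 <= 0:
        raise PostprocessError(
            f"surface {surface!r} has no axial extent and cannot be "
            "unwrapped; compute facet-level statistics on the raw element "
            "values instead")
    length = z1 - z0
    circumference = 2.0 * np.pi * r_mean
    n_z = int(np.ceil(length / cell - 1e-9))
    n_s = int(np.ceil(circumference / cell - 1e-9))
    z_edges = z0 + np.arange(n_z + 1) * (length / n_z)
    s_edges = np.arange(n_s + 1) * (circumference / n_s)

    angle = np.mod(np.arctan2(centroids[:, 1], centroids[:, 0]), 2.0 * np.pi)
    s = r_mean * angle
    iz = np.clip(((z - z0) / (length / n_z)).astype(int), 0, n_z - 1)
    isarc = np.clip((s / (circumference / n_s)).astype(int), 0, n_s - 1)

    vals = _facet_values_kpa(values_mpa, parents)
    area_grid = np.zeros((n_z, n_s))
    accum = np.zeros((n_z, n_s))
    np.add.at(area_grid, (iz, isarc), areas)
    np.add.at(accum, (iz, isarc), areas * vals)
    value_grid = np.zeros_like(accum)
    mask = area_grid > 0
    value_grid[mask] = accum[mask] / area_grid[mask]
    return SurfaceStressSample(values=value_grid, areas=area_grid,
                               cell_size=cell, z_edges=z_edges,
                               s_edges=s_edges, mean_radius=r_mean,
                               surface=surface)


def fraction_above(sample: SurfaceStressSample,
                   threshold: float = DEFAULT_THRESHOLD,
                   weight: str = "area") -> float:
    """Fraction of the surface with sigma_S >= ``threshold`` (kPa).

    ``weight="area"`` (default) weights cells by their sampled area;
    ``weight="count"`` counts cells equally.
    """
    vals = sample.cell_values
    if vals.size == 0:
        raise PostprocessError("sample has no populated cells")
    above = vals >= threshold
    if weight == "count":
        return float(above.mean())
    if weight != "area":
        raise ValueError("weight must be 'area' or 'count'")
    areas = sample.cell_areas
    return float(areas[above].sum() / areas.sum())


def _gaussian(x, amp, mu, sig):
    return amp * np.exp(-0.5 * ((x - mu) / sig) ** 2)


def fit_gaussian(sample: SurfaceStressSample,
                 bin_width: float = DEFAULT_BIN_WIDTH,
                 threshold: float = DEFAULT_THRESHOLD) -> StressSummary:
    """Least-squares Gaussian on the area-weighted sigma_S histogram.

    The fitted mean is reported as the distribution mode.  When the data
    range spans fewer than 6 bins the requested width cannot resolve a
    peak, so the bin width is refined to range/12 (a narrow distribution
    on a coarse axis would otherwise reduce to an unfittable spike).  A
    fit that does not converge falls back to the empirical mode
    (histogram peak) with a warning and ``fit_converged=False``; a
    visibly non-Gaussian shape keeps the fit but clears ``good_fit``.  A
    zero-spread field raises :class:`PostprocessError` (use
    :func:`summarize` for the tolerant path).
    """
    vals = sample.cell_values
    areas = sample.cell_areas
    if vals.size < 10:
        raise PostprocessError(
            f"need at least 10 populated cells for a fit (got {vals.size})")
    spread = float(np.ptp(vals))
    if spread <= 1e-12:
        raise PostprocessError(
            "degenerate stress distribution: all sampled cells are equal; "
            "no Gaussian fit is possible")
    if spread / bin_width < 6.0:
        bin_width = spread / 12.0
    lo = bin_width * np.floor(vals.min() / bin_width)
    hi = bin_width * np.ceil(vals.max() / bin_width + 1e-9)
    n_bins = max(3, int(round((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    freq, _ = np.histogram(vals, bins=edges, weights=areas)
    freq = freq / freq.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])

    w_mean = float(np.average(vals, weights=areas))
    w_std = float(np.sqrt(np.average((vals - w_mean) ** 2, weights=areas)))
    emp_mode = float(centers[np.argmax(freq)])
    p0 = (float(freq.max()), emp_mode, max(w_std, bin_width))
    bounds = ([1e-12, lo - spread, 0.25 * bin_width],
              [2.0 * float(freq.max()), hi + spread, 4.0 * spread])
    converged = True
    try:
        popt, _ = curve_fit(_gaussian, centers, freq, p0=p0, maxfev=20000,
                            bounds=bounds)
        amp, mu, sig = float(popt[0]), float(popt[1]), abs(float(popt[2]))
        if not np.all(np.isfinite(popt)) or amp <= 0:
            raise RuntimeError("non-finite fit")
    except RuntimeError:
        warnings.warn("Gaussian fit did not converge; reporting the "
                      "empirical histogram mode", stacklevel=2)
        converged = False
        amp, mu, sig = p0[0], emp_mode, w_std
    resid = freq - _gaussian(centers, amp, mu, sig)
    ss_tot = float(np.sum((freq - freq.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
    return StressSummary(
        bin_edges=edges, frequencies=freq, mode=mu, width=sig, amplitude=amp,
        fraction_above_threshold=fraction_above(sample, threshold),
        sigma_smax=float(vals.max()), threshold=threshold,
        fit_converged=converged, good_fit=converged and r2 >= 0.8,
        r_squared=r2)


def track_front(series, mesh: VesselMesh, surface: str = "outer_wall",
                loaded_end: str = "end_A") -> FrontTrace:
    """Axial position of the global outer-surface stress maximum over time.

    The front position at each snapshot is the centroid z of the facet
    carrying the largest sigma_S; ties resolve to the position farthest
    from the loaded end.  ``velocity`` is the end-to-end average
    (z_last - z_first) / elapsed time; per-interval velocities are also
    reported.
    """
    if len(series.times) < 2:
        raise PostprocessError("front tracking needs at least 2 snapshots")
    parents, centroids, _ = _surface_facet_data(mesh, surface)
    z = centroids[:, 2]
    if loaded_end not in mesh.node_sets:
        raise MeshError(f"unknown node set {loaded_end!r} for loaded_end")
    z_loaded = float(mesh.nodes[mesh.node_sets[loaded_end], 2].mean())

    positions, peaks = [], []
    for vm in series.von_mises:
        vals = _facet_values_kpa(vm, parents)
        vmax = vals.max()
        if vmax <= 0.0:
            raise PostprocessError(
                "stress field is identically zero on the surface; the "
                "front position is undefined")
        near = np.where(vals >= vmax * (1.0 - 1e-12))[0]
        pick = near[np.argmax(np.abs(z[near] - z_loaded))]
        positions.append(float(z[pick]))
        peaks.append(float(vmax))
    times = np.asarray(series.times, dtype=float)
    positions = np.asarray(positions)
    elapsed = times[-1] - times[0]
    if elapsed <= 0:
        raise PostprocessError("snapshot times must be strictly increasing")
    velocity = float(abs(positions[-1] - positions[0]) / elapsed)
    interval = np.abs(np.diff(positions)) / np.diff(times)
    return FrontTrace(times=times, positions=positions,
                      peak_values=np.asarray(peaks), velocity=velocity,
                      interval_velocities=interval)


def summarize(result, mesh: VesselMesh, surface: str = "outer_wall",
              cell: float = DEFAULT_CELL, bin_width: float = DEFAULT_BIN_WIDTH,
              threshold: float = DEFAULT_THRESHOLD,
              loaded_end: str = "end_A") -> StressSummary:
    """One-stop report for a static state or a dynamic series.

    sigma_Smax is the maximum over the sampled surface (and over time for a
    dynamic series, whose peak-stress snapshot is the one summarised and
    whose front trace is attached).  Zero-spread fields return a summary
    with ``degenerate=True`` instead of raising.
    """
    front = None
    if hasattr(result, "von_mises") and isinstance(result.von_mises, list):
        peaks = [grid_sample(vm, mesh, surface, cell) for vm in result.von_mises]
        maxima = [s.cell_values.max() if s.cell_values.size else 0.0 for s in peaks]
        sample = peaks[int(np.argmax(maxima))]
        sigma_smax = float(max(maxima))
        if sigma_smax > 0.0 and len(result.times) >= 2:
            front = track_front(result, mesh, surface, loaded_end)
    else:
        sample = grid_sample(result.von_mises, mesh, surface, cell)
        sigma_smax = float(sample.cell_values.max()) if sample.cell_values.size else 0.0

    vals = sample.cell_values
    if vals.size == 0 or np.ptp(vals) <= 1e-12:
        v0 = float(vals[0]) if vals.size else 0.0
        edges = np.array([v0 - 0.5 * bin_width, v0 + 0.5 * bin_width])
        return StressSummary(
            bin_edges=edges, frequencies=np.array([1.0]), mode=v0, width=0.0,
            amplitude=1.0,
            fraction_above_threshold=(float(v0 >= threshold) if vals.size else 0.0),
            sigma_smax=sigma_smax, threshold=threshold, fit_converged=False,
            good_fit=False, r_squared=0.0, degenerate=True, front=front)
    summary = fit_gaussian(sample, bin_width=bin_width, threshold=threshold)
    summary.sigma_smax = sigma_smax
    summary.front = front
    return summary
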