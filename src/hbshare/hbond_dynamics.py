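"""Hydrogen-bond distance time series, running averages, and water RDFs.

The radial distribution function g(r) normalizes per-frame shell counts by
the ideal-gas expectation 4π r² Δr ρ_bulk evaluated at bin centers
r_k = (k + ½)Δr.  The bulk density can be given explicitly (Å⁻³) or derived
from the box as N_targets / V averaged over frames (``"from-box"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .errors import ParameterError, SamplingError
from .trajectory_io import Trajectory, minimum_image_displacement

__all__ = [
    "DistanceSeries",
    "TimeSeries",
    "RDFProfile",
    "distance_series",
    "running_average",
    "rdf",
]


@dataclass
class TimeSeries:
    times: np.ndarray
    values: np.ndarray


@dataclass
class DistanceSeries(TimeSeries):
    pair: tuple[int, int] = (0, 1)
    running_window: Optional[float] = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0

    @property
    def standard_error(self) -> float:
        return self.sd / np.sqrt(len(self.values))


@dataclass
class RDFProfile:
    r_centers: np.ndarray     # Å
    g: np.ndarray             # dimensionless
    bin_width: float          # Å
    bulk_density: float       # Å^-3
    n_frames: int
    counts: np.ndarray = None  # raw per-bin counts summed over frames


def distance_series(traj: Trajectory, i: int, j: int) -> DistanceSeries:
    """Per-frame Euclidean distance (Å) between atoms i and j.

    Uses the minimum-image convention for frames that carry a box.
    """
    if i == j:
        raise ParameterError("distance requires two distinct atoms")
    n = traj.n_atoms
    if not (0 <= i < n and 0 <= j < n):
        raise ParameterError(f"atom indices ({i}, {j}) out of range for {n} atoms")
    values = np.empty(traj.n_frames)
    for k, fr in enumerate(traj.frames):
        delta = minimum_image_displacement(
            fr.coordinates[j] - fr.coordinates[i], fr.box
        )
        values[k] = np.sqrt((delta**2).sum())
    return DistanceSeries(times=traj.times, values=values, pair=(i, j))


def running_average(
    series: Union[TimeSeries, DistanceSeries], window: float, rtol: float = 1e-6
) -> TimeSeries:
    """Centered moving mean over a time window (fs), hard edges, no padding.

    Output length is the input length minus the window span in samples; the
    reported times are the window-center times, so an even sample count per
    window yields points halfway between input samples.
    """
    times = np.asarray(series.times, dtype=float)
    values = np.asarray(series.values, dtype=float)
    if len(times) < 2:
        raise SamplingError("need at least two samples")
    spacing = np.diff(times)
    dt = spacing.mean()
    if dt <= 0 or np.any(np.abs(spacing - dt) > rtol * max(abs(dt), 1.0)):
        raise SamplingError("samples must be equally spaced")
    if window < dt:
        raise ParameterError(f"window {window} fs is below the sample spacing {dt} fs")
    k = max(1, int(round(window / dt)))
    if k > len(values):
        raise ParameterError("window longer than the series")
    kernel = np.full(k, 1.0 / k)
    out_vals = np.convolve(values, kernel, mode="valid")
    out_times = np.convolve(times, kernel, mode="valid")
    return TimeSeries(times=out_times, values=out_vals)


def rdf(
    traj: Trajectory,
    center: int,
    targets: Sequence[int],
    bin_width: float = 0.1,
    r_max: float = 10.0,
    bulk_density: Union[float, str] = "from-box",
) -> RDFProfile:
    """Radial distribution function of ``targets`` around ``center``.

    g(r) = <shell count> / (4π r² Δr ρ_bulk), averaged over frames, with r at
    bin centers.  ``bulk_density="from-box"`` uses N_targets/V averaged over
    frames and requires every frame to have a box.
    """
    targets = [t for t in targets if t != center]
    if not targets:
        raise ParameterError("no target atoms")
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    if r_max <= bin_width:
        raise ParameterError("r_max must exceed bin_width")
    n_bins = int(np.ceil(r_max / bin_width))
    edges = bin_width * np.arange(n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    counts = np.zeros(n_bins)
    densities = []
    for fr in traj.frames:
        delta = fr.coordinates[targets] - fr.coordinates[center]
        delta = minimum_image_displacement(delta, fr.box)
        dist = np.sqrt((delta**2).sum(axis=1))
        hist, _ = np.histogram(dist, bins=edges)
        counts += hist
        if bulk_density == "from-box":
            if fr.box is None:
                raise ParameterError(
                    "bulk_density='from-box' requires every frame to have a box"
                )
            densities.append(len(targets) / np.prod(fr.box))
    if bulk_density == "from-box":
        rho_bulk = float(np.mean(densities))
    else:
        rho_bulk = float(bulk_density)
        if rho_bulk <= 0:
            raise ParameterError("bulk_density must be > 0")
    shell = 4.0 * np.pi * centers**2 * bin_width
    g = counts / (traj.n_frames * shell * rho_bulk)
    return RDFProfile(
        r_centers=centers,
        g=g,
        bin_width=bin_width,
        bulk_density=rho_bulk,
        n_frames=traj.n_frames,
        counts=counts,
    )
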