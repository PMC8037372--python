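"""Proton-sharing reaction coordinate, hop detection, P(ξ), and the PMF.

For a donor–H–acceptor triplet the proton-sharing coordinate is

    ξ = d(O_donor···H) − d(H···O_acceptor)   [Å]

so ξ = 0 means the proton sits equidistant between the two oxygens, negative
ξ means it is closer to the donor oxygen, and positive ξ closer to the
acceptor.  The potential of mean force along ξ follows from the sampled
probability density by Boltzmann inversion, A(ξ) = −k_B T ln P(ξ), shifted so
its minimum is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .constants import KB_KCAL_PER_MOL_K, ROOM_TEMPERATURE_K
from .errors import (
    DegenerateDistributionError,
    FitError,
    GeometryError,
    ParameterError,
)
from .trajectory_io import Frame, Trajectory, minimum_image_displacement

__all__ = [
    "HBondTriplet",
    "XiSeries",
    "HistogramDensity",
    "GaussianFit",
    "PMFProfile",
    "HopEvent",
    "xi_value",
    "xi_series",
    "detect_hops",
    "histogram_xi",
    "fit_gaussian",
    "boltzmann_invert",
]


@dataclass(frozen=True)
class HBondTriplet:
    """Donor oxygen / shared hydrogen / acceptor oxygen atom indices."""

    donor_O: int
    hydrogen: int
    acceptor_O: int
    labels: tuple[str, str, str] = ("O_donor", "H", "O_acceptor")

    def __post_init__(self):
        if len({self.donor_O, self.hydrogen, self.acceptor_O}) != 3:
            raise ParameterError("triplet indices must be distinct")


@dataclass
class XiSeries:
    times: np.ndarray
    xi: np.ndarray
    triplet: HBondTriplet

    @property
    def mean(self) -> float:
        return float(np.mean(self.xi))

    @property
    def sd(self) -> float:
        return float(np.std(self.xi, ddof=1))


@dataclass
class HistogramDensity:
    """Normalized histogram: sum(density * width) == 1."""

    edges: np.ndarray      # Å, bin edges aligned so that 0 is an edge
    density: np.ndarray    # Å^-1
    n_samples: int

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)


@dataclass
class GaussianFit:
    mu: float
    sigma: float
    fit_residual: float
    moment_mu: float = float("nan")
    moment_sigma: float = float("nan")


@dataclass
class PMFProfile:
    xi_grid: np.ndarray      # Å (only bins where A is defined; gaps excluded)
    A: np.ndarray            # kcal/mol, shifted so min(A) = 0
    temperature: float       # K
    minimum_xi: float        # Å


@dataclass(frozen=True)
class HopEvent:
    time: float
    direction: int  # +1: crossed from donor side to acceptor side; -1: reverse


def _distance(frame: Frame, i: int, j: int) -> float:
    delta = minimum_image_displacement(
        frame.coordinates[j] - frame.coordinates[i], frame.box
    )
    return float(np.sqrt((delta**2).sum()))


def xi_value(frame: Frame, triplet: HBondTriplet) -> float:
    """ξ = d(donor_O, H) − d(H, acceptor_O) for one frame, in Å."""
    d_dh = _distance(frame, triplet.donor_O, triplet.hydrogen)
    d_ha = _distance(frame, triplet.hydrogen, triplet.acceptor_O)
    if d_dh == 0.0 or d_ha == 0.0:
        raise GeometryError("coincident atom positions in triplet")
    return d_dh - d_ha


def xi_series(traj: Trajectory, triplet: HBondTriplet) -> XiSeries:
    """Evaluate ξ on every frame of a trajectory."""
    xi = np.array([xi_value(fr, triplet) for fr in traj.frames])
    return XiSeries(times=traj.times, xi=xi, triplet=triplet)


def detect_hops(series: XiSeries, hysteresis: float = 0.05) -> list[HopEvent]:
    """Proton-hop events via a two-threshold Schmitt trigger on ξ.

    A hop is recorded when ξ crosses from below −hysteresis to above
    +hysteresis or vice versa; excursions that never clear the far threshold
    are not hops.  The event count is invariant under time reversal.
    """
    if hysteresis < 0:
        raise ParameterError("hysteresis must be >= 0")
    state = 0  # -1: donor side, +1: acceptor side, 0: undetermined
    events: list[HopEvent] = []
    for t, x in zip(series.times, series.xi):
        if x > hysteresis or (hysteresis == 0 and x > 0):
            if state == -1:
                events.append(HopEvent(time=float(t), direction=+1))
            state = +1
        elif x < -hysteresis or (hysteresis == 0 and x < 0):
            if state == +1:
                events.append(HopEvent(time=float(t), direction=-1))
            state = -1
    return events


def histogram_xi(
    series: Union[XiSeries, np.ndarray], bin_width: float = 0.01
) -> HistogramDensity:
    """Normalized P(ξ) histogram with edges aligned so 0 is a bin edge."""
    xi = series.xi if isinstance(series, XiSeries) else np.asarray(series, dtype=float)
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    if xi.size < 2:
        raise ParameterError("need at least 2 samples")
    if np.ptp(xi) == 0:
        raise DegenerateDistributionError("all samples identical")
    lo = np.floor(xi.min() / bin_width)
    hi = np.ceil(xi.max() / bin_width)
    if hi == xi.max() / bin_width:  # max exactly on an edge: open one more bin
        hi += 1
    edges = bin_width * np.arange(lo, hi + 1)
    density, edges = np.histogram(xi, bins=edges, density=True)
    return HistogramDensity(edges=edges, density=density, n_samples=int(xi.size))


def _gauss_pdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-((x - mu) ** 2) / (2.0 * sigma**2)) / (sigma * np.sqrt(2 * np.pi))


def fit_gaussian(hist: HistogramDensity) -> GaussianFit:
    """Nonlinear least-squares fit of a normal density to the histogram.

    Moment-based estimates (histogram mean/sd) seed the fit and are always
    reported for cross-checking.  ``fit_residual`` is the RMS misfit divided
    by the peak density (dimensionless); a unimodal Gaussian sample gives a
    small value, multimodal data a large one.
    """
    nonzero = int(np.count_nonzero(hist.density))
    if nonzero < 5:
        raise ParameterError(f"need >= 5 nonzero bins, got {nonzero}")
    c, d, w = hist.centers, hist.density, hist.widths
    moment_mu = float(np.sum(c * d * w))
    moment_var = float(np.sum((c - moment_mu) ** 2 * d * w))
    moment_sigma = float(np.sqrt(moment_var))
    from scipy.optimize import curve_fit

    try:
        popt, _ = curve_fit(
            _gauss_pdf,
            c,
            d,
            p0=[moment_mu, max(moment_sigma, 1e-6)],
            bounds=([-np.inf, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"gaussian fit failed: {exc}", moment_mu, moment_sigma) from exc
    mu, sigma = float(popt[0]), float(popt[1])
    resid = float(np.sqrt(np.mean((_gauss_pdf(c, mu, sigma) - d) ** 2)) / d.max())
    return GaussianFit(
        mu=mu,
        sigma=sigma,
        fit_residual=resid,
        moment_mu=moment_mu,
        moment_sigma=moment_sigma,
    )


def boltzmann_invert(
    P: Union[HistogramDensity, GaussianFit],
    temperature: float = ROOM_TEMPERATURE_K,
    grid_points: int = 1001,
    grid_halfwidth_sigmas: float = 5.0,
) -> PMFProfile:
    """Potential of mean force A(ξ) = −k_B T ln P(ξ), shifted to min(A) = 0.

    For a histogram input, empty bins are gaps: they are excluded from the
    reported grid so A is finite everywhere it is reported (never ±inf).  For
    a Gaussian-fit input the profile is analytic on a grid of
    ``grid_points`` spanning μ ± ``grid_halfwidth_sigmas``·σ, and the minimum
    location is exactly μ.
    """
    if temperature <= 0:
        raise ParameterError("temperature must be > 0")
    kbt = KB_KCAL_PER_MOL_K * temperature
    if isinstance(P, GaussianFit):
        grid = P.mu + P.sigma * np.linspace(
            -grid_halfwidth_sigmas, grid_halfwidth_sigmas, grid_points
        )
        # −kbT ln N(ξ; μ, σ) shifted: the constant drops, the quadratic stays
        A = kbt * (grid - P.mu) ** 2 / (2.0 * P.sigma**2)
        return PMFProfile(xi_grid=grid, A=A, temperature=temperature, minimum_xi=P.mu)
    mask = P.density > 0
    if not mask.any():
        raise ParameterError("zero density everywhere; nothing to invert")
    grid = P.centers[mask]
    A = -kbt * np.log(P.density[mask])
    A = A - A.min()
    minimum_xi = float(grid[np.argmin(A)])
    return PMFProfile(xi_grid=grid, A=A, temperature=temperature, minimum_xi=minimum_xi)
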