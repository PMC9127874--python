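"""Fluorescence correlation spectroscopy: autocorrelation and 2D-diffusion fit.

The fluctuation autocorrelation of an intensity trace F(t),

    G(tau) = <dF(t) dF(t+tau)> / <F>^2,      dF = F - <F>,

is evaluated on a quasi-logarithmic (multiple-tau style) lag grid.  Each
G(tau) is computed by the direct estimator on the raw, unbinned trace, so
the curve agrees exactly with the brute-force definition at every lag; the
logarithmic grid only thins the lags.  For membrane (2D) diffusion through
a Gaussian observation area the model is

    G(tau) = G0 / (1 + tau / tau_D),      N = 1 / G0,

with tau_D = w0^2 / (4 D) and the mean particle number N referred to the
effective observation area pi * w0^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitFailureError, InsufficientDataError, InvalidParameterError

__all__ = [
    "FCSTrace",
    "AutocorrelationCurve",
    "FCSFit",
    "multiple_tau_lags",
    "autocorrelate",
    "fit_fcs_2d",
    "density_from_intensity",
]


@dataclass
class FCSTrace:
    """Photon-count time series sampled at a fixed interval (seconds)."""

    samples: np.ndarray
    sampling_dt: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_dt <= 0:
            raise InvalidParameterError("sampling_dt must be > 0")
        if np.any(self.samples < 0):
            raise InvalidParameterError("photon counts must be >= 0")

    @property
    def duration(self) -> float:
        return len(self.samples) * self.sampling_dt


@dataclass
class AutocorrelationCurve:
    lags: np.ndarray  # s, strictly increasing, lag 0 excluded
    G: np.ndarray
    n_segments: int = 1
    G_sd: np.ndarray | None = None
    zero_variance: bool = False


@dataclass
class FCSFit:
    N: float
    tau_D: float
    G0: float
    density: float  # particles / µm²
    obs_area: float  # µm²
    r2: float


def multiple_tau_lags(n_cascades: int, points_per_cascade: int) -> np.ndarray:
    """Quasi-logarithmic lag grid in samples: dense first cascade, then
    ``points_per_cascade // 2`` lags per cascade with doubling spacing."""
    if n_cascades < 1 or points_per_cascade < 2:
        raise InvalidParameterError("need n_cascades >= 1, points_per_cascade >= 2")
    lags = list(range(1, points_per_cascade + 1))
    for c in range(1, n_cascades):
        spacing = 2**c
        for _ in range(points_per_cascade // 2):
            lags.append(lags[-1] + spacing)
    return np.asarray(lags, dtype=int)


def _direct_G(x: np.ndarray, lags: np.ndarray) -> np.ndarray:
    mean = x.mean()
    if mean == 0.0 or np.ptp(x) == 0.0:
        return np.zeros(len(lags))
    d = x - mean
    out = np.empty(len(lags))
    n = len(x)
    for i, lag in enumerate(lags):
        out[i] = np.dot(d[:-lag], d[lag:]) / (n - lag) / mean**2
    return out


def autocorrelate(
    trace: FCSTrace,
    n_cascades: int = 8,
    points_per_cascade: int = 16,
    n_segments: int = 1,
) -> AutocorrelationCurve:
    """Normalized fluctuation autocorrelation on a multiple-tau lag grid.

    With ``n_segments > 1`` the trace is split into equal segments, G is
    computed per segment and averaged, and the across-segment SD reported.
    A constant trace yields G == 0 with ``zero_variance`` set.
    """
    x = trace.samples
    if len(x) < 2**n_cascades * points_per_cascade:
        raise InvalidParameterError(
            "trace too short for requested cascades "
            f"({len(x)} < {2**n_cascades * points_per_cascade})"
        )
    lags = multiple_tau_lags(n_cascades, points_per_cascade)
    if np.ptp(x) == 0.0:
        return AutocorrelationCurve(
            lags=lags * trace.sampling_dt, G=np.zeros(len(lags)),
            n_segments=n_segments, G_sd=np.zeros(len(lags)), zero_variance=True,
        )
    seg_len = len(x) // n_segments
    lags = lags[lags < seg_len // 2]
    if len(lags) == 0:
        raise InvalidParameterError("segments too short for the lag grid")
    per_seg = np.stack(
        [_direct_G(x[k * seg_len:(k + 1) * seg_len], lags) for k in range(n_segments)]
    )
    G = per_seg.mean(axis=0)
    sd = per_seg.std(axis=0, ddof=1) if n_segments > 1 else np.zeros(len(lags))
    return AutocorrelationCurve(
        lags=lags * trace.sampling_dt, G=G, n_segments=n_segments, G_sd=sd,
    )


def fit_fcs_2d(
    curve: AutocorrelationCurve,
    obs_area: float | None = None,
    beam_waist: float = 0.25,
) -> FCSFit:
    """Fit ``G(tau) = G0 / (1 + tau/tau_D)`` and convert to particle density.

    ``obs_area`` defaults to ``pi * beam_waist**2`` (µm²; beam waist is the
    1/e² radius of the observation profile).
    """
    if obs_area is None:
        obs_area = math.pi * beam_waist**2
    if obs_area <= 0:
        raise InvalidParameterError("obs_area must be > 0")
    lags = np.asarray(curve.lags, dtype=float)
    G = np.asarray(curve.G, dtype=float)
    if len(lags) < 8:
        raise InsufficientDataError("need at least 8 lag points")
    if curve.zero_variance or np.mean(G[:3]) <= 0:
        raise FitFailureError("no positive correlation amplitude at small lags")

    def model(tau, G0, tau_D):
        return G0 / (1.0 + tau / tau_D)

    g0_guess = float(np.mean(G[:3]))
    below = lags[G < g0_guess / 2.0]
    tau_guess = float(below[0]) if len(below) else float(lags[len(lags) // 2])
    try:
        popt, _ = curve_fit(
            model, lags, G, p0=(g0_guess, tau_guess),
            bounds=((0.0, 0.0), (np.inf, np.inf)), maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological input
        raise FitFailureError(f"autocorrelation fit did not converge: {exc}") from exc
    G0, tau_D = float(popt[0]), float(popt[1])
    if G0 <= 0:
        raise FitFailureError(f"non-positive fitted amplitude G0={G0}")
    resid = G - model(lags, *popt)
    ss_tot = np.sum((G - G.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
    N = 1.0 / G0
    return FCSFit(N=N, tau_D=tau_D, G0=G0, density=N / obs_area,
                  obs_area=obs_area, r2=float(r2))


def density_from_intensity(
    total_signal: float, area: float, per_particle_brightness: float
) -> float:
    """Surface density from total signal: (signal / brightness) / area.

    The intensity-based alternative to the 1/G0 particle-number route; the
    two agree when the brightness calibration is consistent.
    """
    if area <= 0 or per_particle_brightness <= 0:
        raise InvalidParameterError("area and brightness must be > 0")
    if total_signal < 0:
        raise InvalidParameterError("total_signal must be >= 0")
    return (total_signal / per_particle_brightness) / area
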