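"""Per-track mobility analysis and population-level peak decomposition.

For each trajectory the time-averaged mean square displacement

    MSD(n dt) = < |r(t + n dt) - r(t)|^2 >_t

is computed over all ordered point pairs (gaps contribute at their true
time difference).  A linear fit of the first few lags gives the 2D
diffusion coefficient D = slope / 4 with a free intercept absorbing
localization noise.  Per-track Ds (or speeds) are then pooled and their
log10 distribution decomposed into one or two Gaussian components — the
"characteristic value" Ghat of each subpopulation is 10^(component mean),
the peak position of the log-binned histogram.  Model order (1 vs 2
components) is chosen by BIC.  Membrane dwell-time distributions are fitted
with a single exponential A exp(-t/tau).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.mixture import GaussianMixture

from .errors import InsufficientDataError, InvalidParameterError, TooShortTrackError

__all__ = [
    "MSDCurve",
    "DiffusionEstimate",
    "Peak",
    "PeakSet",
    "DwellFit",
    "compute_msd",
    "fit_diffusion",
    "compute_velocity",
    "log_binned_peaks",
    "fit_dwell_exponential",
]


@dataclass
class MSDCurve:
    lags: np.ndarray  # s, strictly increasing
    msd: np.ndarray  # µm²
    n_pairs: np.ndarray  # pair count per lag
    track_id: int | None = None


@dataclass
class DiffusionEstimate:
    D: float  # µm²/s
    intercept: float  # µm²
    r2: float
    n_lags_used: int
    track_id: int | None = None
    low_quality: bool = False


@dataclass
class Peak:
    G_hat: float  # characteristic value, µm²/s or µm/s
    weight: float
    log10_sd: float
    standard_error: float  # SE of G_hat on the linear scale


@dataclass
class PeakSet:
    peaks: list[Peak]  # sorted ascending by G_hat
    n_components: int
    bic_1: float
    bic_2: float
    n_values: int
    n_dropped: int = 0


@dataclass
class DwellFit:
    tau: float  # s
    amplitude: float
    sd_tau: float
    n_tracks: int
    r2: float
    ml_mean: float  # maximum-likelihood mean above the fit floor
    non_exponential: bool = False


def compute_msd(
    track,
    pixel_size: float,
    frame_interval: float,
    max_lag_fraction: float = 1.0,
) -> MSDCurve:
    """Time-averaged MSD of one trajectory over all ordered point pairs.

    ``track`` needs ``frames``, ``x`` and ``y`` (px).  Gapped tracks are
    handled by pairing at the true frame difference.  Lags above
    ``max_lag_fraction`` of the track duration are dropped.
    """
    frames = np.asarray(track.frames, dtype=int)
    if len(frames) < 3:
        raise TooShortTrackError("MSD needs at least 3 points")
    if not (0.0 < max_lag_fraction <= 1.0):
        raise InvalidParameterError("max_lag_fraction must be in (0, 1]")
    x = np.asarray(track.x, dtype=float) * pixel_size
    y = np.asarray(track.y, dtype=float) * pixel_size
    dframe = frames[None, :] - frames[:, None]
    sq = (x[None, :] - x[:, None]) ** 2 + (y[None, :] - y[:, None]) ** 2
    pos = dframe > 0
    diffs = dframe[pos]
    vals = sq[pos]
    max_lag = int(math.floor(max_lag_fraction * (frames[-1] - frames[0])))
    sel = diffs <= max_lag
    diffs, vals = diffs[sel], vals[sel]
    lags = np.unique(diffs)
    msd = np.empty(len(lags))
    n_pairs = np.empty(len(lags), dtype=int)
    for i, d in enumerate(lags):
        m = diffs == d
        msd[i] = vals[m].mean()
        n_pairs[i] = m.sum()
    return MSDCurve(
        lags=lags * frame_interval, msd=msd, n_pairs=n_pairs,
        track_id=getattr(track, "track_id", None),
    )


def fit_diffusion(msd: MSDCurve, n_lags: int = 4) -> DiffusionEstimate:
    """Linear MSD-vs-time fit over the first ``n_lags`` lags; D = slope/4.

    The intercept is free (localization-noise offset).  A negative slope is
    clamped to D = 0 and flagged ``low_quality`` rather than raised: short
    Brownian tracks legitimately produce them.
    """
    if n_lags < 2:
        raise InvalidParameterError("n_lags must be >= 2")
    if n_lags > len(msd.lags):
        raise InsufficientDataError(
            f"MSD curve has {len(msd.lags)} lags, need {n_lags}"
        )
    t = msd.lags[:n_lags]
    m = msd.msd[:n_lags]
    slope, intercept = np.polyfit(t, m, 1)
    pred = slope * t + intercept
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    r2 = 1.0 - float(np.sum((m - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    low = slope < 0
    return DiffusionEstimate(
        D=max(float(slope), 0.0) / 4.0, intercept=float(intercept), r2=r2,
        n_lags_used=n_lags, track_id=msd.track_id, low_quality=bool(low),
    )


def compute_velocity(track, pixel_size: float, frame_interval: float) -> float:
    """Mean instantaneous speed in µm/s.

    Defined as the mean over consecutive point pairs of displacement
    magnitude divided by the elapsed time (gaps use their true duration).
    For a Brownian track the expectation is the Rayleigh mean
    ``sqrt(pi D / dt)``.
    """
    frames = np.asarray(track.frames, dtype=float)
    if len(frames) < 2:
        raise TooShortTrackError("velocity needs at least 2 points")
    x = np.asarray(track.x, dtype=float) * pixel_size
    y = np.asarray(track.y, dtype=float) * pixel_size
    dt = np.diff(frames) * frame_interval
    disp = np.hypot(np.diff(x), np.diff(y))
    return float(np.mean(disp / dt))


def log_binned_peaks(
    values,
    n_bins: int = 30,
    max_components: int = 2,
    seed: int = 0,
    n_init: int = 10,
) -> PeakSet:
    """Characteristic-peak decomposition of a positive-valued distribution.

    Values are log10-transformed and fitted with Gaussian mixtures of 1 and
    2 components (k-means initialization, ``n_init`` restarts, best
    likelihood kept); the lower BIC selects the model.  Each peak position
    Ghat = 10^mean is the mode of the corresponding log-binned histogram
    component; its standard error comes from the within-component spread,
    ``log10_sd / sqrt(weight * n)``, propagated to the linear scale.
    Non-positive values are dropped and counted in ``n_dropped``.
    ``n_bins`` fixes the display-histogram resolution and is carried for
    reporting; the mixture is fitted to the raw log10 values.
    """
    vals = np.asarray(values, dtype=float)
    n_dropped = int(np.sum(~(vals > 0)))
    vals = vals[vals > 0]
    if len(vals) < 30:
        raise InsufficientDataError(f"need >= 30 positive values, got {len(vals)}")
    logv = np.log10(vals)
    if np.ptp(logv) < 1e-9:  # degenerate: all values identical
        g = float(10 ** logv[0])
        return PeakSet(
            peaks=[Peak(G_hat=g, weight=1.0, log10_sd=1e-3, standard_error=0.0)],
            n_components=1, bic_1=math.nan, bic_2=math.nan,
            n_values=len(vals), n_dropped=n_dropped,
        )
    X = logv.reshape(-1, 1)
    fits = {}
    bics = {}
    for k in range(1, max_components + 1):
        gm = GaussianMixture(
            n_components=k, covariance_type="full", n_init=n_init,
            init_params="k-means++", random_state=seed, reg_covar=1e-9,
        ).fit(X)
        fits[k] = gm
        bics[k] = float(gm.bic(X))
    best_k = min(bics, key=bics.get)
    gm = fits[best_k]
    order = np.argsort(gm.means_.ravel())
    peaks = []
    n = len(vals)
    for idx in order:
        mu = float(gm.means_[idx, 0])
        sd = float(math.sqrt(gm.covariances_[idx, 0, 0]))
        w = float(gm.weights_[idx])
        se_mu = sd / math.sqrt(max(w * n, 1.0))
        g = 10.0**mu
        peaks.append(
            Peak(G_hat=g, weight=w, log10_sd=max(sd, 1e-3),
                 standard_error=g * math.log(10.0) * se_mu)
        )
    return PeakSet(
        peaks=peaks, n_components=best_k,
        bic_1=bics.get(1, math.nan), bic_2=bics.get(2, math.nan),
        n_values=n, n_dropped=n_dropped,
    )


def fit_dwell_exponential(
    dwells,
    bin_width: float = 0.1,
    fit_floor: float = 0.0,
    r2_threshold: float = 0.8,
) -> DwellFit:
    """Exponential fit A exp(-t/tau) to the dwell-time frequency histogram.

    Bin centers sit on multiples of ``bin_width`` so frame-quantized dwell
    times fall at centers rather than edges; bins below ``fit_floor`` are
    excluded (robust to short-dwell truncation, since the exponential is
    memoryless).  The maximum-likelihood mean above the floor,
    ``mean(d | d >= floor) - floor``, is reported as a cross-check.  A fit
    with r² below ``r2_threshold`` (or too few occupied bins) is flagged
    ``non_exponential``.
    """
    d = np.asarray(dwells, dtype=float)
    if len(d) < 50:
        raise InsufficientDataError(f"need >= 50 dwell times, got {len(d)}")
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be > 0")
    above = d[d >= fit_floor]
    ml_mean = float(above.mean() - fit_floor) if len(above) else math.nan
    lo = math.floor(d.min() / bin_width) * bin_width - bin_width / 2.0
    edges = np.arange(lo, d.max() + bin_width, bin_width)
    counts, edges = np.histogram(d, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # keep empty bins inside the observed range (dropping them fattens the
    # tail) but drop the half-covered bin below the data minimum
    sel = (centers >= fit_floor) & (centers >= d.min()) & (centers <= d.max())
    t, c = centers[sel], counts[sel].astype(float)
    if np.count_nonzero(c) < 3:
        return DwellFit(tau=max(ml_mean, 1e-12), amplitude=float(c.max()) if len(c) else 0.0,
                        sd_tau=math.nan, n_tracks=len(d), r2=0.0,
                        ml_mean=ml_mean, non_exponential=True)

    def model(tt, A, tau):
        return A * np.exp(-tt / tau)

    p0 = (float(c.max()), max(ml_mean, bin_width))
    try:
        popt, pcov = curve_fit(model, t, c, p0=p0,
                               bounds=((0.0, 1e-12), (np.inf, np.inf)),
                               maxfev=10000)
    except RuntimeError:
        return DwellFit(tau=max(ml_mean, 1e-12), amplitude=p0[0], sd_tau=math.nan,
                        n_tracks=len(d), r2=0.0, ml_mean=ml_mean,
                        non_exponential=True)
    A, tau = (float(v) for v in popt)
    resid = c - model(t, *popt)
    ss_tot = float(np.sum((c - c.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    sd_tau = float(math.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else math.nan
    return DwellFit(tau=tau, amplitude=A, sd_tau=sd_tau, n_tracks=len(d),
                    r2=r2, ml_mean=ml_mean, non_exponential=r2 < r2_threshold)
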