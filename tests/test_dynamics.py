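"""MSD oracle equivalence, diffusion/velocity closed forms, peak decomposition,
dwell-time exponential fitting."""

import math
from types import SimpleNamespace

import numpy as np
import pytest

from nanotrack import brownian_tracks
from nanotrack.dynamics import (
    compute_msd,
    compute_velocity,
    fit_diffusion,
    fit_dwell_exponential,
    log_binned_peaks,
)
from nanotrack.errors import (
    InsufficientDataError,
    InvalidParameterError,
    TooShortTrackError,
)


def _track(frames, x, y):
    return SimpleNamespace(frames=np.asarray(frames), x=np.asarray(x, float),
                           y=np.asarray(y, float), track_id=0)


def _msd_oracle(track, pixel_size, dt, max_lag_fraction=1.0):
    """Brute-force all-ordered-pairs time-averaged MSD."""
    frames = list(track.frames)
    xs = [v * pixel_size for v in track.x]
    ys = [v * pixel_size for v in track.y]
    acc = {}
    max_lag = max_lag_fraction * (frames[-1] - frames[0])
    for i in range(len(frames)):
        for j in range(i + 1, len(frames)):
            lag = frames[j] - frames[i]
            if lag > max_lag:
                continue
            acc.setdefault(lag, []).append(
                (xs[j] - xs[i]) ** 2 + (ys[j] - ys[i]) ** 2
            )
    lags = sorted(acc)
    return (np.array(lags, float) * dt,
            np.array([np.mean(acc[d]) for d in lags]),
            np.array([len(acc[d]) for d in lags]))


@pytest.mark.parametrize("seed", range(5))
def test_msd_equals_brute_force_oracle(seed):
    """Implementation is bit-exact against the double-loop oracle,
    including gapped tracks."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 21))
    frames = np.sort(rng.choice(np.arange(3 * n), size=n, replace=False))
    tr = _track(frames, rng.normal(0, 2, n), rng.normal(0, 2, n))
    curve = compute_msd(tr, pixel_size=0.1, frame_interval=0.1)
    lags, msd, n_pairs = _msd_oracle(tr, 0.1, 0.1)
    assert np.array_equal(curve.lags, lags)
    assert np.array_equal(curve.n_pairs, n_pairs)
    assert np.array_equal(curve.msd, msd)


def test_msd_stationary_track_is_zero():
    tr = _track(range(10), np.ones(10), np.ones(10))
    assert np.all(compute_msd(tr, 0.1, 0.1).msd == 0.0)


def test_msd_ballistic_closed_form():
    v = 2.0  # px / frame
    tr = _track(range(10), v * np.arange(10), np.zeros(10))
    curve = compute_msd(tr, pixel_size=1.0, frame_interval=1.0)
    assert np.allclose(curve.msd, (v * curve.lags) ** 2)


def test_msd_too_short_track_rejected():
    with pytest.raises(TooShortTrackError):
        compute_msd(_track([0, 1], [0, 1], [0, 1]), 0.1, 0.1)


def test_fit_diffusion_exact_line_and_offset():
    lags = np.arange(1, 8) * 0.1
    from nanotrack.dynamics import MSDCurve
    curve = MSDCurve(lags=lags, msd=4 * 0.01 * lags, n_pairs=np.full(7, 10))
    est = fit_diffusion(curve, n_lags=4)
    assert est.D == pytest.approx(0.01, abs=1e-12)
    assert est.intercept == pytest.approx(0.0, abs=1e-12)
    curve2 = MSDCurve(lags=lags, msd=4 * 0.01 * lags + 0.01, n_pairs=np.full(7, 10))
    est2 = fit_diffusion(curve2, n_lags=4)
    assert est2.D == pytest.approx(0.01, abs=1e-12)
    assert est2.intercept == pytest.approx(0.01, abs=1e-12)


def test_fit_diffusion_negative_slope_clamped_flagged():
    from nanotrack.dynamics import MSDCurve
    lags = np.arange(1, 5) * 0.1
    curve = MSDCurve(lags=lags, msd=0.1 - 0.05 * lags, n_pairs=np.full(4, 5))
    est = fit_diffusion(curve)
    assert est.D == 0.0 and est.low_quality


def test_diffusion_ensemble_recovery():
    """Median fitted D within 20% of a generating D typical of slow
    membrane subpopulations."""
    d_true = 0.0022
    tracks = brownian_tracks(500, 50, d_true, 0.1, seed=8)
    ds = []
    for k in range(500):
        tr = _track(np.arange(51), tracks[k, :, 0], tracks[k, :, 1])
        ds.append(fit_diffusion(compute_msd(tr, 1.0, 0.1), n_lags=4).D)
    assert np.median(ds) == pytest.approx(d_true, rel=0.20)


def test_velocity_closed_forms():
    tr = _track(range(5), np.arange(5), np.zeros(5))  # 1 px / frame
    assert compute_velocity(tr, pixel_size=0.1, frame_interval=0.1) == \
        pytest.approx(1.0)
    still = _track(range(5), np.zeros(5), np.zeros(5))
    assert compute_velocity(still, 0.1, 0.1) == 0.0


def test_velocity_brownian_rayleigh_mean():
    """Mean instantaneous speed of a Brownian ensemble equals
    sqrt(pi D / dt) within 5%."""
    d_true, dt = 0.01, 0.1
    tracks = brownian_tracks(100, 120, d_true, dt, seed=15)
    speeds = [compute_velocity(_track(np.arange(121), tracks[k, :, 0],
                                      tracks[k, :, 1]), 1.0, dt)
              for k in range(100)]
    assert np.mean(speeds) == pytest.approx(math.sqrt(math.pi * d_true / dt),
                                            rel=0.05)


def test_peaks_unimodal_recovery():
    rng = np.random.default_rng(4)
    vals = 10 ** rng.normal(-2.5, 0.25, size=2000)
    ps = log_binned_peaks(vals, seed=0)
    assert ps.n_components == 1
    assert ps.peaks[0].G_hat == pytest.approx(10**-2.5, rel=0.10)


def test_peaks_bimodal_recovery():
    """Two membrane subpopulations a decade apart are resolved and located
    within a factor of 1.3."""
    rng = np.random.default_rng(6)
    vals = np.concatenate([
        10 ** rng.normal(math.log10(1.8e-3), 0.25, size=1000),
        10 ** rng.normal(math.log10(3.5e-2), 0.25, size=1000),
    ])
    ps = log_binned_peaks(vals, seed=0)
    assert ps.n_components == 2
    for ghat, target in zip([p.G_hat for p in ps.peaks], [1.8e-3, 3.5e-2]):
        ratio = ghat / target
        assert 1 / 1.3 <= ratio <= 1.3
    assert sum(p.weight for p in ps.peaks) == pytest.approx(1.0)


def test_peaks_degenerate_identical_values():
    ps = log_binned_peaks(np.full(50, 0.02))
    assert ps.n_components == 1
    assert ps.peaks[0].G_hat == pytest.approx(0.02)
    assert ps.peaks[0].log10_sd == pytest.approx(1e-3)


def test_peaks_input_guards():
    with pytest.raises(InsufficientDataError):
        log_binned_peaks(np.ones(10))
    # non-positive values are dropped and counted
    vals = np.concatenate([10 ** np.random.default_rng(0).normal(-2, 0.2, 100),
                           [0.0, -1.0]])
    ps = log_binned_peaks(vals)
    assert ps.n_dropped == 2


def test_dwell_exponential_recovery():
    rng = np.random.default_rng(13)
    dwells = rng.exponential(1.11, size=2000)
    fit = fit_dwell_exponential(dwells, bin_width=0.1)
    assert fit.tau == pytest.approx(1.11, rel=0.10)
    assert not fit.non_exponential
    # least-squares tau and the ML mean agree on clean data
    assert abs(fit.tau - fit.ml_mean) / fit.ml_mean < 0.15


def test_dwell_exponential_truncation_robust():
    rng = np.random.default_rng(14)
    d = rng.exponential(2.0, size=4000)
    d = d[d >= 0.2]
    fit = fit_dwell_exponential(d, bin_width=0.1, fit_floor=0.2)
    assert fit.tau == pytest.approx(2.0, rel=0.10)


def test_dwell_degenerate_flagged_non_exponential():
    fit = fit_dwell_exponential(np.full(100, 0.5), bin_width=0.1)
    assert fit.non_exponential


def test_dwell_insufficient_data():
    with pytest.raises(InsufficientDataError):
        fit_dwell_exponential(np.ones(10))
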