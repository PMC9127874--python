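"""End-to-end analysis: detect -> link -> per-track dynamics -> reports.

Given a calibrated movie and a :class:`~nanotrack.config.RunConfig`, the
pipeline emits spots, trajectories, per-track mobility (D, r², velocity,
dwell) and the characteristic-peak decomposition as CSV files.  Identical
config + inputs produce byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics as dyn
from . import io as ntio
from .config import RunConfig
from .detection import detect_movie
from .errors import InsufficientDataError, TooShortTrackError
from .synthetic import Movie
from .tracking import dwell_times, link_trajectories

log = logging.getLogger("nanotrack")

__all__ = ["PipelineResult", "run_pipeline", "track_dynamics_table"]


@dataclass
class PipelineResult:
    spots: pd.DataFrame
    tracks: pd.DataFrame
    per_track: pd.DataFrame
    peaks: pd.DataFrame
    summary: dict = field(default_factory=dict)


def track_dynamics_table(tracks, config: RunConfig) -> pd.DataFrame:
    """Per-track D, fit quality, velocity and dwell time."""
    rows = []
    for t in tracks:
        try:
            msd = dyn.compute_msd(t, config.pixel_size_um,
                                  config.frame_interval_s,
                                  config.max_lag_fraction)
            est = dyn.fit_diffusion(msd, min(config.msd_n_lags, len(msd.lags)))
            d, r2, lowq = est.D, est.r2, est.low_quality
        except (TooShortTrackError, InsufficientDataError):
            d, r2, lowq = np.nan, np.nan, True
        vel = dyn.compute_velocity(t, config.pixel_size_um,
                                   config.frame_interval_s)
        dwell = (t.last_frame - t.first_frame + 1) * config.frame_interval_s
        censored = t.censored_start or t.censored_end
        rows.append((t.track_id, d, r2, lowq, vel, dwell, censored))
    return pd.DataFrame(
        rows, columns=["track_id", "D_um2_s", "r2", "low_quality",
                       "velocity_um_s", "dwell_s", "censored"],
    )


def run_pipeline(config: RunConfig, movie: Movie, outdir=None) -> PipelineResult:
    """Run detect -> track -> dynamics on one movie.

    An empty movie (no detectable spots) succeeds with empty outputs and a
    warning in the log.  When ``outdir`` is given, all tables are written
    there as CSV together with the config actually used.
    """
    log.info("detection: psf_sigma=%.2f px, snr_min=%.1f",
             config.psf_sigma_px, config.snr_min)
    spots = detect_movie(movie.stack, expected_sigma=config.psf_sigma_px,
                         snr_min=config.snr_min)
    if not spots:
        log.warning("no spots detected; emitting empty outputs")
    tracks = link_trajectories(spots, max_disp=config.max_disp_px,
                               max_gap=config.max_gap,
                               n_frames=movie.n_frames)
    per_track = (track_dynamics_table(tracks, config) if tracks
                 else pd.DataFrame(columns=["track_id", "D_um2_s", "r2",
                                            "low_quality", "velocity_um_s",
                                            "dwell_s", "censored"]))
    peak_rows = []
    d_ok = per_track[~per_track["censored"]]["D_um2_s"].dropna() \
        if len(per_track) else pd.Series(dtype=float)
    try:
        ps = dyn.log_binned_peaks(d_ok.values, n_bins=config.peak_n_bins,
                                  seed=config.seed)
        for i, p in enumerate(ps.peaks):
            peak_rows.append(("D", i, p.G_hat, p.weight, p.standard_error,
                              ps.n_components))
    except InsufficientDataError:
        log.warning("too few positive D estimates for peak decomposition")
    peaks = pd.DataFrame(
        peak_rows, columns=["quantity", "component", "G_hat", "weight",
                            "standard_error", "n_components"],
    )
    dwells = dwell_times(tracks, config.frame_interval_s,
                         exclude_censored=config.exclude_censored_dwells)
    summary = {
        "n_spots": len(spots),
        "n_tracks": len(tracks),
        "n_dwells": len(dwells),
        "mean_dwell_s": float(np.mean(dwells)) if dwells else float("nan"),
    }
    result = PipelineResult(spots=ntio.spots_to_dataframe(spots),
                            tracks=ntio.tracks_to_dataframe(tracks),
                            per_track=per_track, peaks=peaks, summary=summary)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.spots.to_csv(outdir / "spots.csv", index=False)
        result.tracks.to_csv(outdir / "tracks.csv", index=False)
        result.per_track.to_csv(outdir / "per_track.csv", index=False)
        result.peaks.to_csv(outdir / "peaks.csv", index=False)
        config.to_file(outdir / "run_config.txt")
        with open(outdir / "summary.txt", "w") as fh:
            for k, v in summary.items():
                fh.write(f"{k} = {v}\n")
    return result
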