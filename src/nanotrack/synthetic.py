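"""Ground-truthed simulators for TIRF-style membrane imaging experiments.

The simulators emulate the statistical structure of variable-angle TIRF
movies of plasma-membrane particles: mixtures of Brownian lateral diffusers
with exponential membrane dwell times, rendered as Gaussian PSF spots on a
noisy camera background; two-channel movies with a controlled colocalized
fraction; photobleaching (FRAP) experiments that recover only by lateral
exchange; and fluorescence-fluctuation (FCS) traces from particles crossing
a Gaussian observation area.

Coordinate conventions
----------------------
Positions are stored in micrometres.  Pixel ``(row i, col j)`` has its
center at ``(x, y) = (j * pixel_size, i * pixel_size)``; ``x`` runs along
columns, ``y`` along rows.  Emitters live on a margin-extended domain so
that boundary depletion does not bias the in-frame density; reflecting
boundaries at the extended domain keep the particle number and the uniform
spatial distribution stationary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .errors import InvalidParameterError
from .fcs import FCSTrace

__all__ = [
    "PopulationSpec",
    "ImagingSpec",
    "Track",
    "GroundTruth",
    "Movie",
    "render_movie",
    "simulate_movie",
    "simulate_tracks",
    "simulate_two_channel",
    "simulate_frap",
    "simulate_fcs_trace",
    "brownian_tracks",
]


@dataclass(frozen=True)
class PopulationSpec:
    """One diffusive subpopulation of membrane particles.

    Parameters
    ----------
    diffusion_coefficient : float
        Lateral diffusion coefficient D in µm²/s (>= 0; 0 means immobile).
    fraction : float
        Mixture weight in (0, 1]; fractions across populations must sum to 1.
    mean_dwell : float
        Mean membrane dwell time in seconds before disappearance
        (endocytosis); ``math.inf`` means the particle never leaves.
    mean_intensity : float
        Mean integrated spot intensity in camera counts per frame.
    intensity_cv : float
        Coefficient of variation of the per-track intensity (gamma law).
    """

    diffusion_coefficient: float
    fraction: float = 1.0
    mean_dwell: float = math.inf
    mean_intensity: float = 200.0
    intensity_cv: float = 0.1

    def __post_init__(self) -> None:
        if not (self.diffusion_coefficient >= 0.0):
            raise InvalidParameterError("diffusion_coefficient must be >= 0")
        if not (0.0 < self.fraction <= 1.0):
            raise InvalidParameterError("fraction must be in (0, 1]")
        if not (self.mean_dwell > 0.0):
            raise InvalidParameterError("mean_dwell must be > 0")
        if not (self.mean_intensity > 0.0):
            raise InvalidParameterError("mean_intensity must be > 0")
        if self.intensity_cv < 0.0:
            raise InvalidParameterError("intensity_cv must be >= 0")


@dataclass(frozen=True)
class ImagingSpec:
    """Acquisition geometry, calibration and camera noise model.

    Defaults correspond to a typical 100x/1.45 NA TIRF setup: 0.1 µm pixels,
    0.1 s frame interval, PSF sigma 1.3 px.
    """

    n_frames: int
    shape: tuple[int, int] = (64, 64)  # rows, cols
    pixel_size: float = 0.1  # µm / px
    frame_interval: float = 0.1  # s
    psf_sigma: float = 1.3  # px
    background_mean: float = 100.0  # counts
    read_noise_sd: float = 2.0  # counts
    shot_noise: bool = True
    margin_px: int = 10  # extended-domain margin beyond the frame, every side

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise InvalidParameterError("n_frames must be >= 2")
        if self.margin_px < 10:
            raise InvalidParameterError("margin_px must be >= 10")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise InvalidParameterError("pixel_size and frame_interval must be > 0")
        if self.psf_sigma <= 0 or self.psf_sigma >= min(self.shape) / 4:
            raise InvalidParameterError("psf_sigma must be in (0, min(shape)/4)")
        if self.background_mean < 0 or self.read_noise_sd < 0:
            raise InvalidParameterError("noise parameters must be >= 0")


@dataclass
class Track:
    """Ground-truth trajectory of one emitter.

    Positions are true (noise-free) coordinates in µm, one per frame from
    ``birth_frame`` to ``death_frame`` inclusive.  ``intensities`` holds the
    emitted integrated intensity per frame (0 after photobleaching).
    """

    track_id: int
    population_id: int
    birth_frame: int
    death_frame: int
    x_um: np.ndarray
    y_um: np.ndarray
    intensities: np.ndarray
    censored_start: bool = False
    censored_end: bool = False
    channel: str = "A"
    bleached: bool = False

    @property
    def first_frame(self) -> int:
        return self.birth_frame

    @property
    def last_frame(self) -> int:
        return self.death_frame

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.birth_frame, self.death_frame + 1)

    @property
    def n_frames(self) -> int:
        return self.death_frame - self.birth_frame + 1


@dataclass
class GroundTruth:
    """All true tracks of a simulation plus the generating population specs."""

    tracks: list[Track]
    populations: list[PopulationSpec]

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)

    def channel_tracks(self, channel: str) -> list[Track]:
        return [t for t in self.tracks if t.channel == channel]

    def positions_at(self, frame: int, channel: str | None = None) -> np.ndarray:
        """(n, 2) array of true (x, y) µm of emitters alive at ``frame``."""
        pts = [
            (t.x_um[frame - t.birth_frame], t.y_um[frame - t.birth_frame])
            for t in self.tracks
            if t.birth_frame <= frame <= t.death_frame
            and (channel is None or t.channel == channel)
        ]
        return np.asarray(pts, dtype=float).reshape(-1, 2)

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for t in self.tracks:
            for k, f in enumerate(t.frames):
                rows.append(
                    (t.track_id, t.population_id, int(f), t.x_um[k], t.y_um[k],
                     t.censored_start or t.censored_end, t.channel)
                )
        return pd.DataFrame(
            rows,
            columns=["track_id", "population_id", "frame", "x_um", "y_um",
                     "censored", "channel"],
        )


@dataclass
class Movie:
    """Calibrated image stack: frames x rows x cols of nonnegative counts."""

    stack: np.ndarray
    pixel_size: float
    frame_interval: float
    channel_label: str = "A"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise InvalidParameterError("movie calibration must be positive")

    @property
    def n_frames(self) -> int:
        return self.stack.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.stack.shape[1:]


# ---------------------------------------------------------------------------
# track-level simulation


def _validate_populations(populations: list[PopulationSpec]) -> None:
    if not populations:
        raise InvalidParameterError("at least one population required")
    total = sum(p.fraction for p in populations)
    if abs(total - 1.0) > 1e-9:
        raise InvalidParameterError(f"population fractions sum to {total}, not 1")


def _reflect(path: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold a free path into [lo, hi] by specular reflection at both walls."""
    span = hi - lo
    y = np.mod(path - lo, 2.0 * span)
    return lo + np.where(y > span, 2.0 * span - y, y)


def _draw_intensity(pop: PopulationSpec, rng: np.random.Generator) -> float:
    if pop.intensity_cv == 0.0:
        return pop.mean_intensity
    shape = 1.0 / pop.intensity_cv**2
    scale = pop.mean_intensity * pop.intensity_cv**2
    return float(rng.gamma(shape, scale))


def _new_track(
    track_id: int,
    pop_id: int,
    pop: PopulationSpec,
    birth: int,
    imaging: ImagingSpec,
    bounds: tuple[float, float, float, float],
    rng: np.random.Generator,
    censored_start: bool = False,
) -> Track:
    xlo, xhi, ylo, yhi = bounds
    dt = imaging.frame_interval
    if math.isinf(pop.mean_dwell):
        death = imaging.n_frames - 1
        censored_end = True
    else:
        life = rng.exponential(pop.mean_dwell)
        n_alive = max(1, math.ceil(life / dt))
        death = birth + n_alive - 1
        censored_end = death >= imaging.n_frames - 1
        death = min(death, imaging.n_frames - 1)
    n = death - birth + 1
    x0 = rng.uniform(xlo, xhi)
    y0 = rng.uniform(ylo, yhi)
    step_sd = math.sqrt(2.0 * pop.diffusion_coefficient * dt)
    if n > 1 and step_sd > 0:
        steps = rng.normal(0.0, step_sd, size=(n - 1, 2))
        x = _reflect(x0 + np.concatenate([[0.0], np.cumsum(steps[:, 0])]), xlo, xhi)
        y = _reflect(y0 + np.concatenate([[0.0], np.cumsum(steps[:, 1])]), ylo, yhi)
    else:
        x = np.full(n, x0)
        y = np.full(n, y0)
    inten = np.full(n, _draw_intensity(pop, rng))
    return Track(
        track_id=track_id,
        population_id=pop_id,
        birth_frame=birth,
        death_frame=death,
        x_um=x,
        y_um=y,
        intensities=inten,
        censored_start=censored_start,
        censored_end=censored_end,
    )


def _extended_bounds(imaging: ImagingSpec) -> tuple[float, float, float, float]:
    rows, cols = imaging.shape
    px = imaging.pixel_size
    m = imaging.margin_px
    return ((-0.5 - m) * px, (cols - 0.5 + m) * px,
            (-0.5 - m) * px, (rows - 0.5 + m) * px)


def _simulate_tracks(
    populations: list[PopulationSpec],
    imaging: ImagingSpec,
    density: float,
    rng: np.random.Generator,
) -> list[Track]:
    _validate_populations(populations)
    if density < 0 or not math.isfinite(density):
        raise InvalidParameterError("density must be a finite value >= 0")
    bounds = _extended_bounds(imaging)
    area = (bounds[1] - bounds[0]) * (bounds[3] - bounds[2])
    n_expected = density * area
    fractions = np.array([p.fraction for p in populations])
    dt = imaging.frame_interval
    tracks: list[Track] = []
    tid = 0
    # steady-state emitters present at frame 0; residual lifetime of a
    # stationary exponential process is again exponential (memoryless)
    n0 = rng.poisson(n_expected)
    for _ in range(n0):
        pop_id = int(rng.choice(len(populations), p=fractions))
        tracks.append(
            _new_track(tid, pop_id, populations[pop_id], 0, imaging, bounds, rng,
                       censored_start=True)
        )
        tid += 1
    # Poisson births keep the expected particle count stationary
    birth_rate = np.array(
        [
            0.0 if math.isinf(p.mean_dwell) else n_expected * p.fraction * dt / p.mean_dwell
            for p in populations
        ]
    )
    for f in range(1, imaging.n_frames):
        for pop_id, lam in enumerate(birth_rate):
            if lam == 0.0:
                continue
            for _ in range(rng.poisson(lam)):
                tracks.append(
                    _new_track(tid, pop_id, populations[pop_id], f, imaging,
                               bounds, rng)
                )
                tid += 1
    return tracks


def simulate_tracks(
    populations: list[PopulationSpec],
    imaging: ImagingSpec,
    density: float,
    seed: int,
) -> GroundTruth:
    """Simulate ground-truth tracks only, without rendering a movie.

    Useful for ensemble studies (dwell-time or diffusion recovery) where the
    camera model is irrelevant.
    """
    rng = np.random.default_rng(seed)
    return GroundTruth(_simulate_tracks(populations, imaging, density, rng),
                       list(populations))


def brownian_tracks(
    n_tracks: int, n_steps: int, diffusion_coefficient: float, frame_interval: float,
    seed: int,
) -> np.ndarray:
    """Pure Brownian track ensemble: (n_tracks, n_steps + 1, 2) positions in µm.

    Per-axis increments are N(0, 2 D dt); tracks start at the origin.
    """
    if diffusion_coefficient < 0 or frame_interval <= 0:
        raise InvalidParameterError("need D >= 0 and frame_interval > 0")
    rng = np.random.default_rng(seed)
    sd = math.sqrt(2.0 * diffusion_coefficient * frame_interval)
    steps = rng.normal(0.0, sd, size=(n_tracks, n_steps, 2))
    out = np.zeros((n_tracks, n_steps + 1, 2))
    np.cumsum(steps, axis=1, out=out[:, 1:, :])
    return out


# ---------------------------------------------------------------------------
# rendering

def _render(tracks: list[Track], imaging: ImagingSpec, rng: np.random.Generator) -> np.ndarray:
    rows, cols = imaging.shape
    stack = np.zeros((imaging.n_frames, rows, cols), dtype=float)
    px = imaging.pixel_size
    sig = imaging.psf_sigma
    halfw = int(math.ceil(5.0 * sig))  # >=5 sigma: truncated mass < 1e-6
    w = 2 * halfw + 1
    root2s = math.sqrt(2.0) * sig
    offsets = np.arange(-halfw, halfw + 2) - 0.5  # window edges, length w+1
    for t in tracks:
        cx_all = t.x_um / px
        cy_all = t.y_um / px
        # only frames whose PSF window can touch the camera frame matter
        lit = ((t.intensities > 0.0)
               & (cx_all > -halfw - 1) & (cx_all < cols + halfw)
               & (cy_all > -halfw - 1) & (cy_all < rows + halfw))
        if not lit.any():
            continue
        cx = cx_all[lit]
        cy = cy_all[lit]
        inten = t.intensities[lit]
        frames = t.frames[lit]
        jc = np.floor(cx).astype(int)
        ic = np.floor(cy).astype(int)
        # per-pixel integrals of the 2D Gaussian, separable erf, all frames at once
        wx = 0.5 * np.diff(erf((jc[:, None] + offsets[None, :] - cx[:, None]) / root2s), axis=1)
        wy = 0.5 * np.diff(erf((ic[:, None] + offsets[None, :] - cy[:, None]) / root2s), axis=1)
        patches = inten[:, None, None] * wy[:, :, None] * wx[:, None, :]
        for k in range(len(frames)):
            j0, i0 = jc[k] - halfw, ic[k] - halfw
            js0, je0 = max(0, j0), min(cols, j0 + w)
            is0, ie0 = max(0, i0), min(rows, i0 + w)
            if js0 >= je0 or is0 >= ie0:
                continue
            stack[frames[k], is0:ie0, js0:je0] += \
                patches[k, is0 - i0:ie0 - i0, js0 - j0:je0 - j0]
    stack += imaging.background_mean
    if imaging.shot_noise:
        stack = rng.poisson(stack).astype(float)
    if imaging.read_noise_sd > 0:
        stack += rng.normal(0.0, imaging.read_noise_sd, size=stack.shape)
    return np.clip(stack, 0.0, None)


def render_movie(tracks: list[Track], imaging: ImagingSpec, seed: int = 0) -> Movie:
    """Render an explicit list of ground-truth tracks with the camera model.

    Lets callers image hand-constructed emitter configurations (e.g. a
    single spot at an exact pixel center) with the same PSF/noise pipeline
    used by the simulators.
    """
    rng = np.random.default_rng(seed)
    return Movie(_render(tracks, imaging, rng), imaging.pixel_size,
                 imaging.frame_interval)


def simulate_movie(
    populations: list[PopulationSpec],
    imaging: ImagingSpec,
    density: float,
    seed: int,
) -> tuple[Movie, GroundTruth]:
    """Simulate a single-channel TIRF movie with full ground truth.

    Emitters are placed uniformly at random on a margin-extended domain,
    perform 2D Brownian motion (per-axis step variance ``2 D dt``), live for
    exponentially distributed dwell times, and are replaced by a Poisson
    birth process so the expected particle count is stationary.  Spots are
    rendered as integrated 2D Gaussians; Poisson shot noise is applied first,
    then additive Gaussian read noise (EMCCD convention).
    """
    rng = np.random.default_rng(seed)
    tracks = _simulate_tracks(populations, imaging, density, rng)
    stack = _render(tracks, imaging, rng)
    movie = Movie(stack, imaging.pixel_size, imaging.frame_interval)
    return movie, GroundTruth(tracks, list(populations))


# ---------------------------------------------------------------------------
# two-channel simulation

def simulate_two_channel(
    populations_a: list[PopulationSpec],
    populations_b: list[PopulationSpec],
    imaging: ImagingSpec,
    density_a: float,
    density_b: float,
    coloc_fraction: float,
    seed: int,
) -> tuple[Movie, Movie, GroundTruth]:
    """Simulate a two-channel movie with a controlled colocalized fraction.

    A ``coloc_fraction`` of channel-B emitters are jittered copies (offset
    uniform within a 1-px disk) of distinct channel-A tracks; the remainder
    of channel B diffuses independently.  ``coloc_fraction=1`` therefore
    makes channel B a one-to-one copy of channel A.
    """
    if not (0.0 <= coloc_fraction <= 1.0):
        raise InvalidParameterError("coloc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tracks_a = _simulate_tracks(populations_a, imaging, density_a, rng)
    fractions_b = np.array([p.fraction for p in populations_b])
    _validate_populations(populations_b)

    n_coloc = int(round(coloc_fraction * len(tracks_a)))
    tracks_b: list[Track] = []
    tid = len(tracks_a)
    if n_coloc > 0 and tracks_a:
        chosen = rng.choice(len(tracks_a), size=min(n_coloc, len(tracks_a)),
                            replace=False)
        for idx in sorted(chosen):
            src = tracks_a[idx]
            r = imaging.pixel_size * math.sqrt(rng.uniform(0.0, 1.0))
            th = rng.uniform(0.0, 2.0 * math.pi)
            pop_id = int(rng.choice(len(populations_b), p=fractions_b))
            inten = _draw_intensity(populations_b[pop_id], rng)
            tracks_b.append(
                Track(
                    track_id=tid,
                    population_id=pop_id,
                    birth_frame=src.birth_frame,
                    death_frame=src.death_frame,
                    x_um=src.x_um + r * math.cos(th),
                    y_um=src.y_um + r * math.sin(th),
                    intensities=np.full(src.n_frames, inten),
                    censored_start=src.censored_start,
                    censored_end=src.censored_end,
                    channel="B",
                )
            )
            tid += 1
    indep = _simulate_tracks(populations_b, imaging,
                             density_b * (1.0 - coloc_fraction), rng)
    for t in indep:
        t.track_id = tid
        t.channel = "B"
        tracks_b.append(t)
        tid += 1

    imaging_a = imaging
    movie_a = Movie(_render(tracks_a, imaging_a, rng), imaging.pixel_size,
                    imaging.frame_interval, channel_label="A")
    movie_b = Movie(_render(tracks_b, imaging, rng), imaging.pixel_size,
                    imaging.frame_interval, channel_label="B")
    gt = GroundTruth(tracks_a + tracks_b, list(populations_a) + list(populations_b))
    return movie_a, movie_b, gt


# ---------------------------------------------------------------------------
# FRAP simulation

def simulate_frap(
    imaging: ImagingSpec,
    density: float,
    bleach_roi: tuple[int, int, int, int],
    bleach_frame: int,
    bleach_depth: float,
    immobile_fraction: float,
    diffusion_coefficient: float,
    seed: int,
    mean_intensity: float = 200.0,
) -> tuple[Movie, GroundTruth]:
    """Simulate a photobleaching experiment.

    At ``bleach_frame`` every emitter whose true position lies inside
    ``bleach_roi = (x0, y0, w, h)`` (pixel rectangle) goes dark with
    probability ``bleach_depth``.  An ``immobile_fraction`` of all emitters
    has D = 0; recovery happens only by lateral exchange of fluorescent
    mobile emitters into the ROI (no births, infinite dwell).
    """
    x0, y0, w, h = bleach_roi
    rows, cols = imaging.shape
    if x0 < 0 or y0 < 0 or w <= 0 or h <= 0 or x0 + w > cols or y0 + h > rows:
        raise InvalidParameterError("bleach_roi must lie inside the frame")
    if not (0.0 <= bleach_depth <= 1.0 and 0.0 <= immobile_fraction <= 1.0):
        raise InvalidParameterError("bleach_depth/immobile_fraction must be in [0,1]")
    if not (0 < bleach_frame < imaging.n_frames):
        raise InvalidParameterError("bleach_frame must be inside the movie")
    pops = []
    if immobile_fraction < 1.0:
        pops.append(PopulationSpec(diffusion_coefficient, 1.0 - immobile_fraction,
                                   mean_intensity=mean_intensity, intensity_cv=0.0))
    if immobile_fraction > 0.0:
        pops.append(PopulationSpec(0.0, immobile_fraction,
                                   mean_intensity=mean_intensity, intensity_cv=0.0))
    rng = np.random.default_rng(seed)
    tracks = _simulate_tracks(pops, imaging, density, rng)
    px = imaging.pixel_size
    xlo, xhi = (x0 - 0.5) * px, (x0 + w - 0.5) * px
    ylo, yhi = (y0 - 0.5) * px, (y0 + h - 0.5) * px
    for t in tracks:
        k = bleach_frame - t.birth_frame
        if 0 <= k < t.n_frames:
            inside = xlo <= t.x_um[k] < xhi and ylo <= t.y_um[k] < yhi
            if inside and rng.uniform() < bleach_depth:
                t.intensities = t.intensities.copy()
                t.intensities[k:] = 0.0
                t.bleached = True
    stack = _render(tracks, imaging, rng)
    return Movie(stack, px, imaging.frame_interval), GroundTruth(tracks, pops)


# ---------------------------------------------------------------------------
# FCS simulation

def simulate_fcs_trace(
    N_mean: float,
    tau_D: float,
    duration: float,
    sampling_dt: float,
    brightness: float,
    seed: int,
    beam_waist: float = 0.25,
    shot_noise: bool = True,
) -> FCSTrace:
    """Simulate a fluorescence-fluctuation trace from a 2D membrane.

    Particles diffuse in a periodic box (side ``8 * beam_waist``) through a
    Gaussian observation profile ``W(r) = 2 exp(-2 r^2 / w0^2)`` (1/e^2
    radius ``w0 = beam_waist`` µm, peak weight 2 so the trace mean is
    ``N_mean * brightness``).  The effective observation area is
    ``pi w0^2``, so the fluctuation autocorrelation amplitude is
    ``G(0) = 1 / N_mean`` and the model decay time is
    ``tau_D = w0^2 / (4 D)``.
    """
    if N_mean <= 0 or brightness <= 0 or sampling_dt <= 0:
        raise InvalidParameterError("N_mean, brightness, sampling_dt must be > 0")
    if duration < 100 * sampling_dt:
        raise InvalidParameterError("duration must cover at least 100 samples")
    if tau_D <= 0:
        raise InvalidParameterError("tau_D must be > 0 (math.inf allowed)")
    rng = np.random.default_rng(seed)
    w0 = beam_waist
    L = 8.0 * w0
    n_samples = int(round(duration / sampling_dt))
    M = max(1, int(round(N_mean * L * L / (math.pi * w0 * w0))))
    D = 0.0 if math.isinf(tau_D) else w0 * w0 / (4.0 * tau_D)
    step_sd = math.sqrt(2.0 * D * sampling_dt)
    pos = rng.uniform(0.0, L, size=(M, 2))
    signal = np.empty(n_samples)
    chunk = 2048
    start = 0
    while start < n_samples:
        stop = min(start + chunk, n_samples)
        m = stop - start
        if step_sd > 0:
            steps = rng.normal(0.0, step_sd, size=(m, M, 2))
            steps[0] += pos
            path = np.cumsum(steps, axis=0)
        else:
            path = np.broadcast_to(pos, (m, M, 2))
        d = np.mod(path - L / 2.0 + L / 2.0, L) - L / 2.0  # min-image to beam center
        r2 = d[..., 0] ** 2 + d[..., 1] ** 2
        signal[start:stop] = brightness * np.sum(2.0 * np.exp(-2.0 * r2 / (w0 * w0)), axis=1)
        pos = np.mod(path[-1], L)
        start = stop
    samples = rng.poisson(signal).astype(float) if shot_noise else signal
    return FCSTrace(samples=samples, sampling_dt=sampling_dt)
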