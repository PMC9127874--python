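"""Diffraction-limited spot detection, quantification and density segmentation.

Detection is a classic two-stage scheme: a band-pass (difference of
Gaussians at the expected PSF width) proposes candidate maxima, which are
then refined by local 2D Gaussian least-squares fits to subpixel precision.
Spot "size" follows the n x n pixel square convention: the reported side
length is the fitted FWHM, ``2 * sigma * sqrt(2 ln 2)`` pixels.

High-density regions are segmented by Voronoi tessellation of spot centers:
each spot's local density is the inverse area of its Voronoi cell, and
spots above a density threshold are clustered through adjacency of their
cells (the standard localization-microscopy tessellation segmentation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Voronoi, QhullError

from .errors import DegenerateGeometryError, InvalidParameterError

__all__ = [
    "Spot",
    "SpotSummary",
    "DensityResult",
    "VoronoiSegmentation",
    "detect_spots",
    "detect_movie",
    "spot_statistics",
    "compute_density",
    "voronoi_segment",
    "FWHM_FACTOR",
]

FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # sigma -> FWHM


@dataclass
class Spot:
    """One detected spot: subpixel position (pixel-center convention),
    background-subtracted integrated intensity, fitted Gaussian width."""

    frame: int
    x: float  # px
    y: float  # px
    intensity: float  # counts, integrated (2 pi A sigma^2)
    sigma: float  # px
    background: float  # counts
    snr: float


@dataclass
class SpotSummary:
    n: int
    mean_intensity: float
    sd_intensity: float
    mean_size_px: float  # FWHM-equivalent square side
    sd_size_px: float
    mean_sigma_px: float
    sd_sigma_px: float

    @property
    def is_empty(self) -> bool:
        return self.n == 0


EMPTY_SUMMARY = SpotSummary(0, math.nan, math.nan, math.nan, math.nan, math.nan, math.nan)


@dataclass
class DensityResult:
    n_spots: int
    area: float
    density: float  # mean per-frame counts/area
    density_sd: float
    per_frame: list[float]
    unit: str = "um2"


@dataclass
class VoronoiSegmentation:
    cell_areas: np.ndarray  # per spot, µm² (inf for unbounded cells)
    local_density: np.ndarray  # per spot, 1/area (0 for unbounded cells)
    labels: np.ndarray  # cluster id per spot, 0 = below threshold/unbounded
    threshold: float
    n_clusters: int


def _robust_sd(values: np.ndarray) -> float:
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def _gauss2d(coords, amp, x0, y0, sigma, offset):
    x, y = coords
    return (amp * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2.0 * sigma**2))
            + offset)


def detect_spots(
    image: np.ndarray,
    expected_sigma: float = 1.3,
    snr_min: float = 5.0,
    frame: int = 0,
    candidate_floor: float = 3.0,
) -> list[Spot]:
    """Detect spots in one frame; returns spots sorted by intensity (desc).

    Candidates are local maxima of a difference-of-Gaussians band-pass (the
    matched filter for a PSF-sized blob).  Each spot's ``snr`` is its
    matched-filter significance — the band-pass response over the robust
    noise SD of the band-passed image — and candidates below
    ``max(snr_min, candidate_floor)`` are discarded.  Gating on the
    band-passed statistic rather than the fitted amplitude keeps near-
    threshold spots detectable: the smoothed response has several-fold less
    estimation noise than a per-spot amplitude fit.  Overlapping candidates
    within ``2 * expected_sigma`` are suppressed in favour of the stronger
    one; survivors are refined by a local Gaussian least-squares fit in a
    ``(4 sigma + 1)``-pixel window, and fits that diverge or drift away are
    dropped.  A flat image returns an empty list.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InvalidParameterError("image must be 2D")
    if np.any(img < 0):
        raise InvalidParameterError("image must be nonnegative")
    if np.ptp(img) == 0.0:
        return []
    rows, cols = img.shape

    dog = (ndimage.gaussian_filter(img, expected_sigma)
           - ndimage.gaussian_filter(img, 1.6 * expected_sigma))
    sd_dog = _robust_sd(dog)
    if sd_dog == 0.0:
        return []
    size = 2 * int(math.ceil(expected_sigma)) + 1
    is_max = dog == ndimage.maximum_filter(dog, size=size)
    gate = max(snr_min, candidate_floor) * sd_dog
    cand = np.argwhere(is_max & (dog > gate))
    if len(cand) == 0:
        return []
    # suppress weaker candidates within 2 sigma of a stronger one
    order = np.argsort(-dog[cand[:, 0], cand[:, 1]])
    cand = cand[order]
    keep: list[np.ndarray] = []
    min_d2 = (2.0 * expected_sigma) ** 2
    for c in cand:
        if all((c[0] - k[0]) ** 2 + (c[1] - k[1]) ** 2 >= min_d2 for k in keep):
            keep.append(c)

    half = int(round(2.0 * expected_sigma))
    spots: list[Spot] = []
    for ci, cj in keep:
        snr = float(dog[ci, cj] / sd_dog)  # matched-filter significance
        i0, i1 = ci - half, ci + half
        j0, j1 = cj - half, cj + half
        if i0 < 0 or j0 < 0 or i1 >= rows or j1 >= cols:
            continue
        win = img[i0:i1 + 1, j0:j1 + 1]
        yy, xx = np.mgrid[i0:i1 + 1, j0:j1 + 1]
        ring = np.concatenate([win[0], win[-1], win[1:-1, 0], win[1:-1, -1]])
        bg = float(np.median(ring))
        p0 = (max(img[ci, cj] - bg, 1e-3), float(cj), float(ci),
              expected_sigma, bg)
        lo = (0.0, j0 - 0.5, i0 - 0.5, 0.3 * expected_sigma, 0.0)
        hi = (np.inf, j1 + 0.5, i1 + 0.5, 3.0 * expected_sigma, np.inf)
        try:
            popt, _ = curve_fit(
                _gauss2d, (xx.ravel(), yy.ravel()), win.ravel(), p0=p0,
                bounds=(lo, hi), maxfev=2000,
            )
        except RuntimeError:
            continue
        amp, x0, y0, sigma, offset = (float(v) for v in popt)
        if amp <= 0.0:
            continue
        if (x0 - cj) ** 2 + (y0 - ci) ** 2 > (2.0 * expected_sigma) ** 2:
            continue  # fit drifted away from its candidate
        if not (-0.5 <= x0 <= cols - 0.5 and -0.5 <= y0 <= rows - 0.5):
            continue
        spots.append(
            Spot(frame=frame, x=x0, y=y0, intensity=2.0 * math.pi * amp * sigma**2,
                 sigma=sigma, background=bg, snr=snr)
        )
    spots.sort(key=lambda s: -s.intensity)
    return spots


def detect_movie(
    stack: np.ndarray,
    expected_sigma: float = 1.3,
    snr_min: float = 5.0,
    **kwargs,
) -> list[Spot]:
    """Run :func:`detect_spots` on every frame of a stack."""
    out: list[Spot] = []
    for f in range(stack.shape[0]):
        out.extend(detect_spots(stack[f], expected_sigma, snr_min, frame=f, **kwargs))
    return out


def spot_statistics(spots: list[Spot]) -> SpotSummary:
    """Mean +/- SD of intensity and FWHM-square size over a spot list.

    Returns the explicit empty sentinel (``summary.is_empty``) for no spots.
    Sample SD (ddof=1) is used; a single spot reports SD 0.
    """
    if not spots:
        return EMPTY_SUMMARY
    inten = np.array([s.intensity for s in spots])
    sig = np.array([s.sigma for s in spots])
    size = FWHM_FACTOR * sig

    def sd(v):
        return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0

    return SpotSummary(
        n=len(spots),
        mean_intensity=float(inten.mean()), sd_intensity=sd(inten),
        mean_size_px=float(size.mean()), sd_size_px=sd(size),
        mean_sigma_px=float(sig.mean()), sd_sigma_px=sd(sig),
    )


def compute_density(
    spots: list[Spot],
    area: float,
    n_frames: int | None = None,
    unit: str = "um2",
) -> DensityResult:
    """Spot density as counts per unit area, per frame and pooled.

    ``area`` is the observed area in the requested unit (µm² by default,
    px² if ``unit='px2'``).  The pooled density is the mean of the per-frame
    densities, with their SD; for a single frame this is ``n / area``.
    Frames with zero spots only enter if ``n_frames`` is given.
    """
    if area <= 0:
        raise InvalidParameterError("area must be > 0")
    frames = np.array([s.frame for s in spots], dtype=int)
    if n_frames is None:
        frame_ids = np.unique(frames) if len(frames) else np.array([0])
    else:
        frame_ids = np.arange(n_frames)
    counts = np.array([(frames == f).sum() for f in frame_ids], dtype=float)
    per_frame = counts / area
    sd = float(np.std(per_frame, ddof=1)) if len(per_frame) > 1 else 0.0
    return DensityResult(
        n_spots=len(spots), area=area, density=float(per_frame.mean()),
        density_sd=sd, per_frame=per_frame.tolist(), unit=unit,
    )


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def voronoi_segment(
    spots,
    density_threshold: float,
    min_cluster_size: int = 3,
    pixel_size: float = 1.0,
) -> VoronoiSegmentation:
    """Voronoi localization-density segmentation of spot positions.

    ``spots`` may be a list of :class:`Spot` or an (n, 2) array of (x, y)
    coordinates in px; ``pixel_size`` converts to µm so densities come out
    in 1/µm².  Spots whose local density (inverse Voronoi-cell area) meets
    the threshold are merged into clusters via cell adjacency; clusters
    smaller than ``min_cluster_size`` and all unbounded cells get label 0.
    """
    if hasattr(spots, "__len__") and len(spots) and isinstance(spots[0], Spot):
        pts = np.array([[s.x, s.y] for s in spots], dtype=float)
    else:
        pts = np.asarray(spots, dtype=float).reshape(-1, 2)
    if len(pts) < 4:
        raise DegenerateGeometryError("need at least 4 spots for a Voronoi diagram")
    pts_um = pts * pixel_size
    try:
        vor = Voronoi(pts_um)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate spot geometry: {exc}") from exc

    n = len(pts_um)
    areas = np.full(n, np.inf)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            continue
        areas[i] = _polygon_area(vor.vertices[region])
    local_density = np.where(np.isfinite(areas) & (areas > 0), 1.0 / areas, 0.0)

    eligible = (local_density >= density_threshold) & np.isfinite(areas)
    ridge = np.asarray(vor.ridge_points)
    labels = np.zeros(n, dtype=int)
    n_clusters = 0
    if eligible.any() and len(ridge):
        mask = eligible[ridge[:, 0]] & eligible[ridge[:, 1]]
        rp = ridge[mask]
        adj = coo_matrix(
            (np.ones(len(rp)), (rp[:, 0], rp[:, 1])), shape=(n, n)
        )
        n_comp, comp = connected_components(adj + adj.T, directed=False)
        next_label = 1
        for c in range(n_comp):
            members = np.where((comp == c) & eligible)[0]
            if len(members) >= min_cluster_size:
                labels[members] = next_label
                next_label += 1
        n_clusters = next_label - 1
    return VoronoiSegmentation(
        cell_areas=areas, local_density=local_density, labels=labels,
        threshold=density_threshold, n_clusters=n_clusters,
    )
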