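"""Spot detection accuracy, summary statistics, density, Voronoi segmentation."""

import math

import numpy as np
import pytest

from nanotrack import ImagingSpec, PopulationSpec, simulate_movie
from nanotrack.detection import (
    FWHM_FACTOR,
    Spot,
    compute_density,
    detect_spots,
    spot_statistics,
    voronoi_segment,
)
from nanotrack.errors import DegenerateGeometryError, InvalidParameterError
from nanotrack.synthetic import Track, render_movie

from conftest import mutual_match


def _snr_intensity(snr, imaging):
    """Integrated intensity giving the requested peak SNR over background."""
    noise_sd = math.sqrt(imaging.background_mean + imaging.read_noise_sd**2)
    amp = snr * noise_sd
    return amp * 2 * math.pi * imaging.psf_sigma**2


def test_noiseless_centered_emitter_localized_to_millipixel():
    imaging = ImagingSpec(n_frames=2, shape=(21, 21), background_mean=10.0,
                          read_noise_sd=0.0, shot_noise=False)
    track = Track(0, 0, 0, 1, x_um=np.array([1.0, 1.0]),
                  y_um=np.array([1.0, 1.0]),
                  intensities=np.array([500.0, 500.0]))
    movie = render_movie([track], imaging)
    spots = detect_spots(movie.stack[0], expected_sigma=1.3, snr_min=5.0)
    assert len(spots) == 1
    assert spots[0].x == pytest.approx(10.0, abs=1e-3)
    assert spots[0].y == pytest.approx(10.0, abs=1e-3)


def test_flat_image_returns_empty():
    assert detect_spots(np.full((64, 64), 7.0)) == []


def test_detection_f1_and_rmse_at_snr10():
    """>= 19/20-style recall and sub-0.2 px localization at SNR 10."""
    imaging = ImagingSpec(n_frames=4, shape=(128, 128))
    inten = _snr_intensity(10, imaging)
    pops = [PopulationSpec(0.0, 1.0, mean_intensity=inten, intensity_cv=0.0)]
    movie, gt = simulate_movie(pops, imaging, density=0.12, seed=21)
    n_true = n_det = n_match = 0
    sq_err = []
    for f in range(4):
        truth = gt.positions_at(f) / imaging.pixel_size
        in_frame = truth[(truth[:, 0] > 3) & (truth[:, 0] < 124)
                         & (truth[:, 1] > 3) & (truth[:, 1] < 124)]
        spots = detect_spots(movie.stack[f], 1.3, 5.0, frame=f)
        det = np.array([[s.x, s.y] for s in spots]).reshape(-1, 2)
        matches = mutual_match(in_frame, det, radius=2.0)
        n_true += len(in_frame)
        n_det += len(det)
        n_match += len(matches)
        for i, j, _ in matches:
            sq_err.append(np.sum((in_frame[i] - det[j]) ** 2) / 2.0)
    recall = n_match / n_true
    precision = n_match / n_det
    f1 = 2 * precision * recall / (precision + recall)
    rmse = math.sqrt(np.mean(sq_err))
    assert f1 >= 0.95
    assert rmse < 0.2  # px, per-axis


def test_pure_noise_false_positive_rate():
    """<= 1 spurious spot per 512x512 noise-only frame at snr_min = 5."""
    rng = np.random.default_rng(17)
    n_fp = 0
    n_frames = 10
    for _ in range(n_frames):
        frame = np.clip(rng.poisson(100.0, size=(512, 512)).astype(float)
                        + rng.normal(0, 2.0, size=(512, 512)), 0, None)
        n_fp += len(detect_spots(frame, 1.3, 5.0))
    assert n_fp <= n_frames


def _spot(x=0.0, y=0.0, inten=100.0, sigma=1.3, frame=0):
    return Spot(frame=frame, x=x, y=y, intensity=inten, sigma=sigma,
                background=0.0, snr=10.0)


def test_spot_statistics_arithmetic_and_size_convention():
    spots = [_spot(inten=100.0), _spot(inten=300.0)]
    s = spot_statistics(spots)
    assert s.mean_intensity == pytest.approx(200.0)
    assert s.sd_intensity == pytest.approx(141.42, abs=0.01)
    assert s.mean_size_px == pytest.approx(FWHM_FACTOR * 1.3)


def test_spot_statistics_identical_spots_zero_sd():
    s = spot_statistics([_spot()] * 5)
    assert s.sd_intensity == 0.0 and s.sd_size_px == 0.0


def test_spot_statistics_empty_sentinel():
    s = spot_statistics([])
    assert s.is_empty and s.n == 0 and math.isnan(s.mean_intensity)


def test_density_arithmetic():
    spots = [_spot(x=i) for i in range(15)]
    d = compute_density(spots, area=100.0)
    assert d.density == pytest.approx(0.15)
    assert d.n_spots == 15


def test_density_zero_spots_and_invalid_area():
    assert compute_density([], area=10.0).density == 0.0
    with pytest.raises(InvalidParameterError):
        compute_density([], area=0.0)


def test_density_recovery_from_simulation():
    """Detected spot density within 10% of generator truth at SNR 10."""
    imaging = ImagingSpec(n_frames=6, shape=(128, 128))
    inten = _snr_intensity(10, imaging)
    pops = [PopulationSpec(0.0, 1.0, mean_intensity=inten, intensity_cv=0.0)]
    true_density = 0.15  # spots / µm²
    movie, _ = simulate_movie(pops, imaging, density=true_density, seed=31)
    # detection needs a full fit window, so its field of view excludes a
    # 3-px rim; measure the density over that effective area
    area_um2 = (128 - 6) ** 2 * imaging.pixel_size**2
    all_spots = []
    for f in range(6):
        all_spots.extend(detect_spots(movie.stack[f], 1.3, 5.0, frame=f))
    d = compute_density(all_spots, area=area_um2, n_frames=6)
    assert d.density == pytest.approx(true_density, rel=0.10)


def test_voronoi_uniform_grid_single_cluster():
    xs, ys = np.meshgrid(np.arange(10), np.arange(10))
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    seg = voronoi_segment(pts, density_threshold=0.5, min_cluster_size=3)
    # all interior cells have unit area -> one cluster containing them
    assert seg.n_clusters == 1
    interior = (pts[:, 0] > 0) & (pts[:, 0] < 9) & (pts[:, 1] > 0) & (pts[:, 1] < 9)
    assert np.all(seg.labels[interior] == 1)


def test_voronoi_two_blobs_two_clusters():
    rng = np.random.default_rng(5)
    blob1 = rng.normal(0.0, 1.0, size=(25, 2))
    blob2 = rng.normal(0.0, 1.0, size=(25, 2)) + [40.0, 0.0]
    sparse = rng.uniform(-60, 100, size=(30, 1))
    sparse = np.column_stack([sparse, rng.uniform(-60, 100, size=(30, 1))])
    pts = np.vstack([blob1, blob2, sparse])
    seg = voronoi_segment(pts, density_threshold=0.5, min_cluster_size=5)
    assert seg.n_clusters == 2
    assert len(set(seg.labels[:25]) - {0}) == 1
    assert len(set(seg.labels[25:50]) - {0}) == 1
    assert set(seg.labels[:25]) != set(seg.labels[25:50]) or \
        (seg.labels[:25].max() != seg.labels[25:50].max())


def test_voronoi_infinite_threshold_all_background():
    rng = np.random.default_rng(1)
    seg = voronoi_segment(rng.uniform(0, 10, size=(50, 2)),
                          density_threshold=math.inf)
    assert np.all(seg.labels == 0)


def test_voronoi_density_scale_covariance():
    rng = np.random.default_rng(2)
    pts = rng.uniform(0, 10, size=(60, 2))
    seg1 = voronoi_segment(pts, density_threshold=0.0)
    seg2 = voronoi_segment(pts * 3.0, density_threshold=0.0)
    finite = np.isfinite(seg1.cell_areas) & np.isfinite(seg2.cell_areas)
    assert np.allclose(seg2.local_density[finite],
                       seg1.local_density[finite] / 9.0)


def test_voronoi_degenerate_inputs():
    with pytest.raises(DegenerateGeometryError):
        voronoi_segment(np.array([[0.0, 0], [1, 0], [2, 0]]), 1.0)
    with pytest.raises(DegenerateGeometryError):
        voronoi_segment(np.array([[0.0, 0], [1, 1], [2, 2], [3, 3]]), 1.0)
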