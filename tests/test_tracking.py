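"""Linking correctness (incl. exhaustive-assignment oracle), dwell times,
kymograph geometry."""

import itertools
import math

import numpy as np
import pytest

from nanotrack import ImagingSpec, Movie, PopulationSpec, simulate_movie
from nanotrack.detection import Spot
from nanotrack.errors import InvalidParameterError
from nanotrack.synthetic import Track, render_movie
from nanotrack.tracking import dwell_times, link_trajectories, make_kymograph

from conftest import mutual_match


def _spot(frame, x, y, inten=100.0):
    return Spot(frame=frame, x=x, y=y, intensity=inten, sigma=1.3,
                background=0.0, snr=10.0)


def test_two_stationary_emitters_two_full_tracks():
    spots = [_spot(f, 10.0, 10.0) for f in range(20)]
    spots += [_spot(f, 20.0, 10.0) for f in range(20)]
    tracks = link_trajectories(spots, max_disp=3.0, n_frames=20)
    assert len(tracks) == 2
    assert all(t.n_points == 20 for t in tracks)
    assert all(t.censored_start and t.censored_end for t in tracks)


def test_gap_closing_bridges_single_blink():
    spots = [_spot(f, 5.0, 5.0) for f in range(10) if f != 4]
    tracks = link_trajectories(spots, max_disp=2.0, max_gap=1, n_frames=10)
    assert len(tracks) == 1
    assert tracks[0].n_points == 9
    assert 4 not in tracks[0].frames


def test_no_gap_closing_when_max_gap_zero():
    spots = [_spot(f, 5.0, 5.0) for f in range(10) if f != 4]
    tracks = link_trajectories(spots, max_disp=2.0, max_gap=0, n_frames=10)
    assert len(tracks) == 2


def test_linking_invariant_to_spot_order():
    rng = np.random.default_rng(3)
    spots = []
    for f in range(8):
        for k in range(5):
            spots.append(_spot(f, 10.0 * k + rng.uniform(-0.5, 0.5),
                               10.0 + rng.uniform(-0.5, 0.5)))
    t1 = link_trajectories(spots, max_disp=3.0, n_frames=8)
    rng.shuffle(spots)
    t2 = link_trajectories(spots, max_disp=3.0, n_frames=8)
    key = lambda tr: (tr.first_frame, round(tr.x[0], 6), round(tr.y[0], 6))
    for a, b in zip(sorted(t1, key=key), sorted(t2, key=key)):
        assert np.array_equal(a.frames, b.frames)
        assert np.allclose(a.x, b.x) and np.allclose(a.y, b.y)


def test_spot_conservation_with_min_length_one():
    rng = np.random.default_rng(9)
    spots = [_spot(int(f), rng.uniform(0, 50), rng.uniform(0, 50))
             for f in rng.integers(0, 10, size=60)]
    tracks = link_trajectories(spots, max_disp=2.0, n_frames=10, min_length=1)
    assert sum(t.n_points for t in tracks) == len(spots)


def _oracle_total_distance(prev, curr, max_disp):
    """Exhaustive minimum-total-distance matching (<= 6 spots per frame)."""
    best = (math.inf, 0)
    n, m = len(prev), len(curr)
    k = min(n, m)
    best_cost = math.inf
    best_n = 0
    for r in range(k, -1, -1):
        for pi in itertools.permutations(range(n), r):
            for ci in itertools.combinations(range(m), r):
                cost = 0.0
                ok = True
                for a, b in zip(pi, ci):
                    d = math.hypot(prev[a][0] - curr[b][0], prev[a][1] - curr[b][1])
                    if d > max_disp:
                        ok = False
                        break
                    cost += d
                if ok and (r > best_n or (r == best_n and cost < best_cost)):
                    best_cost, best_n = cost, r
        if best_n == r:
            break
    return best_n, best_cost


def test_linking_matches_exhaustive_assignment_on_separated_fixtures():
    """On noiseless well-separated frames, greedy linking equals the optimal
    assignment: same links frame to frame."""
    rng = np.random.default_rng(12)
    for trial in range(10):
        n = int(rng.integers(2, 7))
        base = rng.uniform(5, 60, size=(n, 2))
        # well separated: min pairwise distance > 4 * step size
        while mutual_match(base, base + 4.0, 1e9) and np.min(
            np.linalg.norm(base[:, None] - base[None, :], axis=-1)
            + np.eye(n) * 1e9
        ) < 8.0:
            base = rng.uniform(5, 60, size=(n, 2))
        steps = rng.uniform(-1.0, 1.0, size=(5, n, 2))
        pos = base[None] + np.cumsum(steps, axis=0)
        pos = np.concatenate([base[None], pos])
        spots = [_spot(f, *pos[f, k]) for f in range(6) for k in range(n)]
        tracks = link_trajectories(spots, max_disp=3.0, n_frames=6)
        assert len(tracks) == n
        for t in tracks:
            assert t.n_points == 6
        # every frame-to-frame link count matches the exhaustive optimum
        for f in range(5):
            n_links, _ = _oracle_total_distance(pos[f], pos[f + 1], 3.0)
            assert n_links == n


def test_link_recovery_on_brownian_simulation():
    """>= 95% of ground-truth frame-to-frame links recovered in a sparse
    Brownian field imaged without noise."""
    pops = [PopulationSpec(0.035, 1.0, mean_intensity=500.0, intensity_cv=0.0)]
    imaging = ImagingSpec(n_frames=40, shape=(96, 96))
    _, gt = simulate_movie(pops, imaging, density=0.08, seed=2)
    spots = []
    for t in gt.tracks:
        for k, f in enumerate(t.frames):
            spots.append(_spot(int(f), t.x_um[k] / 0.1, t.y_um[k] / 0.1))
    tracks = link_trajectories(spots, max_disp=3.5, n_frames=40)
    true_links = sum(t.n_frames - 1 for t in gt.tracks)
    found_links = sum(
        np.sum(np.diff(tr.frames) == 1) for tr in tracks
    )
    assert found_links / true_links >= 0.95


def test_dwell_time_arithmetic_and_censoring():
    t1 = link_trajectories([_spot(f, 5, 5) for f in range(0, 11)],
                           max_disp=2, n_frames=30)[0]
    assert not t1.censored_end and t1.censored_start
    spots = [_spot(f, 5, 5) for f in range(3, 14)]
    tracks = link_trajectories(spots, max_disp=2, n_frames=30)
    assert dwell_times(tracks, 0.1) == [pytest.approx(1.1)]
    assert dwell_times(tracks, 0.1, exclude_censored=False) == [pytest.approx(1.1)]
    # fully censored input with exclusion on -> empty
    spots = [_spot(f, 5, 5) for f in range(0, 30)]
    tracks = link_trajectories(spots, max_disp=2, n_frames=30)
    assert dwell_times(tracks, 0.1) == []


def test_kymograph_stationary_and_moving_ridges():
    imaging = ImagingSpec(n_frames=20, shape=(32, 64), background_mean=0.0,
                          read_noise_sd=0.0, shot_noise=False)
    stationary = Track(0, 0, 0, 19, x_um=np.full(20, 1.0),
                       y_um=np.full(20, 1.6), intensities=np.full(20, 500.0))
    moving = Track(1, 0, 0, 19, x_um=(30 + np.arange(20)) * 0.1,
                   y_um=np.full(20, 1.6), intensities=np.full(20, 500.0))
    movie = render_movie([stationary, moving], imaging)
    kymo = make_kymograph(movie, line=(0.0, 16.0, 63.0, 16.0), width=3)
    assert kymo.image.shape[1] == 20
    # stationary emitter: vertical ridge at constant position 10
    ridge = np.argmax(kymo.image[:20], axis=0)
    assert np.all(ridge == 10)
    # moving emitter: ridge slope 1 px/frame
    pos = [20 + np.argmax(kymo.image[20:, f]) for f in range(20)]
    slope = np.polyfit(np.arange(20), pos, 1)[0]
    assert slope == pytest.approx(1.0, abs=0.05)


def test_kymograph_blank_movie_flat():
    movie = Movie(np.full((5, 16, 16), 3.0), 0.1, 0.1)
    kymo = make_kymograph(movie, line=(1.0, 8.0, 14.0, 8.0))
    assert np.allclose(kymo.image, 3.0)


def test_kymograph_line_outside_frame_rejected():
    movie = Movie(np.zeros((3, 16, 16)), 0.1, 0.1)
    with pytest.raises(InvalidParameterError):
        make_kymograph(movie, line=(0.0, 8.0, 20.0, 8.0))
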