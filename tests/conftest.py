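import numpy as np
import pytest

from nanotrack import ImagingSpec, PopulationSpec


@pytest.fixture
def imaging_small():
    """Small quiet acquisition for fast rendering tests."""
    return ImagingSpec(n_frames=20, shape=(64, 64))


@pytest.fixture
def single_mobile_population():
    return [PopulationSpec(diffusion_coefficient=0.035, fraction=1.0,
                           mean_intensity=1100.0, intensity_cv=0.0)]


def dispersed_positions(rng, n, lo, hi, min_sep):
    """Rejection-sample n points in [lo, hi]^2 with a minimum separation
    (well-dispersed spots, as in sparse membrane-particle imaging)."""
    pts = []
    while len(pts) < n:
        p = rng.uniform(lo, hi, size=2)
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_sep**2
               for q in pts):
            pts.append(p)
    return np.array(pts)


def mutual_match(a: np.ndarray, b: np.ndarray, radius: float):
    """Mutual-nearest-neighbor pairs between two point sets (test helper)."""
    from scipy.spatial import cKDTree
    if len(a) == 0 or len(b) == 0:
        return []
    ta, tb = cKDTree(a), cKDTree(b)
    d_ab, j_ab = tb.query(a, k=1)
    _, j_ba = ta.query(b, k=1)
    return [(i, j_ab[i], d_ab[i]) for i in range(len(a))
            if d_ab[i] <= radius and j_ba[j_ab[i]] == i]
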