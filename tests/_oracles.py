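"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: labeling is a pure-Python
breadth-first flood fill, the frustum centroid comes from 1D numerical
integration, and the correlation p-value from the incomplete-beta form of the
t CDF.
"""

from collections import deque
from itertools import product

import numpy as np
from scipy import integrate
from scipy.special import betainc


def neighbor_offsets(connectivity: int):
    offs = [
        d
        for d in product((-1, 0, 1), repeat=3)
        if any(d) and sum(map(abs, d)) <= {6: 1, 18: 2, 26: 3}[connectivity]
    ]
    return offs


def flood_fill_label(volume: np.ndarray, connectivity: int) -> np.ndarray:
    """BFS connected-component labeling, raster-scan seed order."""
    vol = np.asarray(volume) != 0
    labels = np.zeros(vol.shape, dtype=np.int32)
    offs = neighbor_offsets(connectivity)
    next_label = 0
    for idx in zip(*np.nonzero(vol)):
        if labels[idx]:
            continue
        next_label += 1
        queue = deque([idx])
        labels[idx] = next_label
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offs:
                n = (z + dz, y + dy, x + dx)
                if (
                    0 <= n[0] < vol.shape[0]
                    and 0 <= n[1] < vol.shape[1]
                    and 0 <= n[2] < vol.shape[2]
                    and vol[n]
                    and not labels[n]
                ):
                    labels[n] = next_label
                    queue.append(n)
    return labels


def frustum_centroid_from_top_numeric(d_top, d_bot, length):
    """Centroid depth below the wide face by numerical integration."""
    r = lambda t: d_top / 2 + (d_bot / 2 - d_top / 2) * t / length
    num, _ = integrate.quad(lambda t: t * np.pi * r(t) ** 2, 0, length)
    den, _ = integrate.quad(lambda t: np.pi * r(t) ** 2, 0, length)
    return num / den


def two_sided_p_from_r(r, n):
    """Pearson p via the incomplete-beta form of the t CDF (df = n − 2)."""
    df = n - 2
    t2 = r * r * df / (1 - r * r)
    return float(betainc(df / 2.0, 0.5, df / (df + t2)))


def sphere_fit_nonlinear(points, n_starts=8, seed=0):
    """Nonlinear least-squares sphere fit from multiple starts (scipy)."""
    from scipy.optimize import least_squares

    pts = np.asarray(points, float)
    rng = np.random.default_rng(seed)
    spread = pts.std()
    best = None
    for k in range(n_starts):
        c0 = pts.mean(axis=0) + (rng.normal(size=3) * spread if k else 0.0)
        r0 = np.linalg.norm(pts - c0, axis=1).mean()
        res = least_squares(
            lambda p: np.linalg.norm(pts - p[:3], axis=1) - p[3],
            np.r_[c0, r0],
        )
        if best is None or res.cost < best.cost:
            best = res
    return best.x[:3], best.x[3]
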