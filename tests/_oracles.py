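"""Independent oracles used by the test suite.

Each function recomputes a quantity by brute force or direct summation,
deliberately avoiding the code paths it is used to check.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def rotation_grid_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimal RMSD (Å) over rotations by brute-force grid search.

    Coarse rotation-vector grid over SO(3) refined hierarchically to a grid
    step below 1e-3 rad; independent of the Kabsch closed form.
    """
    am = mobile - mobile.mean(axis=0)
    ar = reference - reference.mean(axis=0)

    def eval_set(vecs):
        mats = Rotation.from_rotvec(vecs).as_matrix()
        rot = np.einsum("nij,pj->npi", mats, am)
        d = rot - ar[None]
        r = np.sqrt(np.mean(np.sum(d * d, axis=2), axis=1))
        k = int(np.argmin(r))
        return vecs[k], float(r[k])

    step = 0.2
    ax = np.arange(-np.pi - step, np.pi + step, step)
    grid = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    grid = grid[np.linalg.norm(grid, axis=1) <= np.pi + step]
    best_v, best = eval_set(grid)
    half = step
    while half / 4.0 > 2e-4:
        offs = np.linspace(-half, half, 9)
        local = np.stack(
            np.meshgrid(*[best_v[i] + offs for i in range(3)], indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        v, r = eval_set(local)
        if r < best:
            best_v, best = v, r
        half /= 4.0
    return best * 10.0


def ray_casting_inside(point, polygon) -> bool:
    """Scalar even-odd ray casting (boundary inclusive), one point at a time."""
    x, y = point
    n = len(polygon)
    inside = False
    for k in range(n):
        x1, y1 = polygon[k]
        x2, y2 = polygon[(k + 1) % n]
        # boundary
        dx, dy = x2 - x1, y2 - y1
        L2 = dx * dx + dy * dy
        if L2 > 0:
            t = max(0.0, min(1.0, ((x - x1) * dx + (y - y1) * dy) / L2))
            if (x - (x1 + t * dx)) ** 2 + (y - (y1 + t * dy)) ** 2 <= 1e-18:
                return True
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * dx / dy
            if x < xint:
                inside = not inside
    return inside


def direct_rscc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Pearson correlation over masked voxels by explicit summation."""
    va = [float(v) for v in a[mask]]
    vb = [float(v) for v in b[mask]]
    n = len(va)
    ma = sum(va) / n
    mb = sum(vb) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(va, vb))
    da = sum((x - ma) ** 2 for x in va)
    db = sum((y - mb) ** 2 for y in vb)
    return num / (da * db) ** 0.5


def numeric_gradient(fun, coords: np.ndarray, h: float = 3e-6) -> np.ndarray:
    """Central-difference gradient of a scalar function of (N, 3) coords."""
    grad = np.zeros_like(coords)
    for i in range(coords.shape[0]):
        for d in range(3):
            up = coords.copy()
            dn = coords.copy()
            up[i, d] += h
            dn[i, d] -= h
            grad[i, d] = (fun(up) - fun(dn)) / (2.0 * h)
    return grad


def gaussian_sum(points: np.ndarray, centers: np.ndarray, sigma: float,
                 normalized: bool = True, truncate: float | None = None
                 ) -> np.ndarray:
    """Direct analytic evaluation of a sum of isotropic Gaussians.

    ``truncate`` zeroes each Gaussian beyond that radius (in units of Å,
    e.g. ``4 * sigma`` for the deposit kernel's support).
    """
    total = np.zeros(len(points))
    norm = 1.0 / ((2.0 * np.pi) ** 1.5 * sigma**3) if normalized else 1.0
    if normalized and truncate is not None:
        from scipy.stats import chi

        norm /= chi(3).cdf(truncate / sigma)  # mass inside the support
    for c in centers:
        d2 = np.sum((points - c) ** 2, axis=1)
        term = norm * np.exp(-0.5 * d2 / sigma**2)
        if truncate is not None:
            term = np.where(d2 <= truncate**2, term, 0.0)
        total += term
    return total
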