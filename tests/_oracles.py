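"""Independent oracles used by the test suite.

These deliberately avoid the package's superposition/metric code paths:
the quaternion eigen-decomposition method for minimized RMSD, a brute
grid/polish search over rotations, and exhaustive pair enumeration for
local-distance-difference scores.
"""

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def quaternion_rmsd(mobile: np.ndarray, ref: np.ndarray) -> float:
    """Minimized RMSD via the quaternion (Kearsley) eigenvalue method."""
    mobile = mobile - mobile.mean(axis=0)
    ref = ref - ref.mean(axis=0)
    n = len(mobile)
    sm = mobile + ref
    dm = mobile - ref
    sx, sy, sz = sm[:, 0], sm[:, 1], sm[:, 2]
    dx, dy, dz = dm[:, 0], dm[:, 1], dm[:, 2]
    key = np.empty((4, 4))
    key[0, 0] = np.sum(dx * dx + dy * dy + dz * dz)
    key[1, 1] = np.sum(dx * dx + sy * sy + sz * sz)
    key[2, 2] = np.sum(sx * sx + dy * dy + sz * sz)
    key[3, 3] = np.sum(sx * sx + sy * sy + dz * dz)
    key[0, 1] = key[1, 0] = np.sum(sy * dz - dy * sz)
    key[0, 2] = key[2, 0] = np.sum(dx * sz - sx * dz)
    key[0, 3] = key[3, 0] = np.sum(sx * dy - dx * sy)
    key[1, 2] = key[2, 1] = np.sum(dx * dy - sx * sy)
    key[1, 3] = key[3, 1] = np.sum(dx * dz - sx * sz)
    key[2, 3] = key[3, 2] = np.sum(dy * dz - sy * sz)
    lam_min = np.linalg.eigvalsh(key)[0]
    return float(np.sqrt(max(lam_min, 0.0) / n))


def grid_search_rmsd(mobile: np.ndarray, ref: np.ndarray) -> float:
    """Brute-force minimum RMSD: coarse Euler-angle grid + local polish."""
    mobile_c = mobile - mobile.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)

    def rmsd_of(angles):
        rot = Rotation.from_euler("zyx", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((mobile_c @ rot.T - ref_c) ** 2, axis=1)))

    grid = np.linspace(-np.pi, np.pi, 13)
    best_angles, best = None, np.inf
    for angles in itertools.product(grid, grid, grid):
        value = rmsd_of(angles)
        if value < best:
            best, best_angles = value, angles
    result = minimize(rmsd_of, best_angles, method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
    return float(min(best, result.fun))


def brute_force_lddt(
    coords_ref: np.ndarray,
    coords_frame: np.ndarray,
    residue_of: np.ndarray,
    r0: float,
    thresholds,
) -> np.ndarray:
    """Per-residue lDDT by explicit loops over every atom pair."""
    n_atoms = len(coords_ref)
    n_res = int(residue_of.max()) + 1
    hits = np.zeros(n_res)
    totals = np.zeros(n_res)
    for i in range(n_atoms):
        for j in range(i + 1, n_atoms):
            if residue_of[i] == residue_of[j]:
                continue
            d_ref = np.linalg.norm(coords_ref[i] - coords_ref[j])
            if d_ref >= r0:
                continue
            d_t = np.linalg.norm(coords_frame[i] - coords_frame[j])
            frac = np.mean([abs(d_ref - d_t) < tau for tau in thresholds])
            for res in (residue_of[i], residue_of[j]):
                hits[res] += frac
                totals[res] += 1
    out = np.full(n_res, np.nan)
    mask = totals > 0
    out[mask] = hits[mask] / totals[mask]
    return out


def direct_pearson(x, y) -> float:
    """Pearson r from the raw covariance formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))


def random_rigid_transform(rng) -> tuple[np.ndarray, np.ndarray]:
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return rot.as_matrix(), rng.normal(scale=10.0, size=3)
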