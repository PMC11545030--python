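"""Independent reference implementations used only to cross-check results.

These deliberately avoid the package's code paths: plain loops, grid
searches and closed forms.
"""

import math

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def quaternion_grid_rmsd(mobile, reference, n_grid=20000, seed=0):
    """Brute-force minimal RMSD over rotations: random quaternion grid plus
    a Nelder-Mead polish on the rotation vector.  Translation is optimal at
    centroid alignment, so both sets are centered first."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)

    rng = np.random.default_rng(seed)
    quats = rng.normal(size=(n_grid, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    mats = Rotation.from_quat(quats).as_matrix()
    rotated = np.einsum("mij,nj->mni", mats, mob_c)
    rmsds = np.sqrt(np.mean(np.sum((rotated - ref_c) ** 2, axis=2), axis=1))
    best = int(np.argmin(rmsds))

    def objective(rotvec):
        moved = Rotation.from_rotvec(rotvec).apply(mob_c)
        return np.sqrt(np.mean(np.sum((moved - ref_c) ** 2, axis=1)))

    start = Rotation.from_quat(quats[best]).as_rotvec()
    result = minimize(
        objective, start, method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000},
    )
    return min(float(rmsds[best]), float(result.fun))


def brute_rmsf(frames):
    """From-scratch per-residue RMSF about the time-average, plain loops."""
    frames = [np.asarray(f, float) for f in frames]
    n_frames = len(frames)
    n_points = frames[0].shape[0]
    values = []
    for i in range(n_points):
        mean = sum(f[i] for f in frames) / n_frames
        acc = 0.0
        for f in frames:
            d = f[i] - mean
            acc += float(d @ d)
        values.append(math.sqrt(acc / n_frames))
    return np.array(values)


def subspan_trim_oracle(stable, threshold_percent=60):
    """Exhaustive enumeration of retained sub-spans for fusion trimming.

    Enumerates every contiguous sub-span (0-based index pairs), keeps those
    that start and end on stable residues and whose floored stable percent
    meets the threshold, and returns the (start, end) of the longest,
    breaking ties toward the later terminus.  Returns None when no span
    qualifies.
    """
    stable = list(bool(s) for s in stable)
    length = len(stable)
    candidates = []
    for s in range(length):
        for e in range(s, length):
            if not (stable[s] and stable[e]):
                continue
            window = stable[s : e + 1]
            k = sum(window)
            n = len(window)
            if math.floor(100 * k / n) >= threshold_percent:
                candidates.append((n, e, s))
    if not candidates:
        return None
    n, e, s = max(candidates)
    return s, e


def sampled_rmsf_expectation(sigma, n_frames, n_reps, seed):
    """Monte-Carlo estimate of E[RMSF] for isotropic per-axis Gaussian noise
    (closed form sigma*sqrt(3) as n_frames -> inf), independent of the
    package's trajectory machinery."""
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_reps):
        deviations = rng.normal(scale=sigma, size=(n_frames, 3))
        centered = deviations - deviations.mean(axis=0)
        estimates.append(np.sqrt(np.mean(np.sum(centered**2, axis=1))))
    return float(np.mean(estimates)), float(np.std(estimates, ddof=1))
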