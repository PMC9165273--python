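"""Independent brute-force / analytic oracles used by the test suite.

These deliberately avoid the package's own vectorised code paths: plain
loops, closed forms and enumeration, so agreement is meaningful.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import optimize, special


def brute_force_suvmax(data: np.ndarray, mask: np.ndarray) -> float:
    best = -np.inf
    for idx in np.ndindex(data.shape):
        if mask[idx]:
            best = max(best, data[idx])
    return best


def brute_force_suvpeak(data: np.ndarray, mask: np.ndarray, spacing, radius_mm: float) -> float:
    """O(N*K) scan: for every voxel whose sphere intersects the mask, the mean
    over in-volume voxels whose centres fall inside the sphere."""
    spacing = np.asarray(spacing, dtype=float)
    shape = data.shape
    half = np.floor(radius_mm / spacing).astype(int)
    offsets = [
        off
        for off in itertools.product(*(range(-h, h + 1) for h in half))
        if sum((o * s) ** 2 for o, s in zip(off, spacing)) <= radius_mm**2
    ]
    mask_idx = set(map(tuple, np.argwhere(mask)))
    best = -np.inf
    for centre in np.ndindex(shape):
        sphere = [
            tuple(np.add(centre, off))
            for off in offsets
            if all(0 <= centre[a] + off[a] < shape[a] for a in range(3))
        ]
        if not any(v in mask_idx for v in sphere):
            continue
        mean = np.mean([data[v] for v in sphere])
        best = max(best, mean)
    return float(best)


def pairwise_auc(scores, labels) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def enumerate_glcm(levels: np.ndarray, direction, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts by explicit pair enumeration."""
    mat = np.zeros((n_levels, n_levels))
    d = np.asarray(direction)
    for idx in np.ndindex(levels.shape):
        if levels[idx] == 0:
            continue
        nb = tuple(np.add(idx, d))
        if all(0 <= nb[a] < levels.shape[a] for a in range(3)) and levels[nb] > 0:
            mat[levels[idx] - 1, levels[nb] - 1] += 1
            mat[levels[nb] - 1, levels[idx] - 1] += 1
    return mat


def enumerate_runs(levels: np.ndarray, direction, n_levels: int) -> np.ndarray:
    """Run-length counts by walking every line voxel by voxel."""
    d = np.asarray(direction)
    shape = levels.shape
    mat = np.zeros((n_levels, max(shape)))

    def in_bounds(p):
        return all(0 <= p[a] < shape[a] for a in range(3))

    seen_starts = set()
    for idx in np.ndindex(shape):
        prev = tuple(np.subtract(idx, d))
        if levels[idx] > 0 and (not in_bounds(prev) or levels[prev] != levels[idx]):
            seen_starts.add(idx)
    for start in seen_starts:
        level = levels[start]
        length = 0
        p = np.asarray(start)
        while in_bounds(p) and levels[tuple(p)] == level:
            length += 1
            p = p + d
        mat[level - 1, length - 1] += 1
    return mat


def blurred_sphere_profile(r, radius: float, sigma: float) -> np.ndarray:
    """Radial profile of a unit uniform sphere convolved with an isotropic
    Gaussian of standard deviation sigma (closed form)."""
    r = np.asarray(r, dtype=float)
    out = np.empty_like(r)
    small = r < 1e-9
    s2 = sigma * math.sqrt(2.0)
    a = 0.5 * (special.erf((radius - r) / s2) + special.erf((radius + r) / s2))
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (
            sigma
            / (np.where(small, 1.0, r) * math.sqrt(2.0 * math.pi))
            * (np.exp(-((radius - r) ** 2) / (2 * sigma**2)) - np.exp(-((radius + r) ** 2) / (2 * sigma**2)))
        )
    out = a - np.where(small, 0.0, b)
    # exact value at the centre: erf(R/(s*sqrt2)) - R*sqrt(2/pi)/s * exp(-R^2/2s^2)
    centre = special.erf(radius / s2) - radius * math.sqrt(2.0 / math.pi) / sigma * math.exp(
        -(radius**2) / (2 * sigma**2)
    )
    out[small] = centre
    return out


def blurred_sphere_crossing_radius(radius: float, sigma: float, level: float) -> float:
    """Radius where the blurred unit-sphere profile crosses ``level``."""
    f = lambda r: blurred_sphere_profile(np.array([r]), radius, sigma)[0] - level
    return float(optimize.brentq(f, 1e-6, radius + 8 * sigma))


def newton_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-12, max_iter: int = 200):
    """Unpenalised logistic MLE by Newton-Raphson; returns (coef, intercept)."""
    Z = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Z.shape[1])
    for _ in range(max_iter):
        eta = Z @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        grad = Z.T @ (y - p)
        hess = (Z * w[:, None]).T @ Z
        step = np.linalg.solve(hess + 1e-12 * np.eye(len(beta)), grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    return beta[1:], beta[0]
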