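"""Independent numerical oracles used by the test suite.

These deliberately avoid the closed forms and code paths they check:
finite-difference diffusion for FRAP, exhaustive pair enumeration for
nearest-neighbor distances, and uniform point sampling for area fractions.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_banded


def fd_frap_center_intensity(
    D: float,
    width: float,
    depth: float,
    t_eval: np.ndarray,
    dx: float = 0.01,
    n_steps: int = 20000,
) -> np.ndarray:
    """Crank-Nicolson 1-D diffusion of a rectangular bleach on a long segment.

    Initial intensity 1 - depth inside |x| < width/2, 1 outside; reflecting
    ends far from the bleach. Returns the x = 0 intensity at ``t_eval``.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    t_max = float(t_eval.max())
    half_domain = width / 2 + 6.0 * np.sqrt(2.0 * D * t_max) + 2.0
    x = np.arange(-half_domain, half_domain + dx, dx)
    n = x.size
    center = int(np.argmin(np.abs(x)))
    u = np.where(np.abs(x) < width / 2, 1.0 - depth, 1.0)

    dt = t_max / n_steps
    r = D * dt / (2.0 * dx * dx)

    # banded matrices for (I - r*Lap) u_new = (I + r*Lap) u_old, Neumann ends
    ab = np.zeros((3, n))
    ab[0, 1:] = -r
    ab[1, :] = 1 + 2 * r
    ab[2, :-1] = -r
    ab[1, 0] = ab[1, -1] = 1 + r  # reflecting boundary
    lower = np.full(n - 1, r)
    upper = np.full(n - 1, r)
    diag = np.full(n, 1 - 2 * r)
    diag[0] = diag[-1] = 1 - r

    out = np.empty_like(t_eval)
    next_idx = 0
    t = 0.0
    order = np.argsort(t_eval)
    while next_idx < t_eval.size and t_eval[order[next_idx]] <= 0:
        out[order[next_idx]] = u[center]
        next_idx += 1
    for _ in range(n_steps):
        rhs = diag * u
        rhs[:-1] += upper * u[1:]
        rhs[1:] += lower * u[:-1]
        u = solve_banded((1, 1), ab, rhs)
        t += dt
        while next_idx < t_eval.size and t_eval[order[next_idx]] <= t + 1e-12:
            out[order[next_idx]] = u[center]
            next_idx += 1
    while next_idx < t_eval.size:
        out[order[next_idx]] = u[center]
        next_idx += 1
    return out


def brute_force_signed_distances(
    foci_xy: np.ndarray, foci_r: np.ndarray, ld_xy: np.ndarray, ld_r: np.ndarray
) -> np.ndarray:
    """Plain double loop over all focus/droplet pairs."""
    out = []
    for (fx, fy), fr in zip(foci_xy, foci_r):
        best = np.inf
        for (lx, ly), lr in zip(ld_xy, ld_r):
            d = np.hypot(fx - lx, fy - ly) - (lr + fr)
            best = min(best, d)
        out.append(best)
    return np.array(out)


def mc_area_fraction(
    ld_xy: np.ndarray,
    ld_r: np.ndarray,
    rA: float,
    width: float,
    height: float,
    n_points: int = 200000,
    seed: int = 0,
) -> tuple[float, float]:
    """Uniform point sampling estimate of the dilated-droplet coverage.

    Returns (estimate, standard error).
    """
    rng = np.random.default_rng(seed)
    pts = rng.uniform([0, 0], [width, height], size=(n_points, 2))
    d = np.linalg.norm(pts[:, None, :] - ld_xy[None, :, :], axis=2)
    inside = np.any(d <= (ld_r + rA)[None, :], axis=1)
    p = inside.mean()
    return float(p), float(np.sqrt(p * (1 - p) / n_points))
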