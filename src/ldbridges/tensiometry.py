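"""Interfacial tension by the drop-weight (drop-volume) method.

A drop growing slowly at the tip of a tube of inner diameter ``d``
detaches when its weight overcomes the vertical pull of surface tension;
only part of the drop falls, so the force balance carries an empirical
geometric correction ``f``:

    gamma = m * g / (pi * d * f),        m = v * delta_rho,

where ``v`` is the detached volume and ``delta_rho`` the density contrast
between the drop and the surrounding phase. ``f`` depends on the ratio of
the tube radius to the size of the detached drop and is interpolated from
the classical Harkins-Brown calibration table, tabulated against
``x = r_tube / V^(1/3)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import TableRangeError

__all__ = [
    "DropSeries",
    "TensionResult",
    "correction_factor",
    "surface_tension",
    "HB_TABLE_X",
    "HB_TABLE_F",
]

G_STANDARD = 9.81  # m/s^2

# Harkins & Brown drop-weight correction, f vs x = r_tube / V^(1/3)
# (classical empirical calibration; the x = 0 anchor is the thin-tip Tate
# limit f -> 1, bridged to the tabulated range by monotone interpolation).
HB_TABLE_X = np.array(
    [0.00, 0.30, 0.35, 0.40, 0.45, 0.50, 0.55, 0.60, 0.65, 0.70,
     0.75, 0.80, 0.85, 0.90, 0.95, 1.00, 1.05, 1.10, 1.15, 1.20]
)
HB_TABLE_F = np.array(
    [1.0000, 0.7256, 0.7011, 0.6828, 0.6669, 0.6515, 0.6362, 0.6250, 0.6171, 0.6093,
     0.6032, 0.6000, 0.5992, 0.5998, 0.6034, 0.6098, 0.6179, 0.6280, 0.6407, 0.6535]
)

_HB_SPLINE = PchipInterpolator(HB_TABLE_X, HB_TABLE_F)

# r_tube / V^(1/3) = ratio * (3 / 4pi)^(1/3) for a spherical detached drop
_SPHERE_FACTOR = (3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass
class DropSeries:
    """Detachment volumes from one tensiometry run."""

    drop_volume_uL: np.ndarray
    tube_diameter_um: float
    delta_rho_kg_m3: float
    g_m_s2: float = G_STANDARD

    def __post_init__(self):
        self.drop_volume_uL = np.atleast_1d(np.asarray(self.drop_volume_uL, dtype=float))
        if self.drop_volume_uL.size < 1 or np.any(self.drop_volume_uL <= 0):
            raise ValueError("need >= 1 strictly positive drop volume")
        for name in ("tube_diameter_um", "delta_rho_kg_m3", "g_m_s2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class TensionResult:
    """Mean interfacial tension with per-drop corrections."""

    gamma_mN_m: float
    gamma_sd_mN_m: float
    gamma_per_drop_mN_m: np.ndarray = field(repr=False)
    f_per_drop: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.gamma_mN_m <= 0:
            raise ValueError("gamma must be > 0")
        if np.any(self.f_per_drop <= 0) or np.any(self.f_per_drop > 1.05):
            raise ValueError("correction factors must lie in (0, 1.05]")


def correction_factor(ratio) -> np.ndarray | float:
    """Harkins-Brown correction f for tube-radius / detached-drop-radius.

    Shape-preserving (PCHIP) interpolation of the empirical table; raises
    :class:`TableRangeError` outside the tabulated range.
    """
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio <= 0):
        raise ValueError("ratio must be > 0")
    x = ratio * _SPHERE_FACTOR
    lo, hi = HB_TABLE_X[0], HB_TABLE_X[-1]
    if np.any(x > hi):
        raise TableRangeError(
            f"r_tube/r_drop = {float(np.max(ratio)):.4g} maps to x = {float(np.max(x)):.4g} "
            f"outside the tabulated range [{lo}, {hi}] "
            f"(valid ratio range (0, {hi / _SPHERE_FACTOR:.4g}])"
        )
    out = _HB_SPLINE(x)
    return out if out.ndim else float(out)


def _correction_from_volume(v_m3: np.ndarray, tube_radius_m: float) -> np.ndarray:
    r_drop = (3.0 * v_m3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return np.asarray(correction_factor(tube_radius_m / r_drop))


def surface_tension(series: DropSeries) -> TensionResult:
    """Per-drop gamma_i = m_i g / (pi d f_i), reported as mean +/- SD in mN/m.

    The correction f_i follows directly from each measured volume (the
    detached-drop radius is known), so no iteration is needed on the
    analysis side.
    """
    v_m3 = series.drop_volume_uL * 1e-9
    d_m = series.tube_diameter_um * 1e-6
    m_kg = v_m3 * series.delta_rho_kg_m3
    f = _correction_from_volume(v_m3, d_m / 2.0)
    gamma_N_m = m_kg * series.g_m_s2 / (np.pi * d_m * f)
    gamma = gamma_N_m * 1e3
    return TensionResult(
        gamma_mN_m=float(np.mean(gamma)),
        gamma_sd_mN_m=float(np.std(gamma, ddof=1)) if gamma.size > 1 else 0.0,
        gamma_per_drop_mN_m=gamma,
        f_per_drop=f,
    )


def detachment_volume_uL(
    gamma_mN_m: float,
    tube_diameter_um: float,
    delta_rho_kg_m3: float,
    g_m_s2: float = G_STANDARD,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> float:
    """Ideal detachment volume solving v*delta_rho*g = gamma*pi*d*f(v).

    Damped fixed-point iteration on v; used by the synthetic generator and
    as the inverse of :func:`surface_tension`. Raises if no self-consistent
    solution is reached within the tabulated correction range.
    """
    if gamma_mN_m <= 0 or tube_diameter_um <= 0 or delta_rho_kg_m3 <= 0:
        raise ValueError("gamma, d and delta_rho must be > 0")
    gamma = gamma_mN_m * 1e-3
    d_m = tube_diameter_um * 1e-6
    base = gamma * np.pi * d_m / (delta_rho_kg_m3 * g_m_s2)  # volume for f = 1
    v = base
    for _ in range(max_iter):
        f = float(_correction_from_volume(np.array([v]), d_m / 2.0)[0])
        v_new = base * f
        if abs(v_new - v) <= tol * v:
            return v_new * 1e9
        v = 0.5 * (v + v_new)  # damping keeps the iterate inside the table
    raise RuntimeError(
        "self-consistent detachment volume did not converge within "
        f"{max_iter} iterations (gamma={gamma_mN_m} mN/m, d={tube_diameter_um} um)"
    )
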