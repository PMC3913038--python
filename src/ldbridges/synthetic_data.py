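"""Synthetic inputs for every pipeline stage.

This module generates, with known ground truth, each kind of data the
analyses consume: two-channel fields of disk-shaped lipid droplets with
punctate foci (uniformly placed or droplet-enriched), saturating
exponential targeting time courses with a lag, 1-D tubule FRAP recovery
traces, drop-weight detachment series, and droplet diameter populations
(bimodal control-like, monodisperse, or giant).

All randomness flows through ``numpy.random.default_rng(seed)``; seeded
runs are bit-reproducible. At zero noise every generated curve satisfies
its defining closed form exactly, so the analysis stages can be tested
against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd

from .bridge_kinetics import TimeCourse, closed_form_N
from .errors import PlacementError
from .frap import FrapCurve, recovery_model
from .particles import ParticleSet
from .tensiometry import DropSeries, detachment_volume_uL

__all__ = [
    "FieldSpec",
    "GroundTruth",
    "gen_field",
    "sample_field_particles",
    "gen_timecourse",
    "gen_frap_curve",
    "gen_drop_series",
    "gen_size_population",
]

_MAX_PLACEMENT_TRIES = 1000


@dataclass
class FieldSpec:
    """Parameters of one synthetic two-channel field.

    Droplet radii are drawn from ``ld_radius_law``: ``{"kind": "fixed",
    "radius_um": r}`` or ``{"kind": "lognormal", "median_um": m, "sigma": s}``
    or ``{"kind": "mixture", "components": [...], "weights": [...]}``.
    ``enrichment`` is the probability that a focus is planted overlapping a
    droplet (center within rLD + rA of a droplet center); the remaining
    foci are uniform over the field.
    """

    field_width_um: float = 51.2
    field_height_um: float = 51.2
    pixel_size_um: float = 0.1
    n_ld: int = 50
    ld_radius_law: dict = field(
        default_factory=lambda: {"kind": "lognormal", "median_um": 0.8, "sigma": 0.25}
    )
    n_foci: int = 40
    focus_radius_um: float = 0.15
    enrichment: float = 0.0
    background: float = 100.0
    peak: float = 1000.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if not 0 <= self.enrichment <= 1:
            raise ValueError("enrichment must lie in [0, 1]")
        if self.n_ld < 0 or self.n_foci < 0:
            raise ValueError("particle counts must be >= 0")
        if self.field_width_um <= 0 or self.field_height_um <= 0:
            raise ValueError("field dimensions must be > 0")


@dataclass
class GroundTruth:
    """Planted particle tables and per-focus colocalization flags."""

    ld: pd.DataFrame  # columns x_um, y_um, radius_um
    foci: pd.DataFrame  # columns x_um, y_um, radius_um, planted_colocalized
    spec: FieldSpec

    def particle_sets(self) -> tuple[ParticleSet, ParticleSet]:
        """Ground-truth (foci, lds) particle sets for the analysis stages."""
        kwargs = dict(
            field_width_um=self.spec.field_width_um,
            field_height_um=self.spec.field_height_um,
            pixel_size_um=self.spec.pixel_size_um,
        )
        lds = ParticleSet.from_arrays(
            self.ld[["x_um", "y_um"]].to_numpy(), self.ld["radius_um"].to_numpy(), "ld", **kwargs
        )
        foci = ParticleSet.from_arrays(
            self.foci[["x_um", "y_um"]].to_numpy(),
            self.foci["radius_um"].to_numpy(),
            "focus",
            **kwargs,
        )
        return foci, lds


def _draw_radii(law: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = law.get("kind")
    if kind == "fixed":
        return np.full(n, float(law["radius_um"]))
    if kind == "lognormal":
        return rng.lognormal(np.log(law["median_um"]), law["sigma"], size=n)
    if kind == "mixture":
        comps, weights = law["components"], np.asarray(law["weights"], dtype=float)
        idx = rng.choice(len(comps), size=n, p=weights / weights.sum())
        return np.array([_draw_radii(comps[i], 1, rng)[0] for i in idx])
    raise ValueError(f"unknown radius law kind {kind!r}")


def _place_inside(
    rng: np.random.Generator, w: float, h: float, margin: float
) -> tuple[float, float]:
    if 2 * margin >= w or 2 * margin >= h:
        raise PlacementError(
            f"particle of radius {margin} um cannot fit fully inside a "
            f"{w} x {h} um field"
        )
    return rng.uniform(margin, w - margin), rng.uniform(margin, h - margin)


def sample_field_particles(
    spec: FieldSpec, rng: np.random.Generator | None = None
) -> GroundTruth:
    """Sample droplet and focus positions/radii without rendering an image.

    Droplets and foci lie fully inside the field. A focus planted as
    colocalized (with probability ``enrichment``) is centered uniformly
    within ``rLD + rA`` of a randomly chosen droplet center; the rest are
    uniform over the field.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    w, h = spec.field_width_um, spec.field_height_um

    ld_radii = _draw_radii(spec.ld_radius_law, spec.n_ld, rng)
    ld_xy = np.array([_place_inside(rng, w, h, r) for r in ld_radii]).reshape(-1, 2)

    rA = spec.focus_radius_um
    foci_xy = np.empty((spec.n_foci, 2))
    flags = np.zeros(spec.n_foci, dtype=bool)
    for i in range(spec.n_foci):
        colocalized = spec.n_ld > 0 and rng.random() < spec.enrichment
        if colocalized:
            j = rng.integers(spec.n_ld)
            reach = ld_radii[j] + rA
            for _ in range(_MAX_PLACEMENT_TRIES):
                # uniform over the disk of radius rLD + rA around the LD center
                r = reach * np.sqrt(rng.random())
                theta = rng.uniform(0, 2 * np.pi)
                x = ld_xy[j, 0] + r * np.cos(theta)
                y = ld_xy[j, 1] + r * np.sin(theta)
                if rA <= x <= w - rA and rA <= y <= h - rA:
                    break
            else:
                raise PlacementError(
                    f"could not place a colocalized focus near droplet {j} "
                    f"inside the field after {_MAX_PLACEMENT_TRIES} tries"
                )
            foci_xy[i] = (x, y)
            flags[i] = True
        else:
            foci_xy[i] = _place_inside(rng, w, h, rA)

    ld = pd.DataFrame({"x_um": ld_xy[:, 0], "y_um": ld_xy[:, 1], "radius_um": ld_radii})
    foci = pd.DataFrame(
        {
            "x_um": foci_xy[:, 0],
            "y_um": foci_xy[:, 1],
            "radius_um": np.full(spec.n_foci, rA),
            "planted_colocalized": flags,
        }
    )
    return GroundTruth(ld=ld, foci=foci, spec=spec)


def _render_disks(
    shape: tuple[int, int],
    xy_um: np.ndarray,
    radii_um: np.ndarray,
    pixel_size: float,
    amplitude: float,
) -> np.ndarray:
    """Additively draw anti-aliased disks (coverage-shaded 1-px edge)."""
    img = np.zeros(shape, dtype=np.float64)
    for (x, y), r in zip(xy_um, radii_um):
        cx, cy, rp = x / pixel_size, y / pixel_size, r / pixel_size
        x0, x1 = max(int(cx - rp - 2), 0), min(int(cx + rp + 3), shape[1])
        y0, y1 = max(int(cy - rp - 2), 0), min(int(cy + rp + 3), shape[0])
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.hypot(xx + 0.5 - cx, yy + 0.5 - cy)
        img[y0:y1, x0:x1] += amplitude * np.clip(rp - dist + 0.5, 0.0, 1.0)
    return img


def gen_field(spec: FieldSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a two-channel field ``(2, H, W)``: channel 0 droplets, 1 foci.

    Intensities are ``background`` plus ``peak - background`` per disk with
    additive Gaussian noise of ``noise_sd``.
    """
    rng = np.random.default_rng(spec.seed)
    truth = sample_field_particles(spec, rng)
    h = int(round(spec.field_height_um / spec.pixel_size_um))
    w = int(round(spec.field_width_um / spec.pixel_size_um))
    amp = spec.peak - spec.background
    ld_img = _render_disks(
        (h, w), truth.ld[["x_um", "y_um"]].to_numpy(), truth.ld["radius_um"].to_numpy(),
        spec.pixel_size_um, amp,
    )
    focus_img = _render_disks(
        (h, w), truth.foci[["x_um", "y_um"]].to_numpy(), truth.foci["radius_um"].to_numpy(),
        spec.pixel_size_um, amp,
    )
    stack = np.stack([ld_img, focus_img]) + spec.background
    if spec.noise_sd > 0:
        stack = stack + rng.normal(0.0, spec.noise_sd, size=stack.shape)
    return stack.astype(np.float32), truth


def gen_timecourse(
    tau: float = 3.6,
    lag: float = 5.0,
    plateau: float = 1.0,
    t_grid=None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> TimeCourse:
    """Saturating-exponential targeting curve with a pre-rise lag.

    Defaults mirror the observed targeting kinetics: characteristic time
    tau = 3.6 min with a lag in the 1-25 min range. Noise is additive
    zero-mean Gaussian on every sample.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if lag < 0:
        raise ValueError("lag must be >= 0")
    t = np.arange(0.0, lag + 8 * tau, tau / 8) if t_grid is None else np.asarray(t_grid, float)
    if not np.all(np.diff(t) > 0):
        raise ValueError("t_grid must be strictly increasing")
    y = closed_form_N(t, tau, lag, plateau)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.shape)
    return TimeCourse(t_min=t, intensity=np.asarray(y))


def gen_frap_curve(
    D: float = 0.035,
    bleach_width: float = 2.0,
    depth: float = 0.9,
    t_grid=None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> FrapCurve:
    """Tubule FRAP recovery at the bleach center.

    Defaults to the apparent ER diffusion coefficient D = 0.035 um^2/s; the
    closed form is the 1-D rectangular-bleach solution of
    :func:`ldbridges.frap.recovery_model`.
    """
    if D <= 0 or bleach_width <= 0:
        raise ValueError("D and bleach_width must be > 0")
    if not 0 < depth <= 1:
        raise ValueError("depth must lie in (0, 1]")
    if t_grid is None:
        t_half = (bleach_width / 4.0) ** 2 / D  # recovery time scale
        t_grid = np.linspace(0.0, 12 * t_half, 120)
    t = np.asarray(t_grid, dtype=float)
    y = recovery_model(t, D, bleach_width, depth)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.shape)
    return FrapCurve(
        t_s=t, intensity=np.clip(y, 0.0, None), bleach_width_um=bleach_width, bleach_depth=depth
    )


def gen_drop_series(
    gamma: float = 2.0,
    d: float = 250.0,
    delta_rho: float = 90.0,
    n_drops: int = 15,
    noise_frac: float = 0.01,
    seed: int | None = None,
) -> DropSeries:
    """Drop-detachment volumes consistent with gamma = m g / (pi d f).

    Defaults emulate buffer drops forming in a triglyceride phase from a
    250 um tube: a phospholipid-covered oil/water interfacial tension of a
    few mN/m and a small density contrast. Each ideal detachment volume is
    perturbed by a relative Gaussian error ``noise_frac``.
    """
    if n_drops < 1:
        raise ValueError("n_drops must be >= 1")
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    v_ideal = detachment_volume_uL(gamma, d, delta_rho)
    v = np.full(n_drops, v_ideal)
    if noise_frac > 0:
        v = v * (1.0 + np.random.default_rng(seed).normal(0.0, noise_frac, size=n_drops))
    return DropSeries(drop_volume_uL=v, tube_diameter_um=d, delta_rho_kg_m3=delta_rho)


_SIZE_DEFAULTS = {
    # control cells: many small droplets plus a few large expanding ones
    "bimodal": {
        "weights": (0.75, 0.25),
        "median_um": (0.5, 3.0),
        "sigma": (0.30, 0.25),
    },
    # Arf1/COPI-depleted phenotype: narrow population around 1.3 um
    "monodisperse": {"mean_um": 1.3, "sigma": 0.15},
    # coalesced giant droplets (CCT1-depletion-like): heavy right tail
    "giant": {"median_um": 4.0, "sigma": 0.5},
}


def gen_size_population(
    mode: Literal["bimodal", "monodisperse", "giant"],
    params: dict | None = None,
    n: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Droplet diameter sample (um) for one of three phenotypes.

    ``monodisperse`` draws a narrow lognormal with arithmetic mean
    ``mean_um`` (default 1.3 um); ``bimodal`` a two-component lognormal
    mixture; ``giant`` a broad heavy-tailed lognormal.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode not in _SIZE_DEFAULTS:
        raise ValueError(f"unknown mode {mode!r}; expected one of {sorted(_SIZE_DEFAULTS)}")
    p = {**_SIZE_DEFAULTS[mode], **(params or {})}
    rng = np.random.default_rng(seed)
    if mode == "monodisperse":
        sigma = p["sigma"]
        mu = np.log(p["mean_um"]) - sigma**2 / 2.0  # arithmetic mean = mean_um
        return rng.lognormal(mu, sigma, size=n)
    if mode == "giant":
        return rng.lognormal(np.log(p["median_um"]), p["sigma"], size=n)
    weights = np.asarray(p["weights"], dtype=float)
    comp = rng.choice(len(weights), size=n, p=weights / weights.sum())
    med = np.asarray(p["median_um"], dtype=float)
    sig = np.asarray(p["sigma"], dtype=float)
    return rng.lognormal(np.log(med[comp]), sig[comp])


def spec_to_dict(spec: FieldSpec) -> dict:
    return asdict(spec)
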