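"""Binomial random-placement null for focus-droplet colocalization.

A punctate focus of radius ``rA`` overlaps a droplet of radius ``rLD``
when their centers are closer than ``rLD + rA``; equivalently, when the
focus center falls inside the droplet dilated by ``rA``. If foci were
placed uniformly at random over the field, the chance of a single focus
overlapping any droplet equals the dilated-area fraction ``s``, and the
number of colocalized foci out of ``nA`` follows Binomial(nA, s). An
observed count ``n_exp`` far above the null mode ``n_s`` indicates
enrichment on droplets; far below, exclusion.

The textbook formula sums ``pi (rLD + rA)^2`` over droplets, which
overcounts overlapping dilated disks and can exceed 1; here ``s`` is the
area of the geometric union clipped to the field, so it is always a valid
probability (identical for sparse droplets). Both values are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from shapely.geometry import Point, box
from shapely.ops import unary_union

from .errors import DegenerateVarianceError
from .particles import ParticleSet

__all__ = [
    "ColocResult",
    "FieldAggregate",
    "signed_nn_distances",
    "dilated_area_fraction",
    "binomial_null",
    "coloc_verdict",
    "analyze_field",
    "aggregate_fields",
]

Verdict = Literal["enriched", "excluded", "random-consistent"]


@dataclass
class ColocResult:
    """Colocalization statistics for one field of view."""

    nA: int
    n_exp: int
    s: float
    n_s: int
    tail_p: float
    verdict: Verdict
    signed_distances_um: np.ndarray | None = field(default=None, repr=False)
    s_sum: float | None = None  # naive sum-of-areas value, may exceed 1

    def __post_init__(self):
        if not 0 <= self.n_exp <= self.nA:
            raise ValueError("n_exp must lie in [0, nA]")
        if not 0 <= self.s <= 1:
            raise ValueError("s must lie in [0, 1]")
        if not 0 <= self.tail_p <= 1:
            raise ValueError("tail_p must lie in [0, 1]")


def signed_nn_distances(foci: ParticleSet, lds: ParticleSet) -> np.ndarray:
    """Per-focus signed distance to the nearest droplet boundary contact.

    For each focus the minimum over droplets of
    ``centroid distance - (rLD + rA)``; negative values mean overlap.
    With no droplets every distance is ``+inf``.
    """
    if foci.pixel_size_um != lds.pixel_size_um:
        raise ValueError(
            f"pixel size mismatch: foci {foci.pixel_size_um} vs lds {lds.pixel_size_um}"
        )
    n_foci = len(foci)
    if n_foci == 0:
        return np.empty(0)
    if len(lds) == 0:
        return np.full(n_foci, np.inf)
    fc, fr = foci.centroids(), foci.radii()
    lc, lr = lds.centroids(), lds.radii()
    # (n_foci, n_ld) pairwise center distances minus summed radii
    d = np.linalg.norm(fc[:, None, :] - lc[None, :, :], axis=2)
    signed = d - (lr[None, :] + fr[:, None])
    return signed.min(axis=1)


def dilated_area_fraction(
    lds: ParticleSet,
    rA: float,
    area_f_um2: float | None = None,
    quad_segs: int = 64,
) -> float:
    """Fraction of the field covered by droplets dilated by the focus radius.

    The dilated disks are merged as a geometric union and clipped to the
    field rectangle, so the result is a probability in [0, 1]. With no
    droplets the fraction is 0.
    """
    if rA < 0:
        raise ValueError("rA must be >= 0")
    area_f = lds.area_f_um2 if area_f_um2 is None else area_f_um2
    if area_f <= 0:
        raise ValueError("field area must be > 0")
    if len(lds) == 0:
        return 0.0
    disks = [
        Point(x, y).buffer(r + rA, quad_segs=quad_segs)
        for (x, y), r in zip(lds.centroids(), lds.radii())
    ]
    union = unary_union(disks)
    if lds.field_width_um > 0 and lds.field_height_um > 0:
        union = union.intersection(box(0, 0, lds.field_width_um, lds.field_height_um))
    return min(union.area / area_f, 1.0)


def naive_area_fraction(lds: ParticleSet, rA: float, area_f_um2: float | None = None) -> float:
    """Sum-of-disk-areas variant of ``s``; may exceed 1 for crowded fields."""
    area_f = lds.area_f_um2 if area_f_um2 is None else area_f_um2
    if area_f <= 0:
        raise ValueError("field area must be > 0")
    return float(np.sum(np.pi * (lds.radii() + rA) ** 2) / area_f)


def binomial_null(nA: int, s: float) -> tuple[np.ndarray, int]:
    """Exact Binomial(nA, s) pmf over 0..nA and its mode n_s.

    Ties in the argmax are broken toward smaller n (conservative for
    calling enrichment).
    """
    if nA < 0:
        raise ValueError("nA must be >= 0")
    if not 0 <= s <= 1:
        raise ValueError("s must lie in [0, 1]")
    n = np.arange(nA + 1)
    pmf = stats.binom.pmf(n, nA, s)
    n_s = int(np.argmax(pmf))  # np.argmax returns the first (smallest) maximizer
    return pmf, n_s


def coloc_verdict(
    n_exp: int,
    nA: int,
    s: float,
    alpha: float = 0.01,
    signed_distances_um: np.ndarray | None = None,
    s_sum: float | None = None,
) -> ColocResult:
    """Classify an observed colocalized count against the binomial null.

    ``enriched`` when the upper tail P(X >= n_exp) <= alpha, ``excluded``
    when the lower tail P(X <= n_exp) <= alpha, otherwise consistent with
    random placement. ``tail_p`` is the smaller of the two tails.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    _, n_s = binomial_null(nA, s)
    upper = float(stats.binom.sf(n_exp - 1, nA, s))  # P(X >= n_exp)
    lower = float(stats.binom.cdf(n_exp, nA, s))  # P(X <= n_exp)
    if upper <= alpha:
        verdict: Verdict = "enriched"
    elif lower <= alpha:
        verdict = "excluded"
    else:
        verdict = "random-consistent"
    return ColocResult(
        nA=int(nA),
        n_exp=int(n_exp),
        s=float(s),
        n_s=n_s,
        tail_p=min(upper, lower),
        verdict=verdict,
        signed_distances_um=signed_distances_um,
        s_sum=s_sum,
    )


def analyze_field(
    foci: ParticleSet,
    lds: ParticleSet,
    alpha: float = 0.01,
    rA: float | None = None,
) -> ColocResult:
    """Full per-field analysis: distances, dilated fraction, verdict.

    ``rA`` defaults to the mean focus radius, matching the dilation used by
    the overlap rule.
    """
    distances = signed_nn_distances(foci, lds)
    n_exp = int(np.sum(distances <= 0))
    rA_eff = float(np.mean(foci.radii())) if rA is None and len(foci) else (rA or 0.0)
    s = dilated_area_fraction(lds, rA_eff)
    s_sum = naive_area_fraction(lds, rA_eff) if len(lds) else 0.0
    return coloc_verdict(
        n_exp, len(foci), s, alpha, signed_distances_um=distances, s_sum=s_sum
    )


@dataclass
class FieldAggregate:
    """Condition-level summary across fields."""

    n_fields: int
    mean_observed_fraction: float
    mean_null_fraction: float
    t_statistic: float
    p_value: float
    pooled_verdict: Verdict


def aggregate_fields(results: Sequence[ColocResult], alpha: float = 0.01) -> FieldAggregate:
    """Paired comparison of observed vs null colocalized fractions.

    Two-sided paired t test of n_exp/nA against n_s/nA across fields; the
    pooled verdict is the sign of the mean difference when significant.
    """
    results = [r for r in results if r.nA > 0]
    if len(results) < 2:
        raise ValueError("need >= 2 non-empty fields to aggregate")
    obs = np.array([r.n_exp / r.nA for r in results])
    null = np.array([r.n_s / r.nA for r in results])
    diffs = obs - null
    if np.ptp(diffs) == 0:
        raise DegenerateVarianceError(
            "observed-minus-null fractions are identical across fields; "
            "the paired t statistic is undefined"
        )
    t_stat, p = stats.ttest_rel(obs, null)
    if p < alpha and diffs.mean() > 0:
        verdict: Verdict = "enriched"
    elif p < alpha and diffs.mean() < 0:
        verdict = "excluded"
    else:
        verdict = "random-consistent"
    return FieldAggregate(
        n_fields=len(results),
        mean_observed_fraction=float(obs.mean()),
        mean_null_fraction=float(null.mean()),
        t_statistic=float(t_stat),
        p_value=float(p),
        pooled_verdict=verdict,
    )
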