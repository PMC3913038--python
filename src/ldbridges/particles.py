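"""Particle containers shared by the segmentation and colocalization stages.

A :class:`Particle` is one segmented object — a lipid droplet or a protein
focus — reduced to its centroid and equivalent radius in physical units.
A :class:`ParticleSet` is all particles of one channel in one field of view,
together with the field geometry needed by the random-placement null model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = ["Particle", "ParticleSet"]


@dataclass(frozen=True)
class Particle:
    """One segmented object.

    Attributes
    ----------
    x_um, y_um:
        Centroid position in micrometres (0-based, x = column axis).
    radius_um:
        Equivalent-circle radius, ``sqrt(area / pi)`` in micrometres.
    area_px:
        Object area in pixels.
    channel:
        Channel label, e.g. ``"ld"`` or ``"focus"``.
    """

    x_um: float
    y_um: float
    radius_um: float
    area_px: float
    channel: str

    def __post_init__(self):
        if not self.radius_um > 0:
            raise ValueError(f"radius_um must be > 0, got {self.radius_um}")


@dataclass
class ParticleSet:
    """Particles of one channel plus the field geometry.

    ``area_f_um2`` is the total field area used as the denominator of the
    dilated-area fraction; it defaults to ``width * height``.
    """

    particles: list[Particle] = field(default_factory=list)
    field_width_um: float = 0.0
    field_height_um: float = 0.0
    pixel_size_um: float = 1.0

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        channels = {p.channel for p in self.particles}
        if len(channels) > 1:
            raise ValueError(f"all particles must share a channel, got {channels}")

    @property
    def area_f_um2(self) -> float:
        return self.field_width_um * self.field_height_um

    @property
    def channel(self) -> str | None:
        return self.particles[0].channel if self.particles else None

    def __len__(self) -> int:
        return len(self.particles)

    def __iter__(self) -> Iterator[Particle]:
        return iter(self.particles)

    # -- array views -------------------------------------------------------

    def centroids(self) -> np.ndarray:
        """(n, 2) array of centroids in micrometres (x, y)."""
        if not self.particles:
            return np.empty((0, 2))
        return np.array([[p.x_um, p.y_um] for p in self.particles])

    def radii(self) -> np.ndarray:
        return np.array([p.radius_um for p in self.particles])

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_um": [p.x_um for p in self.particles],
                "y_um": [p.y_um for p in self.particles],
                "radius_um": [p.radius_um for p in self.particles],
                "area_px": [p.area_px for p in self.particles],
                "channel": [p.channel for p in self.particles],
            }
        )

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.attrs = {}
        header = (
            f"# field_width_um={self.field_width_um} "
            f"field_height_um={self.field_height_um} "
            f"pixel_size_um={self.pixel_size_um}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "ParticleSet":
        with open(path) as fh:
            first = fh.readline()
            meta = {}
            if first.startswith("#"):
                for tok in first[1:].split():
                    k, v = tok.split("=")
                    meta[k] = float(v)
                df = pd.read_csv(fh)
            else:
                fh.seek(0)
                df = pd.read_csv(fh)
        particles = [
            Particle(r.x_um, r.y_um, r.radius_um, r.area_px, str(r.channel))
            for r in df.itertuples()
        ]
        return cls(
            particles,
            field_width_um=meta.get("field_width_um", 0.0),
            field_height_um=meta.get("field_height_um", 0.0),
            pixel_size_um=meta.get("pixel_size_um", 1.0),
        )

    @classmethod
    def from_arrays(
        cls,
        xy_um: Iterable,
        radii_um: Iterable,
        channel: str,
        field_width_um: float,
        field_height_um: float,
        pixel_size_um: float = 1.0,
    ) -> "ParticleSet":
        xy = np.asarray(list(xy_um), dtype=float).reshape(-1, 2)
        radii = np.asarray(list(radii_um), dtype=float)
        particles = [
            Particle(float(x), float(y), float(r), float(np.pi * (r / pixel_size_um) ** 2), channel)
            for (x, y), r in zip(xy, radii)
        ]
        return cls(particles, field_width_um, field_height_um, pixel_size_um)
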