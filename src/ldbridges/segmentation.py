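"""Threshold-and-label segmentation of LD and focus channels.

Each channel is binarized with an automatic (Otsu) or fixed threshold,
connected components below a minimum pixel area are discarded, and each
remaining object is reduced to an intensity-weighted centroid and an
equivalent-circle radius in micrometres. Touching droplets are not split:
the downstream random-placement null only needs the total dilated area.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .particles import Particle, ParticleSet

__all__ = ["segment_particles"]


def segment_particles(
    image: np.ndarray,
    channel: str,
    threshold: float | str = "otsu",
    min_area_px: int = 5,
    pixel_size_um: float = 1.0,
) -> ParticleSet:
    """Segment one channel into a :class:`ParticleSet`.

    Parameters
    ----------
    image:
        Single-channel 2-D array.
    channel:
        Label attached to every particle (e.g. ``"ld"``).
    threshold:
        ``"otsu"`` for automatic thresholding, or a numeric cutoff.
    min_area_px:
        Components smaller than this are discarded.
    pixel_size_um:
        Pixel pitch; converts centroids and radii to micrometres.

    An image that is empty after thresholding yields an empty particle set,
    not an error.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D single-channel image, got shape {image.shape}")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")

    h, w = image.shape
    field_kwargs = dict(
        field_width_um=w * pixel_size_um,
        field_height_um=h * pixel_size_um,
        pixel_size_um=pixel_size_um,
    )

    if threshold == "otsu":
        if np.ptp(image) == 0:  # constant image: nothing to segment
            return ParticleSet([], **field_kwargs)
        cut = threshold_otsu(image)
    else:
        cut = float(threshold)
    mask = image > cut
    if not mask.any():
        return ParticleSet([], **field_kwargs)

    labels = label(mask)
    particles = []
    for prop in regionprops(labels, intensity_image=image):
        if prop.area < min_area_px:
            continue
        cy, cx = prop.centroid_weighted
        area_um2 = prop.area * pixel_size_um**2
        particles.append(
            Particle(
                x_um=float(cx * pixel_size_um),
                y_um=float(cy * pixel_size_um),
                radius_um=float(np.sqrt(area_um2 / np.pi)),
                area_px=float(prop.area),
                channel=channel,
            )
        )
    return ParticleSet(particles, **field_kwargs)
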