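"""Probability/intensity fusion into the next iteration's enhanced input.

The original intensities carry local detail; the probability map carries
the long-range structure the network has learned.  Fusion first screens
the intensities — a voxel keeps I(x) only if its probability, on the 8-bit
scale, exceeds a small threshold δ — and then mixes the screened intensity
with the (floored) probability term:

    F(x) = α/(α+β) · Θ(x) · I(x) + β/(α+β) · ⌊(1−α) · IM · P(x)⌋,

where Θ(x) ∈ {0, 1} is the screening indicator (255·P(x) > δ), IM is the
maximum image intensity, and α, β weight the two contributions.  The
result feeds the enhancement filter to produce the next pseudo-label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volio import as_array

__all__ = ["FusionParams", "screen_foreground", "fuse_probability"]


class FusionConfigError(ValueError):
    pass


@dataclass
class FusionParams:
    """Fusion weights and screening threshold.

    ``alpha`` weights the original intensity (0.8 by default), ``beta``
    the probability term (defaults to 1 − α).  ``delta`` screens the
    foreground on the 0–255 probability scale (δ = 2: a voxel keeps its
    intensity only when 255·P > 2).
    """

    alpha: float = 0.8
    beta: float | None = None
    delta: float = 2.0
    im: float = 255.0

    def __post_init__(self):
        if self.beta is None:
            self.beta = 1.0 - self.alpha

    def validate(self) -> None:
        if not (0.0 <= self.alpha <= 1.0) or not (0.0 <= self.beta <= 1.0):
            raise FusionConfigError("alpha and beta must lie in [0, 1]")
        if self.alpha + self.beta <= 0:
            raise FusionConfigError("alpha + beta must be positive")
        if not (0.0 <= self.delta <= self.im):
            raise FusionConfigError(f"delta must lie in [0, IM={self.im}]")


def screen_foreground(image, prob, delta: float = 2.0) -> np.ndarray:
    """Zero the intensity wherever the 8-bit-scale probability is <= δ."""
    img = np.asarray(as_array(image), dtype=np.float64)
    p = np.asarray(as_array(prob), dtype=np.float64)
    if img.shape != p.shape:
        raise ValueError(f"shape mismatch: image {img.shape} vs prob {p.shape}")
    return np.where(255.0 * p > delta, img, 0.0)


def fuse_probability(image, prob, params: FusionParams | None = None) -> np.ndarray:
    """Fuse intensities with the probability map; output clipped to [0, IM]."""
    params = params or FusionParams()
    params.validate()
    img = np.asarray(as_array(image), dtype=np.float64)
    p = np.asarray(as_array(prob), dtype=np.float64)
    if img.shape != p.shape:
        raise ValueError(f"shape mismatch: image {img.shape} vs prob {p.shape}")
    a, b = params.alpha, params.beta
    theta = (255.0 * p > params.delta).astype(np.float64)
    # the 1e-9 guard keeps the floor from dropping a whole intensity level
    # on exact values reached with rounding error ((1-0.8)*255 = 50.999...)
    fused = (a / (a + b)) * theta * img \
        + (b / (a + b)) * np.floor((1.0 - a) * params.im * p + 1e-9)
    return np.clip(fused, 0.0, params.im)
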