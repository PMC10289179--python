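"""Synthetic 3D neuron phantoms.

Generates fMOST-like image volumes together with voxel-exact ground-truth
masks: bright tubular neurites of varying radius whose intensity peaks on
the centerline and decays radially, optional spherical somata attached to
neurite endpoints, an uneven background illumination ramp, and additive
Gaussian (optionally Poisson) noise at a controllable level.  Every stage
of the segmentation pipeline can therefore be exercised and scored without
microscopy data.

Geometry and noise are drawn from independent RNG streams derived from the
same seed, so the ground-truth mask never depends on ``noise_sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["PhantomConfig", "generate_phantom", "rasterize_neurites"]


class PhantomConfigError(ValueError):
    """Raised when a :class:`PhantomConfig` violates its invariants."""


@dataclass
class PhantomConfig:
    """Parameters of the synthetic volume.

    All intensities are on the 8-bit [0, 255] scale.  ``shape`` is (z, y, x).
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    n_neurites: int = 5
    radius_range: tuple[float, float] = (1.5, 3.0)
    soma_radius_range: tuple[float, float] = (5.0, 7.0)
    n_somata: int | None = None          # default: n_neurites // 2
    centerline_intensity: float = 200.0
    soma_intensity: float = 255.0
    background_level: float = 20.0
    illumination_gradient: float = 0.25  # fraction of background per volume span
    noise_sigma: float = 15.0
    intensity_falloff: float = 1.0       # radial decay: exp(-(d/r)^2 * falloff)
    poisson_noise: bool = False
    max_turn_deg: float = 30.0           # max turning angle per centerline step
    step_length: float = 2.0             # voxels per random-walk step
    seed: int = 0

    def validate(self) -> None:
        if any(s < 16 for s in self.shape) or len(self.shape) != 3:
            raise PhantomConfigError(f"shape must be a (z,y,x) triple, each >= 16; got {self.shape}")
        if self.radius_range[0] < 1 or self.radius_range[0] > self.radius_range[1]:
            raise PhantomConfigError(f"radius_range min must be >= 1 and <= max; got {self.radius_range}")
        if 2 * self.radius_range[0] > min(self.shape):
            raise PhantomConfigError("shape too small to contain the minimum tube radius")
        for name in ("centerline_intensity", "soma_intensity", "background_level"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise PhantomConfigError(f"{name} must lie in [0, 255]; got {v}")
        if self.n_neurites < 0 or self.noise_sigma < 0:
            raise PhantomConfigError("n_neurites and noise_sigma must be non-negative")

    @property
    def soma_count(self) -> int:
        return self.n_neurites // 2 if self.n_somata is None else self.n_somata


def _random_centerline(rng: np.random.Generator, shape, step: float, max_turn_deg: float):
    """Piecewise-linear random walk with bounded turning angle.

    Starts at a random interior point with a random heading and walks until
    it leaves the volume (the last point is clipped to the boundary), turning
    at most ``max_turn_deg`` per step.  Returns an (N, 3) float array of
    (z, y, x) points.
    """
    lo = np.array([2.0, 2.0, 2.0])
    hi = np.asarray(shape, float) - 3.0
    start = rng.uniform(lo, hi)
    theta = rng.uniform(0, np.pi)
    phi = rng.uniform(0, 2 * np.pi)
    d = np.array([np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)])
    pts = [start.copy()]
    p = start
    max_steps = int(4 * max(shape) / step)
    cos_max = np.cos(np.deg2rad(max_turn_deg))
    for _ in range(max_steps):
        # Sample a new heading within the turning cone (uniform in the cone).
        cos_a = rng.uniform(cos_max, 1.0)
        sin_a = np.sqrt(max(0.0, 1 - cos_a**2))
        psi = rng.uniform(0, 2 * np.pi)
        # Orthonormal frame around d.
        a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(d, a)
        u /= np.linalg.norm(u)
        v = np.cross(d, u)
        d = cos_a * d + sin_a * (np.cos(psi) * u + np.sin(psi) * v)
        d /= np.linalg.norm(d)
        p = p + step * d
        if np.any(p < 0) or np.any(p > np.asarray(shape, float) - 1):
            pts.append(np.clip(p, 0, np.asarray(shape, float) - 1))
            break
        pts.append(p.copy())
    return np.asarray(pts)


def _resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at (sub-voxel) arc-length spacing."""
    if len(points) < 2:
        return points
    seg = np.diff(points, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    if total == 0:
        return points[:1]
    n = max(2, int(np.ceil(total / spacing)) + 1)
    t = np.linspace(0, total, n)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(t, arclen, points[:, k])
    return out


def rasterize_neurites(shape, centerlines, radii, falloff: float = 1.0,
                       peak: float = 200.0, resample_spacing: float = 0.25):
    """Rasterize tubes around polyline centerlines.

    Parameters
    ----------
    shape : (z, y, x) volume extents.
    centerlines : list of (N, 3) arrays of (z, y, x) points.
    radii : per-neurite tube radius in voxels.
    falloff : radial intensity decay factor.
    peak : centerline intensity.

    Returns
    -------
    mask : bool array — voxels within Euclidean distance ``radius`` of the
        (resampled) centerline.
    intensity : float array — ``peak * exp(-(d/r)^2 * falloff)`` within 2r of
        the centerline, 0 elsewhere; overlapping tubes combine by maximum.
    """
    shape = tuple(int(s) for s in shape)
    mask = np.zeros(shape, dtype=bool)
    intensity = np.zeros(shape, dtype=np.float64)
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    for pts, r in zip(centerlines, radii):
        pts = _resample_polyline(np.asarray(pts, float), resample_spacing)
        tree = cKDTree(pts)
        reach = 2.0 * r  # beyond 2r the profile is < e^{-4} of peak
        lo = np.maximum(np.floor(pts.min(axis=0) - reach).astype(int), 0)
        hi = np.minimum(np.ceil(pts.max(axis=0) + reach).astype(int) + 1, shape)
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        sub = np.stack([zz[sl], yy[sl], xx[sl]], axis=-1).reshape(-1, 3).astype(float)
        d, _ = tree.query(sub, workers=-1)
        d = d.reshape(tuple(h - l for l, h in zip(lo, hi)))
        mask[sl] |= d <= r
        prof = peak * np.exp(-((d / r) ** 2) * falloff)
        prof[d > reach] = 0.0
        intensity[sl] = np.maximum(intensity[sl], prof)
    return mask, intensity


def generate_phantom(config: PhantomConfig):
    """Generate a synthetic neuron volume.

    Returns
    -------
    image : uint8 array (z, y, x) — background + illumination ramp +
        structures + noise, clipped to [0, 255].
    mask : uint8 array, values {0, 1} — voxels inside a tube or a soma ball.
    """
    config.validate()
    shape = tuple(int(s) for s in config.shape)
    ss = np.random.SeedSequence(config.seed)
    geom_rng, noise_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    centerlines, radii = [], []
    for _ in range(config.n_neurites):
        pts = _random_centerline(geom_rng, shape, config.step_length, config.max_turn_deg)
        centerlines.append(pts)
        radii.append(geom_rng.uniform(*config.radius_range))

    mask, intensity = rasterize_neurites(
        shape, centerlines, radii,
        falloff=config.intensity_falloff, peak=config.centerline_intensity,
    )

    # Somata: balls at a random endpoint of a subset of neurites.
    n_som = min(config.soma_count, config.n_neurites)
    if config.n_neurites > 0 and n_som > 0:
        chosen = geom_rng.choice(config.n_neurites, size=n_som, replace=False)
        zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        for i in chosen:
            end = centerlines[i][0] if geom_rng.random() < 0.5 else centerlines[i][-1]
            r = geom_rng.uniform(*config.soma_radius_range)
            d2 = (zz - end[0]) ** 2 + (yy - end[1]) ** 2 + (xx - end[2]) ** 2
            ball = d2 <= r**2
            mask |= ball
            prof = config.soma_intensity * np.exp(-(d2 / r**2) * config.intensity_falloff)
            prof[d2 > (2 * r) ** 2] = 0.0
            intensity = np.maximum(intensity, prof)

    # Background with a linear illumination ramp along x.
    x = np.arange(shape[2], dtype=float)
    ramp = 1.0 + config.illumination_gradient * (x / max(shape[2] - 1, 1) - 0.5)
    image = np.broadcast_to(config.background_level * ramp, shape).astype(np.float64).copy()
    image = np.maximum(image, intensity)

    if config.poisson_noise:
        image = noise_rng.poisson(np.clip(image, 0, None)).astype(np.float64)
    noise = noise_rng.standard_normal(shape)
    image = image + config.noise_sigma * noise

    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return image, mask.astype(np.uint8)
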