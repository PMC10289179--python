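"""Weak-neurite mining by seeded region growing on the probability map.

The network's probability map under-covers weak neurites.  Seeds are the
maximum-probability voxels (P >= 0.5).  For every connected seed component
an adaptive threshold ρ is the mean probability over the component's outer
shell — the union of 5×5×5-minus-center neighborhoods of its voxels minus
all seed voxels — i.e. the local probability floor just outside the seed.
The region then grows to any connected voxel whose probability strictly
exceeds the ρ of an adjacent component, iterated to a fixed point, which
absorbs faint but contiguous neurite continuations while the noise floor
stays excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volio import as_array

__all__ = ["GrowParams", "GrowResult", "seed_region", "adaptive_threshold",
           "region_grow", "refine_labels"]

log = logging.getLogger(__name__)

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
    "8-in-plane": np.ones((1, 3, 3), dtype=bool),
}


@dataclass
class GrowParams:
    """Region-growing parameters.

    ``grow_connectivity``: 6/18/26 (3D) or "8-in-plane" (per-XY-slice
    8-neighborhood).  ``per_component``: one adaptive ρ per connected seed
    component (distant regions have different local noise floors); with
    False a single global ρ is used.
    """

    seed_threshold: float = 0.5
    shell_size: int = 5                      # outer neighborhood is shell³ minus center
    grow_connectivity: object = 26
    max_grow_iters: int = 1000
    per_component: bool = True

    def validate(self) -> None:
        if self.grow_connectivity not in _STRUCTS:
            raise ValueError(f"grow_connectivity must be one of {list(_STRUCTS)}")
        if self.shell_size % 2 != 1 or self.shell_size < 3:
            raise ValueError("shell_size must be an odd integer >= 3")


@dataclass
class GrowResult:
    seed: np.ndarray            # Oreg, bool
    shell: np.ndarray           # Nreg (union over components), bool
    rho: dict                   # component label -> adaptive threshold
    grown: np.ndarray           # Greg, bool
    truncated: bool = False


def seed_region(prob) -> np.ndarray:
    """Maximum-probability classification: the P >= 0.5 voxels."""
    p = np.asarray(as_array(prob), dtype=np.float64)
    return p >= 0.5


def _label_seed(seed):
    return ndimage.label(seed, structure=_STRUCTS[26])


def adaptive_threshold(prob, seed, params: GrowParams | None = None):
    """Per-component adaptive growth threshold ρ.

    For each connected seed component, Nreg is the union of the
    5×5×5-minus-center neighborhoods of its voxels with all seed voxels
    removed, and ρ is the mean probability over Nreg.  If Nreg is empty
    (seed fills the volume) ρ = 1.0, so no growth is possible.

    Returns (rho, labels, shell): a {component label: ρ} dict, the labeled
    seed array, and the union shell mask.
    """
    params = params or GrowParams()
    params.validate()
    p = np.asarray(as_array(prob), dtype=np.float64)
    seed = np.asarray(as_array(seed)).astype(bool)
    if p.shape != seed.shape:
        raise ValueError("probability/seed shape mismatch")
    foot = np.ones((params.shell_size,) * 3, dtype=bool)
    if params.per_component:
        labels, n = _label_seed(seed)
    else:
        labels = seed.astype(np.int32)
        n = 1 if seed.any() else 0
    rho: dict[int, float] = {}
    shell_union = np.zeros(seed.shape, dtype=bool)
    for comp in range(1, n + 1):
        comp_mask = labels == comp
        shell = ndimage.binary_dilation(comp_mask, structure=foot) & ~seed
        shell_union |= shell
        if shell.any():
            rho[comp] = float(p[shell].mean())
        else:
            rho[comp] = 1.0
            log.warning("seed component %d has an empty shell; rho set to 1.0", comp)
    return rho, labels, shell_union


def region_grow(prob, seed, rho, labels=None, params: GrowParams | None = None) -> GrowResult:
    """Grow each seed component to connected voxels with s(v) > ρ.

    Membership has path semantics independent of visiting order: a voxel
    belongs to the grown region of component c exactly when some connected
    path from c's seed reaches it along which every voxel has s(v) > ρ_c
    (strict, as the growth predicate prescribes).  The implementation is a
    monotone threshold relaxation — each voxel carries the smallest ρ that
    has reached it, and a voxel transmits a threshold only if its own
    probability exceeds it — iterated to a fixed point.
    """
    params = params or GrowParams()
    params.validate()
    p = np.asarray(as_array(prob), dtype=np.float64)
    seed = np.asarray(as_array(seed)).astype(bool)
    if labels is None:
        if params.per_component:
            labels, _ = _label_seed(seed)
        else:
            labels = seed.astype(np.int32)
    struct = _STRUCTS[params.grow_connectivity]
    # rho_map holds the growth threshold carried by each grown voxel;
    # +inf outside the region so erosion finds the min neighboring rho.
    rho_map = np.full(p.shape, np.inf)
    for comp, r in rho.items():
        rho_map[labels == comp] = r
    truncated = False
    footprint = struct.astype(bool)
    for _ in range(params.max_grow_iters):
        neigh_min = ndimage.minimum_filter(rho_map, footprint=footprint,
                                           mode="constant", cval=np.inf)
        relax = (p > neigh_min) & (neigh_min < rho_map)
        if not relax.any():
            break
        rho_map[relax] = neigh_min[relax]
    else:
        truncated = True
        log.warning("region growing truncated at max_grow_iters=%d", params.max_grow_iters)
    region = seed | np.isfinite(rho_map)
    shell_union = np.zeros(seed.shape, dtype=bool)
    return GrowResult(seed=seed, shell=shell_union, rho=dict(rho),
                      grown=region, truncated=truncated)


def refine_labels(prob, params: GrowParams | None = None) -> np.ndarray:
    """Full refinement: seed → adaptive ρ → grow.  Returns Greg as uint8 {0, 1}."""
    params = params or GrowParams()
    params.validate()
    p = np.asarray(as_array(prob), dtype=np.float64)
    seed = seed_region(p)
    if not seed.any():
        log.warning("empty seed region; returning empty refined mask")
        return np.zeros(p.shape, dtype=np.uint8)
    rho, labels, shell = adaptive_threshold(p, seed, params)
    result = region_grow(p, seed, rho, labels=labels, params=params)
    result.shell = shell
    return result.grown.astype(np.uint8)
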