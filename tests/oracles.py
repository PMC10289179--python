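"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately written as plain loops / closed forms with
no shared code with the package, so each oracle is an independent check of
the vectorized implementation it validates.
"""

import math

import numpy as np


def brute_force_dt(fg: np.ndarray) -> np.ndarray:
    """Min Euclidean distance from each foreground voxel to any background
    voxel, including the one-voxel virtual background shell around the
    volume; 0 on background."""
    shape = fg.shape
    bg = [tuple(c) for c in np.argwhere(~fg)]
    for z in range(-1, shape[0] + 1):
        for y in range(-1, shape[1] + 1):
            for x in range(-1, shape[2] + 1):
                if not (0 <= z < shape[0] and 0 <= y < shape[1] and 0 <= x < shape[2]):
                    bg.append((z, y, x))
    bg = np.asarray(bg, dtype=float)
    out = np.zeros(shape)
    for c in np.argwhere(fg):
        out[tuple(c)] = np.sqrt(((bg - c) ** 2).sum(axis=1)).min()
    return out


def symmetric_eig3(h: np.ndarray) -> np.ndarray:
    """Closed-form (trigonometric) eigenvalues of a symmetric 3×3 matrix."""
    p1 = h[0, 1] ** 2 + h[0, 2] ** 2 + h[1, 2] ** 2
    q = np.trace(h) / 3.0
    p2 = ((h[0, 0] - q) ** 2 + (h[1, 1] - q) ** 2 + (h[2, 2] - q) ** 2 + 2 * p1)
    p = np.sqrt(p2 / 6.0)
    if p < 1e-30:
        return np.array([h[0, 0], h[1, 1], h[2, 2]])
    b = (h - q * np.eye(3)) / p
    r = np.clip(np.linalg.det(b) / 2.0, -1.0, 1.0)
    phi = np.arccos(r) / 3.0
    e1 = q + 2 * p * np.cos(phi)
    e3 = q + 2 * p * np.cos(phi + 2 * np.pi / 3.0)
    e2 = 3 * q - e1 - e3
    return np.array([e1, e2, e3])


def brute_force_otsu(values: np.ndarray) -> float:
    """Exhaustive 8-bit Otsu: the threshold maximizing between-class variance."""
    hist = np.bincount(values.astype(np.uint8).ravel(), minlength=256).astype(float)
    total = hist.sum()
    best_t, best_var = 0, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (np.arange(t + 1) * hist[: t + 1]).sum() / w0
        m1 = (np.arange(t + 1, 256) * hist[t + 1:]).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def bfs_grow(prob, seed_labels, rho, connectivity=26, order_rng=None):
    """Breadth-first region growing with path semantics: a voxel belongs to
    the grown region of component c iff a connected path from c's seed
    reaches it with s > ρ_c at every step.  One independent BFS per
    component; frontier order may be shuffled (the result must not depend
    on it)."""
    if connectivity == 26:
        offsets = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
                   for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    elif connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        raise ValueError(connectivity)
    shape = prob.shape
    out = np.zeros(shape, dtype=bool)
    for comp, r in rho.items():
        visited = set(tuple(c) for c in np.argwhere(seed_labels == comp))
        frontier = list(visited)
        while frontier:
            if order_rng is not None:
                order_rng.shuffle(frontier)
            nxt = []
            for c in frontier:
                for off in offsets:
                    nb = tuple(np.add(c, off))
                    if not all(0 <= nb[i] < shape[i] for i in range(3)):
                        continue
                    if nb not in visited and prob[nb] > r:
                        visited.add(nb)
                        nxt.append(nb)
            frontier = nxt
        for c in visited:
            out[c] = True
    return out


def scalar_loop_losses(p, g):
    """WCE (as printed) and ε=1 Dice, as plain Python loops."""
    pl = [float(v) for v in np.asarray(p).ravel()]
    gl = [float(v) for v in np.asarray(g).ravel()]
    n = len(pl)
    gamma = sum(gl) / n
    wce = 0.0
    for pi, gi in zip(pl, gl):
        wce += -gamma * gi * math.log(max(pi, 1e-7))
    inter = sum(pi * gi for pi, gi in zip(pl, gl))
    dice = 1.0 - (2.0 * inter + 1.0) / (sum(pl) + sum(gl) + 1.0)
    return wce, dice


def voxel_loop_metrics(pred, gt):
    """Confusion counts and ratio metrics as explicit voxel loops."""
    tp = fp = fn = tn = 0
    for p, g in zip(np.asarray(pred).ravel(), np.asarray(gt).ravel()):
        p, g = bool(p), bool(g)
        if p and g:
            tp += 1
        elif p:
            fp += 1
        elif g:
            fn += 1
        else:
            tn += 1
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    jaccard = tp / (tp + fp + fn) if tp + fp + fn else 0.0
    return tp, fp, fn, tn, precision, recall, f1, jaccard
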