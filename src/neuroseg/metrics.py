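"""Voxel-wise segmentation metrics.

Precision, recall, F1 and Jaccard from the voxel confusion counts, with
the 8-bit binarization convention used throughout the pipeline (a
probability map scaled to 0–255 is thresholded at 200).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .volio import as_array

__all__ = ["SegMetrics", "binarize_prob", "seg_metrics"]


@dataclass
class SegMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    jaccard: float
    undefined: tuple = ()   # names of 0/0 ratios reported as 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["undefined"] = list(self.undefined)
        return d


def binarize_prob(prob8, threshold: float = 200.0) -> np.ndarray:
    """Binarize an 8-bit-scale probability volume at ``threshold`` (inclusive)."""
    p = np.asarray(as_array(prob8), dtype=np.float64)
    return (p >= threshold).astype(np.uint8)


def seg_metrics(pred, gt) -> SegMetrics:
    """Confusion counts and ratio metrics between two binary masks.

    Ratios with a 0/0 denominator are reported as 0 and flagged in
    ``undefined`` so batch evaluation stays total.
    """
    p = np.asarray(as_array(pred)).astype(bool)
    g = np.asarray(as_array(gt)).astype(bool)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    f1 = ratio(2.0 * precision * recall, precision + recall, "f1")
    jaccard = ratio(tp, tp + fp + fn, "jaccard")
    return SegMetrics(tp=tp, fp=fp, fn=fn, tn=tn, precision=precision,
                      recall=recall, f1=f1, jaccard=jaccard,
                      undefined=tuple(undefined))
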