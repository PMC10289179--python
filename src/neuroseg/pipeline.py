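"""The iterative weak-supervision loop.

Each iteration: train the segmentation network on the current input volume
and pseudo-labels, predict a probability map, mine weak neurites by region
growing, fuse the refined probabilities with the original intensities, and
re-run the enhancement filter on the fused volume to produce the next
pseudo-label.  Iterating lets the enhancement filter and the network
correct each other without any manual annotation.

Convergence follows a double-delta rule on the per-iteration F1 history:
iteration t is optimal once both F_t − F_{t−1} and F_{t+1} − F_t fall
below a tolerance (0.005).  When ground truth is available (phantom runs)
F_t is the network F1 on a held-out test sub-volume; in a truly label-free
run the same rule is applied to the Dice between successive pseudo-labels
(label stability).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .enhance import EnhancerParams, enhance_volume, make_pseudolabels
from .fuse import FusionParams, fuse_probability
from .metrics import binarize_prob, seg_metrics
from .nnet import TrainConfig, build_model, predict, train
from .refine import GrowParams, refine_labels
from .volio import as_array, preprocess, predict_averaged, write_stack

__all__ = ["LoopConfig", "IterationState", "check_convergence",
           "run_iteration", "run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class LoopConfig:
    """Configuration of the full iterative run.

    ``split`` divides the volume along z into train/validation/test
    fractions; training uses the train+validation sub-volumes, the F1
    history is measured on the test sub-volume.  ``convergence_source``
    "auto" uses ground truth when supplied and label stability otherwise.
    """

    max_iterations: int = 8
    f1_tolerance: float = 0.005
    convergence_source: str = "auto"   # {"auto", "ground_truth", "label_stability"}
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    tta: bool = True                   # inverse-transform prediction averaging
    equalize: bool = True
    warm_start: bool = False           # reuse previous iteration's weights
    enhancer: EnhancerParams = field(default_factory=EnhancerParams)
    train: TrainConfig = field(default_factory=TrainConfig)
    grow: GrowParams = field(default_factory=GrowParams)
    fusion: FusionParams = field(default_factory=FusionParams)

    def validate(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.f1_tolerance <= 0:
            raise ValueError("f1_tolerance must be positive")
        if self.convergence_source not in ("auto", "ground_truth", "label_stability"):
            raise ValueError(f"unknown convergence_source {self.convergence_source!r}")
        if abs(sum(self.split) - 1.0) > 1e-9 or min(self.split) < 0:
            raise ValueError("split fractions must be non-negative and sum to 1")


@dataclass
class IterationState:
    """Artifacts of one loop iteration.

    ``pseudo_label`` is the label the model of this iteration was trained
    on; ``next_pseudo``/``fused`` feed the next iteration; ``f1`` is F_t.
    Iteration 0 is the loop entry: pseudo-label from the enhancement
    filter on the raw volume, no model, no prediction.
    """

    index: int
    input_image: np.ndarray
    pseudo_label: np.ndarray
    model: object = None
    prob_map: np.ndarray | None = None
    fused: np.ndarray | None = None
    next_pseudo: np.ndarray | None = None
    f1: float | None = None
    rho: dict = field(default_factory=dict)
    seconds: float = 0.0


def check_convergence(f1_history, tolerance: float = 0.005):
    """Smallest interior index t with F_t−F_{t−1} < tol and F_{t+1}−F_t < tol.

    Indices are 0-based into ``f1_history``; detection is retrospective
    (needs F_{t+1}), so histories of length <= 2 return None.
    """
    h = list(f1_history)
    for t in range(1, len(h) - 1):
        if h[t] - h[t - 1] < tolerance and h[t + 1] - h[t] < tolerance:
            return t
    return None


def _z_split(nz: int, fractions):
    a = int(round(nz * fractions[0]))
    b = int(round(nz * (fractions[0] + fractions[1])))
    return slice(0, a), slice(a, b), slice(b, nz)


def _derive_seed(seed: int, t: int) -> int:
    return int(np.random.SeedSequence([seed, t]).generate_state(1)[0] % (2**31))


def _fused_scale_params(config: LoopConfig) -> EnhancerParams:
    """Enhancer thresholds re-expressed on the fused intensity scale.

    Fusion attenuates the kept intensities by α/(α+β); the a-priori
    thresholds I1/I2 keep their meaning on the fused volume only when
    scaled by the same factor — otherwise weak structures the screen
    preserved fall below the foreground binarization each iteration.
    """
    from dataclasses import replace
    f = config.fusion
    factor = f.alpha / (f.alpha + f.beta)
    if factor <= 0:
        return config.enhancer
    return replace(config.enhancer,
                   fg_threshold_i1=config.enhancer.fg_threshold_i1 * factor,
                   soma_threshold_i2=config.enhancer.soma_threshold_i2 * factor)


def initial_state(raw, config: LoopConfig) -> IterationState:
    """Loop entry: enhancement filter + threshold segmentation on the raw volume."""
    raw = as_array(raw)
    enhanced = enhance_volume(raw, config.enhancer)
    pseudo = make_pseudolabels(enhanced, config.enhancer)
    if not pseudo.any():
        raise PipelineError("initial pseudo-label is empty: the enhancement filter "
                            "produced a degenerate output on this volume")
    return IterationState(index=0, input_image=np.asarray(raw), pseudo_label=pseudo)


def run_iteration(prev: IterationState, raw, config: LoopConfig,
                  gt=None) -> IterationState:
    """One loop iteration: train → predict → refine → fuse → re-enhance."""
    config.validate()
    raw = as_array(raw)
    t0 = time.time()
    t = prev.index + 1
    if not prev.pseudo_label.any():
        raise PipelineError(f"pseudo-label entering iteration {t} is empty")
    tr_sl, va_sl, te_sl = _z_split(raw.shape[0], config.split)

    image01 = preprocess(prev.input_image, equalize=config.equalize)
    pairs = [(image01[sl], prev.pseudo_label[sl]) for sl in (tr_sl, va_sl)
             if sl.stop - sl.start > 0 and prev.pseudo_label[sl].size]
    tcfg_kwargs = {**vars(config.train)}
    tcfg_kwargs["seed"] = _derive_seed(config.seed, t)
    tcfg = TrainConfig(**tcfg_kwargs)
    if config.warm_start and prev.model is not None:
        model = prev.model
        model.config = tcfg
    else:
        model = build_model(tcfg)
    train(model, pairs, tcfg)

    if config.tta:
        prob = predict_averaged(lambda v: predict(model, v), image01)
    else:
        prob = predict(model, image01)

    refined = refine_labels(prob, config.grow)
    prob_refined = np.maximum(prob, refined.astype(np.float64))
    fused = fuse_probability(raw, prob_refined, config.fusion)
    next_pseudo = make_pseudolabels(
        enhance_volume(fused, _fused_scale_params(config)), config.enhancer)

    source = config.convergence_source
    if source == "auto":
        source = "ground_truth" if gt is not None else "label_stability"
    if source == "ground_truth":
        pred_mask = binarize_prob(prob[te_sl] * 255.0, 200.0)
        f1 = seg_metrics(pred_mask, as_array(gt)[te_sl]).f1
    else:
        # Label stability: Dice between the pseudo-label this iteration
        # trained on and the one it produced.
        f1 = _dice(prev.pseudo_label, next_pseudo)

    return IterationState(index=t, input_image=fused, pseudo_label=next_pseudo,
                          model=model, prob_map=prob, fused=fused,
                          next_pseudo=next_pseudo, f1=float(f1),
                          seconds=time.time() - t0)


def _dice(a, b) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    s = a.sum() + b.sum()
    if s == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / s


def run_pipeline(raw, gt=None, config: LoopConfig | None = None, workdir=None):
    """Run the loop to convergence (or ``max_iterations``).

    Returns (final_mask, report).  The final mask is the best iteration's
    probability map binarized at 200 on the 8-bit scale; "best" is the
    convergence-optimal iteration, falling back to the argmax of the F1
    history.  The report records the per-iteration history, parameters and
    timing; with ``workdir`` every iteration's artifacts are written as
    TIFF stacks.
    """
    config = config or LoopConfig()
    config.validate()
    raw = as_array(raw)
    gt_arr = None if gt is None else as_array(gt)
    tr_sl, va_sl, te_sl = _z_split(raw.shape[0], config.split)

    state = initial_state(raw, config)
    report = {
        "f1_history": [],
        "pseudo_f1": None,
        "seconds": [],
        "seed": config.seed,
        "converged_at": None,
        "best_iteration": None,
    }
    if gt_arr is not None:
        report["pseudo_f1"] = seg_metrics(state.pseudo_label[te_sl], gt_arr[te_sl]).f1
    states = [state]
    if workdir is not None:
        _dump_iteration(Path(workdir), state)

    for _ in range(config.max_iterations):
        state = run_iteration(states[-1], raw, config, gt=gt_arr)
        states.append(state)
        report["f1_history"].append(state.f1)
        report["seconds"].append(state.seconds)
        log.info("iteration %d: F1=%.4f (%.1fs)", state.index, state.f1, state.seconds)
        if workdir is not None:
            _dump_iteration(Path(workdir), state)
        conv = check_convergence(report["f1_history"], config.f1_tolerance)
        if conv is not None:
            report["converged_at"] = conv + 1  # history index -> iteration number
            break

    hist = report["f1_history"]
    if report["converged_at"] is not None:
        best = report["converged_at"]
    else:
        best = int(np.argmax(hist)) + 1
    report["best_iteration"] = best
    best_state = states[best]
    final_mask = binarize_prob(best_state.prob_map * 255.0, 200.0)
    if gt_arr is not None:
        report["final_f1"] = seg_metrics(final_mask[te_sl], gt_arr[te_sl]).f1
        report["final_f1_full"] = seg_metrics(final_mask, gt_arr).f1
    if workdir is not None:
        write_stack((final_mask * 255).astype(np.uint8), Path(workdir) / "final_mask.tif")
    return final_mask, report


def _dump_iteration(workdir: Path, state: IterationState) -> None:
    d = workdir / f"iter_{state.index}"
    d.mkdir(parents=True, exist_ok=True)
    write_stack((state.pseudo_label * 255).astype(np.uint8), d / "pseudo.tif")
    if state.prob_map is not None:
        write_stack(state.prob_map.astype(np.float32), d / "prob.tif")
    if state.fused is not None:
        write_stack(np.clip(state.fused, 0, 255).astype(np.uint8), d / "fused.tif")
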