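"""Prediction-accuracy evaluation.

Model accuracy is the Pearson correlation coefficient

    r = sum((x - mean(x)) (y - mean(y)))
        / sqrt(sum((x - mean(x))^2) sum((y - mean(y))^2))

between ground-truth test pixels ``x`` and model output ``y``.  Sparse
channels (the lectin rule) are evaluated only on test images that actually
contain signal — background shot noise cannot be predicted, so blank
images would dilute the statistic; an image participates when the fraction
of ground-truth pixels above a robust threshold (median + 3 MAD) exceeds
``signal_threshold``.  Both per-image and pooled coefficients are
reported; pooled r over concatenated test pixels is the headline number.

The module also provides the seeded synthetic benchmarks used to exercise
the training pipeline (identity task, vessel phantom) and the
noise-robustness curve: accuracy as a function of Gaussian noise added to
the *training* ground truth, the test targets staying clean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from . import synthetic_data as sd
from .prediction import PairedDataset, PredictionModel, TrainConfig, train
from .unet import UNet


class UndefinedCorrelationError(ValueError):
    """Pearson r is undefined (a constant argument)."""


class EmptyEvaluationError(RuntimeError):
    """No test image survived the signal mask."""


@dataclass
class EvaluationReport:
    per_image_r: list[float]
    pooled_r: float
    mask_rule: str                      # "all_images" | "signal_images_only"
    n_images_used: int
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        for r in list(self.per_image_r) + [self.pooled_r]:
            if not -1.0000001 <= r <= 1.0000001:
                raise ValueError(f"correlation {r} outside [-1, 1]")


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation between ground truth ``x`` and prediction ``y``."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(np.sum(dx * dx))
    sy = float(np.sum(dy * dy))
    if sx == 0.0 and sy == 0.0:
        raise UndefinedCorrelationError("both sequences are constant")
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("one sequence is constant")
    return float(np.sum(dx * dy) / np.sqrt(sx * sy))


def _has_signal(img: np.ndarray, signal_threshold: float) -> bool:
    med = float(np.median(img))
    mad = float(np.median(np.abs(img - med)))
    thresh = med + 3.0 * mad
    frac = float(np.mean(img > thresh))
    return frac > signal_threshold


def evaluate(model: PredictionModel, test: PairedDataset,
             mask_rule: str = "all_images",
             signal_threshold: float = 0.001,
             noise_sigma: float = 0.0) -> EvaluationReport:
    """Evaluate a model on the test split of a paired dataset.

    Under ``signal_images_only`` an image participates iff the fraction of
    ground-truth pixels above median + 3 MAD exceeds ``signal_threshold``
    (default 0.1%).
    """
    if mask_rule not in ("all_images", "signal_images_only"):
        raise ValueError(f"unknown mask rule {mask_rule!r}")
    from .prediction import _predict_slice  # late import avoids cycle noise
    test_in, test_tgt = test.subset("test")
    if not test_in:
        raise EmptyEvaluationError("dataset has no test images")
    ps = model.config.patch_size
    per_r: list[float] = []
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for gt, inp in zip(test_tgt, test_in):
        if mask_rule == "signal_images_only" and not _has_signal(gt, signal_threshold):
            continue
        pred = _predict_slice(model.net, inp, ps)
        xs.append(gt.ravel())
        ys.append(pred.ravel())
        try:
            per_r.append(pearson(gt, pred))
        except UndefinedCorrelationError:
            pass  # a constant image contributes to the pool only
    if not xs:
        raise EmptyEvaluationError("no test image passed the signal mask")
    pooled = pearson(np.concatenate(xs), np.concatenate(ys))
    return EvaluationReport(per_image_r=per_r, pooled_r=pooled,
                            mask_rule=mask_rule, n_images_used=len(xs),
                            noise_sigma=noise_sigma)


# --------------------------------------------------------------------------
# seeded benchmarks
# --------------------------------------------------------------------------

def identity_dataset(n_images: int = 8, side: int = 64, seed: int = 0,
                     config: TrainConfig | None = None) -> PairedDataset:
    """Identity task: target equals the SRS input.

    A learnable sanity benchmark — a correctly wired network reaches
    held-out r close to 1.
    """
    config = config or TrainConfig.desk_scale()
    spec = dc_replace(sd.default_phantom_spec(seed),
                      field_shape=(n_images, side, side))
    channels, _ = sd.generate_tissue_phantom(spec)
    srs = channels["CH3-2940"]
    vols = [srs.with_voxels(srs.voxels[z:z + 1]) for z in range(srs.n_slices)]
    return build_paired(vols, vols, config)


def vessel_dataset(n_images: int = 16, side: int = 96, seed: int = 0,
                   config: TrainConfig | None = None) -> PairedDataset:
    """Vessel phantom benchmark: predict the lectin-like channel from SRS."""
    config = config or TrainConfig.desk_scale()
    spec = dc_replace(sd.default_phantom_spec(seed),
                      field_shape=(n_images, side, side))
    channels, _ = sd.generate_tissue_phantom(spec)
    return build_paired([channels["CH3-2940"]], [channels["lectin"]], config)


def build_paired(srs, target, config):
    from .prediction import build_dataset
    return build_dataset(srs, target, config)


def noise_robustness_curve(ds: PairedDataset, config: TrainConfig,
                           sigmas: list[float], seed: int = 0,
                           mask_rule: str = "all_images"
                           ) -> list[tuple[float, float]]:
    """Accuracy vs training-target noise.

    For each sigma (in units of the clean targets' pooled standard
    deviation) the *training* ground truth is degraded with zero-mean
    Gaussian noise, the model retrained from the same seed, and pooled r
    measured against the *clean* test targets.  Returns [(sigma, r), ...];
    accuracy decreases as training-target noise grows.
    """
    if list(sigmas) != sorted(sigmas) or (len(sigmas) > 0 and sigmas[0] != 0):
        raise ValueError("sigmas must be ascending and start at 0")
    tgt_std = float(np.std(np.concatenate([t.ravel() for t in ds.targets])))
    curve: list[tuple[float, float]] = []
    for k, sigma in enumerate(sigmas):
        targets = []
        rng = np.random.default_rng(seed + 7919 * k)
        for i, t in enumerate(ds.targets):
            if ds.split[i] == "train" and sigma > 0:
                targets.append((t + rng.normal(0, sigma * tgt_std, t.shape)
                                ).astype(np.float32))
            else:
                targets.append(t)
        noisy = PairedDataset(inputs=ds.inputs, targets=targets,
                              split=list(ds.split),
                              channel_label=ds.channel_label)
        model = train(noisy, config)
        # score against the clean targets
        clean_test = PairedDataset(inputs=ds.inputs, targets=ds.targets,
                                   split=list(ds.split),
                                   channel_label=ds.channel_label)
        rep = evaluate(model, clean_test, mask_rule=mask_rule,
                       noise_sigma=sigma)
        curve.append((float(sigma), rep.pooled_r))
    return curve
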