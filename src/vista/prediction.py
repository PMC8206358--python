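"""Label-free prediction pipeline.

From a single protein-CH3 vibrational channel, a per-target U-Net predicts
fluorescence-equivalent structural channels (virtual lectin, DAPI, MAP2,
NeuN).  The training regime follows the standard patch-sampling recipe:
both channels are rolling-ball background subtracted and percentile
normalized per slice, z-slices are paired into 2-D images, split randomly
into test and training sets at a 1:3 ratio, and the network is trained on
randomly positioned square patches with Adam on a mean-squared-error loss.
Whole-image inference tiles the input with half-overlapping windows
blended by a smooth taper; applying the model twice to the same input
gives bitwise-identical output.

Training is 2-D per slice: stacks are acquired with a z-step larger than
the axial resolution, so neighbouring slices are quasi-independent.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core_io import ImageVolume
from .unet import Adam, DivergenceError, UNet


class PairingError(ValueError):
    """Mismatched input/target volumes."""


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    Defaults mirror the full-scale regime (128-px patches, batch 32,
    learning rate 1e-3, MSE loss); ``steps`` counts optimizer iterations —
    one sampled batch each — and defaults to the desk-scale 2,000
    (50,000 at full scale).  ``desk_scale()`` returns a configuration small
    enough to train in minutes on one CPU core.
    """

    patch_size: int = 128
    batch_size: int = 32
    learning_rate: float = 1e-3
    steps: int = 2000
    test_fraction: float = 0.25
    seed: int = 0
    depth: int = 4
    base_channels: int = 32
    rolling_ball_radius: int | None = 50
    norm_percentiles: tuple[float, float] = (1.0, 99.9)

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patch_size % (2 ** self.depth) != 0:
            raise ValueError("patch_size must be divisible by 2**depth")

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainConfig":
        kw = dict(patch_size=64, batch_size=8, steps=600, depth=2,
                  base_channels=8, rolling_ball_radius=None)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class PairedDataset:
    """Pixel-registered (SRS input, fluorescence target) 2-D slice pairs."""

    inputs: list[np.ndarray]
    targets: list[np.ndarray]
    split: list[str]                      # "train" | "test" per pair
    channel_label: str = ""

    def __post_init__(self) -> None:
        if not (len(self.inputs) == len(self.targets) == len(self.split)):
            raise PairingError("inputs, targets and split must align")
        for a, b in zip(self.inputs, self.targets):
            if a.shape != b.shape:
                raise PairingError(f"pair shapes differ: {a.shape} vs {b.shape}")

    def _idx(self, which: str) -> list[int]:
        return [i for i, s in enumerate(self.split) if s == which]

    @property
    def train_indices(self) -> list[int]:
        return self._idx("train")

    @property
    def test_indices(self) -> list[int]:
        return self._idx("test")

    def subset(self, which: str) -> tuple[list[np.ndarray], list[np.ndarray]]:
        idx = self._idx(which)
        return [self.inputs[i] for i in idx], [self.targets[i] for i in idx]


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

def ball_structuring_function(radius: int) -> np.ndarray:
    """Height profile of the top half of a ball: sqrt(r^2 - d^2) inside
    radius r, -inf outside (excluded from the footprint)."""
    r = int(radius)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    d2 = yy * yy + xx * xx
    h = np.full(d2.shape, -np.inf)
    inside = d2 <= r * r
    h[inside] = np.sqrt(float(r * r) - d2[inside])
    return h


def rolling_ball_subtract(img: np.ndarray, radius: int) -> np.ndarray:
    """Rolling-ball background subtraction.

    The background is the upper envelope of a ball of the given radius
    rolled under the intensity surface — grayscale opening (erosion then
    dilation) against the ball structuring function; the result is
    ``img - background`` clipped at zero.
    """
    img = np.asarray(img, dtype=np.float64)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius >= min(img.shape):
        raise ValueError(f"radius {radius} must be smaller than the image "
                         f"side {min(img.shape)}")
    h = ball_structuring_function(radius)
    footprint = np.isfinite(h)
    hv = np.where(footprint, h, 0.0)
    ero = ndimage.grey_erosion(img, structure=hv, footprint=footprint,
                               mode="constant", cval=np.inf)
    bg = ndimage.grey_dilation(ero, structure=hv, footprint=footprint,
                               mode="constant", cval=-np.inf)
    return np.clip(img - bg, 0.0, None)


def percentile_normalize(img: np.ndarray,
                         percentiles: tuple[float, float] = (1.0, 99.9)
                         ) -> np.ndarray:
    """Window to the (low, high) percentile range and rescale to [0, 1].

    Degenerate slices (zero percentile window, e.g. an all-zero target)
    are passed through as zeros rather than dividing by zero.
    """
    img = np.asarray(img, dtype=np.float64)
    lo, hi = np.percentile(img, percentiles)
    if hi <= lo:
        return np.zeros_like(img, dtype=np.float32)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0).astype(np.float32)


def preprocess_slice(img: np.ndarray, config: TrainConfig) -> np.ndarray:
    if config.rolling_ball_radius is not None:
        img = rolling_ball_subtract(img, config.rolling_ball_radius)
    return percentile_normalize(img, config.norm_percentiles)


# --------------------------------------------------------------------------
# dataset assembly
# --------------------------------------------------------------------------

def build_dataset(srs: list[ImageVolume], target: list[ImageVolume],
                  config: TrainConfig) -> PairedDataset:
    """Pair z-slices of matched volumes into a preprocessed 2-D dataset.

    Each (volume, z) slice pair becomes one image pair; both channels are
    rolling-ball subtracted then percentile normalized per slice.  The
    test/train split is drawn once per image (never per patch) from the
    config seed at ``test_fraction`` (default 1:3 test:train).
    """
    if len(srs) != len(target):
        raise PairingError(f"{len(srs)} input vs {len(target)} target volumes")
    inputs: list[np.ndarray] = []
    targets: list[np.ndarray] = []
    label = target[0].channel_label if target else ""
    for vs, vt in zip(srs, target):
        if vs.shape != vt.shape:
            raise PairingError(f"volume shapes differ: {vs.shape} vs {vt.shape}")
        for z in range(vs.n_slices):
            inputs.append(preprocess_slice(vs.voxels[z], config))
            targets.append(preprocess_slice(vt.voxels[z], config))
    n = len(inputs)
    if n < 4:
        raise PairingError(f"need >= 4 image pairs to split, got {n}")
    rng = np.random.default_rng(config.seed)
    n_test = max(1, round(config.test_fraction * n))
    test_idx = set(rng.choice(n, size=n_test, replace=False).tolist())
    split = ["test" if i in test_idx else "train" for i in range(n)]
    return PairedDataset(inputs=inputs, targets=targets, split=split,
                         channel_label=label)


# --------------------------------------------------------------------------
# model container
# --------------------------------------------------------------------------

@dataclass
class PredictionModel:
    """Trained weights plus the normalization/tiling contract to apply them."""

    net: UNet
    config: TrainConfig
    channel_label: str
    loss_trace: list[float] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        """Weights (npz) with a JSON header describing config and channel."""
        header = json.dumps({
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.config).items()},
            "channel_label": self.channel_label,
            "depth": self.net.depth,
            "base_channels": self.net.base,
        })
        np.savez(str(path), __header__=np.frombuffer(header.encode(), dtype=np.uint8),
                 **{f"param/{k}": v for k, v in self.net.params.items()},
                 loss_trace=np.asarray(self.loss_trace, dtype=np.float64))

    @classmethod
    def load(cls, path: str | Path) -> "PredictionModel":
        with np.load(str(path)) as z:
            header = json.loads(bytes(z["__header__"]).decode())
            cfg = header["config"]
            cfg["norm_percentiles"] = tuple(cfg["norm_percentiles"])
            config = TrainConfig(**cfg)
            net = UNet(depth=header["depth"], base_channels=header["base_channels"])
            for k in list(net.params):
                net.params[k] = z[f"param/{k}"]
            trace = z["loss_trace"].tolist()
        return cls(net=net, config=config,
                   channel_label=header["channel_label"], loss_trace=trace)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def train(ds: PairedDataset, config: TrainConfig) -> PredictionModel:
    """Patch-based U-Net training.

    Batches of ``batch_size`` patch positions are sampled uniformly over
    the training images each step; ``steps`` Adam iterations minimize the
    MSE between prediction and fluorescence target.  The loss trace is
    recorded; a non-finite loss raises :class:`~vista.unet.DivergenceError`
    with the offending step.  Test images never enter training.
    """
    tr_in, tr_tgt = ds.subset("train")
    if not tr_in:
        raise PairingError("dataset has no training images")
    ps = config.patch_size
    for img in tr_in:
        if img.shape[0] < ps or img.shape[1] < ps:
            raise ValueError(f"patch_size {ps} exceeds image shape {img.shape}")

    rng = np.random.default_rng(config.seed)
    net = UNet(depth=config.depth, base_channels=config.base_channels,
               seed=config.seed)
    opt = Adam(net.params, lr=config.learning_rate)
    trace: list[float] = []

    n_img = len(tr_in)
    for step in range(config.steps):
        xb = np.empty((config.batch_size, 1, ps, ps), dtype=np.float32)
        tb = np.empty_like(xb)
        for j in range(config.batch_size):
            i = int(rng.integers(n_img))
            H, W = tr_in[i].shape
            y0 = int(rng.integers(H - ps + 1))
            x0 = int(rng.integers(W - ps + 1))
            xb[j, 0] = tr_in[i][y0:y0 + ps, x0:x0 + ps]
            tb[j, 0] = tr_tgt[i][y0:y0 + ps, x0:x0 + ps]
        cache: dict = {}
        y = net.forward(xb, cache)
        r = y - tb
        loss = float(np.mean(r * r))
        if not np.isfinite(loss):
            raise DivergenceError(step)
        trace.append(loss)
        opt.step(net.backward(((2.0 / r.size) * r).astype(np.float32), cache))

    return PredictionModel(net=net, config=config,
                           channel_label=ds.channel_label, loss_trace=trace)


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------

def _taper(ps: int) -> np.ndarray:
    w = np.hanning(ps + 2)[1:-1]
    return (w[:, None] * w[None, :]).astype(np.float64) + 1e-6


def _predict_slice(net: UNet, img: np.ndarray, ps: int,
                   margin: int | None = None) -> np.ndarray:
    """Overlap-tile inference on one 2-D slice.

    Tile cores of size ``ps`` at stride ``ps/2`` are blended with a smooth
    taper; each core is predicted with a mirror-padded context ``margin``
    wide (covering the network's receptive field) that is cropped away, so
    tile seams carry no convolution-padding artefacts.
    """
    H, W = img.shape
    d = 2 ** net.depth
    if margin is None:
        # receptive-field half-width of the network: two 3x3 convs per block
        # at scales 1..2^depth down and up again
        margin = 12 * d - 8
    m = -(-max(margin, 1) // d) * d  # round up to the pooling grid
    padH = max(ps - H, 0)
    padW = max(ps - W, 0)
    if padH or padW:
        img = np.pad(img, ((0, padH), (0, padW)), mode="reflect")
    Hp, Wp = img.shape
    ctx = np.pad(img, m, mode="reflect")
    stride = ps // 2
    ys = sorted({min(y, Hp - ps) for y in range(0, Hp - ps + stride, stride)})
    xs = sorted({min(x, Wp - ps) for x in range(0, Wp - ps + stride, stride)})
    acc = np.zeros((Hp, Wp), dtype=np.float64)
    wacc = np.zeros((Hp, Wp), dtype=np.float64)
    taper = _taper(ps)
    for y0 in ys:
        for x0 in xs:
            tile = ctx[y0:y0 + ps + 2 * m, x0:x0 + ps + 2 * m]
            out = net.forward(tile[np.newaxis, np.newaxis].astype(np.float32))
            core = out[0, 0, m:m + ps, m:m + ps].astype(np.float64)
            acc[y0:y0 + ps, x0:x0 + ps] += core * taper
            wacc[y0:y0 + ps, x0:x0 + ps] += taper
    return (acc / wacc)[:H, :W].astype(np.float32)


def predict(model: PredictionModel, v: ImageVolume) -> ImageVolume:
    """Tiled whole-volume inference producing a virtual channel.

    Each slice is preprocessed exactly as in training (the contract stored
    in the model), tiled with half-overlapping windows blended by a smooth
    taper, and passed through the network.  Images smaller than one tile
    are reflectively padded, never rejected.  The output channel label is
    ``"v-<target>"``.
    """
    ps = model.config.patch_size
    out = np.stack([
        _predict_slice(model.net, preprocess_slice(v.voxels[z], model.config), ps)
        for z in range(v.n_slices)])
    label = f"v-{model.channel_label}" if model.channel_label else "v-pred"
    return v.with_voxels(out, channel_label=label)
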