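"""Image-volume data model and I/O.

All volumes are 3-D single-channel intensity stacks indexed ``(z, y, x)``
with physical sizes in nanometres throughout (in-plane pixel size and
z-step).  Lengths quoted for expanded samples follow the post-expansion
convention: physical length of an in-plane segment = pixel count ×
``pixel_size_xy``.

Volumes are stored as multi-page grayscale TIFF files with a JSON sidecar
(`<stem>.json`) carrying the metadata; this keeps the metadata bit-exact
and diff-able, independent of TIFF tag dialects.  16-bit integer input is
promoted to float *without rescaling* so quantitative intensities survive
for retention analysis.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger("vista")

#: Default in-plane pixel size (nm/px) assumed when no metadata is available.
DEFAULT_PIXEL_SIZE_XY = 497.0
#: Default z-step (nm) — volumetric stacks are acquired at 1 µm steps.
DEFAULT_Z_STEP = 1000.0


class ExpansionState(str, Enum):
    UNPROCESSED = "unprocessed"
    EXPANDED = "expanded"


class FormatError(ValueError):
    """Raised for unreadable or unsupported image files."""


class DimensionError(ValueError):
    """Raised when image shapes are incompatible."""


@dataclass
class ImageVolume:
    """A 3-D single-channel intensity stack with physical metadata.

    Parameters
    ----------
    voxels
        3-D float array indexed ``(z, y, x)``; arbitrary intensity units.
    pixel_size_xy
        In-plane pixel size, nm/px.
    z_step
        Axial step between slices, nm.
    channel_label
        Free-text channel name, e.g. ``"CH3-2940"``, ``"lectin"``, ``"DAPI"``.
    expansion_state
        Whether the sample was physically expanded before imaging.
    expansion_factor
        Linear expansion ratio; present iff the state is ``expanded``.
    """

    voxels: np.ndarray
    pixel_size_xy: float = DEFAULT_PIXEL_SIZE_XY
    z_step: float = DEFAULT_Z_STEP
    channel_label: str = ""
    expansion_state: ExpansionState = ExpansionState.UNPROCESSED
    expansion_factor: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim == 2:
            v = v[np.newaxis]
        if v.ndim != 3:
            raise DimensionError(f"voxels must be 2-D or 3-D, got ndim={v.ndim}")
        if not np.issubdtype(v.dtype, np.floating):
            v = v.astype(np.float32)
        if not np.all(np.isfinite(v)):
            raise ValueError("voxels contain non-finite values")
        self.voxels = v
        if self.pixel_size_xy <= 0:
            raise ValueError("pixel_size_xy must be > 0")
        if self.z_step <= 0:
            raise ValueError("z_step must be > 0")
        self.expansion_state = ExpansionState(self.expansion_state)
        if self.expansion_state is ExpansionState.EXPANDED:
            if self.expansion_factor is None or self.expansion_factor < 1:
                raise ValueError("expanded volumes require expansion_factor >= 1")
        elif self.expansion_factor is not None:
            raise ValueError("expansion_factor only valid for expanded volumes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def metadata(self) -> dict:
        return {
            "pixel_size_xy": self.pixel_size_xy,
            "z_step": self.z_step,
            "channel_label": self.channel_label,
            "expansion_state": self.expansion_state.value,
            "expansion_factor": self.expansion_factor,
        }

    def with_voxels(self, voxels: np.ndarray, **updates) -> "ImageVolume":
        """Copy of this volume with new voxel data (metadata preserved)."""
        kw = self.metadata()
        kw.update(updates)
        return ImageVolume(voxels=voxels, **kw)


@dataclass
class AnalysisReport:
    """Serializable result container with provenance.

    ``kind`` names the analysis; ``payload`` maps result keys (units encoded
    in the key name, e.g. ``"psf_fwhm_nm"``) to values; ``provenance``
    records input identifiers, parameters and the seed.
    """

    kind: str
    payload: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    VALID_KINDS = ("resolution", "expansion", "retention", "evaluation")

    def __post_init__(self) -> None:
        if self.kind not in self.VALID_KINDS:
            raise ValueError(f"unknown report kind {self.kind!r}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=_jsonify))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisReport":
        d = json.loads(Path(path).read_text())
        return cls(kind=d["kind"], payload=d["payload"], provenance=d["provenance"])


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_volume(path: str | Path, metadata: str | Path | None = None,
                **overrides) -> ImageVolume:
    """Read a multi-page grayscale TIFF as an :class:`ImageVolume`.

    Metadata is taken from the JSON sidecar when present (``metadata``
    argument, else ``<stem>.json`` next to the TIFF), else from keyword
    overrides, else defaults with a logged warning.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(str(path)) as tf:
            for i, page in enumerate(tf.pages):
                if page.samplesperpixel != 1:
                    raise FormatError(
                        f"{path}: page {i} has {page.samplesperpixel} samples "
                        "per pixel; only grayscale volumes are supported")
            arr = tf.asarray()
    except (FileNotFoundError, PermissionError, FormatError):
        raise
    except Exception as exc:  # tifffile raises assorted types on bad input
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise FormatError(
            f"{path}: expected grayscale pages, got array of shape {arr.shape}")

    meta: dict = {}
    sidecar = Path(metadata) if metadata is not None else _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    elif not overrides:
        logger.warning("no metadata sidecar for %s; using defaults "
                       "(pixel_size_xy=%g nm, z_step=%g nm)",
                       path, DEFAULT_PIXEL_SIZE_XY, DEFAULT_Z_STEP)
    meta.update({k: v for k, v in overrides.items() if v is not None})
    meta = {k: v for k, v in meta.items()
            if k in ("pixel_size_xy", "z_step", "channel_label",
                     "expansion_state", "expansion_factor")}
    if arr.dtype.kind in "ui":
        arr = arr.astype(np.float32)
    return ImageVolume(voxels=arr, **meta)


def write_volume(v: ImageVolume, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF plus JSON metadata sidecar."""
    path = Path(path)
    data = v.voxels
    if data.dtype != np.float32:
        data = data.astype(np.float32)
    tifffile.imwrite(str(path), data, photometric="minisblack")
    _sidecar_path(path).write_text(json.dumps(v.metadata(), indent=2))


def max_intensity_projection(v: ImageVolume) -> np.ndarray:
    """Maximum intensity projection along z: ``out[y, x] = max_z voxels``."""
    if v.n_slices < 1:
        raise DimensionError("volume has no z-slices")
    return v.voxels.max(axis=0)


# named colors for channel merging (RGB in [0, 1])
COLORS = {
    "white": (1.0, 1.0, 1.0),
    "red": (1.0, 0.0, 0.0),
    "green": (0.0, 1.0, 0.0),
    "blue": (0.0, 0.0, 1.0),
    "cyan": (0.0, 1.0, 1.0),
    "magenta": (1.0, 0.0, 1.0),
    "yellow": (1.0, 1.0, 0.0),
    "orange": (1.0, 0.5, 0.0),
}


def merge_channels(channels: list[tuple[np.ndarray, str | tuple[float, float, float]]],
                   normalization: tuple[float, float] | list[tuple[float, float]] = (0.0, 100.0),
                   ) -> np.ndarray:
    """Additively composite up to 8 tinted channels into an RGB image.

    Each 2-D channel is rescaled to [0, 1] by its percentile window
    ``(low, high)``, multiplied by its RGB tint, summed and clipped at 1 —
    the standard multi-color overlay used for tandem multi-channel volume
    renderings.
    """
    if not 1 <= len(channels) <= 8:
        raise ValueError("merge_channels takes 1-8 channels")
    shapes = {np.asarray(img).shape for img, _ in channels}
    if len(shapes) != 1:
        raise DimensionError(f"channel shapes differ: {sorted(shapes)}")
    if isinstance(normalization[0], (int, float)):
        norms = [normalization] * len(channels)
    else:
        norms = list(normalization)
        if len(norms) != len(channels):
            raise ValueError("one percentile pair per channel required")

    out = np.zeros((*next(iter(shapes)), 3), dtype=np.float64)
    for (img, color), (plo, phi) in zip(channels, norms):
        img = np.asarray(img, dtype=np.float64)
        lo, hi = np.percentile(img, [plo, phi])
        scaled = np.zeros_like(img) if hi <= lo else np.clip((img - lo) / (hi - lo), 0, 1)
        rgb = COLORS[color] if isinstance(color, str) else tuple(color)
        out += scaled[..., None] * np.asarray(rgb)
    return np.clip(out, 0.0, 1.0)
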