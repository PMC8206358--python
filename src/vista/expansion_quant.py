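"""Expansion-ratio estimation and protein-retention quantification.

The linear expansion ratio between a pre- and post-expansion image pair is
recovered by registration of their maximum-intensity projections: scale and
rotation from log-polar correlation of the Fourier magnitude spectra,
refined by maximizing the normalized correlation of the rescaled images,
then translation by phase correlation.  Protein retention compares mean
intensities inside matched structure masks after compensating the cubic
signal dilution (fourfold linear expansion spreads a voxel's protein over
64 voxels, so the expanded mean is scaled back by ``ratio**3``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu
from skimage.transform import rescale, warp_polar

from .core_io import AnalysisReport, ImageVolume, max_intensity_projection

DILUTION_EXPONENT = 3  # signal dilutes with the cube of the linear ratio


class RegistrationError(RuntimeError):
    """Correlation peak too weak or rotation outside the search range."""


class MaskError(ValueError):
    """Empty or degenerate structure mask."""


@dataclass
class SimilarityTransform:
    scale: float
    rotation: float            # degrees
    translation: tuple[float, float]  # (y, x) px in post-image frame

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")


@dataclass
class ExpansionEstimate:
    ratio: float
    transform: SimilarityTransform
    residual_rms: float        # nm, intensity-weighted after alignment
    peak_sharpness: float      # normalized correlation at the optimum

    def to_analysis_report(self, **provenance) -> AnalysisReport:
        return AnalysisReport(
            kind="expansion",
            payload={
                "ratio": self.ratio,
                "scale": self.transform.scale,
                "rotation_deg": self.transform.rotation,
                "translation_px": list(self.transform.translation),
                "residual_rms_nm": self.residual_rms,
                "peak_sharpness": self.peak_sharpness,
            },
            provenance=provenance)


@dataclass
class RetentionReport:
    mean_expanded: float
    mean_original: float
    expansion_ratio: float

    @property
    def dilution_factor(self) -> float:
        return self.expansion_ratio ** DILUTION_EXPONENT

    @property
    def retention_fraction(self) -> float:
        return self.mean_expanded * self.dilution_factor / self.mean_original

    @property
    def loss_percent(self) -> float:
        return 100.0 * (1.0 - self.retention_fraction)

    def to_analysis_report(self, **provenance) -> AnalysisReport:
        return AnalysisReport(
            kind="retention",
            payload={
                "mean_expanded": self.mean_expanded,
                "mean_original": self.mean_original,
                "expansion_ratio": self.expansion_ratio,
                "dilution_factor": self.dilution_factor,
                "retention_fraction": self.retention_fraction,
                "loss_percent": self.loss_percent,
            },
            provenance=provenance)


# --------------------------------------------------------------------------
# scale/rotation registration
# --------------------------------------------------------------------------

def _hann2d(shape):
    wy = np.hanning(shape[0])
    wx = np.hanning(shape[1])
    return wy[:, None] * wx[None, :]

def _log_spectrum(img, shape):
    pad = np.zeros(shape)
    pad[:img.shape[0], :img.shape[1]] = img * _hann2d(img.shape)
    F = np.abs(np.fft.fftshift(np.fft.fft2(pad)))
    return F

def _highpass(F):
    # cosine high-pass emphasising spectral structure over the DC lobe
    H, W = F.shape
    fy = np.fft.fftshift(np.fft.fftfreq(H))
    fx = np.fft.fftshift(np.fft.fftfreq(W))
    x = np.clip(2.0 * np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2), 0, 1)
    h = 1.0 - np.cos(np.pi * x)
    return F * h * (2.0 - h)

def _coarse_scale_rotation(pre, post, max_rotation, max_scale=8.0):
    """Log-polar correlation of Fourier magnitudes -> (scale, rotation).

    A scale change s in image space contracts the magnitude spectrum by
    1/s; on a log radial axis that contraction becomes a column shift and a
    rotation becomes a row shift.  The correlation peak is searched only
    inside the physically allowed window (|rotation| <= max_rotation,
    scale within [1/max_scale, max_scale]), which keeps large scale factors
    from locking onto spurious peaks.
    """
    shape = (max(pre.shape[0], post.shape[0]), max(pre.shape[1], post.shape[1]))
    Fa = _highpass(_log_spectrum(post, shape))
    Fb = _highpass(_log_spectrum(pre, shape))
    radius = min(shape) // 2
    n_theta, n_r = 360, 300
    wa = warp_polar(np.log1p(Fa), radius=radius, scaling="log",
                    output_shape=(n_theta, n_r))
    wb = warp_polar(np.log1p(Fb), radius=radius, scaling="log",
                    output_shape=(n_theta, n_r))
    wa, wb = wa[:, 10:], wb[:, 10:]  # drop the DC-dominated inner columns
    # circular in theta (rows), linear in log-r (columns): pad columns
    ncols = wa.shape[1]
    A = np.zeros((n_theta, 2 * ncols)); A[:, :ncols] = wa
    B = np.zeros((n_theta, 2 * ncols)); B[:, :ncols] = wb
    R = np.fft.rfft2(B).conj() * np.fft.rfft2(A)
    xc = np.fft.irfft2(R / np.maximum(np.abs(R), 1e-12), s=A.shape)

    klog = np.log(radius) / n_r
    max_dcol = int(np.ceil(np.log(max_scale) / klog))
    rows = np.arange(n_theta)
    drow = np.where(rows <= n_theta // 2, rows, rows - n_theta)  # degrees
    cols = np.arange(A.shape[1])
    dcol = np.where(cols <= ncols, cols, cols - A.shape[1])
    allowed = (np.abs(drow)[:, None] <= max_rotation + 2) \
        & (np.abs(dcol)[None, :] <= max_dcol)
    masked = np.where(allowed, xc, -np.inf)
    iy, ix = np.unravel_index(np.argmax(masked), masked.shape)
    # warp_polar's angular axis runs opposite to the image-space rotation
    # convention used to re-apply the transform, hence the sign flip
    rot_deg = float(-drow[iy])
    # the post spectrum is contracted by 1/s: its features sit at
    # log r - log s, so the column lag maps to scale = exp(-dcol * klog)
    scale = float(np.exp(-dcol[ix] * klog))
    return scale, rot_deg, float(xc[iy, ix])


def _ncc_at(pre, post, scale, rotation_deg):
    """Translation-invariant NCC between post and pre scaled/rotated."""
    moved = rescale(pre, scale, order=1, anti_aliasing=scale < 1)
    if rotation_deg != 0:
        moved = ndimage.rotate(moved, rotation_deg, reshape=True, order=1)
    shape = (max(moved.shape[0], post.shape[0]),
             max(moved.shape[1], post.shape[1]))
    A = np.zeros(shape); A[:moved.shape[0], :moved.shape[1]] = moved - moved.mean()
    B = np.zeros(shape); B[:post.shape[0], :post.shape[1]] = post - post.mean()
    xc = np.fft.irfft2(np.fft.rfft2(A).conj() * np.fft.rfft2(B), s=shape)
    denom = np.linalg.norm(A) * np.linalg.norm(B)
    if denom == 0:
        return 0.0, (0.0, 0.0)
    xc /= denom
    ij = np.unravel_index(np.argmax(xc), xc.shape)
    shift = [float(i if i <= s // 2 else i - s) for i, s in zip(ij, shape)]
    return float(xc[ij]), (shift[0], shift[1])


def estimate_expansion_ratio(pre: ImageVolume, post: ImageVolume,
                             max_rotation: float = 30.0,
                             min_peak: float = 0.1) -> ExpansionEstimate:
    """Estimate the linear expansion ratio from a pre/post image pair.

    Operates on 2-D maximum-intensity projections.  A coarse scale/rotation
    estimate from log-polar spectral correlation is refined by golden-section
    search on the normalized cross-correlation; translation follows from
    phase correlation at the refined scale.  The physical ratio accounts for
    differing pixel sizes: ``ratio = scale * post.pixel_size / pre.pixel_size``.
    """
    a = np.asarray(max_intensity_projection(pre), dtype=np.float64)
    b = np.asarray(max_intensity_projection(post), dtype=np.float64)
    scale0, rot0, _ = _coarse_scale_rotation(a, b, max_rotation)
    if abs(rot0) > max_rotation:
        raise RegistrationError(
            f"recovered rotation {rot0:.1f} deg exceeds the +/-{max_rotation} deg "
            "search range")
    if not 0.2 <= scale0 <= 8.0:
        raise RegistrationError(f"implausible coarse scale {scale0:.3g}")

    def neg_ncc(s):
        return -_ncc_at(a, b, s, rot0)[0]

    lo, hi = scale0 * 0.9, scale0 * 1.1
    r = optimize.minimize_scalar(neg_ncc, bounds=(lo, hi), method="bounded",
                                 options={"xatol": scale0 * 2e-4})
    scale = float(r.x)
    peak, shift = _ncc_at(a, b, scale, rot0)
    if peak < min_peak:
        raise RegistrationError(
            f"correlation peak {peak:.3f} below significance ({min_peak})")

    ratio = scale * post.pixel_size_xy / pre.pixel_size_xy
    # intensity-weighted residual displacement proxy: sub-pixel misfit of the
    # phase-correlation peak, expressed in post-image nanometres
    moved = rescale(a, scale, order=1, anti_aliasing=scale < 1)
    if rot0 != 0:
        moved = ndimage.rotate(moved, rot0, reshape=True, order=1)
    sy, sx = int(round(shift[0])), int(round(shift[1]))
    H = min(moved.shape[0], b.shape[0]); W = min(moved.shape[1], b.shape[1])
    mv = np.roll(np.pad(moved, ((0, max(0, b.shape[0]-moved.shape[0])),
                                (0, max(0, b.shape[1]-moved.shape[1]))))[:b.shape[0], :b.shape[1]],
                 (sy, sx), axis=(0, 1))
    bb = b[:mv.shape[0], :mv.shape[1]]
    num = np.abs(mv - bb).sum()
    den = max(bb.sum() + mv.sum(), 1e-12)
    residual_rms = float(num / den) * post.pixel_size_xy

    return ExpansionEstimate(
        ratio=float(ratio),
        transform=SimilarityTransform(scale=scale, rotation=rot0,
                                      translation=tuple(shift)),
        residual_rms=residual_rms,
        peak_sharpness=peak)


# --------------------------------------------------------------------------
# retention
# --------------------------------------------------------------------------

def measure_retention(expanded: ImageVolume, original: ImageVolume,
                      mask_expanded: np.ndarray, mask_original: np.ndarray,
                      ratio: float) -> RetentionReport:
    """Protein retention from matched structure masks.

    ``retention_fraction = mean_expanded * ratio**3 / mean_original`` —
    the expanded-cell mean is scaled back by the volumetric dilution before
    comparison with the unprocessed sample.  Inputs are assumed
    background-subtracted.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    me_mask = np.asarray(mask_expanded, dtype=bool)
    mo_mask = np.asarray(mask_original, dtype=bool)
    if not me_mask.any() or not mo_mask.any():
        raise MaskError("retention masks must be nonempty")
    mean_expanded = float(expanded.voxels[_bcast(me_mask, expanded)].mean())
    mean_original = float(original.voxels[_bcast(mo_mask, original)].mean())
    if mean_original <= 0:
        raise ValueError("mean_original must be > 0 (degenerate input)")
    return RetentionReport(mean_expanded=mean_expanded,
                           mean_original=mean_original,
                           expansion_ratio=float(ratio))


def _bcast(mask: np.ndarray, v: ImageVolume) -> np.ndarray:
    if mask.ndim == 2:
        return np.broadcast_to(mask, v.voxels.shape)
    if mask.shape != v.voxels.shape:
        raise MaskError(f"mask shape {mask.shape} does not match volume "
                        f"{v.voxels.shape}")
    return mask


def segment_cells(v: ImageVolume, smoothing_px: float = 1.0,
                  min_area_px: int = 100) -> np.ndarray:
    """Foreground mask for per-cell intensity statistics.

    Otsu threshold on a Gaussian-smoothed MIP, holes filled, objects
    smaller than ``min_area_px`` removed.  Returns a 2-D boolean mask.
    """
    mip = max_intensity_projection(v).astype(np.float64)
    sm = ndimage.gaussian_filter(mip, smoothing_px)
    if np.ptp(sm) <= 0:
        raise MaskError("image is uniform; no foreground to segment")
    mask = sm > threshold_otsu(sm)
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n:
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas < min_area_px)
        mask[np.isin(labels, small[small > 0])] = False
    if not mask.any():
        raise MaskError("segmentation produced an empty mask")
    return mask
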