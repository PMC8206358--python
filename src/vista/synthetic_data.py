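"""Seeded phantom generators for every stage of the pipeline.

Three families of synthetic data are produced, each with full ground truth:

* **bead calibration stacks** — sub-resolution polystyrene-like beads,
  modeled as uniform circles (the same object model the resolution module
  deconvolves), blurred by an isotropic Gaussian PSF, with optional
  Poisson–Gaussian noise;
* **multi-structure tissue phantoms** — nuclei (ellipsoids, with darker
  chromosome-void regions inside), blood vessels (random-walk tubes),
  neuronal somata (blobs with a nucleus inside) and dendrites (branching
  filaments), rendered both as a composite protein-CH3 SRS channel through
  a linear forward model and as per-structure fluorescence channels
  (DAPI-like, lectin-like, MAP2-like, NeuN-like);
* **pre/post-expansion pairs** — isotropic geometric scaling with cubic
  signal dilution, per-structure retention, and an optional smooth random
  distortion field.

Every generator is a pure function of its spec including the seed:
identical specs give bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .core_io import ExpansionState, ImageVolume

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class StructureKind(str, Enum):
    BEAD = "bead"
    NUCLEUS = "nucleus"
    VESSEL = "vessel"
    SOMA = "soma"
    DENDRITE = "dendrite"
    CHROMOSOME_VOID = "chromosome_void"


class PlacementError(RuntimeError):
    """Field too small to place the requested objects at the required spacing."""


@dataclass
class NoiseSpec:
    """Detector noise model.

    ``poisson_gaussian`` is the default (shot noise plus read noise, the
    regime of a shot-noise-limited stimulated Raman detector); ``gaussian``
    adds read noise only and is kept for analytically tractable tests.
    ``photon_scale`` converts intensity units to expected counts.
    """

    model: str = "poisson_gaussian"
    read_sigma: float = 0.0
    photon_scale: float = 1000.0

    def __post_init__(self) -> None:
        if self.model not in ("gaussian", "poisson_gaussian"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.read_sigma < 0:
            raise ValueError("read_sigma must be >= 0")

    def apply(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(img, dtype=np.float64)
        if self.model == "poisson_gaussian" and self.photon_scale > 0:
            counts = rng.poisson(np.clip(out, 0, None) * self.photon_scale)
            out = counts / self.photon_scale
        if self.read_sigma > 0:
            out = out + rng.normal(0.0, self.read_sigma, out.shape)
        return out.astype(np.float32)


NOISELESS = NoiseSpec(model="gaussian", read_sigma=0.0, photon_scale=0.0)


@dataclass
class BackgroundSpec:
    """Residual spectral-crosstalk background in the CH3 channel.

    ``gel_ch2_weight`` scales a spatially smooth hydrogel (CH2) background,
    ``water_oh_weight`` a uniform water (O–H) background.  Setting both to
    zero emulates full deuteration of gel monomer and water.
    """

    gel_ch2_weight: float = 0.0
    water_oh_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.gel_ch2_weight < 0 or self.water_oh_weight < 0:
            raise ValueError("background weights must be >= 0")


@dataclass
class StructureSpec:
    kind: StructureKind
    count: int = 1
    size_nm: float = 1000.0          # characteristic radius (nm)
    protein_density: float = 1.0     # relative CH3 intensity per voxel
    retention: float = 1.0           # fraction surviving homogenization

    def __post_init__(self) -> None:
        self.kind = StructureKind(self.kind)
        if self.protein_density < 0:
            raise ValueError("protein_density must be >= 0")
        if not 0.0 <= self.retention <= 1.0:
            raise ValueError("retention must be in [0, 1]")


@dataclass
class PhantomSpec:
    field_shape: tuple[int, int, int] = (16, 96, 96)
    pixel_size_xy: float = 160.0
    z_step: float = 1000.0
    structures: list[StructureSpec] = field(default_factory=list)
    psf_fwhm_xy: float = 320.0
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_fwhm_xy <= 0:
            raise ValueError("psf_fwhm_xy must be > 0")
        if len(self.field_shape) != 3 or any(s < 1 for s in self.field_shape):
            raise ValueError("field_shape must be a positive (z, y, x) triple")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_fwhm_xy / FWHM_PER_SIGMA / self.pixel_size_xy

    def density_of(self, kind: StructureKind) -> float:
        for s in self.structures:
            if s.kind is StructureKind(kind):
                return s.protein_density
        return 0.0

    def retention_of(self, kind: StructureKind) -> float:
        for s in self.structures:
            if s.kind is StructureKind(kind):
                return s.retention
        return 1.0


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom: unblurred per-kind density maps
    (support in {0, 1} scaled later by protein density), bead geometry, and
    the expansion transform when applicable."""

    density_maps: dict = field(default_factory=dict)   # kind -> (z,y,x) array
    bead_centers: np.ndarray | None = None             # (n, 2) px (y, x)
    bead_diameter_nm: float | None = None
    expansion_ratio: float | None = None
    distortion_rms_nm: float = 0.0

    def structure_mask(self) -> np.ndarray:
        """Union support of all structure kinds.

        Maps are thresholded at 0.5 so that interpolated (zoomed) truth
        does not inflate the support with near-zero boundary voxels.
        """
        masks = [m >= 0.5 for m in self.density_maps.values()]
        if not masks:
            raise ValueError("truth has no density maps")
        out = masks[0]
        for m in masks[1:]:
            out = out | m
        return out


def default_phantom_spec(seed: int = 0) -> PhantomSpec:
    """Four-structure tissue phantom emulating expanded brain tissue.

    Protein densities rank vessels > nuclei > somata > dendrites, with a
    darker chromosome region inside each nucleus; sizes are reduced-scale
    cartoons chosen so several objects of every kind fit a 96-px field.
    """
    return PhantomSpec(
        structures=[
            StructureSpec(StructureKind.NUCLEUS, count=5, size_nm=1100.0,
                          protein_density=1.0),
            StructureSpec(StructureKind.CHROMOSOME_VOID, count=5, size_nm=400.0,
                          protein_density=0.35),
            StructureSpec(StructureKind.VESSEL, count=3, size_nm=350.0,
                          protein_density=1.5),
            StructureSpec(StructureKind.SOMA, count=4, size_nm=800.0,
                          protein_density=0.8),
            StructureSpec(StructureKind.DENDRITE, count=6, size_nm=170.0,
                          protein_density=0.6),
        ],
        noise=NoiseSpec(model="poisson_gaussian", read_sigma=0.01,
                        photon_scale=1000.0),
        seed=seed,
    )


# --------------------------------------------------------------------------
# bead calibration stacks
# --------------------------------------------------------------------------

def _render_beads_2d(shape_yx: tuple[int, int], centers_px: np.ndarray,
                     diameter_nm: float, psf_fwhm_nm: float,
                     pixel_size_nm: float, supersample: int = 5) -> np.ndarray:
    """Render uniform circles convolved with a Gaussian PSF.

    The field is rasterised on a ``supersample``-times finer grid (area
    weighting of sub-pixel coverage), blurred there, then block-averaged
    down to the acquisition grid.
    """
    H, W = shape_yx
    s = int(supersample)
    hi = np.zeros((H * s, W * s), dtype=np.float64)
    radius_px = 0.5 * diameter_nm / pixel_size_nm
    yy = (np.arange(H * s) + 0.5) / s
    xx = (np.arange(W * s) + 0.5) / s
    for cy, cx in centers_px:
        if radius_px <= 0:
            # point emitter: deposit total weight 1 px² at nearest fine pixel
            iy = min(int(cy * s), H * s - 1)
            ix = min(int(cx * s), W * s - 1)
            hi[iy, ix] += s * s
            continue
        ys = slice(max(0, int((cy - radius_px) * s) - 1),
                   min(H * s, int((cy + radius_px) * s) + 2))
        xs = slice(max(0, int((cx - radius_px) * s) - 1),
                   min(W * s, int((cx + radius_px) * s) + 2))
        dy = yy[ys, None] - cy
        dx = xx[None, xs] - cx
        hi[ys, xs] += (dy * dy + dx * dx <= radius_px * radius_px)
    sigma_hi = psf_fwhm_nm / FWHM_PER_SIGMA / pixel_size_nm * s
    hi = ndimage.gaussian_filter(hi, sigma_hi, mode="constant")
    # point-sample the blurred field at pixel centres (box binning would
    # re-broaden the PSF the calibration is supposed to measure)
    return hi[s // 2::s, s // 2::s]


def generate_bead_stack(diameter: float = 100.0, psf_fwhm: float = 320.0,
                        pixel_size: float = 80.0, n_beads: int = 20,
                        noise: NoiseSpec = NOISELESS, seed: int = 0,
                        field_yx: tuple[int, int] | None = None,
                        amplitude: float = 1.0, supersample: int = 5,
                        ) -> tuple[ImageVolume, PhantomTruth]:
    """Simulate a single-slice calibration image of sub-resolution beads.

    Beads are uniform circles of the given diameter placed with centres at
    least 3 PSF-FWHMs apart, convolved with an isotropic 2-D Gaussian PSF
    and corrupted by the requested noise.  The truth records exact centres.
    """
    if diameter < 0:
        raise ValueError("diameter must be >= 0")
    rng = np.random.default_rng(seed)
    min_sep_px = 3.0 * psf_fwhm / pixel_size
    # margin accommodates the longest profile the calibration will sample
    margin_px = (3.0 * psf_fwhm + diameter) / pixel_size
    if field_yx is None:
        # 2x the close-packing pitch so rejection sampling converges fast
        side = int(np.ceil(2.0 * np.sqrt(n_beads) * min_sep_px + 2 * margin_px)) + 4
        field_yx = (side, side)
    H, W = field_yx

    centers: list[tuple[float, float]] = []
    for _ in range(20000):
        if len(centers) == n_beads:
            break
        c = (margin_px + rng.random() * (H - 2 * margin_px),
             margin_px + rng.random() * (W - 2 * margin_px))
        if H - 2 * margin_px <= 0 or W - 2 * margin_px <= 0:
            raise PlacementError("field too small for bead margins")
        if all((c[0] - y) ** 2 + (c[1] - x) ** 2 >= min_sep_px ** 2
               for y, x in centers):
            centers.append(c)
    else:
        raise PlacementError(
            f"could not place {n_beads} beads at >= {min_sep_px:.1f} px separation "
            f"in a {H}x{W} field")

    centers_arr = np.array(centers, dtype=np.float64)
    img = _render_beads_2d(field_yx, centers_arr, diameter, psf_fwhm,
                           pixel_size, supersample=supersample) * amplitude
    img = noise.apply(img, rng)
    vol = ImageVolume(voxels=img[np.newaxis].astype(np.float32),
                      pixel_size_xy=pixel_size, channel_label="beads-3050")
    truth = PhantomTruth(bead_centers=centers_arr, bead_diameter_nm=diameter)
    return vol, truth


# --------------------------------------------------------------------------
# tissue phantom structure rasterisers
# --------------------------------------------------------------------------

def _physical_grid(shape, pixel_size, z_step):
    z, y, x = np.indices(shape).astype(np.float64)
    return z * z_step, y * pixel_size, x * pixel_size


def _ellipsoid_mask(shape, center_phys, semi_axes_phys, pixel_size, z_step):
    zz, yy, xx = _physical_grid(shape, pixel_size, z_step)
    cz, cy, cx = center_phys
    az, ay, ax = semi_axes_phys
    return (((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2
            + ((xx - cx) / ax) ** 2) <= 1.0


def _tube_from_path(shape, path_px, radius_px, z_aspect=6.25):
    """Binary tube: voxels within ``radius_px`` of a polyline.

    The centreline is rasterised, then dilated via a Euclidean distance
    transform on the anisotropy-corrected grid (``z_aspect`` = z-step over
    in-plane pixel size, so thin tubes stay single-slice).
    """
    skel = np.zeros(shape, dtype=bool)
    pts = np.clip(np.round(path_px).astype(int), 0,
                  np.array(shape) - 1)
    skel[pts[:, 0], pts[:, 1], pts[:, 2]] = True
    if radius_px < 0.5:
        return skel
    dist = ndimage.distance_transform_edt(~skel, sampling=(z_aspect, 1.0, 1.0))
    return dist <= radius_px


def _random_walk_path(rng, shape, n_steps, step_px=1.0, curvature=0.25,
                      start=None, direction=None):
    """Smooth 3-D random walk with bounded curvature, reflected at borders."""
    lim = np.array(shape, dtype=np.float64) - 1
    p = np.array(start if start is not None
                 else rng.random(3) * lim, dtype=np.float64)
    d = np.array(direction if direction is not None
                 else rng.normal(size=3), dtype=np.float64)
    d[0] *= 0.2  # walks stay mostly in-plane, like vessels in a thin slab
    d /= np.linalg.norm(d)
    path = [p.copy()]
    for _ in range(n_steps):
        turn = rng.normal(scale=curvature, size=3)
        turn[0] *= 0.2
        d = d + turn
        d /= np.linalg.norm(d)
        p = p + d * step_px
        for ax in range(3):
            if p[ax] < 0:
                p[ax] = -p[ax]
                d[ax] = -d[ax]
            elif p[ax] > lim[ax]:
                p[ax] = 2 * lim[ax] - p[ax]
                d[ax] = -d[ax]
        path.append(p.copy())
    return np.array(path)


def _render_structures(spec: PhantomSpec, rng: np.random.Generator) -> dict:
    """Rasterise every structure kind to a binary density map on the grid."""
    shape = spec.field_shape
    px, zs = spec.pixel_size_xy, spec.z_step
    phys_extent = (shape[0] * zs, shape[1] * px, shape[2] * px)
    maps = {k: np.zeros(shape, dtype=np.float64) for k in
            {s.kind for s in spec.structures}}

    nucleus_centers: list[np.ndarray] = []
    soma_centers: list[np.ndarray] = []

    def rand_center(margin_nm):
        lo = np.array([min(margin_nm, phys_extent[0] / 2), margin_nm, margin_nm])
        hi = np.array(phys_extent) - lo
        return lo + rng.random(3) * np.maximum(hi - lo, 1e-9)

    order = {StructureKind.NUCLEUS: 0, StructureKind.SOMA: 1,
             StructureKind.VESSEL: 2, StructureKind.DENDRITE: 3,
             StructureKind.CHROMOSOME_VOID: 4}
    for s in sorted(spec.structures, key=lambda s: order.get(s.kind, 9)):
        m = maps[s.kind]
        if s.kind is StructureKind.NUCLEUS:
            for _ in range(s.count):
                c = rand_center(s.size_nm)
                axes = s.size_nm * rng.uniform(0.75, 1.25, size=3)
                m[:] = np.maximum(m, _ellipsoid_mask(shape, c, axes, px, zs))
                nucleus_centers.append(c)
        elif s.kind is StructureKind.SOMA:
            for _ in range(s.count):
                c = rand_center(s.size_nm)
                axes = s.size_nm * rng.uniform(0.8, 1.2, size=3)
                m[:] = np.maximum(m, _ellipsoid_mask(shape, c, axes, px, zs))
                soma_centers.append(c)
                # each soma carries a nucleus inside
                if StructureKind.NUCLEUS in maps:
                    nmask = _ellipsoid_mask(shape, c, axes * 0.5, px, zs)
                    maps[StructureKind.NUCLEUS][:] = np.maximum(
                        maps[StructureKind.NUCLEUS], nmask)
                    nucleus_centers.append(c)
        elif s.kind is StructureKind.VESSEL:
            r_px = max(s.size_nm / px, 0.5)
            for _ in range(s.count):
                n_steps = int(1.2 * max(shape[1], shape[2]))
                path = _random_walk_path(rng, shape, n_steps)
                m[:] = np.maximum(m, _tube_from_path(shape, path, r_px, zs/px))
        elif s.kind is StructureKind.DENDRITE:
            r_px = max(s.size_nm / px, 0.0)
            starts = soma_centers if soma_centers else None
            for i in range(s.count):
                if starts:
                    c = starts[i % len(starts)]
                    start = np.array([c[0] / zs, c[1] / px, c[2] / px])
                else:
                    start = None
                n_steps = int(0.8 * max(shape[1], shape[2]))
                path = _random_walk_path(rng, shape, n_steps, curvature=0.35,
                                         start=start)
                m[:] = np.maximum(m, _tube_from_path(shape, path, r_px, zs/px))
                if rng.random() < 0.6:  # one side branch
                    j = rng.integers(n_steps // 4, 3 * n_steps // 4)
                    bpath = _random_walk_path(rng, shape, n_steps // 2,
                                              curvature=0.35, start=path[j])
                    m[:] = np.maximum(m, _tube_from_path(shape, bpath, r_px, zs/px))
        elif s.kind is StructureKind.CHROMOSOME_VOID:
            # darker chromosome regions carved inside nuclei
            if not nucleus_centers:
                continue
            for i in range(min(s.count, len(nucleus_centers))):
                c = np.asarray(nucleus_centers[i]) + rng.normal(0, s.size_nm / 2, 3)
                axes = s.size_nm * rng.uniform(0.8, 1.2, size=3)
                m[:] = np.maximum(m, _ellipsoid_mask(shape, c, axes, px, zs))
        elif s.kind is StructureKind.BEAD:
            raise ValueError("use generate_bead_stack for bead phantoms")

    # voids displace nuclear protein: remove void support from the nucleus map
    if StructureKind.CHROMOSOME_VOID in maps and StructureKind.NUCLEUS in maps:
        void = maps[StructureKind.CHROMOSOME_VOID] > 0
        maps[StructureKind.CHROMOSOME_VOID] = void.astype(np.float64) \
            * (maps[StructureKind.NUCLEUS] > 0)
        maps[StructureKind.NUCLEUS][void] = 0.0
    return maps


# --------------------------------------------------------------------------
# forward models
# --------------------------------------------------------------------------

def _background_field(spec: PhantomSpec, shape, rng: np.random.Generator
                      ) -> np.ndarray:
    """Smooth hydrogel CH2 field plus uniform water O-H term (pre-blur)."""
    bg = np.zeros(shape, dtype=np.float64)
    b = spec.background
    if b.gel_ch2_weight > 0:
        rough = rng.random(shape)
        smooth = ndimage.gaussian_filter(rough, (0.5, 8.0, 8.0), mode="reflect")
        smooth /= max(smooth.mean(), 1e-12)
        bg += b.gel_ch2_weight * smooth
    if b.water_oh_weight > 0:
        bg += b.water_oh_weight
    return bg


def srs_forward_model(truth: PhantomTruth, spec: PhantomSpec,
                      noise: bool = True,
                      retention_override: dict | float | None = None,
                      ) -> ImageVolume:
    """Linear CH3 forward model.

    SRS = sum over kinds of (protein_density x retention x density map)
    + gel background + water background, blurred by the in-plane PSF, then
    noised.  ``retention_override`` replaces the per-structure retention
    (scalar applied to all kinds, or a kind -> fraction mapping); renders of
    unprocessed samples should use ``retention_override=1.0``.
    """
    shape = next(iter(truth.density_maps.values())).shape
    img = np.zeros(shape, dtype=np.float64)
    for kind, dmap in truth.density_maps.items():
        if retention_override is None:
            ret = spec.retention_of(kind)
        elif isinstance(retention_override, dict):
            ret = retention_override.get(StructureKind(kind),
                                         spec.retention_of(kind))
        else:
            ret = float(retention_override)
        img += spec.density_of(kind) * ret * dmap
    rng = np.random.default_rng(spec.seed + 1000003)
    img += _background_field(spec, shape, rng)
    img = ndimage.gaussian_filter(img, (0, spec.psf_sigma_px, spec.psf_sigma_px),
                                  mode="reflect")
    if noise:
        img = spec.noise.apply(img, rng)
    return ImageVolume(voxels=img.astype(np.float32),
                       pixel_size_xy=spec.pixel_size_xy, z_step=spec.z_step,
                       channel_label="CH3-2940")


_FLUOR_CHANNELS = {
    "DAPI": (StructureKind.NUCLEUS, StructureKind.CHROMOSOME_VOID),
    "lectin": (StructureKind.VESSEL,),
    "MAP2": (StructureKind.SOMA, StructureKind.DENDRITE),
    "NeuN": (StructureKind.SOMA,),
}


def generate_tissue_phantom(spec: PhantomSpec
                            ) -> tuple[dict[str, ImageVolume], PhantomTruth]:
    """Generate a tissue phantom: SRS composite plus fluorescence channels.

    Returns a map ``label -> ImageVolume`` containing the ``"CH3-2940"``
    composite and one fluorescence-like channel per structure family present
    (nuclei -> DAPI, vessels -> lectin, somata+dendrites -> MAP2,
    somata -> NeuN), plus the ground truth density maps.
    """
    if not spec.structures:
        raise ValueError("PhantomSpec has no structures")
    rng = np.random.default_rng(spec.seed)
    maps = _render_structures(spec, rng)
    truth = PhantomTruth(density_maps=maps)

    channels: dict[str, ImageVolume] = {}
    channels["CH3-2940"] = srs_forward_model(truth, spec, noise=True,
                                             retention_override=1.0)
    sig = (0, spec.psf_sigma_px, spec.psf_sigma_px)
    for label, kinds in _FLUOR_CHANNELS.items():
        present = [k for k in kinds if k in maps
                   and k is not StructureKind.CHROMOSOME_VOID]
        if not present:
            continue
        f = np.zeros(spec.field_shape, dtype=np.float64)
        for k in present:
            f += maps[k]
        # chromosome regions still stain with DNA dyes
        if label == "DAPI" and StructureKind.CHROMOSOME_VOID in maps:
            f += maps[StructureKind.CHROMOSOME_VOID]
        f = ndimage.gaussian_filter(np.clip(f, 0, 1), sig, mode="reflect")
        frng = np.random.default_rng(spec.seed + abs(hash(label)) % 100000)
        f = spec.noise.apply(f, frng)
        channels[label] = ImageVolume(voxels=f.astype(np.float32),
                                      pixel_size_xy=spec.pixel_size_xy,
                                      z_step=spec.z_step, channel_label=label)
    return channels, truth


# --------------------------------------------------------------------------
# expansion simulation
# --------------------------------------------------------------------------

def _smooth_displacement(shape, rms_px, rng, corr_px=12.0):
    """Smooth random in-plane displacement field with the given RMS (px)."""
    fields = []
    for _ in range(2):
        f = ndimage.gaussian_filter(rng.standard_normal(shape),
                                    (0.5, corr_px, corr_px), mode="reflect")
        fields.append(f)
    cur = np.sqrt(np.mean([f ** 2 for f in fields]))
    scale = rms_px / max(cur, 1e-12)
    return [f * scale for f in fields]


def simulate_expansion(channels: dict[str, ImageVolume], truth: PhantomTruth,
                       spec: PhantomSpec, ratio: float,
                       distortion_rms: float = 0.0, seed: int = 0,
                       retention: dict | float | None = None,
                       ) -> tuple[dict[str, ImageVolume], dict[str, ImageVolume],
                                  PhantomTruth]:
    """Simulate isotropic physical expansion of a phantom.

    The post-expansion geometry is the pre-expansion geometry scaled by
    ``ratio`` on all three axes (imaged with the same pixel size, so
    features grow in pixels); conserved per-voxel signal is divided by
    ``ratio**3`` — fourfold expansion dilutes intensities 64-fold.  Protein
    retention (``retention`` scalar or kind -> fraction map, defaulting to
    the spec's per-structure values) further attenuates the CH3 structure
    signal of the post image.  ``distortion_rms`` (nm, in pre-expansion
    units) adds a smooth random displacement field.  Returns
    ``(pre_channels, post_channels, post_truth)``.
    """
    if ratio < 1:
        raise ValueError("expansion ratio must be >= 1")
    rng = np.random.default_rng(seed)
    dilution = float(ratio) ** 3

    def zoom3(a: np.ndarray) -> np.ndarray:
        if a.shape[0] == 1:
            z = ndimage.zoom(a[0], ratio, order=1, mode="grid-constant",
                             grid_mode=True)[np.newaxis]
            vol_factor = ratio ** 2
        else:
            z = ndimage.zoom(a, ratio, order=1, mode="grid-constant",
                             grid_mode=True)
            vol_factor = ratio ** 3
        # physical expansion conserves total signal; undo the small mass
        # drift of linear interpolation at the field boundary
        s = float(a.sum())
        if s > 0 and z.sum() > 0:
            z *= s * vol_factor / float(z.sum())
        return z

    disp = None
    post: dict[str, ImageVolume] = {}
    sig_px = spec.psf_sigma_px
    post_spec = replace(spec, seed=spec.seed + 777)
    for label, vol in channels.items():
        if label.startswith("CH3"):
            # re-render structure signal with post-homogenization retention
            base = np.zeros(spec.field_shape, dtype=np.float64)
            for kind, dmap in truth.density_maps.items():
                if retention is None:
                    ret = spec.retention_of(kind)
                elif isinstance(retention, dict):
                    ret = retention.get(StructureKind(kind),
                                        spec.retention_of(kind))
                else:
                    ret = float(retention)
                base += spec.density_of(kind) * ret * dmap
            brng = np.random.default_rng(seed + 13)
            base += _background_field(post_spec, spec.field_shape, brng)
        else:
            f = np.zeros(spec.field_shape, dtype=np.float64)
            for k in _FLUOR_CHANNELS.get(label, ()):
                if k in truth.density_maps:
                    f += truth.density_maps[k]
            if label == "DAPI" and StructureKind.CHROMOSOME_VOID in truth.density_maps:
                f += truth.density_maps[StructureKind.CHROMOSOME_VOID]
            base = np.clip(f, 0, 1)
        big = zoom3(base) / dilution
        if distortion_rms > 0:
            if disp is None:
                rms_px = distortion_rms * ratio / spec.pixel_size_xy
                disp = _smooth_displacement(big.shape, rms_px, rng)
            zz, yy, xx = np.indices(big.shape).astype(np.float64)
            big = ndimage.map_coordinates(big, [zz, yy + disp[0], xx + disp[1]],
                                          order=1, mode="reflect")
        big = ndimage.gaussian_filter(big, (0, sig_px, sig_px), mode="reflect")
        nrng = np.random.default_rng(seed + abs(hash(label)) % 100000)
        big = spec.noise.apply(big, nrng)
        post[label] = ImageVolume(voxels=big.astype(np.float32),
                                  pixel_size_xy=spec.pixel_size_xy,
                                  z_step=spec.z_step, channel_label=label,
                                  expansion_state=ExpansionState.EXPANDED,
                                  expansion_factor=float(ratio))

    post_maps = {k: zoom3(m) for k, m in truth.density_maps.items()}
    truth_post = PhantomTruth(density_maps=post_maps,
                              expansion_ratio=float(ratio),
                              distortion_rms_nm=float(distortion_rms))
    return dict(channels), post, truth_post


def degrade_ground_truth(v: ImageVolume, noise_sigma: float, seed: int = 0
                         ) -> ImageVolume:
    """Add zero-mean Gaussian noise of the given sigma (intensity units).

    Used to build the noise-robustness curve: training targets are degraded
    while test targets stay clean.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_sigma == 0:
        return v.with_voxels(v.voxels.copy())
    rng = np.random.default_rng(seed)
    noisy = v.voxels + rng.normal(0.0, noise_sigma, v.voxels.shape)
    return v.with_voxels(noisy.astype(np.float32))


# --------------------------------------------------------------------------
# YAML spec loading (CLI)
# --------------------------------------------------------------------------

def spec_from_yaml(path: str | Path) -> PhantomSpec:
    """Load a :class:`PhantomSpec` from a YAML file (``"default"`` allowed)."""
    if str(path) == "default":
        return default_phantom_spec()
    d = yaml.safe_load(Path(path).read_text()) or {}
    structures = [StructureSpec(**s) for s in d.pop("structures", [])]
    background = BackgroundSpec(**d.pop("background", {}))
    noise = NoiseSpec(**d.pop("noise", {}))
    if "field_shape" in d:
        d["field_shape"] = tuple(d["field_shape"])
    base = default_phantom_spec()
    spec = PhantomSpec(structures=structures or base.structures,
                       background=background, noise=noise, **d)
    return spec
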