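"""Synthetic lymph-node phantom generator.

Builds voxelised lymph nodes whose compartment topology mirrors a real murine
node: an ellipsoidal organ wrapped in a subcapsular sinus, a deep cortical
unit (DCU, the T-cell paracortex) displaced toward one pole, a medullary
region at the opposite pole threaded by medullary sinuses, B-cell follicles
in the cortical shell, spherical-to-ovoid B-cell nodules confined to the
medulla, adipocytes at the medullary-cortical border (lipomatosis), and
capillary segments placed per-compartment until a requested volume fraction
is reached.

The phantom represents the *embedded* specimen: linear dimensions of objects
are the true (native-tissue) sizes multiplied by (1 - shrinkage_s), matching
what resin-embedded tomography sees. ``simulate_shrinkage`` applies the same
contraction to an already-built volume, which is how single-object size
experiments are run.

All randomness flows through one ``numpy.random.Generator`` seeded from
``PhantomSpec.seed``; identical specs give bit-identical volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats

from .volumes import CLASS_MAP, NAME_TO_LABEL, LabelVolume, TileSet, Volume3D

BACKGROUND = NAME_TO_LABEL["background"]
PARENCHYMA = NAME_TO_LABEL["parenchyma"]
MEDULLARY_SINUS = NAME_TO_LABEL["medullary_sinus"]
DCU = NAME_TO_LABEL["dcu"]
FOLLICLE = NAME_TO_LABEL["follicle"]
SUBCAPSULAR_SINUS = NAME_TO_LABEL["subcapsular_sinus"]
NODULE = NAME_TO_LABEL["nodule"]
FAT_PAD = NAME_TO_LABEL["fat_pad"]
OUTER_VASCULATURE = NAME_TO_LABEL["outer_vasculature"]
VENULE = NAME_TO_LABEL["venule"]
CAPILLARY = NAME_TO_LABEL["capillary"]
ADJACENT_TISSUE = NAME_TO_LABEL["adjacent_tissue"]

#: Per-class intensity base levels (arbitrary units in [0, 1]). Cell-dense
#: compartments (follicles, nodules) are brightest, lumina darkest, matching
#: the contrast ordering of lead-stained phase tomograms.
DEFAULT_INTENSITY: dict[int, float] = {
    BACKGROUND: 0.05,
    PARENCHYMA: 0.55,
    MEDULLARY_SINUS: 0.25,
    DCU: 0.50,
    FOLLICLE: 0.85,
    SUBCAPSULAR_SINUS: 0.30,
    NODULE: 0.90,
    FAT_PAD: 0.12,
    OUTER_VASCULATURE: 0.20,
    VENULE: 0.20,
    CAPILLARY: 0.35,
    ADJACENT_TISSUE: 0.15,
}

DEFAULT_COMPARTMENT_PARAMS: dict = {
    # thicknesses/positions in normalised ellipsoid coordinates
    "subcapsular_thickness": 0.05,
    "adjacent_thickness": 0.05,
    "dcu_radius_fraction": 0.42,
    "dcu_center_zeta": -0.40,   # DCU displaced toward the -z pole
    "medulla_zeta_min": 0.12,   # medulla occupies the +z pole
    "sinus_fraction": 0.08,     # medullary-sinus volume fraction of the medulla
    "sinus_diam_um": (25.0, 60.0),
    "venule_count": 6,
    "venule_radius_um": 12.0,
    "outer_vessel_count": 3,
}


class PlacementError(RuntimeError):
    """Rejection sampling could not place an object in its host compartment."""

    def __init__(self, compartment: str, detail: str = ""):
        self.compartment = compartment
        msg = f"could not place object in compartment {compartment!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


@dataclass
class PhantomSpec:
    """Full parameterisation of a synthetic lymph node.

    Diameter laws are maximum Feret diameters. ``nodule_diam_true_um`` is the
    (mean, sd) of the nodule size law at native (unshrunk) scale; nodules are
    rasterised at the embedded scale, i.e. multiplied by
    ``(1 - shrinkage_s)``. The law is truncated to
    ``nodule_diam_window_um`` (embedded scale): objects outside that window
    would not satisfy the morphological nodule definition in the first place.
    """

    shape_voxels: tuple[int, int, int] = (128, 128, 128)
    voxel_um: float = 1.8
    ln_radii_um: tuple[float, float, float] = (100.8, 105.0, 110.0)
    compartment_params: dict = field(
        default_factory=lambda: dict(DEFAULT_COMPARTMENT_PARAMS)
    )
    follicle_count: int = 8
    follicle_diam_um: tuple[float, float] = (160.0, 30.0)
    nodule_count: int = 12
    nodule_diam_true_um: tuple[float, float] = (128.57, 38.57)
    # slightly inside the (30, 180) µm acceptance window so that digitised
    # Feret measurements (which overshoot by about half a voxel) of every
    # generated nodule still fall inside the window
    nodule_diam_window_um: tuple[float, float] = (30.0, 172.0)
    nodule_axis_ratio_range: tuple[float, float] = (0.7, 1.0)
    capillary_fraction: dict = field(default_factory=dict)
    adipocyte_count: int = 0
    adipocyte_diam_um: tuple[float, float] = (28.0, 63.0)
    shrinkage_s: float = 0.30
    noise_sd: float = 0.05
    seed: int = 0
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape_voxels):
            raise ValueError("shape_voxels must be positive")
        if self.voxel_um <= 0:
            raise ValueError("voxel_um must be positive")
        if not 0.0 <= self.shrinkage_s < 1.0:
            raise ValueError("shrinkage_s must be in [0, 1)")
        for name, frac in self.capillary_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"capillary fraction for {name!r} outside [0, 1]")
        for count in (self.follicle_count, self.nodule_count, self.adipocyte_count):
            if count < 0:
                raise ValueError("object counts must be >= 0")
        for d in (*self.follicle_diam_um[:1], *self.nodule_diam_true_um[:1],
                  *self.adipocyte_diam_um):
            if d <= 0:
                raise ValueError("diameters must be positive")
        lo, hi = self.nodule_axis_ratio_range
        if not 0 < lo <= hi <= 1.0:
            raise ValueError("axis ratio range must satisfy 0 < lo <= hi <= 1")

    @property
    def params(self) -> dict:
        merged = dict(DEFAULT_COMPARTMENT_PARAMS)
        merged.update(self.compartment_params)
        return merged


# ---------------------------------------------------------------------------
# rasterisation helpers


def _ellipsoid_box(center: np.ndarray, semi: np.ndarray, shape: tuple[int, int, int]):
    """Local boolean ellipsoid; returns (slices, mask, clipped_flag)."""
    lo = np.floor(center - semi).astype(int) - 1
    hi = np.ceil(center + semi).astype(int) + 2
    clipped = bool(np.any(lo < 0) or np.any(hi > np.asarray(shape)))
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, shape)
    if np.any(hi <= lo):
        return None, None, True
    zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    rho2 = (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    )
    mask = rho2 <= 1.0
    sl = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
    return sl, mask, clipped


def _tube_box(p0: np.ndarray, p1: np.ndarray, radius: float,
              shape: tuple[int, int, int]):
    """Local boolean capsule (cylinder with hemispherical caps) between p0 and p1."""
    lo = np.floor(np.minimum(p0, p1) - radius).astype(int) - 1
    hi = np.ceil(np.maximum(p0, p1) + radius).astype(int) + 2
    clipped = bool(np.any(lo < 0) or np.any(hi > np.asarray(shape)))
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, shape)
    if np.any(hi <= lo):
        return None, None, True
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    pts = np.stack([zz, yy, xx], axis=-1).astype(float)
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        dist2 = np.sum((pts - p0) ** 2, axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist2 = np.sum((pts - proj) ** 2, axis=-1)
    mask = dist2 <= radius**2
    sl = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
    return sl, mask, clipped


def rasterize_ellipsoid(diam_vox: float, axis_ratios: tuple[float, float],
                        margin: int = 2) -> np.ndarray:
    """Standalone boolean ellipsoid with maximum diameter ``diam_vox`` (voxels).

    The largest semi-axis equals ``diam_vox / 2``; the remaining two axes are
    scaled by ``axis_ratios``. Used for single-object size experiments.
    """
    semi = np.array([diam_vox / 2.0,
                     diam_vox / 2.0 * axis_ratios[0],
                     diam_vox / 2.0 * axis_ratios[1]])
    half = int(np.ceil(semi.max())) + margin
    n = 2 * half + 1
    c = np.full(3, half, dtype=float)
    sl, mask, _ = _ellipsoid_box(c, semi, (n, n, n))
    out = np.zeros((n, n, n), dtype=bool)
    out[sl] = mask
    return out


def _truncnorm_sampler(mean: float, sd: float, window: tuple[float, float],
                       match_mean: bool = False):
    """Truncated-normal sampler on ``window``.

    With ``match_mean`` the location is re-solved so that the *truncated*
    distribution's mean equals ``mean`` — reported size laws are means over
    the observed (in-window) population, so the generator reproduces that
    moment rather than the latent one.
    """
    loc = mean
    if match_mean:
        for _ in range(40):
            a, b = (window[0] - loc) / sd, (window[1] - loc) / sd
            shift = stats.truncnorm(a, b, loc=loc, scale=sd).mean() - mean
            if abs(shift) < 1e-9:
                break
            loc -= shift
    a, b = (window[0] - loc) / sd, (window[1] - loc) / sd
    dist = stats.truncnorm(a, b, loc=loc, scale=sd)

    def draw(rng: np.random.Generator) -> float:
        return float(dist.ppf(rng.uniform(1e-12, 1 - 1e-12)))

    return draw


def sample_nodule_diameters(n: int, spec: PhantomSpec,
                            rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` nodule maximum diameters at native (unshrunk) scale, µm."""
    mean, sd = spec.nodule_diam_true_um
    lo, hi = spec.nodule_diam_window_um
    scale = 1.0 - spec.shrinkage_s
    draw = _truncnorm_sampler(mean, sd, (lo / scale, hi / scale),
                              match_mean=True)
    return np.array([draw(rng) for _ in range(n)])


# ---------------------------------------------------------------------------
# generator


def _place_blobs(labels: np.ndarray, region: np.ndarray, count: int,
                 diam_sampler, ratio_sampler, label_value: int,
                 compartment: str, rng: np.random.Generator,
                 max_attempts: int) -> int:
    """Place ``count`` non-overlapping ellipsoids fully inside ``region``.

    Sizes are drawn once per object and only *positions* are rejection
    sampled, so the realised size law is exactly the sampling law (re-drawing
    sizes on rejection would bias the law small near compartment boundaries).
    A candidate position is accepted only if every voxel of the ellipsoid
    grown by a two-voxel separation margin (> sqrt(3), the 26-connectivity
    diagonal) is currently parenchyma and inside the host region, so objects
    neither overlap nor touch and never leak out of their compartment.
    """
    candidates = np.argwhere(region & (labels == PARENCHYMA))
    if count > 0 and len(candidates) == 0:
        raise PlacementError(compartment, "host region is empty")
    placed = 0
    # draw the full size multiset first, then place largest-first: packing
    # order does not change the realised size law but large objects need the
    # empty compartment to find room
    draws = []
    for _ in range(count):
        diam = diam_sampler(rng)
        r1, r2 = ratio_sampler(rng)
        semi = np.array([diam / 2.0, diam / 2.0 * r1, diam / 2.0 * r2])
        draws.append(semi[rng.permutation(3)])
    draws.sort(key=lambda s: -float(np.prod(s)))
    for semi in draws:
        for _attempt in range(max_attempts):
            center = candidates[rng.integers(len(candidates))].astype(float)
            sl, grown, clipped = _ellipsoid_box(center, semi + 2.0, labels.shape)
            if clipped or sl is None:
                continue
            box = labels[sl]
            if np.all((box[grown] == PARENCHYMA) & region[sl][grown]):
                sl_in, mask, _ = _ellipsoid_box(center, semi, labels.shape)
                labels[sl_in][mask] = label_value
                placed += 1
                break
        else:
            raise PlacementError(
                compartment,
                f"placed {placed}/{count} after {max_attempts} attempts each",
            )
    return placed


def _place_capillaries(labels: np.ndarray, host_label: int, fraction: float,
                       rng: np.random.Generator, voxel_um: float,
                       compartment: str, max_attempts: int = 500_000) -> float:
    """Convert host-class voxels into 3-voxel-thick capillary segments until
    the converted fraction reaches ``fraction`` of the host's original volume.

    Returns the realised fraction (converted / original host voxels).
    Segments are confined to the host: every tube voxel must currently be the
    host class or already capillary.
    """
    host0 = int(np.count_nonzero(labels == host_label))
    if host0 == 0:
        raise PlacementError(compartment, "compartment empty")
    target = fraction * host0
    if target < 1:
        return 0.0
    candidates = np.argwhere(labels == host_label)
    converted = 0
    attempts = 0
    while converted < target:
        attempts += 1
        if attempts > max_attempts:
            realised = converted / host0
            if abs(realised - fraction) <= 0.1 * fraction:
                break
            raise PlacementError(
                compartment,
                f"capillary fraction {realised:.4f} vs requested {fraction:.4f}",
            )
        p0 = candidates[rng.integers(len(candidates))].astype(float)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        length = rng.uniform(4.0, 12.0)
        p1 = p0 + d * length
        sl, mask, clipped = _tube_box(p0, p1, 1.0, labels.shape)
        if clipped or sl is None:
            continue
        box = labels[sl]
        vals = box[mask]
        if not np.all((vals == host_label) | (vals == CAPILLARY)):
            continue
        new = mask & (box == host_label)
        n_new = int(np.count_nonzero(new))
        if n_new == 0:
            continue
        box[new] = CAPILLARY
        converted += n_new
    return converted / host0


def _place_tubes(labels: np.ndarray, region: np.ndarray, count: int,
                 radius_vox: float, length_range: tuple[float, float],
                 label_value: int, rng: np.random.Generator) -> None:
    """Lay ``count`` tube segments through ``region``; only voxels currently
    belonging to the region's base class are converted (pass-through style)."""
    candidates = np.argwhere(region)
    if len(candidates) == 0 or count == 0:
        return
    for _ in range(count):
        p0 = candidates[rng.integers(len(candidates))].astype(float)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        p1 = p0 + d * rng.uniform(*length_range)
        sl, mask, _ = _tube_box(p0, p1, radius_vox, labels.shape)
        if sl is None:
            continue
        box = labels[sl]
        conv = mask & region[sl]
        box[conv] = label_value


def generate_phantom(spec: PhantomSpec) -> tuple[Volume3D, LabelVolume]:
    """Generate a synthetic lymph node: intensity volume plus label partition.

    Raises :class:`PlacementError` when a compartment cannot host the
    requested objects within the rejection-sampling budget.
    """
    rng = np.random.default_rng(spec.seed)
    params = spec.params
    shape = tuple(spec.shape_voxels)
    vox = spec.voxel_um
    semi_vox = np.asarray(spec.ln_radii_um, dtype=float) / vox
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0

    zz, yy, xx = np.ogrid[0:shape[0], 0:shape[1], 0:shape[2]]
    rho = np.sqrt(
        ((zz - center[0]) / semi_vox[0]) ** 2
        + ((yy - center[1]) / semi_vox[1]) ** 2
        + ((xx - center[2]) / semi_vox[2]) ** 2
    ).astype(np.float32)
    zeta = np.broadcast_to(
        ((zz - center[0]) / semi_vox[0]).astype(np.float32), shape
    )

    t_scs = params["subcapsular_thickness"]
    t_adj = params["adjacent_thickness"]

    labels = np.zeros(shape, dtype=np.uint8)
    labels[rho <= 1.0 + t_adj] = ADJACENT_TISSUE
    labels[rho <= 1.0] = SUBCAPSULAR_SINUS
    interior = rho <= 1.0 - t_scs
    labels[interior] = PARENCHYMA

    # deep cortical unit: ellipsoid displaced toward the -z pole
    dcu_frac = params["dcu_radius_fraction"]
    dcu_center = center.copy()
    dcu_center[0] += params["dcu_center_zeta"] * semi_vox[0]
    sl, mask, _ = _ellipsoid_box(dcu_center, dcu_frac * semi_vox, shape)
    if sl is not None:
        box = labels[sl]
        box[mask & (box == PARENCHYMA)] = DCU

    medulla = interior & (zeta >= params["medulla_zeta_min"]) & (labels == PARENCHYMA)
    safe_interior = rho <= 1.0 - t_scs - 0.02

    # follicles: cortical shell, outside medulla and DCU
    cortex = (
        interior
        & (zeta < params["medulla_zeta_min"] - 0.05)
        & (rho >= 0.40 * (1 - t_scs))
        & safe_interior
    )
    fol_mean, fol_sd = spec.follicle_diam_um
    fol_draw = _truncnorm_sampler(fol_mean / vox, fol_sd / vox,
                                  (0.65 * fol_mean / vox, 1.3 * fol_mean / vox))
    _place_blobs(
        labels, cortex, spec.follicle_count, fol_draw,
        lambda r: tuple(r.uniform(0.8, 1.0, size=2)), FOLLICLE, "cortex",
        rng, spec.max_attempts,
    )

    # nodules: spherical-to-ovoid ellipsoids confined to the medulla,
    # embedded-scale diameters
    embed = 1.0 - spec.shrinkage_s
    nod_draw_um = _truncnorm_sampler(
        spec.nodule_diam_true_um[0], spec.nodule_diam_true_um[1],
        (spec.nodule_diam_window_um[0] / embed,
         spec.nodule_diam_window_um[1] / embed),
        match_mean=True,
    )
    lo_r, hi_r = spec.nodule_axis_ratio_range
    _place_blobs(
        labels, medulla & safe_interior, spec.nodule_count,
        lambda r: nod_draw_um(r) * embed / vox,
        lambda r: tuple(r.uniform(lo_r, hi_r, size=2)),
        NODULE, "medulla", rng, spec.max_attempts,
    )

    # adipocytes: spheres at the medullary-cortical border
    border = (
        interior
        & (np.abs(zeta - params["medulla_zeta_min"]) < 0.18)
        & safe_interior
    )
    adip_lo, adip_hi = spec.adipocyte_diam_um
    _place_blobs(
        labels, border, spec.adipocyte_count,
        lambda r: r.uniform(adip_lo, adip_hi) / vox,
        lambda r: (1.0, 1.0), FAT_PAD, "medullary-cortical border",
        rng, spec.max_attempts,
    )

    # medullary sinuses: overlapping blobs until the requested fraction of the
    # medulla is sinus lumen (they form one connected network in reality; the
    # phantom only needs their spatial support). Placed after the discrete
    # objects so that the sinus network wraps around them instead of
    # size-biasing their rejection sampling.
    sinus_lo, sinus_hi = params["sinus_diam_um"]
    sinus_target = params["sinus_fraction"] * int(np.count_nonzero(medulla))
    med_candidates = np.argwhere(medulla & safe_interior & (labels == PARENCHYMA))
    n_sinus = 0
    attempts = 0
    while n_sinus < sinus_target and len(med_candidates):
        attempts += 1
        if attempts > spec.max_attempts * 10:
            raise PlacementError("medullary_sinus", "sinus fraction unreachable")
        c = med_candidates[rng.integers(len(med_candidates))].astype(float)
        diam = rng.uniform(sinus_lo, sinus_hi) / vox
        semi = np.full(3, diam / 2.0) * rng.uniform(0.7, 1.3, size=3)
        sl, mask, clipped = _ellipsoid_box(c, semi, shape)
        if clipped or sl is None:
            continue
        box = labels[sl]
        conv = mask & (box == PARENCHYMA) & medulla[sl]
        box[conv] = MEDULLARY_SINUS
        n_sinus += int(np.count_nonzero(conv))

    # venules through the medulla, outer vessels in the adjacent-tissue shell
    _place_tubes(
        labels, medulla & (labels == PARENCHYMA), params["venule_count"],
        params["venule_radius_um"] / vox, (20.0, 60.0), VENULE, rng,
    )
    _place_tubes(
        labels, labels == ADJACENT_TISSUE, params["outer_vessel_count"],
        max(1.0, 10.0 / vox), (20.0, 80.0), OUTER_VASCULATURE, rng,
    )

    # capillaries per compartment
    for name, frac in spec.capillary_fraction.items():
        host = NAME_TO_LABEL[name]
        _place_capillaries(labels, host, frac, rng, vox, name)

    # intensity: class base level + Gaussian noise
    levels = np.zeros(max(CLASS_MAP) + 1, dtype=np.float32)
    for lab, lev in DEFAULT_INTENSITY.items():
        levels[lab] = lev
    data = levels[labels] + rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    return (
        Volume3D(data=data, voxel_um=vox),
        LabelVolume(labels=labels, voxel_um=vox),
    )


# ---------------------------------------------------------------------------
# shrinkage


def simulate_shrinkage(vol, s: float):
    """Contract all linear dimensions by (1 - s) via resampling.

    Trilinear interpolation for intensity volumes, nearest neighbour for label
    volumes; ``voxel_um`` is unchanged (the *specimen* shrinks, not the
    detector).
    """
    if not 0.0 <= s < 1.0:
        raise ValueError("shrinkage s must be in [0, 1)")
    if s == 0.0:
        if isinstance(vol, LabelVolume):
            return LabelVolume(vol.labels.copy(), vol.voxel_um, dict(vol.class_map))
        return Volume3D(vol.data.copy(), vol.voxel_um)
    factor = 1.0 - s
    if isinstance(vol, LabelVolume):
        out = ndimage.zoom(vol.labels, factor, order=0, mode="nearest",
                           grid_mode=False)
        return LabelVolume(out, vol.voxel_um, dict(vol.class_map))
    out = ndimage.zoom(vol.data, factor, order=1, mode="nearest",
                       grid_mode=False)
    return Volume3D(out.astype(vol.data.dtype, copy=False), vol.voxel_um)


# ---------------------------------------------------------------------------
# SEM-like view rendering


def render_sem_view(vol: Volume3D, pose, affine, tiling: dict) -> TileSet:
    """Render an SEM-style overview mosaic of a virtual slice through ``vol``.

    Forward model (ground truth stored in ``TileSet.meta`` for tests):
    extract the slice at ``pose``, upsample, apply the in-plane affine
    (anisotropic scale + shear + rotation), invert contrast (backscatter SEM
    convention), then cut overlapping tiles with per-tile radial vignetting,
    offset jitter and additive noise.

    ``tiling`` keys: out_shape, upscale, tile_shape, overlap_fraction,
    jitter_px, vignette_strength, noise_sd, seed.
    """
    from skimage.transform import rescale

    from .register import apply_inplane_affine, extract_virtual_slice

    if affine.sx <= 0 or affine.sy <= 0:
        raise ValueError("degenerate in-plane affine (non-positive determinant)")

    out_shape = tuple(tiling.get("out_shape", vol.shape[1:]))
    upscale = int(tiling.get("upscale", 1))
    jitter = int(tiling.get("jitter_px", 0))
    overlap = float(tiling.get("overlap_fraction", 0.1))
    vignette = float(tiling.get("vignette_strength", 0.0))
    noise_sd = float(tiling.get("noise_sd", 0.0))
    rng = np.random.default_rng(tiling.get("seed", 0))

    img = extract_virtual_slice(vol, pose, out_shape)
    if upscale > 1:
        img = rescale(img, upscale, order=1, preserve_range=True)
    img = apply_inplane_affine(img, affine)
    img = (img.max() + img.min()) - img  # SEM contrast

    tile_shape = tuple(tiling.get("tile_shape", img.shape))
    th, tw = tile_shape
    stride_r = max(1, int(round(th * (1.0 - overlap))))
    stride_c = max(1, int(round(tw * (1.0 - overlap))))
    rows = list(range(0, max(img.shape[0] - th, 0) + 1, stride_r)) or [0]
    cols = list(range(0, max(img.shape[1] - tw, 0) + 1, stride_c)) or [0]

    tiles: list[np.ndarray] = []
    offsets: list[tuple[int, int]] = []
    jitters: list[tuple[int, int]] = []
    rr, cc = np.mgrid[0:th, 0:tw]
    r2 = ((rr - (th - 1) / 2) ** 2 + (cc - (tw - 1) / 2) ** 2)
    r2 = r2 / r2.max() if r2.max() > 0 else r2
    gain = 1.0 - vignette * r2
    for r0 in rows:
        for c0 in cols:
            jr = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            jc = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            ar = int(np.clip(r0 + jr, 0, img.shape[0] - th))
            ac = int(np.clip(c0 + jc, 0, img.shape[1] - tw))
            tile = img[ar:ar + th, ac:ac + tw] * gain
            if noise_sd > 0:
                tile = tile + rng.normal(0.0, noise_sd, size=tile.shape)
            tiles.append(tile.astype(np.float32))
            offsets.append((r0, c0))
            jitters.append((ar - r0, ac - c0))

    pixel_um = vol.voxel_um / upscale
    return TileSet(
        tiles=tiles,
        nominal_offsets=offsets,
        overlap_fraction=overlap,
        pixel_um=pixel_um,
        vignette_model={"strength": vignette, "profile": "radial-quadratic"},
        meta={
            "pose": pose,
            "affine": affine,
            "upscale": upscale,
            "jitters": jitters,
            "panorama": img.astype(np.float32),
        },
    )
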