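"""Mutual-information 2D-to-3D virtual-slice registration.

Finds the oblique plane through a tomographic volume that matches a 2D
micrograph, by maximising the mutual information (MI) between the micrograph
and trilinearly resampled virtual slices. The search is a deterministic
coordinate-descent hill-climb over a rigid slice pose (three rotations, three
translations) plus an in-plane affine of the micrograph (anisotropic scale,
shear, in-plane rotation), run coarse-to-fine over an image pyramid with
step-halving schedules.

Conventions
-----------
* Angles in degrees, translations in full-resolution voxels.
* The slice plane lives in a right-handed (x, y, z) frame with origin at the
  volume centre; rotations are applied in z*y*x order; array indexing is
  (z, y, x).
* The forward imaging model is ``img = A(slice(vol, pose))`` with ``A`` the
  in-plane affine; the optimizer therefore compares ``slice(vol, pose)``
  against ``A^{-1}(img)``.
* Out-of-volume samples are filled with 0 and masked out of the MI histogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.transform import AffineTransform, downscale_local_mean, resize, warp

from .volumes import Volume3D

__all__ = [
    "SlicePose",
    "InPlaneAffine",
    "Schedule",
    "RegistrationResult",
    "extract_virtual_slice",
    "apply_inplane_affine",
    "mutual_information",
    "register_slice",
    "reapply_full_res",
    "refine_region",
]


def _norm_angle(a: float) -> float:
    """Normalise an angle to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


@dataclass
class SlicePose:
    """Rigid pose of a virtual slice plane: rotations (deg) about the volume
    x/y/z axes and translation of the plane origin relative to the volume
    centre, in voxels."""

    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0

    def normalized(self) -> "SlicePose":
        return SlicePose(
            _norm_angle(self.rx), _norm_angle(self.ry), _norm_angle(self.rz),
            self.tx, self.ty, self.tz,
        )


@dataclass
class InPlaneAffine:
    """Anisotropic scale, shear (x' = x + k*y) and in-plane rotation (deg)."""

    sx: float = 1.0
    sy: float = 1.0
    k: float = 0.0
    theta2d: float = 0.0

    def __post_init__(self) -> None:
        if self.sx <= 0 or self.sy <= 0:
            raise ValueError("scale factors must be positive")

    def matrix(self, shape: tuple[int, int]) -> np.ndarray:
        """Forward homogeneous 3x3 matrix acting on (x, y) about the image centre."""
        th = math.radians(self.theta2d)
        rot = np.array([[math.cos(th), -math.sin(th), 0.0],
                        [math.sin(th), math.cos(th), 0.0],
                        [0.0, 0.0, 1.0]])
        sk = np.array([[self.sx, self.sx * self.k, 0.0],
                       [0.0, self.sy, 0.0],
                       [0.0, 0.0, 1.0]])
        cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
        t_fwd = np.array([[1.0, 0.0, cx], [0.0, 1.0, cy], [0.0, 0.0, 1.0]])
        t_back = np.array([[1.0, 0.0, -cx], [0.0, 1.0, -cy], [0.0, 0.0, 1.0]])
        return t_fwd @ rot @ sk @ t_back


DEFAULT_STEPS: dict[str, float] = {
    "rx": 4.0, "ry": 4.0, "tz": 4.0, "tx": 4.0, "ty": 4.0,
    "theta2d": 4.0, "sx": 0.04, "sy": 0.04, "k": 0.04,
}
MIN_STEPS: dict[str, float] = {
    "rx": 0.125, "ry": 0.125, "tz": 0.125, "tx": 0.125, "ty": 0.125,
    "theta2d": 0.125, "sx": 0.002, "sy": 0.002, "k": 0.002,
}
#: fixed parameter sweep order: plane depth and orientation first, then
#: in-plane translation, rotation, scale and shear
SWEEP_ORDER = ("tz", "rx", "ry", "tx", "ty", "theta2d", "sx", "sy", "k")
INPLANE_ORDER = ("tx", "ty", "theta2d", "sx", "sy", "k")


@dataclass
class Schedule:
    """Coarse-to-fine search schedule."""

    pyramid_factors: tuple[int, ...] = (8, 4, 2, 1)
    step_sizes: dict = field(default_factory=lambda: dict(DEFAULT_STEPS))
    min_steps: dict = field(default_factory=lambda: dict(MIN_STEPS))
    shrink_factor: float = 0.5
    max_sweeps: int = 60
    bins: int = 64
    binarize: bool = False

    def __post_init__(self) -> None:
        f = self.pyramid_factors
        if list(f) != sorted(f, reverse=True) or f[-1] != 1:
            raise ValueError("pyramid_factors must strictly decrease to 1")
        if any(s <= 0 for s in self.step_sizes.values()):
            raise ValueError("steps must be positive")


@dataclass
class RegistrationResult:
    pose: SlicePose
    affine: InPlaneAffine
    mi_bits: float
    trace: list  # (level, sweep, mi_bits)
    converged: bool
    #: True when the optimizer ended below the initialisation's MI and the
    #: initialisation was returned instead (capture failure, not silent)
    fallback_to_init: bool = False
    img_shape: tuple[int, int] = (0, 0)


# ---------------------------------------------------------------------------
# geometry


def _rotation_matrix(pose: SlicePose) -> np.ndarray:
    """R = Rz @ Ry @ Rx in (x, y, z) coordinates."""
    rx, ry, rz = (math.radians(a) for a in (pose.rx, pose.ry, pose.rz))
    Rx = np.array([[1, 0, 0],
                   [0, math.cos(rx), -math.sin(rx)],
                   [0, math.sin(rx), math.cos(rx)]])
    Ry = np.array([[math.cos(ry), 0, math.sin(ry)],
                   [0, 1, 0],
                   [-math.sin(ry), 0, math.cos(ry)]])
    Rz = np.array([[math.cos(rz), -math.sin(rz), 0],
                   [math.sin(rz), math.cos(rz), 0],
                   [0, 0, 1]])
    return Rz @ Ry @ Rx


def _slice_coords(vol_shape: tuple[int, int, int], pose: SlicePose,
                  out_shape: tuple[int, int]) -> np.ndarray:
    """(3, H, W) array of (z, y, x) sample coordinates for the slice plane."""
    H, W = out_shape
    R = _rotation_matrix(pose)
    e_u = R @ np.array([1.0, 0.0, 0.0])  # in-plane x direction
    e_v = R @ np.array([0.0, 1.0, 0.0])  # in-plane y direction
    center = (np.asarray(vol_shape, dtype=float) - 1.0) / 2.0  # (z, y, x)
    origin_xyz = center[::-1] + np.array([pose.tx, pose.ty, pose.tz])
    u = np.arange(W) - (W - 1) / 2.0
    v = np.arange(H) - (H - 1) / 2.0
    uu, vv = np.meshgrid(u, v)
    pts = (origin_xyz[:, None, None]
           + e_u[:, None, None] * uu[None]
           + e_v[:, None, None] * vv[None])  # (x,y,z) stacked
    return pts[::-1]  # reorder to (z, y, x)


def extract_virtual_slice(vol: Volume3D, pose: SlicePose,
                          out_shape: tuple[int, int],
                          return_mask: bool = False):
    """Trilinearly sample the volume on the plane defined by ``pose``.

    Out-of-volume samples are 0; with ``return_mask=True`` a boolean validity
    mask is returned alongside.
    """
    if out_shape[0] <= 0 or out_shape[1] <= 0:
        raise ValueError("out_shape must be positive")
    coords = _slice_coords(vol.shape, pose, out_shape)
    data = vol.data
    if not np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    img = ndimage.map_coordinates(data, coords, order=1, mode="constant",
                                  cval=0.0)
    if not return_mask:
        return img
    hi = np.asarray(vol.shape, dtype=float) - 1.0
    mask = np.all((coords >= 0.0) & (coords <= hi[:, None, None]), axis=0)
    return img, mask


def apply_inplane_affine(img: np.ndarray, aff: InPlaneAffine,
                         inverse: bool = False, return_mask: bool = False):
    """Warp ``img`` by the in-plane affine about the image centre.

    Forward maps slice-plane coordinates to micrograph coordinates
    (``out = A(img)``); ``inverse=True`` undoes that mapping.
    """
    M = aff.matrix(img.shape)
    if abs(np.linalg.det(M)) < 1e-12:
        raise ValueError("degenerate in-plane affine")
    # skimage.warp wants the output->input map
    inv_map = M if inverse else np.linalg.inv(M)
    tform = AffineTransform(matrix=np.linalg.inv(inv_map))
    out = warp(img.astype(np.float64), tform.inverse, order=1, mode="constant",
               cval=0.0, preserve_range=True)
    if not return_mask:
        return out
    ones = warp(np.ones_like(img, dtype=np.float64), tform.inverse, order=1,
                mode="constant", cval=0.0, preserve_range=True)
    return out, ones > 0.999


# ---------------------------------------------------------------------------
# mutual information


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 64,
                       mask: np.ndarray | None = None) -> float:
    """Histogram mutual information in bits, with per-image min-max binning."""
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    av = a[mask] if mask is not None else a.ravel()
    bv = b[mask] if mask is not None else b.ravel()
    if av.size == 0:
        raise ValueError("empty overlap after masking")
    a_lo, a_hi = float(av.min()), float(av.max())
    b_lo, b_hi = float(bv.min()), float(bv.max())
    if a_hi == a_lo or b_hi == b_lo:
        return 0.0  # a constant image is independent of anything
    joint, _, _ = np.histogram2d(av, bv, bins=bins,
                                 range=[[a_lo, a_hi], [b_lo, b_hi]])
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    denom = np.outer(px, py)
    mi = float(np.sum(pxy[nz] * np.log2(pxy[nz] / denom[nz])))
    return max(mi, 0.0)


def _effective_bins(n_valid: int, bins: int) -> int:
    """Shrink the histogram at coarse pyramid levels so bins stay populated."""
    return int(max(8, min(bins, math.sqrt(n_valid / 5.0))))


# ---------------------------------------------------------------------------
# optimisation


_PARAMS_POSE = ("rx", "ry", "rz", "tx", "ty", "tz")
_PARAMS_AFF = ("sx", "sy", "k", "theta2d")


def _unpack(p: dict) -> tuple[SlicePose, InPlaneAffine]:
    pose = SlicePose(**{k: p[k] for k in _PARAMS_POSE})
    aff = InPlaneAffine(**{k: p[k] for k in _PARAMS_AFF})
    return pose, aff


def _objective(p: dict, vol_level: Volume3D, img_level: np.ndarray,
               factor: int, sched: Schedule) -> float:
    pose, aff = _unpack(p)
    pose_l = replace(pose, tx=pose.tx / factor, ty=pose.ty / factor,
                     tz=pose.tz / factor)
    if aff.sx <= 0.05 or aff.sy <= 0.05:
        return -np.inf
    sl, sl_mask = extract_virtual_slice(vol_level, pose_l, img_level.shape,
                                        return_mask=True)
    moving, mv_mask = apply_inplane_affine(img_level, aff, inverse=True,
                                           return_mask=True)
    mask = sl_mask & mv_mask
    n = int(np.count_nonzero(mask))
    if n < 0.3 * mask.size:
        return -np.inf
    if sched.binarize:
        sv, mv = sl[mask], moving[mask]
        try:
            sb = sv > threshold_otsu(sv)
            mb = mv > threshold_otsu(mv)
        except ValueError:
            return -np.inf
        joint = np.zeros((2, 2))
        np.add.at(joint, (sb.astype(int), mb.astype(int)), 1)
        pxy = joint / joint.sum()
        px, py = pxy.sum(1), pxy.sum(0)
        nz = pxy > 0
        return float(np.sum(pxy[nz] * np.log2(pxy[nz] / np.outer(px, py)[nz])))
    return mutual_information(sl, moving, _effective_bins(n, sched.bins), mask)


def _hill_climb(p: dict, order: tuple[str, ...], vol_level: Volume3D,
                img_level: np.ndarray, factor: int, sched: Schedule,
                level_idx: int, trace: list) -> tuple[dict, float]:
    steps = {k: sched.step_sizes.get(k, DEFAULT_STEPS[k]) for k in order}
    floors = {k: sched.min_steps.get(k, MIN_STEPS[k]) for k in order}
    current = _objective(p, vol_level, img_level, factor, sched)
    for sweep in range(sched.max_sweeps):
        improved = False
        for name in order:
            for sign in (+1.0, -1.0):
                while True:
                    cand = dict(p)
                    cand[name] = p[name] + sign * steps[name]
                    val = _objective(cand, vol_level, img_level, factor, sched)
                    if val > current + 1e-12:
                        p, current = cand, val
                        improved = True
                    else:
                        break
        trace.append((level_idx, sweep, current))
        if not improved:
            if all(steps[k] * sched.shrink_factor < floors[k] for k in order):
                break
            for k in order:
                steps[k] = max(steps[k] * sched.shrink_factor, floors[k])
    return p, current


def _downscale_volume(vol: Volume3D, factor: int) -> Volume3D:
    if factor == 1:
        return vol
    data = downscale_local_mean(vol.data, (factor,) * 3)
    return Volume3D(data.astype(np.float32), vol.voxel_um * factor)


def register_slice(vol: Volume3D, img: np.ndarray,
                   init: tuple[SlicePose, InPlaneAffine] | None = None,
                   sched: Schedule | None = None,
                   order: tuple[str, ...] = SWEEP_ORDER) -> RegistrationResult:
    """Coarse-to-fine MI maximisation of a slice pose + in-plane affine.

    ``img`` must already be at CT contrast (i.e. an inverted SEM micrograph).
    The optimizer is fully deterministic: registering the same pair twice with
    the same schedule is bit-identical.
    """
    sched = sched or Schedule()
    pose0, aff0 = init if init is not None else (SlicePose(), InPlaneAffine())
    p = {**{k: getattr(pose0, k) for k in _PARAMS_POSE},
         **{k: getattr(aff0, k) for k in _PARAMS_AFF}}
    img = np.asarray(img, dtype=np.float64)
    mi_init = _objective(p, _downscale_volume(vol, sched.pyramid_factors[-1]),
                         downscale_local_mean(img, (sched.pyramid_factors[-1],) * 2)
                         if sched.pyramid_factors[-1] > 1 else img,
                         sched.pyramid_factors[-1], sched)

    p_init = dict(p)
    trace: list = []
    current = -np.inf
    for li, factor in enumerate(sched.pyramid_factors):
        vol_l = _downscale_volume(vol, factor)
        img_l = downscale_local_mean(img, (factor, factor)) if factor > 1 else img
        p, current = _hill_climb(p, order, vol_l, img_l, factor, sched, li, trace)

    fallback = bool(current < mi_init - 1e-9)
    if fallback:
        # a coarse level degraded a good initialisation and the fine level
        # could not recover: never return something worse than the init
        p, current = p_init, mi_init
    pose, aff = _unpack(p)
    return RegistrationResult(
        pose=pose.normalized(), affine=aff, mi_bits=float(current),
        trace=trace, converged=bool(current >= mi_init - 1e-9),
        fallback_to_init=fallback,
        img_shape=img.shape,
    )


def reapply_full_res(result: RegistrationResult, img_hi: np.ndarray,
                     vol: Volume3D) -> tuple[np.ndarray, np.ndarray]:
    """Re-apply saved affine parameters at full micrograph resolution.

    Returns ``(shear-corrected full-resolution micrograph, CT slice upscaled
    bilinearly to the micrograph grid)``, sharing one coordinate system.
    """
    h0, w0 = result.img_shape
    if h0 <= 0:
        raise ValueError("result does not record a registered image shape")
    ratio_h = img_hi.shape[0] / h0
    ratio_w = img_hi.shape[1] / w0
    if abs(ratio_h - round(ratio_h)) > 1e-9 or abs(ratio_w - round(ratio_w)) > 1e-9:
        raise ValueError("high-resolution image is not an integer upscale")
    ratio = int(round(ratio_h))
    corrected = apply_inplane_affine(img_hi, result.affine, inverse=True)
    sl = extract_virtual_slice(vol, result.pose, (h0, w0))
    sl_hi = resize(sl, img_hi.shape, order=1, mode="edge",
                   preserve_range=True, anti_aliasing=False) if ratio > 1 else sl
    return corrected, sl_hi


def refine_region(vol: Volume3D, img_zoom: np.ndarray,
                  prior: RegistrationResult,
                  sched: Schedule | None = None) -> RegistrationResult:
    """Refine a zoomed micrograph against the volume, keeping the slice-plane
    orientation (rx, ry) and depth from ``prior`` and optimising only the
    in-plane parameters (tx, ty, theta2d, sx, sy, k)."""
    sched = sched or Schedule(pyramid_factors=(2, 1))
    res = register_slice(vol, img_zoom, init=(prior.pose, prior.affine),
                         sched=sched, order=INPLANE_ORDER)
    return res
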