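"""CT-stack conditioning and SEM flat-field / stitch / invert chains.

The CT chain removes slowly varying background (edge gradients at the
air-resin interface) by wide-Gaussian subtraction, sharpens with an unsharp
mask, then clips and normalises intensities to [0, 1] float32. The SEM chain
divides each backscatter tile by a Gaussian-smoothed feature-empty reference
(shading correction), stitches tiles on their nominal grid with optional
phase-correlation refinement and feathered linear blending, and finally
inverts contrast so stained tissue is bright, as in the tomograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .volumes import TileSet, Volume3D

__all__ = [
    "PreprocessParams",
    "background_subtract",
    "unsharp_mask",
    "clip_normalize",
    "flatfield_correct",
    "stitch_tiles",
    "invert",
    "to_uint8",
]


@dataclass
class PreprocessParams:
    """Tunable knobs of the conditioning chains.

    ``bg_sigma_px`` is the Gaussian background sigma (valid range 300-500 px
    at the native 1.8 µm pitch); ``unsharp_weight`` the mask weight (valid
    0.4-0.6); ``flatfield_sigma_px`` the smoothing applied to the
    feature-empty reference tile before division.
    """

    bg_sigma_px: float = 400.0
    unsharp_radius_px: float = 1.5
    unsharp_weight: float = 0.5
    clip_lo: float | None = None
    clip_hi: float | None = None
    flatfield_sigma_px: float = 50.0
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.bg_sigma_px <= 0:
            raise ValueError("bg_sigma_px must be positive")
        if not 0.0 < self.unsharp_weight < 1.0:
            raise ValueError("unsharp_weight must be in (0, 1)")
        if (self.clip_lo is not None and self.clip_hi is not None
                and not self.clip_lo < self.clip_hi):
            raise ValueError("clip_lo must be < clip_hi")


def _check_finite(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("non-finite input image")
    return img


def background_subtract(img: np.ndarray, sigma_px: float) -> np.ndarray:
    """Subtract a wide-Gaussian background estimate, re-adding the global mean
    so the result stays in the original intensity range."""
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    img = _check_finite(img)
    bg = ndimage.gaussian_filter(img, sigma_px, mode="nearest")
    return img - bg + img.mean()


def unsharp_mask(img: np.ndarray, radius_px: float, weight: float) -> np.ndarray:
    """Renormalised subtractive unsharp mask:
    ``(img - weight * blur(img)) / (1 - weight)``."""
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    if not 0.0 < weight < 1.0:
        raise ValueError("weight must be in (0, 1)")
    img = _check_finite(img)
    blurred = ndimage.gaussian_filter(img, radius_px, mode="nearest")
    return (img - weight * blurred) / (1.0 - weight)


def clip_normalize(vol: Volume3D, lo: float, hi: float) -> Volume3D:
    """Clip to [lo, hi] and map affinely to [0, 1], stored as float32."""
    if not lo < hi:
        raise ValueError("lo must be < hi")
    data = np.clip(vol.data.astype(np.float64), lo, hi)
    data = (data - lo) / (hi - lo)
    return Volume3D(data.astype(np.float32), vol.voxel_um)


def flatfield_correct(tile: np.ndarray, reference: np.ndarray,
                      epsilon: float = 1e-6,
                      sigma_ff: float = 50.0) -> np.ndarray:
    """Shading correction: divide by the Gaussian-smoothed feature-empty
    reference (``sigma_ff = 0`` uses the raw reference), then rescale to unit
    mean."""
    tile = _check_finite(tile)
    reference = _check_finite(reference)
    if tile.shape != reference.shape:
        raise ValueError("tile/reference shape mismatch")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    flat = (ndimage.gaussian_filter(reference, sigma_ff, mode="nearest")
            if sigma_ff > 0 else reference)
    corrected = tile / np.maximum(flat, epsilon)
    m = corrected.mean()
    return corrected / m if m != 0 else corrected


def _feather_weight(shape: tuple[int, int]) -> np.ndarray:
    """Separable tent weight, maximal at the tile centre, >0 everywhere."""
    wr = 1.0 - np.abs(np.linspace(-1, 1, shape[0])) * (1.0 - 1.0 / shape[0])
    wc = 1.0 - np.abs(np.linspace(-1, 1, shape[1])) * (1.0 - 1.0 / shape[1])
    return np.outer(wr, wc)


def stitch_tiles(tiles: TileSet, refine: bool = False,
                 max_shift_px: int = 8) -> np.ndarray:
    """Assemble a mosaic by feathered linear blending on (optionally refined)
    tile offsets.

    With ``refine=True`` each tile's offset is re-estimated by phase
    correlation of its overlap with the composite of previously placed tiles,
    constrained to ±``max_shift_px`` around the nominal offset; ties prefer
    the smallest displacement. Blend weights sum to 1 at every covered output
    pixel, so constant tiles stitch to an exactly constant composite.
    """
    offsets = [np.array(o, dtype=int) for o in tiles.nominal_offsets]
    shapes = [t.shape for t in tiles.tiles]
    if refine and len(tiles.tiles) > 1:
        refined = [offsets[0]]
        placed = [(offsets[0], tiles.tiles[0])]
        for off, tile in zip(offsets[1:], tiles.tiles[1:]):
            best = np.zeros(2, dtype=int)
            best_area = 0
            for poff, ptile in placed:
                r0 = max(off[0], poff[0])
                c0 = max(off[1], poff[1])
                r1 = min(off[0] + tile.shape[0], poff[0] + ptile.shape[0])
                c1 = min(off[1] + tile.shape[1], poff[1] + ptile.shape[1])
                if r1 - r0 < 8 or c1 - c0 < 8:
                    continue
                a = ptile[r0 - poff[0]:r1 - poff[0], c0 - poff[1]:c1 - poff[1]]
                b = tile[r0 - off[0]:r1 - off[0], c0 - off[1]:c1 - off[1]]
                shift, _, _ = phase_cross_correlation(a, b, normalization=None)
                shift = np.round(shift).astype(int)
                area = (r1 - r0) * (c1 - c0)
                # trust the estimate from the widest overlap; ties prefer the
                # smaller displacement
                better = (area > best_area
                          or (area == best_area
                              and np.sum(shift**2) < np.sum(best**2)))
                if np.all(np.abs(shift) <= max_shift_px) and better:
                    best = shift
                    best_area = area
            refined.append(off + best)
            placed.append((off + best, tile))
        offsets = refined
        if not _connected(offsets, shapes):
            raise ValueError("refined mosaic became disconnected")
    if not _connected(offsets, shapes):
        raise ValueError("tiles do not form a connected mosaic")

    origin = np.min(offsets, axis=0)
    extent = np.max([o - origin + np.array(s) for o, s in zip(offsets, shapes)],
                    axis=0)
    acc = np.zeros(tuple(extent), dtype=np.float64)
    wacc = np.zeros(tuple(extent), dtype=np.float64)
    for off, tile in zip(offsets, tiles.tiles):
        r, c = off - origin
        w = _feather_weight(tile.shape)
        acc[r:r + tile.shape[0], c:c + tile.shape[1]] += w * tile
        wacc[r:r + tile.shape[0], c:c + tile.shape[1]] += w
    out = np.zeros_like(acc)
    covered = wacc > 0
    out[covered] = acc[covered] / wacc[covered]
    return out


def _connected(offsets, shapes) -> bool:
    """Tiles form one component under the 'rectangles touch or overlap' relation."""
    n = len(offsets)
    if n == 1:
        return True
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            ri = (offsets[i][0], offsets[i][0] + shapes[i][0])
            rj = (offsets[j][0], offsets[j][0] + shapes[j][0])
            ci = (offsets[i][1], offsets[i][1] + shapes[i][1])
            cj = (offsets[j][1], offsets[j][1] + shapes[j][1])
            if ri[0] <= rj[1] and rj[0] <= ri[1] and ci[0] <= cj[1] and cj[0] <= ci[1]:
                adj[i].append(j)
                adj[j].append(i)
    seen = {0}
    stack = [0]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == n


def invert(img: np.ndarray) -> np.ndarray:
    """Contrast inversion: ``(max + min) - img``. An involution."""
    img = _check_finite(img)
    return (img.max() + img.min()) - img


def to_uint8(img: np.ndarray) -> np.ndarray:
    """Lossy 8-bit export (storage convenience, not part of the analysis path)."""
    img = _check_finite(img)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros(img.shape, dtype=np.uint8)
    return np.round(255.0 * (img - lo) / (hi - lo)).astype(np.uint8)
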