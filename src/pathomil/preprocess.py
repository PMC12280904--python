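"""Slide preprocessing: tissue masking, tiling, stain normalization, augmentation.

Converts a raw RGB slide image into analysis-ready tiles:

1. Otsu thresholding on grayscale luminance separates tissue (dark) from
   white background.
2. The non-background region is cut into non-overlapping square tiles
   (512 px in production); partial edge tiles are dropped, and a tile is
   kept only if at least ``min_tissue_fraction`` of it is tissue.
3. Macenko stain normalization maps each tile's hematoxylin/eosin optical
   density basis onto a reference basis, removing staining batch effects.
4. Per-channel z-scoring standardizes intensities for the CNN.
5. Seeded augmentation (flips, blur, color jitter, sprinkle occlusion)
   regularizes patch-model training.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import DegenerateHistogramError, RGBPatch, StainEstimationError

__all__ = [
    "TissueMask",
    "StainReference",
    "AugmentConfig",
    "ZScoredPatch",
    "compute_tissue_mask",
    "tile_slide",
    "estimate_stain_reference",
    "macenko_normalize",
    "zscore_patch",
    "augment_patch",
]

#: ITU-R 601 luma weights used to collapse RGB to grayscale for masking.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class TissueMask:
    """Boolean tissue mask at a stated downsample factor.

    ``mask[i, j]`` is True where the downsampled luminance is below the
    Otsu threshold (tissue is dark, background is white).
    """

    mask: np.ndarray
    otsu_threshold: int
    downsample: int
    tissue_fraction_per_tile: dict[tuple[int, int], float] = field(default_factory=dict)


@dataclass(frozen=True)
class StainReference:
    """Macenko stain basis: H and E optical-density directions + scale.

    ``stain_vectors`` is 3x2 with unit-norm columns (H first, then E);
    ``max_concentrations`` holds the 99th-percentile concentration of each
    stain, used to match dynamic range between source and reference.
    """

    stain_vectors: np.ndarray
    max_concentrations: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.stain_vectors, dtype=float)
        c = np.asarray(self.max_concentrations, dtype=float)
        if v.shape != (3, 2):
            raise ValueError("stain_vectors must be 3x2")
        if not np.allclose(np.linalg.norm(v, axis=0), 1.0, atol=1e-8):
            raise ValueError("stain vector columns must have unit norm")
        if (c <= 0).any():
            raise ValueError("max_concentrations must be positive")
        object.__setattr__(self, "stain_vectors", v)
        object.__setattr__(self, "max_concentrations", c)


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation switches; all randomness flows from ``seed``.

    ``sprinkle_fraction`` is the target fraction of pixels occluded by
    random square cutouts when ``progress`` is 1; the occluded fraction
    grows linearly with ``progress`` (training-epoch fraction), which is
    how "progressive sprinkling" is realized here.
    """

    hflip: bool = False
    vflip: bool = False
    blur: bool = False
    color_jitter: bool = False
    sprinkle: bool = False
    jitter_magnitude: float = 0.05
    sprinkle_fraction: float = 0.1
    progress: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sprinkle_fraction <= 1.0:
            raise ValueError("sprinkle_fraction must be in [0, 1]")
        if not 0.0 <= self.progress <= 1.0:
            raise ValueError("progress must be in [0, 1]")


@dataclass(frozen=True)
class ZScoredPatch:
    """Float patch with per-channel zero mean / unit sd.

    Channels that were constant in the input cannot be standardized; they
    are mapped to zeros and flagged in ``degenerate_channels``.
    """

    values: np.ndarray
    degenerate_channels: tuple[int, ...] = ()


def _luminance_u8(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3 or img.size == 0:
        raise ValueError("expected a non-empty HxWx3 RGB image")
    return np.rint(img.astype(float) @ _LUMA).clip(0, 255).astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> int:
    """Otsu optimum over the 256-level histogram of an 8-bit image.

    Returns the level ``t`` maximizing the between-class variance of the
    split ``{< t}`` vs ``{>= t}``; ties break toward the smallest ``t``.
    """
    hist = np.bincount(np.asarray(gray, dtype=np.uint8).ravel(), minlength=256)
    if (hist > 0).sum() < 2:
        raise DegenerateHistogramError("histogram has a single occupied level")
    counts = [int(c) for c in hist]
    total_n = sum(counts)
    total_s = sum(t * c for t, c in zip(range(256), counts))
    # between-class variance at split {<t} vs {>=t} is proportional to
    # (S0*N1 - S1*N0)^2 / (N0*N1); compared exactly with integer arithmetic
    best_t, best_num, best_den = None, -1, 1
    n0 = s0 = 0
    for t in range(1, 256):
        n0 += counts[t - 1]
        s0 += (t - 1) * counts[t - 1]
        n1 = total_n - n0
        if n0 == 0 or n1 == 0:
            continue
        num = (s0 * n1 - (total_s - s0) * n0) ** 2
        den = n0 * n1
        if num * best_den > best_num * den:  # strict: ties keep the smaller t
            best_t, best_num, best_den = t, num, den
    return best_t


def compute_tissue_mask(image: np.ndarray, downsample: int = 1) -> TissueMask:
    """Otsu-threshold the luminance of ``image`` into tissue vs background.

    Parameters
    ----------
    image
        HxWx3 RGB raster, intensities in [0, 255].
    downsample
        Operate on every ``downsample``-th pixel (thumbnail masking).
    """
    if downsample < 1:
        raise ValueError("downsample must be a positive integer")
    gray = _luminance_u8(image)[::downsample, ::downsample]
    t = otsu_threshold(gray)
    return TissueMask(mask=gray < t, otsu_threshold=t, downsample=downsample)


def tile_slide(
    image: np.ndarray,
    mask: TissueMask,
    slide_id: str = "slide",
    tile_size: int = 512,
    min_tissue_fraction: float = 0.5,
) -> list[RGBPatch]:
    """Cut the image into non-overlapping tiles, keeping tissue-rich ones.

    Partial tiles at the right/bottom edge are dropped so every patch is
    exactly ``tile_size`` square. A tile is retained iff its tissue
    fraction (from ``mask``) is at least ``min_tissue_fraction``; the
    fraction of every candidate tile is recorded on the mask.
    """
    if tile_size < 32:
        raise ValueError("tile_size must be >= 32")
    img = np.asarray(image)
    h, w = img.shape[:2]
    n_rows, n_cols = h // tile_size, w // tile_size
    if n_rows == 0 or n_cols == 0:
        warnings.warn(f"image {h}x{w} smaller than one {tile_size}px tile; no patches")
        return []
    d = mask.downsample
    patches: list[RGBPatch] = []
    for r in range(n_rows):
        for c in range(n_cols):
            y, x = r * tile_size, c * tile_size
            sub = mask.mask[y // d : (y + tile_size) // d, x // d : (x + tile_size) // d]
            frac = float(sub.mean()) if sub.size else 0.0
            mask.tissue_fraction_per_tile[(r, c)] = frac
            if frac >= min_tissue_fraction:
                patches.append(
                    RGBPatch(
                        slide_id=slide_id,
                        grid_row=r,
                        grid_col=c,
                        origin_xy=(x, y),
                        pixels=img[y : y + tile_size, x : x + tile_size],
                    )
                )
    return patches


# Macenko defaults: OD floor, robust angle percentiles, concentration percentile.
_OD_FLOOR = 0.15
_ANGLE_PERCENTILES = (1.0, 99.0)
_CONC_PERCENTILE = 99.0


def _optical_density(pixels: np.ndarray) -> np.ndarray:
    flat = np.asarray(pixels, dtype=float).reshape(-1, 3)
    return -np.log10(np.maximum(flat, 1.0) / 255.0)


def _estimate_stains(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (stain_vectors 3x2, concentrations 2xN, full OD Nx3)."""
    od = _optical_density(pixels)
    # stained pixels: any channel absorbs above the floor (pure eosin has
    # near-zero red OD, so an all-channel criterion would drop it)
    fg = od[(od > _OD_FLOOR).any(axis=1)]
    if fg.shape[0] < 20 or np.median(fg.sum(axis=1)) <= _OD_FLOOR:
        raise StainEstimationError("too few stained pixels to estimate stain vectors")
    cov = np.cov(fg.T)
    evals, evecs = np.linalg.eigh(cov)
    plane = evecs[:, -2:]  # top-2 eigenvectors span the stain plane
    if np.ptp(evals) < 1e-12:
        raise StainEstimationError("degenerate optical-density covariance")
    # orient the plane so projections are mostly positive
    proj = fg @ plane
    for k in range(2):
        if proj[:, k].sum() < 0:
            plane[:, k] *= -1
            proj[:, k] *= -1
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, _ANGLE_PERCENTILES)
    v1 = plane @ np.array([np.cos(lo), np.sin(lo)])
    v2 = plane @ np.array([np.cos(hi), np.sin(hi)])
    # hematoxylin has the larger red-channel optical density
    he = np.column_stack([v1, v2] if v1[0] > v2[0] else [v2, v1])
    he = np.abs(he)  # stains absorb; OD components are non-negative
    he /= np.linalg.norm(he, axis=0)
    conc, *_ = np.linalg.lstsq(he, od.T, rcond=None)
    return he, np.maximum(conc, 0.0), od


def estimate_stain_reference(patch: RGBPatch | np.ndarray) -> StainReference:
    """Estimate the Macenko stain basis of one tile."""
    pixels = patch.pixels if isinstance(patch, RGBPatch) else patch
    he, conc, _ = _estimate_stains(pixels)
    max_c = np.percentile(conc, _CONC_PERCENTILE, axis=1)
    if (max_c <= 0).any():
        raise StainEstimationError("vanishing stain concentration")
    return StainReference(stain_vectors=he, max_concentrations=max_c)


def macenko_normalize(patch: RGBPatch, ref: StainReference) -> RGBPatch:
    """Re-express the tile in the reference stain basis (Macenko method).

    Raises :class:`StainEstimationError` for near-white tiles; callers may
    skip such tiles.
    """
    he, conc, od = _estimate_stains(patch.pixels)
    max_c = np.percentile(conc, _CONC_PERCENTILE, axis=1)
    max_c = np.where(max_c > 0, max_c, 1.0)
    conc_scaled = conc * (ref.max_concentrations / max_c)[:, None]
    # transfer the in-plane stain component; keep the off-plane residual so
    # self-normalization is an exact fixed point and texture detail survives
    residual = od - (he @ conc).T
    od_norm = (ref.stain_vectors @ conc_scaled).T + residual
    out = (255.0 * 10.0 ** (-od_norm)).clip(0, 255)
    out = np.rint(out).astype(np.uint8).reshape(patch.pixels.shape)
    return replace(patch, pixels=out)


def zscore_patch(patch: RGBPatch | np.ndarray) -> ZScoredPatch:
    """Standardize each RGB channel to zero mean, unit sd.

    Constant channels become all-zeros and are flagged rather than raising,
    so blank control tiles survive batch pipelines.
    """
    pixels = patch.pixels if isinstance(patch, RGBPatch) else patch
    x = np.asarray(pixels, dtype=float)
    mu = x.mean(axis=(0, 1))
    sd = x.std(axis=(0, 1))
    degenerate = tuple(int(c) for c in np.flatnonzero(sd == 0))
    safe_sd = np.where(sd == 0, 1.0, sd)
    out = (x - mu) / safe_sd
    for c in degenerate:
        out[:, :, c] = 0.0
    return ZScoredPatch(values=out, degenerate_channels=degenerate)


def _patch_rng(patch: RGBPatch, seed: int) -> np.random.Generator:
    # per-patch child stream: order-independent augmentation (one stream per tile)
    sid = zlib.crc32(patch.slide_id.encode())
    return np.random.default_rng([seed & 0x7FFFFFFF, sid, patch.grid_row, patch.grid_col])


def augment_patch(patch: RGBPatch, cfg: AugmentConfig) -> RGBPatch:
    """Apply the enabled augmentations; deterministic under a fixed seed.

    Flips mirror the tile; blur is a mild Gaussian; color jitter scales and
    shifts each channel by up to ``jitter_magnitude``; sprinkle occludes
    ``sprinkle_fraction * progress`` of pixels with gray squares.
    """
    rng = _patch_rng(patch, cfg.seed)
    px = patch.pixels.astype(float)
    if cfg.hflip:
        px = px[:, ::-1]
    if cfg.vflip:
        px = px[::-1, :]
    if cfg.blur:
        px = ndimage.gaussian_filter(px, sigma=(1.0, 1.0, 0.0))
    if cfg.color_jitter:
        scale = 1.0 + rng.uniform(-cfg.jitter_magnitude, cfg.jitter_magnitude, size=3)
        shift = rng.uniform(-cfg.jitter_magnitude, cfg.jitter_magnitude, size=3) * 255.0
        px = px * scale + shift
    if cfg.sprinkle and cfg.sprinkle_fraction * cfg.progress > 0:
        size = patch.size
        sq = max(2, size // 16)
        target = cfg.sprinkle_fraction * cfg.progress * size * size
        n_squares = int(round(target / (sq * sq)))
        for _ in range(n_squares):
            r = int(rng.integers(0, size - sq + 1))
            c = int(rng.integers(0, size - sq + 1))
            px[r : r + sq, c : c + sq] = 127.0
    out = np.rint(px).clip(0, 255).astype(np.uint8)
    return replace(patch, pixels=out)
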