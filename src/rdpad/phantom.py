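"""Synthetic speckle phantoms.

Piecewise-constant tissue phantoms (axis-aligned rectangles and disks on
a constant background) corrupted by fully developed multiplicative
speckle: each pixel is multiplied by an independent unit-mean gamma
variate with shape L ("looks"), the standard L-look intensity speckle
model of the Lee/Kuan filter lineage.  The coefficient of variation of
such noise is 1/sqrt(L); L = 1 (exponential noise) is the strongest,
fully-developed case and the default.

Alongside the clean and noisy images the generator derives two pixel
sets used by the contrast metric: the edge set (pixels with at least one
differing 4-neighbor in the clean image) and the homogeneous set (all
4-neighbors equal, borders reflected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Disk", "Rect", "Phantom", "make_clean", "make_masks",
           "add_speckle", "make_phantom"]


@dataclass(frozen=True)
class Disk:
    """Filled disk: center (cy, cx), radius r (pixels), intensity level."""

    cy: float
    cx: float
    r: float
    level: float


@dataclass(frozen=True)
class Rect:
    """Axis-aligned filled rectangle: top-left corner, size, intensity."""

    top: int
    left: int
    height: int
    width: int
    level: float


Shape = Disk | Rect


@dataclass
class Phantom:
    """A clean/noisy phantom pair with its derived masks."""

    clean: np.ndarray
    noisy: np.ndarray
    edge_mask: np.ndarray
    homog_mask: np.ndarray
    seed: int
    looks: float


def make_clean(
    height: int,
    width: int,
    shapes: list[Shape] | tuple[Shape, ...] = (),
    background: float = 100.0,
) -> np.ndarray:
    """Render the noise-free piecewise-constant image.

    Shapes are painted in order (later shapes overwrite earlier ones).
    All intensity levels must be strictly positive: speckle is
    multiplicative, and zero regions would make any ratio-to-mean
    statistic undefined.
    """
    if height < 16 or width < 16:
        raise ValueError("phantom must be at least 16 x 16")
    if background <= 0:
        raise ValueError("background level must be positive")
    img = np.full((height, width), float(background))
    ii, jj = np.mgrid[0:height, 0:width]
    for s in shapes:
        if s.level <= 0:
            raise ValueError("shape intensity levels must be positive")
        if isinstance(s, Disk):
            mask = (ii - s.cy) ** 2 + (jj - s.cx) ** 2 <= s.r**2
        elif isinstance(s, Rect):
            mask = (
                (ii >= s.top)
                & (ii < s.top + s.height)
                & (jj >= s.left)
                & (jj < s.left + s.width)
            )
        else:
            raise TypeError(f"unknown shape {type(s).__name__}")
        img[mask] = float(s.level)
    return img


def make_masks(clean: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Edge and homogeneous boolean masks of a piecewise-constant image.

    A pixel is an edge pixel iff any of its 4-neighbors differs in the
    clean image; homogeneous iff all four are equal (symmetric reflection
    at the borders, so border pixels of a constant region count as
    homogeneous).  The two masks partition the image and are disjoint by
    construction.
    """
    clean = np.asarray(clean, dtype=float)
    P = np.pad(clean, 1, mode="symmetric")
    differs = (
        (P[:-2, 1:-1] != clean)
        | (P[2:, 1:-1] != clean)
        | (P[1:-1, :-2] != clean)
        | (P[1:-1, 2:] != clean)
    )
    return differs, ~differs


def add_speckle(clean: np.ndarray, looks: float = 1.0, seed: int = 0) -> np.ndarray:
    """Multiply by unit-mean gamma speckle with shape ``looks``.

    The noise n ~ Gamma(shape=looks, scale=1/looks) has mean 1 and
    variance 1/looks per pixel, independent across pixels; the output is
    clean * n and stays strictly positive.  Same (clean, looks, seed)
    reproduces the output bit for bit.
    """
    clean = np.asarray(clean, dtype=float)
    if np.any(clean <= 0):
        raise ValueError("clean image must be strictly positive")
    if looks <= 0:
        raise ValueError("looks must be positive")
    rng = np.random.default_rng(seed)
    noise = rng.gamma(shape=looks, scale=1.0 / looks, size=clean.shape)
    out = clean * noise
    # gamma variates can underflow to 0 for very small shape parameters
    return np.maximum(out, np.finfo(float).tiny)


def make_phantom(
    height: int,
    width: int,
    shapes: list[Shape] | tuple[Shape, ...] = (),
    background: float = 100.0,
    looks: float = 1.0,
    seed: int = 0,
) -> Phantom:
    """Build a complete clean/noisy phantom with derived masks."""
    clean = make_clean(height, width, shapes, background)
    edge, homog = make_masks(clean)
    noisy = add_speckle(clean, looks=looks, seed=seed)
    return Phantom(
        clean=clean,
        noisy=noisy,
        edge_mask=edge,
        homog_mask=homog,
        seed=int(seed),
        looks=float(looks),
    )
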