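"""Instantaneous coefficient of variation (ICOV) estimators.

The ICOV q(i,j;t) generalizes the ratio std/mean to diffusion filtering:
in fully developed speckle it hovers around the speckle scale q0(t), while
at edges it spikes, so downstream diffusivity rules can tell noise from
structure.  Three estimators are provided:

* ``icov_srad``  -- the differential form built from one-sided gradients
  and the 4-neighbor Laplacian (the SRAD lineage).
* ``icov_dpad``  -- the windowed form: unbiased variance over mean squared
  on a 5x5 square neighborhood (the DPAD / Kuan-filter lineage).
* ``icov_rdpad`` -- the pairwise-difference form on the 13-pixel diamond
  (city-block radius 2) inside the 5x5 square.

All estimators return the *squared* coefficient q^2 as a field; all are
zero on constant images and invariant under global intensity scaling.
Borders are handled by symmetric reflection throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ICOVField",
    "NoiseScale",
    "diamond_window",
    "DIAMOND_OFFSETS",
    "icov",
    "icov_srad",
    "icov_dpad",
    "icov_rdpad",
    "q0_schedule",
]

#: Relative floor applied to intensities before any ratio statistic.
EPS_FRACTION = 1e-6

#: (di, dj) offsets of the 13-pixel diamond window, in the canonical order:
#: center, then the city-block distance-1 ring (N, W, E, S), then the
#: distance-2 ring in row-major order.
DIAMOND_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 0),
    (-1, 0), (0, -1), (0, 1), (1, 0),
    (-2, 0), (-1, -1), (-1, 1), (0, -2), (0, 2), (1, -1), (1, 1), (2, 0),
)


@dataclass
class ICOVField:
    """Squared instantaneous coefficient of variation, per pixel."""

    q2: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        self.q2 = np.asarray(self.q2, dtype=float)
        if self.scheme not in {"srad", "dpad", "rdpad"}:
            raise ValueError(f"unknown ICOV scheme {self.scheme!r}")

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.q2, dtype=dtype)


def _as_positive(img: np.ndarray) -> np.ndarray:
    """Validate and floor an intensity grid for ratio statistics.

    Images must be 2-D and nonnegative; they are floored at
    ``EPS_FRACTION * max`` so that divisions by local intensity or local
    mean are well defined everywhere.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if img.size == 0:
        raise ValueError("empty image")
    if np.any(img < 0) or not np.all(np.isfinite(img)):
        raise ValueError("image intensities must be finite and nonnegative")
    peak = float(img.max())
    floor = EPS_FRACTION * (peak if peak > 0 else 1.0)
    return np.maximum(img, floor)


def icov_srad(img: np.ndarray) -> ICOVField:
    """Differential ICOV of the SRAD lineage.

    q^2 = [ (1/2)(|grad I|/I)^2 - (1/16)(lap I / I)^2 ]
          / [ 1 + (1/4)(lap I / I) ]^2

    with |grad I|^2 approximated by the sum of the four one-sided
    (N, S, E, W) squared differences -- i.e. the average of forward and
    backward gradient magnitudes -- and the standard 4-neighbor Laplacian.
    Numerically negative q^2 is clipped to zero.
    """
    I = _as_positive(img)
    P = np.pad(I, 1, mode="symmetric")
    dN = P[:-2, 1:-1] - I
    dS = P[2:, 1:-1] - I
    dW = P[1:-1, :-2] - I
    dE = P[1:-1, 2:] - I
    G2 = (dN**2 + dS**2 + dW**2 + dE**2) / I**2
    L = (dN + dS + dW + dE) / I
    num = 0.5 * G2 - (1.0 / 16.0) * L**2
    den = (1.0 + 0.25 * L) ** 2
    q2 = np.clip(num / den, 0.0, None)
    return ICOVField(q2=q2, scheme="srad")


def icov_dpad(img: np.ndarray, size: int = 5) -> ICOVField:
    """Windowed ICOV of the DPAD lineage.

    q^2 = s^2 / mean^2 with the unbiased sample variance s^2 over a
    ``size`` x ``size`` square window (default 5x5, N=25 samples, Bessel
    factor N/(N-1)).
    """
    if size < 3 or size % 2 == 0:
        raise ValueError("window size must be an odd integer >= 3")
    I = _as_positive(img)
    n = size * size
    mean = ndimage.uniform_filter(I, size=size, mode="reflect")
    mean_sq = ndimage.uniform_filter(I * I, size=size, mode="reflect")
    var = (n / (n - 1.0)) * np.clip(mean_sq - mean**2, 0.0, None)
    q2 = var / mean**2
    return ICOVField(q2=q2, scheme="dpad")


def icov_rdpad(img: np.ndarray) -> ICOVField:
    """Pairwise-difference ICOV on the 13-pixel diamond window.

    With v_0..v_12 the diamond intensities around a pixel,

        q^2 = (1/12) * sum_{m<n} (v_n - v_m)^2  /  sum_m v_m^2 .

    The pair sum is evaluated through the identity
    sum_{m<n} (v_n - v_m)^2 = 13 * sum v^2 - (sum v)^2, which is exact and
    lets the field be computed by two footprint convolutions.  Note the
    denominator is the raw sum of squares, not a variance normalizer, so
    unlike the other two schemes q^2 here is bounded (by 13/12).
    """
    I = _as_positive(img)
    foot = _diamond_footprint()
    S1 = ndimage.correlate(I, foot, mode="reflect")
    S2 = ndimage.correlate(I * I, foot, mode="reflect")
    num = (13.0 * S2 - S1**2) / 12.0
    q2 = np.clip(num, 0.0, None) / S2
    return ICOVField(q2=q2, scheme="rdpad")


def _diamond_footprint() -> np.ndarray:
    foot = np.zeros((5, 5))
    for di, dj in DIAMOND_OFFSETS:
        foot[di + 2, dj + 2] = 1.0
    return foot


def diamond_window(img: np.ndarray, i: int, j: int) -> np.ndarray:
    """Extract the ordered 13-vector v_0..v_12 of the diamond at (i, j).

    Ordering: center first, then the city-block distance-1 ring in
    (N, W, E, S) order, then the distance-2 ring in row-major order.
    Borders are reflected symmetrically.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if not (0 <= i < img.shape[0] and 0 <= j < img.shape[1]):
        raise IndexError(f"pixel ({i}, {j}) outside image {img.shape}")
    P = np.pad(img, 2, mode="symmetric")
    return np.array([P[i + 2 + di, j + 2 + dj] for di, dj in DIAMOND_OFFSETS])


_SCHEMES = {"srad": icov_srad, "dpad": icov_dpad, "rdpad": icov_rdpad}


def icov(img: np.ndarray, scheme: str) -> ICOVField:
    """Dispatch to one of the three ICOV estimators by name."""
    try:
        fn = _SCHEMES[scheme]
    except KeyError:
        raise ValueError(
            f"unknown ICOV scheme {scheme!r}; expected one of {sorted(_SCHEMES)}"
        ) from None
    return fn(img)


def q0_schedule(
    mode: str,
    q0_initial: float = 1.0,
    rho: float = 1.0 / 6.0,
    t: float = 0.0,
    q2_field: ICOVField | np.ndarray | None = None,
) -> float:
    """Speckle scale q0(t).

    ``decay`` mode returns q0_initial * exp(-rho * t), the exponential
    schedule of the SRAD lineage; the diffusion engine evaluates it at
    diffusion time t = n * dt, the units in which rho is conventionally
    stated.  ``median`` mode estimates q0 from the data as
    sqrt(median(q^2)) of the supplied ICOV field, the data-driven
    alternative of the DPAD lineage; the estimate is floored at a tiny
    positive value so q0(t) > 0 always holds.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if mode == "decay":
        if q0_initial <= 0:
            raise ValueError("q0_initial must be positive")
        return float(q0_initial * np.exp(-rho * t))
    if mode == "median":
        if q2_field is None:
            raise ValueError("median mode requires a q2 field")
        q2 = np.asarray(q2_field, dtype=float)
        return max(float(np.sqrt(np.median(q2))), 1e-8)
    raise ValueError(f"unknown q0 mode {mode!r}; expected 'decay' or 'median'")


@dataclass
class NoiseScale:
    """The speckle scale q0 and its per-iteration update rule."""

    q0_initial: float = 1.0
    rho: float = 1.0 / 6.0
    mode: str = "decay"

    def __post_init__(self) -> None:
        if self.mode not in {"decay", "median"}:
            raise ValueError(f"unknown q0 mode {self.mode!r}")
        if self.q0_initial <= 0:
            raise ValueError("q0_initial must be positive")

    def value_at(self, t: float, q2_field=None) -> float:
        return q0_schedule(self.mode, self.q0_initial, self.rho, t, q2_field)
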