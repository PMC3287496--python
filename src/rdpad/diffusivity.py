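"""Diffusion coefficient rules c(q) for speckle-reducing diffusion.

Each rule maps the squared ICOV field q^2 and the squared speckle scale
q0^2 to a per-pixel diffusion coefficient.  Where q ~ q0 the pixel looks
like pure speckle and diffusion runs; where q >> q0 the pixel looks like
an edge and diffusion is damped (SRAD, DPAD) or stopped outright at a
hard cutoff (Tauber, RDPAD -- the Tukey-biweight "edge-stopping"
behavior).

All coefficients are clamped to [0, 1].  The raw robust forms reach 2 at
their minimum argument and the raw SRAD form exceeds 1 for q < q0; the
clamp keeps the explicit time stepping stable and preserves the
convention that diffusivity never exceeds the isotropic value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiffusivityField",
    "tukey_kernel",
    "robust_ratio",
    "rdpad_cutoff",
    "c_srad",
    "c_dpad",
    "c_tauber",
    "c_rdpad",
    "diffusivity",
]

logger = logging.getLogger(__name__)

_Q2_EPS = 1e-12  # floor on q^2 before 1/q^2 in the DPAD rule


@dataclass
class DiffusivityField:
    """Per-pixel diffusion coefficients in [0, 1]."""

    c: np.ndarray
    rule: str

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        if self.rule not in {"srad", "dpad", "tauber", "rdpad"}:
            raise ValueError(f"unknown diffusivity rule {self.rule!r}")

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.c, dtype=dtype)


def _check_q02(q02):
    """q0^2 may be a positive scalar or an array matching q^2 elementwise."""
    q02 = np.asarray(q02, dtype=float)
    if np.any(q02 <= 0):
        raise ValueError("q0^2 must be positive")
    return q02 if q02.ndim else float(q02)


def tukey_kernel(x, sigma_e: float):
    """Tukey biweight influence kernel.

    Returns (1/2)[1 - (x/sigma_e)^2]^2 for |x| <= sigma_e and exactly 0
    beyond: arguments past the scale sigma_e are outliers and contribute
    nothing.  This is the shared primitive behind the Tauber and RDPAD
    rules.
    """
    if sigma_e <= 0:
        raise ValueError("sigma_e must be positive")
    x = np.asarray(x, dtype=float)
    u = x / sigma_e
    out = np.where(np.abs(u) <= 1.0, 0.5 * (1.0 - u**2) ** 2, 0.0)
    return out if out.ndim else float(out)


def robust_ratio(q2, q02: float):
    """Normalized excess R = (q^2 - q0^2) / (q0^2 (1 + q^2)).

    R = 0 exactly at q^2 = q0^2; the minimum R = -1 is reached at q^2 = 0.
    The RDPAD rule is the Tukey kernel applied to R.
    """
    q02 = _check_q02(q02)
    q2 = np.asarray(q2, dtype=float)
    out = (q2 - q02) / (q02 * (1.0 + q2))
    return out if out.ndim else float(out)


def rdpad_cutoff(q02: float) -> float:
    """The q^2 level 2 q0^2 / (1 - q0^2) above which c_rdpad is zero.

    Algebraically equivalent to the R <= 1 test when q0^2 < 1; for
    q0^2 >= 1 the closed form is meaningless (R never reaches 1) and
    +inf is returned.
    """
    q02 = float(_check_q02(q02))
    if q02 >= 1.0:
        return float("inf")
    return 2.0 * q02 / (1.0 - q02)


def _finish(raw: np.ndarray, rule: str) -> DiffusivityField:
    c = np.clip(raw, 0.0, 1.0)
    return DiffusivityField(c=c, rule=rule)


def c_srad(q2, q02: float) -> DiffusivityField:
    """SRAD rule: c = 1 / (1 + (q^2 - q0^2) / (q0^2 (1 + q0^2)))."""
    q02 = _check_q02(q02)
    q2 = np.asarray(q2, dtype=float)
    raw = 1.0 / (1.0 + (q2 - q02) / (q02 * (1.0 + q02)))
    return _finish(raw, "srad")


def c_dpad(q2, q02: float, clamp: bool = True) -> DiffusivityField:
    """DPAD rule: c = (1 + 1/q^2) / (1 + 1/q0^2).

    Strictly positive for every finite q^2, so diffusion never fully
    stops -- the behavior the robust rules are designed to fix.  With
    ``clamp=False`` the raw value is returned (it exceeds 1 for
    q < q0); the raw form satisfies the algebraic identity
    c * (1 + R) = 1 with the robust ratio R.
    """
    q02 = _check_q02(q02)
    q2 = np.maximum(np.asarray(q2, dtype=float), _Q2_EPS)
    raw = (1.0 + 1.0 / q2) / (1.0 + 1.0 / q02)
    if not clamp:
        return DiffusivityField(c=raw, rule="dpad")
    return _finish(raw, "dpad")


def c_tauber(q2, q02: float) -> DiffusivityField:
    """Tauber rule: Tukey kernel on the SRAD normalized excess.

    With S = (q^2 - q0^2) / (q0^2 (1 + q0^2)):
    c = (1/2)(1 - S)^2 if S <= 1, else 0.
    """
    q02 = _check_q02(q02)
    q2 = np.asarray(q2, dtype=float)
    S = (q2 - q02) / (q02 * (1.0 + q02))
    raw = np.where(S <= 1.0, 0.5 * (1.0 - S) ** 2, 0.0)
    return _finish(raw, "tauber")


def c_rdpad(q2, q02: float) -> DiffusivityField:
    """RDPAD rule: Tukey kernel on the robust ratio R.

    c = (1/2)(1 - R)^2 if R <= 1, else 0.  For q0^2 < 1 the condition
    R <= 1 is equivalent to q^2 <= 2 q0^2 / (1 - q0^2): above that level
    the coefficient is exactly zero and diffusion stops, whereas the DPAD
    rule would still diffuse.
    """
    q02 = _check_q02(q02)
    if np.any(np.asarray(q02) >= 1.0):
        logger.warning(
            "q0^2 = %.4g >= 1: the algebraic cutoff 2q0^2/(1-q0^2) is "
            "undefined; using the R <= 1 test directly", q02,
        )
    R = robust_ratio(q2, q02)
    R = np.asarray(R, dtype=float)
    raw = np.where(R <= 1.0, 0.5 * (1.0 - R) ** 2, 0.0)
    return _finish(raw, "rdpad")


_RULES = {"srad": c_srad, "dpad": c_dpad, "tauber": c_tauber, "rdpad": c_rdpad}


def diffusivity(rule: str, q2, q02: float) -> DiffusivityField:
    """Dispatch to one of the four diffusivity rules by name."""
    try:
        fn = _RULES[rule]
    except KeyError:
        raise ValueError(
            f"unknown diffusivity rule {rule!r}; expected one of {sorted(_RULES)}"
        ) from None
    return fn(q2, q02)
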