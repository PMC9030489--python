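"""Signal conditioning: zero-phase low-pass filtering, mean removal, and
derivation of the five directional series the sway measures operate on.

Directions follow the body-axis convention AP (anterior-posterior), ML
(medial-lateral), IS (inferior-superior), plus the planar resultant
2DR = sqrt(AP^2 + ML^2) in the transverse plane and the full resultant
3DR = sqrt(AP^2 + ML^2 + IS^2), computed samplewise from the detrended
axes. Gravity is handled purely by per-axis mean removal: trials are
static postures, so the gravity projection is a constant offset.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps


class FilterError(ValueError):
    """Invalid filter parameters or too-short input."""


@dataclass
class DirectionalSignals:
    """AP/ML/IS axis series plus 2-D and 3-D resultant magnitudes."""

    ap: np.ndarray
    ml: np.ndarray
    is_: np.ndarray
    r2d: np.ndarray
    r3d: np.ndarray
    rate: float

    @property
    def n(self) -> int:
        return self.ap.size

    @property
    def duration(self) -> float:
        return self.n / self.rate


def butterworth_zero_phase(
    x: np.ndarray,
    rate: float,
    cutoff: float,
    order: int = 4,
    design_order: int | None = None,
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (forward-backward).

    ``order`` is the *effective* order after the two passes, so an
    order/2 design is applied forward and backward (the conventional
    reading of a "fourth-order zero-phase" filter). Pass
    ``design_order=4`` to instead apply a literal 4th-order design in
    each direction. Edge transients are suppressed with reflective
    padding of length 3 x order; output length equals input length.
    """
    x = np.asarray(x, dtype=float)
    if design_order is None:
        if order % 2:
            raise FilterError("effective order must be even")
        design_order = order // 2
    if cutoff <= 0 or cutoff >= rate / 2:
        raise FilterError(f"cutoff {cutoff} Hz outside (0, Nyquist={rate / 2})")
    padlen = 3 * order
    if x.shape[0] <= padlen:
        raise FilterError(f"series length {x.shape[0]} <= padding {padlen}")
    b, a = _lowpass_design(design_order, float(cutoff), float(rate))
    return sps.filtfilt(b, a, x, axis=0, padtype="even", padlen=padlen)


@lru_cache(maxsize=64)
def _lowpass_design(order: int, cutoff: float, rate: float):
    return sps.butter(order, cutoff, btype="low", fs=rate)


def detrend(x: np.ndarray) -> np.ndarray:
    """Remove the series mean (gravity/DC offset)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise FilterError("cannot detrend an empty series")
    return x - x.mean(axis=0)


def derive_directions(
    acc: np.ndarray, rate: float, detrend_axes: bool = True
) -> DirectionalSignals:
    """Split a (n, 3) AP/ML/IS acceleration block into directional series.

    Resultants are computed samplewise from the (optionally detrended)
    axes, so r2d <= r3d everywhere and both are nonnegative.
    """
    acc = np.asarray(acc, dtype=float)
    if acc.ndim != 2 or acc.shape[1] != 3:
        raise ValueError(f"expected shape (n, 3), got {acc.shape}")
    if detrend_axes:
        acc = detrend(acc)
    ap, ml, is_ = acc[:, 0], acc[:, 1], acc[:, 2]
    r2d = np.hypot(ap, ml)
    r3d = np.sqrt(ap**2 + ml**2 + is_**2)
    return DirectionalSignals(ap=ap, ml=ml, is_=is_, r2d=r2d, r3d=r3d, rate=rate)


def preprocess_acc(
    acc: np.ndarray,
    rate: float,
    cutoff: float = 10.0,
    order: int = 4,
    detrend_axes: bool = True,
) -> DirectionalSignals:
    """Filter a raw (n, 3) acceleration block and derive directions."""
    filtered = butterworth_zero_phase(acc, rate, cutoff, order=order)
    return derive_directions(filtered, rate, detrend_axes=detrend_axes)


def preprocess_cop(
    cop: np.ndarray, rate: float, cutoff: float = 10.0, order: int = 4
) -> np.ndarray:
    """Filter a raw (n, 2) AP/ML COP trajectory."""
    cop = np.asarray(cop, dtype=float)
    if cop.ndim != 2 or cop.shape[1] != 2:
        raise ValueError(f"expected shape (n, 2), got {cop.shape}")
    return butterworth_zero_phase(cop, rate, cutoff, order=order)
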