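"""Orthonormal multilevel Haar DWT and its inverse.

The payload lives in the level-k approximation band.  The orthonormal
normalization (filter taps 1/sqrt(2)) is essential: it makes the transform an
isometry (Parseval), so the embedding distortion measured on coefficients
equals the distortion of the reconstructed signal and the coefficient-domain
SNR objective is exactly the time-domain SNR.

Signal lengths are required to be exact multiples of 2**k, so the
'periodization' filter bank never actually extends the signal and the Haar
transform is block-local: approximation coefficient i depends only on samples
[i*2**k, (i+1)*2**k).  Whole-signal transformation with contiguous grouping of
the approximation band is therefore identical to transforming contiguous
frames one at a time.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pywt

from .signal_core import ECGSignal

_SQRT2 = math.sqrt(2.0)


@dataclasses.dataclass(frozen=True)
class WaveletSpec:
    """The orthonormal Haar filter pair."""

    low_pass: tuple = (1.0 / _SQRT2, 1.0 / _SQRT2)
    high_pass: tuple = (1.0 / _SQRT2, -1.0 / _SQRT2)
    name: str = "haar-orthonormal"


HAAR = WaveletSpec()


@dataclasses.dataclass
class CoeffPyramid:
    """k-level decomposition: one approximation band plus k detail bands.

    ``details[j-1]`` is the level-j detail band, of length L / 2**j.
    """

    approx: np.ndarray
    details: list
    level: int
    original_length: int
    sample_rate_hz: float = 0.0
    record_id: str = ""

    def validate(self) -> None:
        L, k = self.original_length, self.level
        if len(self.details) != k:
            raise ValueError(f"expected {k} detail bands, got {len(self.details)}")
        if len(self.approx) != L // 2 ** k:
            raise ValueError(
                f"approximation band length {len(self.approx)} != {L // 2 ** k}"
            )
        for j, band in enumerate(self.details, start=1):
            if len(band) != L // 2 ** j:
                raise ValueError(
                    f"level-{j} detail band length {len(band)} != {L // 2 ** j}"
                )

    def energy(self) -> float:
        total = float(np.sum(self.approx ** 2))
        for band in self.details:
            total += float(np.sum(band ** 2))
        return total

    def copy(self) -> "CoeffPyramid":
        return CoeffPyramid(
            self.approx.copy(),
            [b.copy() for b in self.details],
            self.level,
            self.original_length,
            self.sample_rate_hz,
            self.record_id,
        )


def dwt(signal, level: int) -> CoeffPyramid:
    """k-level orthonormal Haar analysis of a signal (or bare array)."""
    if isinstance(signal, ECGSignal):
        x = signal.samples
        rate, rid = signal.sample_rate_hz, signal.record_id
    else:
        x = np.asarray(signal, dtype=float)
        rate, rid = 0.0, ""
    if level < 1:
        raise ValueError("level must be >= 1")
    L = x.size
    if L % 2 ** level != 0:
        raise ValueError(f"length {L} is not divisible by 2**{level}")
    coeffs = pywt.wavedec(x, "haar", mode="periodization", level=level)
    # wavedec returns [cA_k, cD_k, ..., cD_1]; store details as level 1..k.
    details = list(reversed(coeffs[1:]))
    return CoeffPyramid(coeffs[0], details, level, L, rate, rid)


def idwt(pyramid: CoeffPyramid) -> ECGSignal:
    """Perfect-reconstruction synthesis (inverse of :func:`dwt`)."""
    pyramid.validate()
    coeffs = [np.asarray(pyramid.approx, float)] + [
        np.asarray(b, float) for b in reversed(pyramid.details)
    ]
    x = pywt.waverec(coeffs, "haar", mode="periodization")
    rate = pyramid.sample_rate_hz if pyramid.sample_rate_hz > 0 else 1.0
    return ECGSignal(x[: pyramid.original_length], rate, pyramid.record_id)
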