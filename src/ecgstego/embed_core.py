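"""The embedding method: frame statistics, thresholds, the SNR-optimal
frame modification, and reassembly of the embedded signal.

One payload bit is carried by a frame of ``n`` consecutive level-k
approximation coefficients.  With ``m`` the mean of the frame's coefficient
magnitudes and ``eps`` the embedding strength, the two decision thresholds
are ``h1 = m + eps`` and ``h0 = m - eps``; a bit of 1 pushes the modified
mean magnitude to at least ``h1`` and a bit of 0 to at most ``h0 - delta``
(the small margin ``delta`` closes the strict inequality so the optimum is
attained).  Among all modifications satisfying the rule, the one maximizing
the frame SNR

    -10 * log10( sum(|c_hat| - |c|)^2 / sum |c|^2 )

is the least-squares projection of the original magnitudes onto the feasible
set: a uniform shift of +eps for bit 1, and a uniform shift of -(eps+delta)
with KKT water-filling (clamping at zero) for bit 0.  Coefficient signs are
preserved and reapplied; only the approximation band is touched, so by
orthonormality the whole-signal SNR degrades by exactly the per-frame costs.
"""

from __future__ import annotations

import dataclasses
import math
from typing import NamedTuple

import numpy as np
import pandas as pd

from .haar_wavelet import dwt, idwt
from .payload_codec import BitPayload
from .signal_core import ECGSignal, plan_layout
from .sa_solver import SAParams, anneal_frames, project_mean_floor, project_sum_cap


@dataclasses.dataclass
class EmbedParams:
    """Embedding strength, layout and solver choice.

    ``strength`` (eps) is on the coefficient amplitude scale.  ``margin``
    (delta) defaults to 1e-6 * strength.  The default solver is the
    stochastic ``"sa"`` path; ``"oracle"`` is the closed-form optimum used
    as the verification reference and fast path.
    """

    strength: float = 4000.0
    block_size: int = 4
    level: int = 5
    margin: float | None = None
    solver: str = "sa"
    sa: SAParams = dataclasses.field(default_factory=SAParams)
    store_sidecar: bool = False

    def __post_init__(self):
        if self.strength <= 0:
            raise ValueError("embedding strength must be positive")
        if self.margin is not None and self.margin < 0:
            raise ValueError("margin must be non-negative")
        if self.solver not in ("oracle", "sa"):
            raise ValueError(f"unknown solver {self.solver!r}")

    @property
    def delta(self) -> float:
        return self.margin if self.margin is not None else 1e-6 * self.strength


def frame_mean(magnitudes) -> float:
    """m = (1/n) * sum |c_i| over the frame."""
    mags = np.asarray(magnitudes, dtype=float)
    if mags.size == 0:
        raise ValueError("empty frame")
    if np.any(mags < 0):
        raise ValueError("magnitudes must be non-negative")
    return float(mags.mean())


def thresholds(m: float, strength: float):
    """(h1, h0) = (m + eps, m - eps)."""
    if strength <= 0:
        raise ValueError("embedding strength must be positive")
    return m + strength, m - strength


class FrameModification(NamedTuple):
    magnitudes: np.ndarray
    infeasible: bool


def optimal_frame_modification(
    magnitudes, bit: int, strength: float, delta: float = 0.0
) -> FrameModification:
    """Exact minimizer of the squared modification under the embedding rule.

    Bit 1: add ``strength`` uniformly (the projection onto the mean floor).
    Bit 0: subtract ``strength + delta`` uniformly with water-filling —
    magnitudes that would go negative are clamped at zero and the residual
    reduction spreads over the rest.  A frame whose total magnitude cannot
    reach the bit-0 target is embedded at the all-zero point and flagged
    infeasible-for-margin.
    """
    mags = np.asarray(magnitudes, dtype=float)
    if mags.size == 0:
        raise ValueError("empty frame")
    if np.any(mags < 0):
        raise ValueError("magnitudes must be non-negative")
    if strength < 0 or delta < 0:
        raise ValueError("strength and delta must be non-negative")
    m = mags.mean()
    if bit == 1:
        if strength == 0:
            return FrameModification(mags.copy(), False)
        out = project_mean_floor(mags + strength, np.array([m + strength]))[0]
        return FrameModification(out, False)
    if bit == 0:
        target_sum = (m - strength - delta) * mags.size
        if target_sum < 0:
            return FrameModification(np.zeros_like(mags), True)
        out = project_sum_cap(mags, np.array([target_sum]))[0]
        return FrameModification(out, False)
    raise ValueError(f"bit must be 0 or 1, got {bit!r}")


def frame_snr(original, modified) -> float:
    """-10*log10 of the squared modification over the frame energy, in dB."""
    orig = np.asarray(original, dtype=float)
    mod = np.asarray(modified, dtype=float)
    if orig.shape != mod.shape:
        raise ValueError("frames must have equal lengths")
    cost = float(((mod - orig) ** 2).sum())
    if cost == 0.0:
        return math.inf
    energy = float((orig ** 2).sum())
    if energy == 0.0:
        raise ValueError("frame SNR undefined: zero-energy frame was modified")
    return -10.0 * math.log10(cost / energy)


@dataclasses.dataclass
class EmbedResult:
    """The embedded signal plus per-frame and whole-signal diagnostics."""

    signal: ECGSignal
    bits: np.ndarray
    frames: pd.DataFrame  # frame, bit, m, h1, h0, statistic, snr_db, infeasible
    snr_db: float
    rmse: float
    similarity: float
    params: EmbedParams
    layout: object
    pyramid: object = None  # the embedded CoeffPyramid (details untouched)

    @property
    def n_infeasible(self) -> int:
        return int(self.frames["infeasible"].sum())

    def write_sidecar(self, path) -> None:
        self.frames[["frame", "m", "statistic", "bit"]].to_csv(path, index=False)


def _payload_bits(payload) -> np.ndarray:
    if isinstance(payload, BitPayload):
        return payload.bits.copy()
    arr = np.asarray(payload).astype(np.uint8)
    if arr.ndim != 1 or not np.all((arr == 0) | (arr == 1)):
        raise ValueError("payload must be a BitPayload or a 1-D 0/1 sequence")
    return arr


def embed(signal: ECGSignal, payload, params: EmbedParams) -> EmbedResult:
    """Embed the payload bits into the level-k approximation band.

    Pipeline: k-level DWT; for each bit-carrying frame replace the
    coefficient magnitudes by the solver output (closed-form oracle, or SA
    started from the perturbed oracle point); reapply signs; frames beyond
    the payload stay untouched; IDWT.  The detail bands of the output are
    bit-identical to the input's.
    """
    from .evaluation import rmse as _rmse, similarity as _similarity, snr as _snr

    bits = _payload_bits(payload)
    layout = plan_layout(signal.length, params.level, params.block_size)
    if bits.size > layout.capacity_bits:
        raise ValueError(
            f"payload of {bits.size} bits exceeds capacity I={layout.capacity_bits} "
            f"(L={signal.length}, k={params.level}, n={params.block_size})"
        )
    pyramid = dwt(signal, params.level)
    approx = pyramid.approx
    n = params.block_size
    B = bits.size
    used = approx[: B * n]
    signs = np.where(used < 0, -1.0, 1.0)
    mags = np.abs(used).reshape(B, n)
    m = mags.mean(axis=1)
    eps, delta = params.strength, params.delta

    oracle = np.empty_like(mags)
    infeasible = np.zeros(B, dtype=bool)
    for f in range(B):
        oracle[f], infeasible[f] = optimal_frame_modification(
            mags[f], int(bits[f]), eps, delta
        )
    if params.solver == "oracle" or B == 0:
        new_mags = oracle
    else:
        new_mags = anneal_frames(mags, bits, eps, delta, params.sa, initial=oracle)

    stats = new_mags.mean(axis=1) if B else np.empty(0)
    _check_feasible(new_mags, m, bits, infeasible, eps, delta)

    snrs = np.array(
        [frame_snr(mags[f], new_mags[f]) if mags[f].any() else math.inf for f in range(B)]
    )
    new_pyramid = pyramid.copy()
    new_pyramid.approx[: B * n] = (signs.reshape(B, n) * new_mags).ravel()
    embedded = idwt(new_pyramid)
    embedded = dataclasses.replace(embedded, record_id=signal.record_id)

    frames = pd.DataFrame(
        {
            "frame": np.arange(B),
            "bit": bits.astype(int),
            "m": m,
            "h1": m + eps,
            "h0": m - eps,
            "statistic": stats,
            "snr_db": snrs,
            "infeasible": infeasible,
        }
    )
    return EmbedResult(
        signal=embedded,
        bits=bits,
        frames=frames,
        snr_db=_snr(signal, embedded),
        rmse=_rmse(signal, embedded),
        similarity=_similarity(signal, embedded),
        params=params,
        layout=layout,
        pyramid=new_pyramid,
    )


def _check_feasible(new_mags, m, bits, infeasible, eps, delta):
    """Every embedded frame must satisfy its rule under exact comparison.

    The comparison mirrors the arithmetic the projections enforce: the
    bit-1 rule on the frame mean, the bit-0 rule on the frame sum (its cap
    is ``(m - eps - delta) * n``, the form water-filling works with).
    """
    n = new_mags.shape[1] if new_mags.ndim == 2 else 0
    for f in range(len(m)):
        if bits[f] == 1:
            if not new_mags[f].mean() >= m[f] + eps:
                raise AssertionError(
                    f"frame {f}: bit-1 mean {new_mags[f].mean()!r} below "
                    f"h1={m[f] + eps!r}"
                )
        elif infeasible[f]:
            if new_mags[f].any():
                raise AssertionError(
                    f"frame {f}: infeasible-for-margin frame not at the zero point"
                )
        elif not new_mags[f].sum() <= (m[f] - eps - delta) * n:
            raise AssertionError(
                f"frame {f}: bit-0 sum {new_mags[f].sum()!r} above "
                f"n*(h0-delta)={(m[f] - eps - delta) * n!r}"
            )
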