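"""Blind extraction of the payload bits from a received signal.

The embedding rule compares each frame's mean coefficient magnitude with
thresholds built from the ORIGINAL frame mean, which a blind receiver does
not have.  Blind mode therefore derives a single global threshold tau from
the received signal itself: embedding pushes the statistics of bit-1 and
bit-0 frames symmetrically to m + eps and m - eps, and whitening keeps the
two populations balanced, so the mean of all frame statistics sits between
them.  Sidecar mode preserves the literal per-frame rule (threshold m =
(h1 + h0) / 2 read from a sidecar written at embed time) for verification.
Extraction is read-only and never modifies the input signal.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .haar_wavelet import dwt
from .payload_codec import BitPayload, DEFAULT_WHITENING_SEED, HEADER_BITS
from .signal_core import ECGSignal, plan_layout


@dataclasses.dataclass
class ExtractParams:
    """Layout (must match the embedding), mode, and payload framing."""

    block_size: int = 4
    level: int = 5
    mode: str = "blind"  # "blind" or "sidecar"
    header_aware: bool = True
    whitening_seed: int | None = DEFAULT_WHITENING_SEED
    sidecar_means: np.ndarray | None = None

    def __post_init__(self):
        if self.mode not in ("blind", "sidecar"):
            raise ValueError(f"unknown extraction mode {self.mode!r}")


def frame_statistic(magnitudes) -> float:
    """(1/n) * sum |c*_i| over the received frame; sign-invariant."""
    mags = np.abs(np.asarray(magnitudes, dtype=float))
    if mags.size == 0:
        raise ValueError("empty frame")
    return float(mags.mean())


def frame_statistics(signal: ECGSignal, params: ExtractParams) -> np.ndarray:
    """All frame statistics of the received signal, in frame order."""
    layout = plan_layout(signal.length, params.level, params.block_size)
    pyramid = dwt(signal, params.level)
    mags = np.abs(pyramid.approx).reshape(layout.frame_count, params.block_size)
    return mags.mean(axis=1)


def extract_bits(signal: ECGSignal, params: ExtractParams):
    """Decode one bit per frame; returns (bits, statistics, thresholds).

    Blind: threshold tau = mean of all frame statistics, bit 1 iff
    statistic >= tau (ties decode as 1).  Sidecar: per-frame threshold m.
    """
    stats = frame_statistics(signal, params)
    if params.mode == "blind":
        if np.ptp(stats) == 0.0:
            raise ValueError(
                "all frame statistics are identical: no embedding signal to "
                "derive a blind threshold from"
            )
        tau = np.full(stats.size, stats.mean())
    else:
        if params.sidecar_means is None:
            raise ValueError("sidecar mode requires sidecar_means")
        tau = np.asarray(params.sidecar_means, dtype=float)
        if tau.size == 0:
            raise ValueError("sidecar provides no frame means")
        if tau.size > stats.size:
            raise ValueError(
                f"sidecar provides {tau.size} frame means for {stats.size} frames"
            )
        # the sidecar covers the bit-carrying frames only; decode just those
        stats = stats[: tau.size]
    bits = (stats >= tau).astype(np.uint8)
    return bits, stats, tau


def extract(signal: ECGSignal, params: ExtractParams) -> BitPayload:
    """Recover the payload from a (possibly attacked) signal.

    With ``header_aware`` the 16-bit length header is decoded first and only
    the header-declared body bits are kept; bits beyond the declared payload
    belong to frames that were never modified and are discarded.
    """
    bits, _, _ = extract_bits(signal, params)
    if not params.header_aware:
        return BitPayload(bits, params.whitening_seed)
    probe = BitPayload(bits, params.whitening_seed)
    n_body = probe.body_length_bits
    if HEADER_BITS + n_body > bits.size:
        raise ValueError(
            f"undecodable header: declared body of {n_body} bits exceeds the "
            f"{bits.size - HEADER_BITS} bits available"
        )
    return BitPayload(bits[: HEADER_BITS + n_body], params.whitening_seed)
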