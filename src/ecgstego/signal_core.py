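"""Host-signal data model, file I/O, frame-layout arithmetic, and a
synthetic PQRST ECG generator.

Amplitudes live on a 16-bit integer scale (nominally -32768..32767) but are
kept in floating point throughout; quantization to integers happens only at
WAV export, the single place where rounding occurs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy.io import wavfile

DEFAULT_SAMPLE_RATE_HZ = 44100.0

#: Default rhythm: one beat every 128 samples.  Under the audio-rate label
#: used by the robustness protocol this is a time-compressed strip; at an
#: honest acquisition rate of 250 Hz the identical trace is a ~117 bpm
#: rhythm (beat period 0.512 s).
DEFAULT_HEART_RATE_BPM = DEFAULT_SAMPLE_RATE_HZ * 60.0 / 128.0
DEFAULT_BASELINE = 11000.0
DEFAULT_R_AMPLITUDE = 1200.0
DEFAULT_NOISE_SD = 20.0

#: Five-Gaussian PQRST parameterization: (label, offset, width, amplitude).
#: Offsets and widths are fractions of the beat period relative to the R
#: peak; amplitudes are fractions of ``r_amplitude``.  Fixed constants so
#: fixtures are reproducible.
PQRST_BUMPS = (
    ("P", -0.200, 0.035, 0.15),
    ("Q", -0.040, 0.012, -0.12),
    ("R", 0.000, 0.022, 1.00),
    ("S", 0.040, 0.014, -0.25),
    ("T", 0.250, 0.060, 0.30),
)

WAV_MIN, WAV_MAX = -32768, 32767


@dataclasses.dataclass(frozen=True)
class ECGSignal:
    """A 1-D host signal with its nominal sample-rate metadata."""

    samples: np.ndarray
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    record_id: str = ""

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("signal must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal amplitudes must be finite")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def length(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    def with_samples(self, samples: np.ndarray) -> "ECGSignal":
        return dataclasses.replace(self, samples=np.asarray(samples, float))


@dataclasses.dataclass(frozen=True)
class FrameLayout:
    """How a signal of length L maps onto bit-carrying frames.

    A k-level transform leaves ``L / 2**k`` approximation coefficients;
    grouped into blocks of ``block_size`` they form ``frame_count`` frames,
    each carrying one payload bit.
    """

    total_length: int
    level: int
    block_size: int
    frame_count: int

    @property
    def approx_length(self) -> int:
        return self.total_length // (2 ** self.level)

    @property
    def capacity_bits(self) -> int:
        return self.frame_count


def plan_layout(total_length: int, level: int, block_size: int) -> FrameLayout:
    """Frame arithmetic: I = L / (n * 2**k).  Fails rather than pads."""
    if total_length < 1 or level < 1 or block_size < 1:
        raise ValueError("total_length, level and block_size must be positive")
    scale = 2 ** level
    if total_length % scale != 0:
        raise ValueError(
            f"signal length {total_length} is not divisible by 2**{level}={scale}"
        )
    approx = total_length // scale
    if approx % block_size != 0:
        raise ValueError(
            f"approximation band of {approx} coefficients is not divisible "
            f"by block size {block_size}"
        )
    return FrameLayout(total_length, level, block_size, approx // block_size)


# ---------------------------------------------------------------------------
# File I/O.  CSV: one sample per line, optional "# sample_rate_hz=<v>" header.
# WAV: 16-bit PCM mono.


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "wav16"):
            raise ValueError(f"unknown format {fmt!r}")
        return fmt
    return "wav16" if path.suffix.lower() == ".wav" else "csv"


def read_signal(path, format: str | None = None) -> ECGSignal:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "wav16":
        rate, data = wavfile.read(path)
        if data.ndim != 1:
            raise ValueError(f"{path}: expected mono WAV, got {data.ndim} channels")
        if data.dtype != np.int16:
            raise ValueError(f"{path}: expected 16-bit PCM, got {data.dtype}")
        if data.size == 0:
            raise ValueError(f"{path}: empty signal")
        return ECGSignal(data.astype(float), float(rate), record_id=path.stem)
    rate = DEFAULT_SAMPLE_RATE_HZ
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("sample_rate_hz="):
                    rate = float(body.split("=", 1)[1])
                continue
            values.append(float(line))
    if not values:
        raise ValueError(f"{path}: empty signal")
    return ECGSignal(np.array(values, dtype=float), rate, record_id=path.stem)


def write_signal(signal: ECGSignal, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "wav16":
        # Round-to-nearest-even: the only place quantization occurs.
        rounded = np.rint(signal.samples)
        if rounded.min() < WAV_MIN or rounded.max() > WAV_MAX:
            raise ValueError(
                f"sample range [{rounded.min():g}, {rounded.max():g}] overflows "
                f"16-bit PCM ([{WAV_MIN}, {WAV_MAX}]); refusing to clip"
            )
        wavfile.write(path, int(round(signal.sample_rate_hz)), rounded.astype(np.int16))
        return
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz={signal.sample_rate_hz!r}\n")
        for v in signal.samples:
            fh.write(f"{float(v)!r}\n")


# ---------------------------------------------------------------------------
# Synthetic generator: the universal test fixture.


def synth_ecg(
    n_samples: int,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    heart_rate_bpm: float = DEFAULT_HEART_RATE_BPM,
    r_amplitude: float = DEFAULT_R_AMPLITUDE,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    baseline: float = DEFAULT_BASELINE,
    record_id: str | None = None,
) -> ECGSignal:
    """Generate a synthetic PQRST trace on the 16-bit ADC scale.

    Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) with fixed
    relative offsets and amplitudes (:data:`PQRST_BUMPS`) scaled so the R
    deflection above the baseline is ``r_amplitude``.  ``baseline`` is the
    DC pedestal a raw single-supply acquisition front-end leaves under the
    trace.  Beat centers sit at (j + 1/2) beat periods, the waveform is
    phase-folded (hence exactly periodic for ``noise_sd=0``), and additive
    Gaussian sensor noise of sd ``noise_sd`` is drawn from ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if heart_rate_bpm <= 0 or sample_rate_hz <= 0:
        raise ValueError("heart_rate_bpm and sample_rate_hz must be positive")
    if r_amplitude <= 0:
        raise ValueError("r_amplitude must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    period = sample_rate_hz * 60.0 / heart_rate_bpm  # samples per beat
    t = np.arange(n_samples, dtype=float)
    # phase in beat periods relative to the nearest beat center, in [-0.5, 0.5)
    phase = (t / period) % 1.0 - 0.5
    wave = np.zeros(n_samples)
    for _, offset, width, amp in PQRST_BUMPS:
        for wrap in (-1.0, 0.0, 1.0):  # keep the fold exactly periodic
            d = phase - offset + wrap
            wave += amp * np.exp(-0.5 * (d / width) ** 2)
    samples = baseline + r_amplitude * wave
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, noise_sd, n_samples)
    return ECGSignal(
        samples,
        sample_rate_hz,
        record_id=record_id if record_id is not None else f"synth-{seed}",
    )
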