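"""Serialize a patient record to a whitened, length-prefixed bit vector.

Wire format: a 16-bit big-endian header giving the body length in bits,
followed by the body (MSB-first bits of a delimited UTF-8 serialization),
the whole stream XORed with a pseudorandom whitening mask derived from a
fixed public seed.  Whitening keeps the embedded 0/1 ratio near 1/2 for any
payload, which the self-derived blind extraction threshold relies on; the
length header lets extraction stop at the true payload end when the payload
is shorter than the frame capacity.
"""

from __future__ import annotations

import dataclasses

import numpy as np

#: Fixed public whitening seed.  Pass ``whitening_seed=None`` to disable.
DEFAULT_WHITENING_SEED = 7919

HEADER_BITS = 16
MAX_BODY_BITS = 2 ** 16 - 1

_FIELD_SEP = "\x1f"
_ESC = "\x1b"


@dataclasses.dataclass(frozen=True)
class PatientRecord:
    name: str = ""
    birthdate: str = ""
    treatment_date: str = ""
    history: str = ""

    _FIELDS = ("name", "birthdate", "treatment_date", "history")


def whiten(bits, seed: int | None):
    """XOR with a reproducible pseudorandom {0,1} stream; an involution.

    ``seed=None`` disables whitening (identity).
    """
    bits = _as_bits(bits)
    if seed is None or bits.size == 0:
        return bits.copy()
    mask = np.random.default_rng(seed).integers(0, 2, size=bits.size, dtype=np.uint8)
    return bits ^ mask


def _as_bits(bits) -> np.ndarray:
    arr = np.asarray(bits)
    arr = arr.astype(np.uint8)
    if arr.ndim != 1 or not np.all((arr == 0) | (arr == 1)):
        raise ValueError("bits must be a 1-D sequence of 0/1")
    return arr


def bytes_to_bits(data: bytes) -> np.ndarray:
    return np.unpackbits(np.frombuffer(data, dtype=np.uint8))


def bits_to_bytes(bits) -> bytes:
    bits = _as_bits(bits)
    if bits.size % 8 != 0:
        raise ValueError(f"bit count {bits.size} is not a whole number of bytes")
    return np.packbits(bits).tobytes()


@dataclasses.dataclass(frozen=True)
class BitPayload:
    """The on-wire bit vector B: whitened 16-bit length header plus body."""

    bits: np.ndarray
    whitening_seed: int | None = DEFAULT_WHITENING_SEED

    def __post_init__(self):
        object.__setattr__(self, "bits", _as_bits(self.bits))

    def __len__(self) -> int:
        return self.bits.size

    @classmethod
    def from_body(cls, body_bits, whitening_seed: int | None = DEFAULT_WHITENING_SEED):
        body = _as_bits(body_bits)
        if body.size > MAX_BODY_BITS:
            raise ValueError(
                f"body of {body.size} bits exceeds the {MAX_BODY_BITS}-bit "
                "header range"
            )
        header = np.array(
            [(body.size >> (HEADER_BITS - 1 - i)) & 1 for i in range(HEADER_BITS)],
            dtype=np.uint8,
        )
        wire = whiten(np.concatenate([header, body]), whitening_seed)
        return cls(wire, whitening_seed)

    @classmethod
    def from_bytes(cls, data: bytes, whitening_seed: int | None = DEFAULT_WHITENING_SEED):
        return cls.from_body(bytes_to_bits(data), whitening_seed)

    def _clear_bits(self) -> np.ndarray:
        if self.bits.size < HEADER_BITS:
            raise ValueError(
                f"payload of {self.bits.size} bits is shorter than the "
                f"{HEADER_BITS}-bit header"
            )
        return whiten(self.bits, self.whitening_seed)

    @property
    def body_length_bits(self) -> int:
        header = self._clear_bits()[:HEADER_BITS]
        return int(np.sum(header.astype(np.int64) << np.arange(HEADER_BITS - 1, -1, -1)))

    @property
    def body_bits(self) -> np.ndarray:
        clear = self._clear_bits()
        n = self.body_length_bits
        if HEADER_BITS + n > clear.size:
            raise ValueError(
                f"header declares {n} body bits but only "
                f"{clear.size - HEADER_BITS} are present (truncated payload)"
            )
        return clear[HEADER_BITS : HEADER_BITS + n]

    def to_bytes(self) -> bytes:
        return bits_to_bytes(self.body_bits)


# ---------------------------------------------------------------------------
# Record serialization: four fields joined by an escape-coded separator.


def _escape(s: str) -> str:
    return s.replace(_ESC, _ESC + _ESC).replace(_FIELD_SEP, _ESC + _FIELD_SEP)


def _split_fields(s: str) -> list:
    fields = [""]
    it = iter(s)
    for ch in it:
        if ch == _ESC:
            nxt = next(it, None)
            if nxt is None:
                raise ValueError("dangling escape in serialized record")
            fields[-1] += nxt
        elif ch == _FIELD_SEP:
            fields.append("")
        else:
            fields[-1] += ch
    return fields


def serialize_record(record: PatientRecord) -> bytes:
    text = _FIELD_SEP.join(
        _escape(getattr(record, f)) for f in PatientRecord._FIELDS
    )
    return text.encode("utf-8")


def encode_record(
    record: PatientRecord, whitening_seed: int | None = DEFAULT_WHITENING_SEED
) -> BitPayload:
    return BitPayload.from_bytes(serialize_record(record), whitening_seed)


def decode_record(payload: BitPayload) -> PatientRecord:
    data = payload.to_bytes()
    if not data:
        return PatientRecord()  # degenerate zero-length body
    try:
        text = data.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise ValueError(f"payload body is not valid UTF-8: {exc}") from exc
    fields = _split_fields(text)
    if len(fields) != len(PatientRecord._FIELDS):
        raise ValueError(
            f"expected {len(PatientRecord._FIELDS)} record fields, got {len(fields)}"
        )
    return PatientRecord(*fields)


def encode_text(text: str, whitening_seed: int | None = DEFAULT_WHITENING_SEED) -> BitPayload:
    """Frame free-form UTF-8 text (no record structure)."""
    return BitPayload.from_bytes(text.encode("utf-8"), whitening_seed)


def decode_text(payload: BitPayload) -> str:
    return payload.to_bytes().decode("utf-8")
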