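"""Secure-payload layer: canonical serialization, AES-128-CBC, Base64.

Mirrors the telemetry path of an IoT vitals monitor: a record is rendered
to canonical bytes, PKCS#7-padded, encrypted with AES-128 in CBC mode under
a device key, Base64-encoded and placed in a store that only ever holds
ciphertext; the consumer side fetches, decrypts and parses.  A fresh random
16-byte IV is drawn per message (a fixed IV under CBC would leak equality
of records) and travels alongside the ciphertext.

The "cloud" is an in-process key-value store with the same contract as the
real thing (put ciphertext, notify, get ciphertext); simulated time uses a
virtual clock so a five-second send period is testable without sleeping.
"""

from __future__ import annotations

import base64
import binascii
import secrets
from dataclasses import dataclass, field

import numpy as np

from . import aes
from .errors import (
    AuthenticationError,
    InvalidKeyError,
    PayloadFormatError,
)
from .vitals import VitalRecord

#: default telemetry send period, seconds
DEFAULT_SEND_PERIOD_S = 5.0

FIELD_TAGS = ("heart_rate", "spo2", "temperature", "full_record")

# canonical field order and renderings for serialization
_SERIAL_FIELDS = ("subject_id", "timestamp", "hr", "spo2", "temp")


@dataclass(frozen=True)
class SecretKey:
    """A 128-bit AES key with an identifier for key management."""

    key_bytes: bytes
    key_id: str = "default"

    def __post_init__(self):
        if len(self.key_bytes) != 16:
            raise InvalidKeyError(
                f"key must be exactly 16 bytes (128 bits), got {len(self.key_bytes)}"
            )

    @classmethod
    def from_hex(cls, hex_string: str, key_id: str = "default") -> "SecretKey":
        """Parse a 32-hex-character key (the key-file format)."""
        try:
            raw = bytes.fromhex(hex_string.strip())
        except ValueError as exc:
            raise InvalidKeyError(f"invalid hex key: {exc}") from exc
        return cls(raw, key_id)


@dataclass(frozen=True)
class EncryptedRecord:
    """What the cloud stores: Base64 ciphertext, IV, key id, field tag."""

    ciphertext_b64: str
    iv: bytes
    key_id: str
    field_tag: str = "full_record"

    def __post_init__(self):
        if len(self.iv) != 16:
            raise InvalidKeyError("IV must be exactly 16 bytes")
        if self.field_tag not in FIELD_TAGS:
            raise PayloadFormatError(f"unknown field tag {self.field_tag!r}")

    def ciphertext(self) -> bytes:
        try:
            raw = base64.b64decode(self.ciphertext_b64, validate=True)
        except (binascii.Error, ValueError) as exc:
            raise PayloadFormatError(f"malformed Base64 ciphertext: {exc}") from exc
        if not raw or len(raw) % 16:
            raise PayloadFormatError(
                "ciphertext must decode to a positive multiple of 16 bytes"
            )
        return raw


# --------------------------------------------------------------------------
# canonical serialization
# --------------------------------------------------------------------------

def serialize_record(rec: VitalRecord) -> bytes:
    """Render a record as deterministic key:value lines.

    Fixed field order; heart rate and SpO2 as integers, temperature with
    four decimals (enough for the 0.0625 degC sensor grid), timestamp with
    three.  Serialization canonicalizes: deserialize(serialize(r)) equals r
    exactly for records already on this grid.
    """
    lines = [
        f"subject_id:{rec.subject_id}",
        f"timestamp:{rec.timestamp:.3f}",
        f"hr:{round(rec.heart_rate_bpm)}",
        f"spo2:{round(rec.spo2_percent)}",
        f"temp:{rec.temperature_c:.4f}",
    ]
    return ("\n".join(lines) + "\n").encode("utf-8")


def deserialize_record(payload: bytes) -> VitalRecord:
    """Inverse of :func:`serialize_record`; strict about structure."""
    try:
        text = payload.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise PayloadFormatError("payload is not valid UTF-8") from exc
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if not line:
            continue
        key, sep, value = line.partition(":")
        if not sep:
            raise PayloadFormatError(f"malformed line {line!r}")
        fields[key] = value
    if tuple(fields) != _SERIAL_FIELDS:
        raise PayloadFormatError(
            f"expected fields {_SERIAL_FIELDS}, got {tuple(fields)}"
        )
    try:
        return VitalRecord(
            heart_rate_bpm=float(fields["hr"]),
            spo2_percent=float(fields["spo2"]),
            temperature_c=float(fields["temp"]),
            timestamp=float(fields["timestamp"]),
            subject_id=fields["subject_id"],
        )
    except ValueError as exc:
        raise PayloadFormatError(f"invalid field value: {exc}") from exc


def serialize_field(rec: VitalRecord, field_tag: str) -> bytes:
    """Per-field rendering, matching the one-value-per-ciphertext mode."""
    if field_tag == "heart_rate":
        return str(round(rec.heart_rate_bpm)).encode()
    if field_tag == "spo2":
        return str(round(rec.spo2_percent)).encode()
    if field_tag == "temperature":
        return f"{rec.temperature_c:.4f}".encode()
    raise PayloadFormatError(f"unknown field tag {field_tag!r}")


# --------------------------------------------------------------------------
# encryption / decryption
# --------------------------------------------------------------------------

def encrypt_record(
    plaintext: bytes,
    key: SecretKey,
    iv: bytes,
    field_tag: str = "full_record",
) -> EncryptedRecord:
    """AES-128-CBC with PKCS#7 padding, then standard Base64 (no wrapping)."""
    ct = aes.cbc_encrypt(plaintext, key.key_bytes, iv)
    return EncryptedRecord(
        ciphertext_b64=base64.b64encode(ct).decode("ascii"),
        iv=iv,
        key_id=key.key_id,
        field_tag=field_tag,
    )


def decrypt_payload(enc: EncryptedRecord, key: SecretKey) -> bytes:
    """Decrypt to raw plaintext bytes; never returns partial data."""
    if enc.key_id != key.key_id:
        raise InvalidKeyError(
            f"key id mismatch: payload needs {enc.key_id!r}, got {key.key_id!r}"
        )
    ct = enc.ciphertext()
    try:
        return aes.cbc_decrypt(ct, key.key_bytes, enc.iv)
    except PayloadFormatError as exc:
        # wrong key and corrupted ciphertext both surface as padding
        # failures; report them uniformly
        raise AuthenticationError(f"decryption failed: {exc}") from exc


def decrypt_record(enc: EncryptedRecord, key: SecretKey) -> VitalRecord:
    """Decrypt and parse a full-record payload."""
    plaintext = decrypt_payload(enc, key)
    try:
        return deserialize_record(plaintext)
    except PayloadFormatError as exc:
        raise AuthenticationError(f"decrypted payload did not parse: {exc}") from exc


def encrypt_vital_record(
    rec: VitalRecord,
    key: SecretKey,
    iv: bytes | None = None,
    per_field: bool = False,
) -> list[EncryptedRecord]:
    """Encrypt one record, whole (default) or one ciphertext per vital."""
    if per_field:
        out = []
        for tag in ("heart_rate", "spo2", "temperature"):
            this_iv = iv if iv is not None else secrets.token_bytes(16)
            out.append(encrypt_record(serialize_field(rec, tag), key, this_iv, tag))
        return out
    this_iv = iv if iv is not None else secrets.token_bytes(16)
    return [encrypt_record(serialize_record(rec), key, this_iv)]


# --------------------------------------------------------------------------
# in-process cloud store and telemetry loop
# --------------------------------------------------------------------------

class InMemoryCipherStore:
    """Stand-in for the cloud database: holds ciphertext only, notifies."""

    def __init__(self):
        self._items: dict[str, EncryptedRecord] = {}
        self._listeners: list = []

    def put(self, path: str, enc: EncryptedRecord) -> None:
        self._items[path] = enc
        for cb in self._listeners:
            cb(path)

    def get(self, path: str) -> EncryptedRecord:
        return self._items[path]

    def subscribe(self, callback) -> None:
        self._listeners.append(callback)

    def paths(self) -> list[str]:
        return sorted(self._items)

    def dump_text(self) -> str:
        """Everything at rest, as text — used to audit for plaintext leaks."""
        parts = []
        for path in self.paths():
            enc = self._items[path]
            parts.append(
                f"{path}|{enc.field_tag}|{enc.key_id}|"
                f"{enc.iv.hex()}|{enc.ciphertext_b64}"
            )
        return "\n".join(parts)


@dataclass
class TranscriptEntry:
    time_s: float
    event: str  # "sent" | "delivered" | "failed"
    index: int
    detail: str = ""


@dataclass
class TelemetryResult:
    delivered: list[VitalRecord]
    failures: list[tuple[int, str]]
    transcript: list[TranscriptEntry]
    store: InMemoryCipherStore


def telemetry_roundtrip(
    records: list[VitalRecord],
    key: SecretKey,
    period_s: float = DEFAULT_SEND_PERIOD_S,
    seed: int | None = None,
    corrupt_indices: tuple[int, ...] = (),
) -> TelemetryResult:
    """Send records through the full encrypt -> store -> decrypt loop.

    Each record is serialized, encrypted with a fresh IV, stored, fetched
    and decrypted on a virtual clock ticking every ``period_s`` seconds.
    ``seed`` makes the IV draws reproducible (default: OS entropy).
    ``corrupt_indices`` is a test hook that flips one ciphertext byte for
    the given records after storage; a corrupted record is reported as a
    per-record failure without stopping the stream.
    """
    if period_s <= 0:
        raise InvalidKeyError("period_s must be positive")
    rng = np.random.default_rng(seed) if seed is not None else None

    store = InMemoryCipherStore()
    transcript: list[TranscriptEntry] = []
    delivered: list[VitalRecord] = []
    failures: list[tuple[int, str]] = []

    for i, rec in enumerate(records):
        t = i * period_s
        iv = (
            rng.integers(0, 256, 16, dtype=np.uint8).tobytes()
            if rng is not None
            else secrets.token_bytes(16)
        )
        enc = encrypt_record(serialize_record(rec), key, iv)
        if i in corrupt_indices:
            raw = bytearray(enc.ciphertext())
            raw[0] ^= 0xFF
            enc = EncryptedRecord(
                base64.b64encode(bytes(raw)).decode("ascii"),
                enc.iv,
                enc.key_id,
                enc.field_tag,
            )
        store.put(f"records/{i}", enc)
        transcript.append(TranscriptEntry(t, "sent", i))

        try:
            out = decrypt_record(store.get(f"records/{i}"), key)
        except (AuthenticationError, PayloadFormatError, InvalidKeyError) as exc:
            failures.append((i, str(exc)))
            transcript.append(TranscriptEntry(t, "failed", i, str(exc)))
        else:
            delivered.append(out)
            transcript.append(TranscriptEntry(t, "delivered", i))

    return TelemetryResult(delivered, failures, transcript, store)
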