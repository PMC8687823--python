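"""AES-128 block cipher with CBC mode and PKCS#7 padding.

A self-contained implementation of the 128-bit-key Advanced Encryption
Standard: 10 rounds of SubBytes / ShiftRows / MixColumns / AddRoundKey over
a 4x4 byte state, with the S-box derived at import time from the
multiplicative inverse in GF(2^8) followed by the standard affine map.
Correctness is pinned to the published known-answer vectors (single-block
ECB and multi-block CBC) in the test suite rather than to any prose
description of the algorithm.

Throughput is irrelevant here — payloads are single vital-sign records of a
few dozen bytes — so clarity wins over table-driven speed tricks.
"""

from __future__ import annotations

from .errors import InvalidKeyError, PayloadFormatError

BLOCK_SIZE = 16
_N_ROUNDS = 10  # AES-128


def _gf_mul(a: int, b: int) -> int:
    """Multiply in GF(2^8) modulo the AES polynomial x^8+x^4+x^3+x+1."""
    p = 0
    for _ in range(8):
        if b & 1:
            p ^= a
        hi = a & 0x80
        a = (a << 1) & 0xFF
        if hi:
            a ^= 0x1B
        b >>= 1
    return p


def _build_sbox() -> tuple[list[int], list[int]]:
    # multiplicative inverses (0 maps to 0)
    inv = [0] * 256
    for x in range(1, 256):
        for y in range(1, 256):
            if _gf_mul(x, y) == 1:
                inv[x] = y
                break
    sbox = [0] * 256
    for x in range(256):
        b = inv[x]
        # affine transform: bit-rotations of b xored together, plus 0x63
        s = b
        for r in (1, 2, 3, 4):
            s ^= ((b << r) | (b >> (8 - r))) & 0xFF
        sbox[x] = s ^ 0x63
    inv_sbox = [0] * 256
    for x, s in enumerate(sbox):
        inv_sbox[s] = x
    return sbox, inv_sbox


_SBOX, _INV_SBOX = _build_sbox()
_RCON = [0x01, 0x02, 0x04, 0x08, 0x10, 0x20, 0x40, 0x80, 0x1B, 0x36]


def _expand_key(key: bytes) -> list[list[int]]:
    """Expand a 16-byte key into 44 four-byte words."""
    if len(key) != 16:
        raise InvalidKeyError(f"AES-128 key must be 16 bytes, got {len(key)}")
    w = [list(key[4 * i : 4 * i + 4]) for i in range(4)]
    for i in range(4, 4 * (_N_ROUNDS + 1)):
        t = list(w[i - 1])
        if i % 4 == 0:
            t = t[1:] + t[:1]                      # RotWord
            t = [_SBOX[b] for b in t]              # SubWord
            t[0] ^= _RCON[i // 4 - 1]
        w.append([a ^ b for a, b in zip(w[i - 4], t)])
    return w


def _add_round_key(state: list[int], words: list[list[int]]) -> None:
    for c in range(4):
        for r in range(4):
            state[4 * c + r] ^= words[c][r]


def _shift_rows(state: list[int]) -> list[int]:
    # state is column-major: element (row r, column c) lives at 4c + r
    return [state[4 * ((c + r) % 4) + r] for c in range(4) for r in range(4)]


def _inv_shift_rows(state: list[int]) -> list[int]:
    return [state[4 * ((c - r) % 4) + r] for c in range(4) for r in range(4)]


def _mix_columns(state: list[int], inverse: bool = False) -> list[int]:
    m = (
        (0x0E, 0x0B, 0x0D, 0x09) if inverse else (0x02, 0x03, 0x01, 0x01)
    )
    out = [0] * 16
    for c in range(4):
        col = state[4 * c : 4 * c + 4]
        for r in range(4):
            out[4 * c + r] = (
                _gf_mul(m[(0 - r) % 4], col[0])
                ^ _gf_mul(m[(1 - r) % 4], col[1])
                ^ _gf_mul(m[(2 - r) % 4], col[2])
                ^ _gf_mul(m[(3 - r) % 4], col[3])
            )
    return out


def encrypt_block(block: bytes, key: bytes) -> bytes:
    """Encrypt one 16-byte block (raw ECB primitive)."""
    if len(block) != BLOCK_SIZE:
        raise PayloadFormatError("AES block must be exactly 16 bytes")
    w = _expand_key(key)
    state = list(block)
    _add_round_key(state, w[0:4])
    for rnd in range(1, _N_ROUNDS):
        state = [_SBOX[b] for b in state]
        state = _shift_rows(state)
        state = _mix_columns(state)
        _add_round_key(state, w[4 * rnd : 4 * rnd + 4])
    state = [_SBOX[b] for b in state]
    state = _shift_rows(state)
    _add_round_key(state, w[4 * _N_ROUNDS : 4 * _N_ROUNDS + 4])
    return bytes(state)


def decrypt_block(block: bytes, key: bytes) -> bytes:
    """Decrypt one 16-byte block (raw ECB primitive)."""
    if len(block) != BLOCK_SIZE:
        raise PayloadFormatError("AES block must be exactly 16 bytes")
    w = _expand_key(key)
    state = list(block)
    _add_round_key(state, w[4 * _N_ROUNDS : 4 * _N_ROUNDS + 4])
    state = _inv_shift_rows(state)
    state = [_INV_SBOX[b] for b in state]
    for rnd in range(_N_ROUNDS - 1, 0, -1):
        _add_round_key(state, w[4 * rnd : 4 * rnd + 4])
        state = _mix_columns(state, inverse=True)
        state = _inv_shift_rows(state)
        state = [_INV_SBOX[b] for b in state]
    _add_round_key(state, w[0:4])
    return bytes(state)


def pkcs7_pad(data: bytes) -> bytes:
    """Append n bytes of value n so the length is a positive multiple of 16."""
    n = BLOCK_SIZE - len(data) % BLOCK_SIZE
    return data + bytes([n]) * n


def pkcs7_unpad(data: bytes) -> bytes:
    if not data or len(data) % BLOCK_SIZE:
        raise PayloadFormatError("padded data length must be a positive multiple of 16")
    n = data[-1]
    if not 1 <= n <= BLOCK_SIZE or data[-n:] != bytes([n]) * n:
        raise PayloadFormatError("invalid PKCS#7 padding")
    return data[:-n]


def cbc_encrypt(plaintext: bytes, key: bytes, iv: bytes) -> bytes:
    """PKCS#7-pad and encrypt in cipher-block-chaining mode."""
    if len(iv) != BLOCK_SIZE:
        raise InvalidKeyError(f"IV must be 16 bytes, got {len(iv)}")
    data = pkcs7_pad(plaintext)
    out = bytearray()
    prev = iv
    for i in range(0, len(data), BLOCK_SIZE):
        block = bytes(a ^ b for a, b in zip(data[i : i + BLOCK_SIZE], prev))
        prev = encrypt_block(block, key)
        out += prev
    return bytes(out)


def cbc_decrypt(ciphertext: bytes, key: bytes, iv: bytes) -> bytes:
    """Decrypt CBC ciphertext and strip PKCS#7 padding."""
    if len(iv) != BLOCK_SIZE:
        raise InvalidKeyError(f"IV must be 16 bytes, got {len(iv)}")
    if not ciphertext or len(ciphertext) % BLOCK_SIZE:
        raise PayloadFormatError(
            "ciphertext length must be a positive multiple of 16"
        )
    out = bytearray()
    prev = iv
    for i in range(0, len(ciphertext), BLOCK_SIZE):
        block = ciphertext[i : i + BLOCK_SIZE]
        out += bytes(a ^ b for a, b in zip(decrypt_block(block, key), prev))
        prev = block
    return pkcs7_unpad(bytes(out))
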