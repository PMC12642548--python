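"""Seeded 64-bit hashing and the bit decomposition that drives bucket assignment.

Every sampler in this package keys its decisions off a single seeded 64-bit
hash of each item.  For the geometric samplers the hash value ``h`` is split
into

* ``zpl`` -- the number of leading zero bits (zero-prefix length),
* ``i = zpl + 1`` -- the bucket index (position of the leftmost set bit),
* ``h_prime`` -- the value of the bits strictly after the leftmost 1.

For uniform hashes the bucket index is geometric with parameter 1/2, which is
what gives the sketches their logarithmic / power-law growth.

The hash itself (``smx64``) is a seeded chain of splitmix64 finalizer rounds
over little-endian 8-byte blocks, with the item length folded into the
initial state.  It is deterministic, portable across platforms, and has both
a scalar and a numpy-vectorized implementation that agree bit-for-bit.
Sketches are only comparable when built with the identical hash function and
seed, so the hash name is recorded in sketch file headers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HASH_NAME",
    "HashDecomposition",
    "hash64",
    "hash64_array",
    "decompose",
    "decompose_array",
]

HASH_NAME = "smx64"

_MASK64 = (1 << 64) - 1
_P1 = 0x9E3779B97F4A7C15
_P2 = 0xBF58476D1CE4E5B9
_P3 = 0x94D049BB133111EB


def _mix(x: int) -> int:
    """splitmix64 finalizer on a Python int (mod 2^64)."""
    x ^= x >> 30
    x = (x * _P2) & _MASK64
    x ^= x >> 27
    x = (x * _P3) & _MASK64
    x ^= x >> 31
    return x


def _init_state(length: int, seed: int) -> int:
    # Fold the item length into the state so that zero-padding of the final
    # block cannot collide with explicit trailing NUL bytes.
    return _mix((seed & _MASK64) ^ ((_P1 * (length + 1)) & _MASK64))


def hash64(item: bytes, seed: int = 0) -> int:
    """Seeded 64-bit hash of a byte string (``smx64``).

    Deterministic and identical across platforms and runs; different seeds
    behave like independent hash functions.
    """
    h = _init_state(len(item), seed)
    for off in range(0, len(item), 8):
        chunk = int.from_bytes(item[off : off + 8].ljust(8, b"\x00"), "little")
        h = _mix(h ^ chunk)
    return h


def _mix_u64(x: np.ndarray) -> np.ndarray:
    x = x ^ (x >> np.uint64(30))
    x = x * np.uint64(_P2)
    x = x ^ (x >> np.uint64(27))
    x = x * np.uint64(_P3)
    x = x ^ (x >> np.uint64(31))
    return x


def hash64_array(items, seed: int = 0) -> np.ndarray:
    """Vectorized ``hash64`` over an array of equal-length byte strings.

    ``items`` is coerced to a numpy byte-string array (dtype ``S<L>``); every
    element is hashed as exactly ``L`` bytes, so items must not rely on
    trailing NUL bytes (numpy's ``S`` dtype cannot represent them).  Agrees
    elementwise with :func:`hash64`.
    """
    a = np.asarray(items)
    if a.dtype.kind != "S":
        a = np.asarray(items, dtype=np.bytes_)
    length = a.dtype.itemsize
    n = a.size
    if n == 0:
        return np.empty(0, dtype=np.uint64)
    u8 = np.frombuffer(a.tobytes(), dtype=np.uint8).reshape(n, length)
    nblocks = (length + 7) // 8
    if length % 8:
        pad = np.zeros((n, nblocks * 8 - length), dtype=np.uint8)
        u8 = np.concatenate([u8, pad], axis=1)
    blocks = u8.reshape(n, nblocks, 8).astype(np.uint64)
    # Endian-independent little-endian block assembly.
    shifts = (np.uint64(8) * np.arange(8, dtype=np.uint64)).astype(np.uint64)
    with np.errstate(over="ignore"):
        words = (blocks << shifts).sum(axis=2, dtype=np.uint64)
        h = np.full(n, _init_state(length, seed), dtype=np.uint64)
        for j in range(nblocks):
            h = _mix_u64(h ^ words[:, j])
    return h


@dataclass(frozen=True)
class HashDecomposition:
    """A 64-bit hash split into zero-prefix length, bucket index and suffix.

    Invariants: ``i == zpl + 1``; for ``h > 0``,
    ``h == 2**(63 - zpl) + h_prime`` with ``h_prime < 2**(63 - zpl)``;
    ``h == 0`` maps to ``zpl == 64``, ``i == 65``, ``h_prime == 0`` (the
    all-zero word has, by convention, a zero-prefix spanning the whole word).
    """

    h: int
    zpl: int
    i: int
    h_prime: int


def decompose(h: int) -> HashDecomposition:
    """Split a 64-bit hash into (h, zpl, i, h_prime)."""
    if not 0 <= h < 1 << 64:
        raise ValueError(f"hash out of 64-bit range: {h}")
    if h == 0:
        return HashDecomposition(0, 64, 65, 0)
    zpl = 64 - h.bit_length()
    return HashDecomposition(h, zpl, zpl + 1, h ^ (1 << (63 - zpl)))


def decompose_array(h) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`decompose`: returns ``(zpl, i, h_prime)`` arrays.

    ``zpl`` and ``h_prime`` are uint64, ``i`` is int64 in [1, 65].
    """
    h = np.asarray(h, dtype=np.uint64)
    zpl = np.zeros(h.shape, dtype=np.uint64)
    x = h.copy()
    for s in (32, 16, 8, 4, 2, 1):
        m = x < (np.uint64(1) << np.uint64(64 - s))
        zpl[m] += np.uint64(s)
        x[m] <<= np.uint64(s)
    zero = h == 0
    zpl[zero] = 64
    i = (zpl + np.uint64(1)).astype(np.int64)
    shift = np.uint64(63) - np.minimum(zpl, np.uint64(63))
    h_prime = np.where(zero, np.uint64(0), h ^ (np.uint64(1) << shift))
    return zpl, i, h_prime
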