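"""Bit-packed traceback storage: a full compound path in two 32-bit words.

The DP traceback stores, per table cell, one ``(k, r_prev)`` tuple per
position: the sidechain index chosen there and the rank of the predecessor
state.  Keeping one such layer per position costs ``8 * n * w'_max * R``
bytes.  Instead, the whole path can be carried along with the cell: the n
sidechain indices are concatenated into one 32-bit word (field ``s`` using
``floor(log2(k_s)) + 1`` bits) and the n predecessor ranks into a second
32-bit word (uniform ``floor(log2(R)) + 1``-bit fields), cutting traceback
storage to ``8 * w'_max * R`` bytes — a ``100 * (1 - 1/n)`` % saving.  The
scheme is only applicable when both words fit:

* sum_s floor(log2(k_s)) + 1  <= 32   (sidechain-index word)
* n * (floor(log2(R)) + 1)    <= 32   (predecessor-rank word)

Layout contract (see ``docs/packing.md``): position 0 occupies the
least-significant bits of each word, subsequent positions follow upward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "TracebackRecord",
    "PackedTraceback",
    "PackingError",
    "bits_for_sidechain",
    "bits_for_rank",
    "field_offsets",
    "check_compression_feasible",
    "pack",
    "unpack",
    "uncompressed_traceback_bytes",
    "compressed_traceback_bytes",
    "traceback_saving_fraction",
]


class PackingError(Exception):
    """A traceback value does not fit its bit field, or fields exceed 32 bits."""


class TracebackRecord(NamedTuple):
    """Per-position traceback: chosen sidechain index and predecessor rank."""

    k: int
    r_prev: int


@dataclass(frozen=True)
class PackedTraceback:
    """A full compound traceback in two 32-bit unsigned words."""

    k_word: int
    r_word: int


def bits_for_sidechain(k_s: int) -> int:
    """Bits to store a sidechain index at a position with ``k_s`` sidechains.

    ``floor(log2(k_s)) + 1`` as the device implementation charges it.  Note
    this spends one extra bit at exact powers of two (``k_s = 4`` -> 3 bits
    although indices 0..3 fit in 2); the feasibility inequalities and the
    packed layout use the formula as-is for fidelity to the resource model.
    """
    if k_s < 1:
        raise ValueError(f"k_s must be >= 1, got {k_s}")
    return int(k_s).bit_length()  # == floor(log2(k_s)) + 1 for k_s >= 1


def bits_for_rank(R: int) -> int:
    """Uniform field width for predecessor ranks, ``floor(log2(R)) + 1``."""
    if R < 1:
        raise ValueError(f"R must be >= 1, got {R}")
    return int(R).bit_length()


def check_compression_feasible(K: Sequence[int], R: int) -> tuple[bool, bool]:
    """Whether the two packed words fit in 32 bits each.

    Returns ``(eq1_ok, eq2_ok)``: the sidechain-index word constraint
    ``sum_s floor(log2(k_s))+1 <= 32`` and the rank word constraint
    ``n * (floor(log2(R))+1) <= 32``.
    """
    K = list(int(k) for k in K)
    if not K:
        raise ValueError("K must be nonempty")
    eq1_ok = sum(bits_for_sidechain(k) for k in K) <= 32
    eq2_ok = len(K) * bits_for_rank(R) <= 32
    return eq1_ok, eq2_ok


def field_offsets(K: Sequence[int], R: int) -> tuple[list[int], list[int], int]:
    """Bit offsets of each position's fields in the packed words.

    Returns ``(k_offsets, r_offsets, r_width)`` with position 0 at the
    least-significant end.
    """
    k_off: list[int] = []
    pos = 0
    for k in K:
        k_off.append(pos)
        pos += bits_for_sidechain(int(k))
    r_width = bits_for_rank(R)
    r_off = [s * r_width for s in range(len(list(K)))]
    return k_off, r_off, r_width


def pack(records: Sequence[TracebackRecord], K: Sequence[int], R: int) -> PackedTraceback:
    """Concatenate n per-position traceback records into two 32-bit words."""
    K = [int(k) for k in K]
    if len(records) != len(K):
        raise PackingError(f"{len(records)} records for {len(K)} positions")
    eq1, eq2 = check_compression_feasible(K, R)
    if not (eq1 and eq2):
        raise PackingError(
            f"layout exceeds 32 bits (k-word ok: {eq1}, r-word ok: {eq2})"
        )
    k_off, r_off, r_width = field_offsets(K, R)
    k_word = 0
    r_word = 0
    for s, rec in enumerate(records):
        wk = bits_for_sidechain(K[s])
        if not (0 <= rec.k < K[s]):
            raise PackingError(f"position {s}: k = {rec.k} outside [0, {K[s]})")
        if not (0 <= rec.r_prev < R):
            raise PackingError(f"position {s}: r_prev = {rec.r_prev} outside [0, {R})")
        if rec.k >> wk:
            raise PackingError(f"position {s}: k = {rec.k} exceeds {wk}-bit field")
        k_word |= rec.k << k_off[s]
        r_word |= rec.r_prev << r_off[s]
    return PackedTraceback(k_word=k_word, r_word=r_word)


def unpack(packed: PackedTraceback, K: Sequence[int], R: int) -> list[TracebackRecord]:
    """Exact inverse of :func:`pack` under the same ``(K, R)`` layout."""
    K = [int(k) for k in K]
    k_off, r_off, r_width = field_offsets(K, R)
    out: list[TracebackRecord] = []
    for s, k_s in enumerate(K):
        wk = bits_for_sidechain(k_s)
        k = (packed.k_word >> k_off[s]) & ((1 << wk) - 1)
        r = (packed.r_word >> r_off[s]) & ((1 << r_width) - 1)
        out.append(TracebackRecord(k=k, r_prev=r))
    return out


def uncompressed_traceback_bytes(n: int, R: int, w_prime_max: int) -> int:
    """Traceback bytes with one raw layer per position: ``8 n w'_max R``."""
    return 8 * n * w_prime_max * R


def compressed_traceback_bytes(R: int, w_prime_max: int) -> int:
    """Traceback bytes in packed mode: ``8 w'_max R`` (two words per cell)."""
    return 8 * w_prime_max * R


def traceback_saving_fraction(n: int) -> float:
    """Percent of traceback memory saved by packing: ``100 (1 - 1/n)``."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return 100.0 * (1.0 - 1.0 / n)
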