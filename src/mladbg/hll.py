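"""Cardinality sketches for label k-mer sets.

Label-change scores only need order-of-magnitude accuracy for conditional
label probabilities, so per-label node sets are summarised by HyperLogLog
counters.  The sketch error is configurable; an exact-set backend with the
same interface is available for tests and small graphs.
"""

from __future__ import annotations

import base64
import hashlib
import math

import numpy as np

__all__ = ["HyperLogLog", "ExactCardinality", "make_sketch"]

_HASH_BITS = 64


def _hash64(item: str | bytes) -> int:
    if isinstance(item, str):
        item = item.encode()
    return int.from_bytes(hashlib.blake2b(item, digest_size=8).digest(), "big")


class HyperLogLog:
    """Standard HyperLogLog counter over 64-bit hashes.

    The register count is the smallest power of two whose standard relative
    error 1.04/sqrt(m) is at or below ``error_rate``.  Small cardinalities
    use the linear-counting correction; no large-range correction is needed
    with a 64-bit hash at the scales handled here.
    """

    def __init__(self, error_rate: float = 0.05, _registers: np.ndarray | None = None):
        if not 0.0 < error_rate < 1.0:
            raise ValueError(f"error_rate must be in (0,1), got {error_rate}")
        self.error_rate = error_rate
        p = max(4, min(18, math.ceil(2 * math.log2(1.04 / error_rate))))
        self.p = p
        self.m = 1 << p
        if _registers is not None:
            self.registers = np.asarray(_registers, dtype=np.uint8).copy()
            if self.registers.shape != (self.m,):
                raise ValueError("register array does not match precision")
        else:
            self.registers = np.zeros(self.m, dtype=np.uint8)

    # -- construction -------------------------------------------------
    def add(self, item: str | bytes) -> None:
        h = _hash64(item)
        idx = h >> (_HASH_BITS - self.p)
        rem = h & ((1 << (_HASH_BITS - self.p)) - 1)
        # rank = position of the leftmost 1-bit in the remaining bits
        rank = (_HASH_BITS - self.p) - rem.bit_length() + 1
        if rank > self.registers[idx]:
            self.registers[idx] = rank

    def update(self, items) -> None:
        for it in items:
            self.add(it)

    # -- queries ------------------------------------------------------
    def cardinality(self) -> float:
        m = self.m
        alpha = 0.7213 / (1.0 + 1.079 / m)
        est = alpha * m * m / np.sum(np.exp2(-self.registers.astype(np.float64)))
        if est <= 2.5 * m:
            zeros = int(np.count_nonzero(self.registers == 0))
            if zeros:
                return m * math.log(m / zeros)
        return float(est)

    def union(self, other: "HyperLogLog") -> "HyperLogLog":
        if other.p != self.p:
            raise ValueError("cannot merge sketches of different precision")
        return HyperLogLog(
            self.error_rate, _registers=np.maximum(self.registers, other.registers)
        )

    # -- text serialisation -------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": "hll",
            "error_rate": self.error_rate,
            "registers": base64.b64encode(self.registers.tobytes()).decode(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HyperLogLog":
        regs = np.frombuffer(base64.b64decode(d["registers"]), dtype=np.uint8)
        return cls(d["error_rate"], _registers=regs)


class ExactCardinality:
    """Exact-set stand-in with the HyperLogLog interface."""

    def __init__(self, items=()):
        self.items = set(items)

    def add(self, item) -> None:
        self.items.add(item)

    def update(self, items) -> None:
        self.items.update(items)

    def cardinality(self) -> float:
        return float(len(self.items))

    def union(self, other: "ExactCardinality") -> "ExactCardinality":
        return ExactCardinality(self.items | other.items)

    def to_dict(self) -> dict:
        return {"kind": "exact", "items": sorted(self.items)}

    @classmethod
    def from_dict(cls, d: dict) -> "ExactCardinality":
        return cls(d["items"])


def make_sketch(backend: str, error_rate: float):
    if backend == "hll":
        return HyperLogLog(error_rate)
    if backend == "exact":
        return ExactCardinality()
    raise ValueError(f"unknown sketch backend {backend!r}")


def sketch_from_dict(d: dict):
    return HyperLogLog.from_dict(d) if d["kind"] == "hll" else ExactCardinality.from_dict(d)
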