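"""Baseline samplers: bottom-k MinHash and FracMinHash.

Both follow the single-hash bottom-sketch convention used by the common
genomic sketching tools: bottom-k keeps the ``k_top`` smallest distinct hash
values (fixed-size sketch); FracMinHash keeps every distinct hash at or
below ``scale * 2**64`` (sketch size grows linearly with the number of
distinct elements, binomial(n, scale)).  Both are dependable and mergeable,
and both carry exact frequency counts for retained elements.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .hashing import hash64, hash64_array
from .sketch_core import IncompatibleSketchError

__all__ = [
    "BaselineParams",
    "BaselineSketch",
    "build_minhash",
    "build_fracminhash",
    "merge_baseline",
    "baseline_jaccard",
]

_HASH_RANGE = 1 << 64


@dataclass(frozen=True)
class BaselineParams:
    """Parameters of a baseline sampler.

    algo is "minhash" (bottom-k, parameter ``k_top``) or "fracminhash"
    (retention fraction ``scale`` in (0, 1]); exactly the matching parameter
    must be set.
    """

    algo: str
    k_top: int | None = None
    scale: float | None = None
    seed: int = 0
    kmer_size: int | None = None
    canonical: bool = True

    def __post_init__(self):
        if self.algo == "minhash":
            if self.k_top is None or self.k_top < 1:
                raise ValueError("minhash requires integer k_top >= 1")
            if self.scale is not None:
                raise ValueError("scale is not a parameter of minhash")
        elif self.algo == "fracminhash":
            if self.scale is None or not 0.0 < self.scale <= 1.0:
                raise ValueError("fracminhash requires scale in (0, 1]")
            if self.k_top is not None:
                raise ValueError("k_top is not a parameter of fracminhash")
        else:
            raise ValueError(f"unknown baseline algo: {self.algo!r}")

    @property
    def threshold(self) -> int:
        """FracMinHash retention threshold: keep h <= floor(scale * 2^64)."""
        if self.scale is None:
            raise ValueError("threshold is defined only for fracminhash")
        return min(_HASH_RANGE - 1, int(self.scale * _HASH_RANGE))


class BaselineSketch:
    """Retained distinct hashes with exact frequencies."""

    __slots__ = ("params", "entries", "n_stream", "_heap")

    def __init__(self, params: BaselineParams):
        self.params = params
        self.entries: dict[int, int] = {}  # hash -> frequency
        self.n_stream = 0
        self._heap: list[int] = []  # minhash only: max-heap via negated hashes

    def insert(self, item: bytes) -> None:
        self.insert_hash(hash64(item, self.params.seed))

    def insert_hash(self, h: int, count: int = 1) -> None:
        self.n_stream += count
        cur = self.entries.get(h)
        if cur is not None:
            self.entries[h] = cur + count
            return
        if self.params.algo == "fracminhash":
            if h <= self.params.threshold:
                self.entries[h] = count
            return
        # bottom-k: keep the k_top smallest distinct hashes seen so far
        if len(self.entries) < self.params.k_top:
            self.entries[h] = count
            heapq.heappush(self._heap, -h)
        elif h < -self._heap[0]:
            evicted = -heapq.heappushpop(self._heap, -h)
            del self.entries[evicted]
            self.entries[h] = count

    def sample_size(self) -> int:
        return len(self.entries)

    def hash_set(self) -> set[int]:
        return set(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BaselineSketch):
            return NotImplemented
        return self.params == other.params and self.entries == other.entries


def _bulk_build(hashes, counts, params: BaselineParams) -> BaselineSketch:
    sketch = BaselineSketch(params)
    sketch.n_stream = int(counts.sum())
    if params.algo == "fracminhash":
        keep = hashes <= np.uint64(params.threshold)
    else:
        k = params.k_top
        if hashes.size > k:
            kth = np.partition(hashes, k - 1)[k - 1]
            keep = hashes <= kth
        else:
            keep = np.ones(hashes.shape, dtype=bool)
    sketch.entries = dict(zip(hashes[keep].tolist(), counts[keep].tolist()))
    if params.algo == "minhash":
        sketch._heap = [-h for h in sketch.entries]
        heapq.heapify(sketch._heap)
    return sketch


def _build(stream, params: BaselineParams) -> BaselineSketch:
    if isinstance(stream, np.ndarray) and stream.dtype.kind == "S":
        hashes = hash64_array(stream, params.seed)
        uniq, counts = np.unique(hashes, return_counts=True)
        return _bulk_build(uniq, counts, params)
    sketch = BaselineSketch(params)
    for item in stream:
        sketch.insert(item)
    return sketch


def build_minhash(stream, params: BaselineParams) -> BaselineSketch:
    """Bottom-k sketch: the ``k_top`` smallest distinct hashes of the stream."""
    if params.algo != "minhash":
        raise ValueError("build_minhash requires minhash params")
    return _build(stream, params)


def build_fracminhash(stream, params: BaselineParams) -> BaselineSketch:
    """Scaled sketch: all distinct hashes h <= floor(scale * 2^64)."""
    if params.algo != "fracminhash":
        raise ValueError("build_fracminhash requires fracminhash params")
    return _build(stream, params)


def baseline_sketch_from_hashes(hashes, params: BaselineParams, counts=None) -> BaselineSketch:
    """Baseline sketch from precomputed 64-bit hashes."""
    hashes = np.asarray(hashes, dtype=np.uint64)
    if counts is None:
        hashes, counts = np.unique(hashes, return_counts=True)
    else:
        counts = np.asarray(counts, dtype=np.int64)
    return _bulk_build(hashes, counts, params)


def merge_baseline(a: BaselineSketch, b: BaselineSketch) -> BaselineSketch:
    """Merge two baseline sketches (union, then re-apply the pruning rule)."""
    if a.params != b.params:
        raise IncompatibleSketchError(
            f"baseline parameters differ: {a.params} vs {b.params}"
        )
    combined = dict(a.entries)
    for h, c in b.entries.items():
        combined[h] = combined.get(h, 0) + c
    hashes = np.fromiter(combined.keys(), dtype=np.uint64, count=len(combined))
    counts = np.fromiter(combined.values(), dtype=np.int64, count=len(combined))
    out = _bulk_build(hashes, counts, a.params)
    out.n_stream = a.n_stream + b.n_stream
    return out


def baseline_jaccard(a: BaselineSketch, b: BaselineSketch) -> float:
    """Jaccard estimate from two compatible baseline sketches.

    bottom-k: take the ``k_top`` smallest hashes of the union of the two
    sketches (a bottom-k sketch of A ∪ B) and count the fraction present in
    both sketches.  FracMinHash: plain |a ∩ b| / |a ∪ b| on retained hash
    sets (both sides retain the same hash range).
    """
    if a.params != b.params:
        raise IncompatibleSketchError(
            f"baseline parameters differ: {a.params} vs {b.params}"
        )
    sa, sb = a.hash_set(), b.hash_set()
    union = sa | sb
    if not union:
        raise ValueError("both sketches are empty; Jaccard undefined")
    if a.params.algo == "fracminhash":
        return len(sa & sb) / len(union)
    x = sorted(union)[: a.params.k_top]
    return sum(1 for h in x if h in sa and h in sb) / len(x)
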