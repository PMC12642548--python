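"""MaxGeomHash (MGH) and alpha-MaxGeomHash sketches.

A sketch is a variable-size random sample of the *distinct* elements of a
stream.  Each item is hashed to 64 bits; the number of leading zero bits of
the hash selects a bucket ``i`` (geometric with parameter 1/2), and within
each bucket only the entries with the largest hash suffix ``h_prime`` are
kept:

* **MGH** keeps at most ``b`` entries per bucket, giving an expected sample
  size of ``b*lg(n/b) + b + eps`` for ``n`` distinct elements, with O(1)
  variance.
* **alpha-MGH** lets the capacity of bucket ``i`` grow as
  ``gamma * 2**(beta*i)`` with ``beta = alpha/(1-alpha)``, giving expected
  size ``Theta(n**alpha)``.

Because every keep/evict decision depends only on the hash value, sketches
are order-independent, dependable (an element's membership is decided at its
first occurrence and evicted elements never return, so retained frequency
counts are exact multiset frequencies) and mergeable: merging per-partition
sketches reproduces the sketch of the whole stream exactly.

Two construction paths are provided and produce identical sketches: a
streaming one-pass insert (:meth:`Sketch.insert`), and a vectorized bulk
path (:class:`DistinctHashes`) used by the simulation suite for large inputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .hashing import decompose, decompose_array, hash64, hash64_array

__all__ = [
    "IncompatibleSketchError",
    "SketchParams",
    "BucketEntry",
    "Sketch",
    "DistinctHashes",
    "capacity",
    "build_sketch",
    "sketch_from_hashes",
    "merge",
    "sample_size",
    "max_bucket_index",
    "expected_size_mgh",
    "eb_constant",
    "expected_size_alpha",
]

MAX_BUCKET = 65  # 64-bit hashes: i = zpl + 1 ranges over [1, 65]
_CAP_CEILING = 1 << 62  # capacities beyond any realizable bucket load


class IncompatibleSketchError(ValueError):
    """Raised when combining sketches built under different parameters/seeds."""


@dataclass(frozen=True)
class SketchParams:
    """Algorithm variant and its parameters.

    variant : "mgh" (per-bucket cap ``b``) or "alpha_mgh" (cap
        ``gamma * 2**(beta*i)``, ``beta = alpha/(1-alpha)``).
    seed : hash seed; sketches are comparable only under equal seeds.
    kmer_size / canonical : k-mer settings when sketching sequences
        (``kmer_size=None`` for generic item streams).
    """

    variant: str
    b: int | None = None
    alpha: float | None = None
    gamma: float = 1.0
    seed: int = 0
    kmer_size: int | None = None
    canonical: bool = True

    def __post_init__(self):
        if self.variant == "mgh":
            if self.b is None or self.b < 1:
                raise ValueError("mgh requires integer b >= 1")
            if self.alpha is not None:
                raise ValueError("alpha is not a parameter of mgh")
        elif self.variant == "alpha_mgh":
            if self.alpha is None or not 0.0 < self.alpha < 1.0:
                raise ValueError("alpha_mgh requires alpha strictly in (0, 1)")
            if self.b is not None:
                raise ValueError("b is not a parameter of alpha_mgh")
            if self.gamma <= 0:
                raise ValueError("gamma must be positive")
        else:
            raise ValueError(f"unknown variant: {self.variant!r}")
        if self.kmer_size is not None and self.kmer_size < 1:
            raise ValueError("kmer_size must be a positive integer")

    @property
    def beta(self) -> float:
        if self.alpha is None:
            raise ValueError("beta is defined only for alpha_mgh")
        return self.alpha / (1.0 - self.alpha)


def capacity(i: int, params: SketchParams) -> int:
    """Maximum number of entries retained in bucket ``i``.

    MGH: the constant ``b``.  alpha-MGH: ``gamma * 2**(beta*i)`` rounded to
    the nearest integer (half away from zero), floored at 1.
    """
    if i < 1:
        raise ValueError("bucket index must be >= 1")
    if params.variant == "mgh":
        return params.b
    exponent = math.log2(params.gamma) + params.beta * i
    if exponent >= 62:
        return _CAP_CEILING
    return max(1, math.floor(params.gamma * 2.0 ** (params.beta * i) + 0.5))


@dataclass
class BucketEntry:
    """One sampled distinct element.

    ``h`` is the element key (full 64-bit hash), ``h_prime`` the ranking
    suffix, ``freq`` the exact multiset frequency among retained elements.
    ``payload`` optionally retains the item bytes for debugging; it does not
    take part in equality or serialization.
    """

    h: int
    h_prime: int
    freq: int = 1
    payload: bytes | None = None


class Sketch:
    """A bucketed random sample of the distinct elements of a stream.

    ``buckets`` maps bucket index ``i`` (1..65) to a dict keyed by full hash.
    Within a bucket all hashes share the same zero-prefix length, so ranking
    by ``(h_prime, h)`` coincides with ranking by ``h``; ties are impossible
    between distinct keys.
    """

    __slots__ = ("params", "buckets", "n_stream", "_R")

    def __init__(self, params: SketchParams):
        self.params = params
        self.buckets: dict[int, dict[int, BucketEntry]] = {}
        self.n_stream = 0  # items processed (logging only; not compared)
        self._R = 0

    # -- construction -----------------------------------------------------

    def insert(self, item: bytes, *, keep_payload: bool = False) -> None:
        """Process one stream item (Algorithm: hash, bucket, keep-or-evict)."""
        h = hash64(item, self.params.seed)
        self.insert_hash(h, payload=item if keep_payload else None)

    def insert_hash(self, h: int, count: int = 1, payload: bytes | None = None) -> None:
        """Process ``count`` occurrences of an item with precomputed hash."""
        self.n_stream += count
        d = decompose(h)
        bucket = self.buckets.get(d.i)
        if bucket is None:
            self.buckets[d.i] = {h: BucketEntry(h, d.h_prime, count, payload)}
            if d.i > self._R:
                self._R = d.i
            return
        entry = bucket.get(h)
        if entry is not None:
            entry.freq += count
            return
        cap = capacity(d.i, self.params)
        if len(bucket) < cap:
            bucket[h] = BucketEntry(h, d.h_prime, count, payload)
            return
        # Bucket full: admit only if the suffix outranks the current minimum,
        # evicting it.  The minimum only grows, so evicted keys never return.
        min_h, min_entry = min(bucket.items(), key=lambda kv: kv[1].h_prime)
        if d.h_prime > min_entry.h_prime:
            del bucket[min_h]
            bucket[h] = BucketEntry(h, d.h_prime, count, payload)

    def update(self, stream, *, keep_payload: bool = False) -> None:
        for item in stream:
            self.insert(item, keep_payload=keep_payload)

    # -- queries ----------------------------------------------------------

    @property
    def R(self) -> int:
        """Largest occupied bucket index (0 when empty)."""
        return self._R

    def sample_size(self) -> int:
        return sum(len(b) for b in self.buckets.values())

    def entries(self):
        """Iterate entries in canonical order (bucket asc, h_prime desc)."""
        for i in sorted(self.buckets):
            for entry in sorted(
                self.buckets[i].values(), key=lambda e: (e.h_prime, e.h), reverse=True
            ):
                yield i, entry

    def __len__(self) -> int:
        return self.sample_size()

    def __eq__(self, other) -> bool:
        if not isinstance(other, Sketch):
            return NotImplemented
        if self.params != other.params:
            return False
        if self.buckets.keys() != other.buckets.keys():
            return False
        for i, bucket in self.buckets.items():
            ob = other.buckets[i]
            if bucket.keys() != ob.keys():
                return False
            for h, e in bucket.items():
                oe = ob[h]
                if e.h_prime != oe.h_prime or e.freq != oe.freq:
                    return False
        return True

    def __repr__(self) -> str:
        return (
            f"<Sketch {self.params.variant} size={self.sample_size()} "
            f"R={self.R} n_stream={self.n_stream}>"
        )

    def copy(self) -> "Sketch":
        out = Sketch(self.params)
        out.n_stream = self.n_stream
        out._R = self._R
        out.buckets = {
            i: {h: replace(e) for h, e in bucket.items()}
            for i, bucket in self.buckets.items()
        }
        return out


class DistinctHashes:
    """Bulk view of a hashed stream: distinct hashes with multiplicities.

    Precomputes the bucket decomposition and the within-bucket ranking once;
    :meth:`select`, :meth:`size` and :meth:`sketch` then apply a capacity
    rule in O(n).  Used by the simulation suite where the same hashed stream
    is sketched under several parameter settings.
    """

    def __init__(self, hashes, counts=None):
        hashes = np.asarray(hashes, dtype=np.uint64)
        if counts is None:
            hashes, counts = np.unique(hashes, return_counts=True)
        else:
            counts = np.asarray(counts, dtype=np.int64)
            if counts.shape != hashes.shape:
                raise ValueError("counts must match hashes")
        self.n_distinct = int(hashes.size)
        self.n_stream = int(counts.sum())
        _, i, hp = decompose_array(hashes)
        order = np.lexsort((np.bitwise_not(hashes), i))  # i asc, h desc
        self._h = hashes[order]
        self._hp = hp[order]
        self._i = i[order]
        self._counts = counts[order]
        if self.n_distinct:
            starts = np.flatnonzero(np.r_[True, self._i[1:] != self._i[:-1]])
            sizes = np.diff(np.r_[starts, self.n_distinct])
            self._rank = np.arange(self.n_distinct) - np.repeat(starts, sizes)
            self._uniq_i, self._inv_i = np.unique(self._i, return_inverse=True)
        else:
            self._rank = np.empty(0, dtype=np.int64)
            self._uniq_i = np.empty(0, dtype=np.int64)
            self._inv_i = np.empty(0, dtype=np.int64)

    def _keep_mask(self, params: SketchParams) -> np.ndarray:
        caps = np.array(
            [min(capacity(int(i), params), _CAP_CEILING) for i in self._uniq_i],
            dtype=np.int64,
        )
        return self._rank < caps[self._inv_i]

    def select(self, params: SketchParams):
        """Kept ``(h, h_prime, i, counts)`` arrays, bucket-major, suffix desc."""
        keep = self._keep_mask(params)
        return self._h[keep], self._hp[keep], self._i[keep], self._counts[keep]

    def size(self, params: SketchParams) -> int:
        return int(self._keep_mask(params).sum())

    def sketch(self, params: SketchParams) -> Sketch:
        h, hp, i, counts = self.select(params)
        out = Sketch(params)
        out.n_stream = self.n_stream
        buckets = out.buckets
        for hv, hpv, iv, cv in zip(h.tolist(), hp.tolist(), i.tolist(), counts.tolist()):
            buckets.setdefault(iv, {})[hv] = BucketEntry(hv, hpv, cv)
        out._R = max(buckets) if buckets else 0
        return out


def build_sketch(stream, params: SketchParams, *, keep_payloads: bool = False) -> Sketch:
    """Sketch a finite stream of byte-string items.

    Equivalent to folding :meth:`Sketch.insert` over the stream; the result
    does not depend on stream order.  Numpy byte-string arrays take a
    vectorized path (identical output, no payload retention).
    """
    if isinstance(stream, np.ndarray) and stream.dtype.kind == "S" and not keep_payloads:
        hashes = hash64_array(stream, params.seed)
        return DistinctHashes(hashes).sketch(params)
    sketch = Sketch(params)
    sketch.update(stream, keep_payload=keep_payloads)
    return sketch


def sketch_from_hashes(hashes, params: SketchParams, counts=None) -> Sketch:
    """Sketch from precomputed 64-bit hashes (with optional multiplicities)."""
    return DistinctHashes(hashes, counts).sketch(params)


def _check_compatible(a: SketchParams, b: SketchParams) -> None:
    if a != b:
        raise IncompatibleSketchError(
            f"sketch parameters differ: {a} vs {b}; sketches are only "
            "comparable under identical variant, parameters and hash seed"
        )


def merge(a: Sketch, b: Sketch) -> Sketch:
    """Merge two sketches of (parts of) a stream.

    Per bucket, entries are united by hash (frequencies of shared hashes are
    summed) and pruned back to the bucket capacity, keeping the largest
    suffixes.  For disjoint stream partitions this equals the direct sketch
    of the concatenated stream, including frequencies; for overlapping
    streams the element content is still exact (multiset-union semantics)
    but summed counts double-count the overlap.
    """
    _check_compatible(a.params, b.params)
    out = Sketch(a.params)
    out.n_stream = a.n_stream + b.n_stream
    for i in set(a.buckets) | set(b.buckets):
        combined: dict[int, BucketEntry] = {}
        for src in (a.buckets.get(i), b.buckets.get(i)):
            if not src:
                continue
            for h, e in src.items():
                cur = combined.get(h)
                if cur is None:
                    combined[h] = BucketEntry(h, e.h_prime, e.freq, e.payload)
                else:
                    cur.freq += e.freq
                    if cur.payload is None:
                        cur.payload = e.payload
        cap = capacity(i, a.params)
        if len(combined) > cap:
            kept = sorted(combined.values(), key=lambda e: e.h_prime, reverse=True)[:cap]
            combined = {e.h: e for e in kept}
        out.buckets[i] = combined
    out._R = max(out.buckets) if out.buckets else 0
    return out


def sample_size(sketch: Sketch) -> int:
    """Total number of retained entries, summed over buckets."""
    return sketch.sample_size()


def max_bucket_index(sketch: Sketch) -> int:
    """Largest occupied bucket index R (0 for an empty sketch)."""
    return sketch.R


# -- theoretical size laws -----------------------------------------------


def expected_size_mgh(n: float, b: int) -> float:
    """Leading terms of the expected MGH sample size: ``b*lg(n/b) + b``.

    The exact expectation carries an additional bounded error term (see
    :func:`eb_constant`), omitted here as in the size-law plots.
    """
    if n < b:
        warnings.warn(
            "expected_size_mgh evaluated with n < b; the asymptotic formula "
            "is extrapolated below its regime",
            stacklevel=2,
        )
    return b * math.log2(n / b) + b


def eb_constant(b: int) -> float:
    """The constant E_b bounding the size-law error term:
    ``sum_{m=0}^{b-1} (b - m) * exp(-b) * b**m / m!``.

    Evaluated through the Poisson(b) pmf for numerical stability at large b.
    Not used by any estimator; exposed for the size analysis.
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    m = np.arange(b)
    return float(np.sum((b - m) * stats.poisson.pmf(m, b)))


def expected_size_alpha(n: float, alpha: float) -> float:
    """Leading term of the expected alpha-MGH sample size:
    ``(2**(1/(1-alpha)) - 1) / (2**(alpha/(1-alpha)) - 1) * n**alpha``
    (the O(log n) correction is omitted).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be strictly in (0, 1)")
    coeff = (2.0 ** (1.0 / (1.0 - alpha)) - 1.0) / (2.0 ** (alpha / (1.0 - alpha)) - 1.0)
    return coeff * n**alpha
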