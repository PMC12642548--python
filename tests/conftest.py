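"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from kmersketch.hashing import decompose, hash64
from kmersketch.sketch_core import SketchParams, capacity


def brute_force_buckets(items, params):
    """Independent oracle for the sketch content of a stream.

    Hashes every item, groups distinct hashes by bucket index, and keeps per
    bucket the ``capacity(i)`` hashes with the largest suffix, with exact
    multiset frequencies.  Returns ``{i: {h: freq}}``.  Sorts everything --
    no streaming, no eviction logic shared with the implementation.
    """
    freqs = Counter()
    for item in items:
        freqs[hash64(item, params.seed)] += 1
    per_bucket: dict[int, list[tuple[int, int]]] = {}
    for h in freqs:
        d = decompose(h)
        per_bucket.setdefault(d.i, []).append((d.h_prime, h))
    out = {}
    for i, entries in per_bucket.items():
        entries.sort(reverse=True)
        kept = entries[: capacity(i, params)]
        out[i] = {h: freqs[h] for _, h in kept}
    return out


def sketch_as_dict(sketch):
    """Sketch content in the oracle's ``{i: {h: freq}}`` form."""
    return {
        i: {h: e.freq for h, e in bucket.items()}
        for i, bucket in sketch.buckets.items()
        if bucket
    }


def random_stream(rng, n_distinct, max_repeat=3, length=8):
    """A shuffled stream over ``n_distinct`` random items with duplicates."""
    alphabet = np.frombuffer(b"ACGTacgt0123456789", dtype=np.uint8)
    items = set()
    while len(items) < n_distinct:
        draw = alphabet[rng.integers(0, alphabet.size, size=(n_distinct, length))]
        items.update(np.frombuffer(draw.tobytes(), dtype=f"S{length}").tolist())
    items = sorted(items)[:n_distinct]
    stream = []
    for item in items:
        stream.extend([item] * int(rng.integers(1, max_repeat + 1)))
    rng.shuffle(stream)
    return stream


@pytest.fixture
def rng():
    return np.random.default_rng(20250926)


@pytest.fixture
def mgh_params():
    return SketchParams("mgh", b=4, seed=11)
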