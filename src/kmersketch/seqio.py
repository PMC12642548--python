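"""FASTA/FASTQ ingestion, canonical k-mer streaming and sketch files.

Sequences are uppercased and decomposed into length-k windows over the
A/C/G/T alphabet; windows containing any other character (N, IUPAC ambiguity
codes, ...) are skipped.  With canonicalization on, each window is replaced
by the lexicographic minimum of itself and its reverse complement, so a
sequence and its reverse complement produce the same k-mer multiset.

Sketches are stored as diffable plain text (one file per sketch):

    #kmersketch v1 algo=mgh b=90 gamma=1.0 seed=42 hash=smx64 k=31 canonical=1
    <bucket>\t<hash as 16 lowercase hex digits>\t<count>

with entries sorted by bucket ascending, then suffix (equivalently hash)
descending.  The writer is canonical -- equal sketches serialize to
byte-identical files -- and reading is transparent to gzip compression.
Baseline sketches share the format with ``algo=minhash k_top=...`` or
``algo=fracminhash scale=...`` and a single pseudo-bucket 0.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .hashing import HASH_NAME, decompose
from .baselines import BaselineParams, BaselineSketch
from .sketch_core import (
    BucketEntry,
    DistinctHashes,
    Sketch,
    SketchParams,
    capacity,
    merge,
)

__all__ = [
    "KmerConfig",
    "SketchFormatError",
    "canonical_kmers",
    "sketch_file",
    "write_sketch",
    "read_sketch",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")
_VALID = frozenset(b"ACGT")
_CHUNK_KMERS = 1 << 20  # k-mers buffered before a vectorized sketch update


class SketchFormatError(ValueError):
    """Raised on malformed or inconsistent sketch files."""


@dataclass(frozen=True)
class KmerConfig:
    """k-mer extraction settings (length and strand canonicalization)."""

    k: int = 31
    canonical: bool = True

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be a positive integer")


def canonical_kmers(sequence, config: KmerConfig = KmerConfig()):
    """Yield the valid k-mers of a sequence as byte strings.

    Input may be str or bytes and is uppercased first.  Only windows made
    entirely of A/C/G/T are emitted; with ``config.canonical`` each window
    is the lexicographic minimum of itself and its reverse complement.
    Sequences shorter than k yield nothing.
    """
    seq = sequence.encode() if isinstance(sequence, str) else bytes(sequence)
    seq = seq.upper()
    k = config.k
    run = 0
    for idx in range(len(seq)):
        run = run + 1 if seq[idx] in _VALID else 0
        if run >= k:
            w = seq[idx - k + 1 : idx + 1]
            if config.canonical:
                rc = w.translate(_COMPLEMENT)[::-1]
                yield w if w <= rc else rc
            else:
                yield w


def _open_text(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "r")


def _detect_format(handle) -> str:
    pos = handle.tell()
    first = ""
    for line in handle:
        if line.strip():
            first = line.lstrip()[0]
            break
    handle.seek(pos)
    if first == ">" or first == "":  # empty input: an empty FASTA stream
        return "fasta"
    if first == "@":
        return "fastq"
    raise SketchFormatError("input is neither FASTA nor FASTQ (no '>' or '@' record)")


def sketch_file(path, params: SketchParams) -> Sketch:
    """Stream the canonical k-mers of a FASTA/FASTQ file into one sketch.

    Multi-record files form a single stream (one sketch per file).  Input
    may be gzip-compressed.  k-mers are buffered and folded in vectorized
    chunks; chunk sketches are merged, which reproduces the direct
    whole-stream sketch exactly (retention is decided globally by hash rank,
    and per-chunk counts of retained elements sum to the true frequencies).
    """
    if params.kmer_size is None:
        raise ValueError("params.kmer_size must be set to sketch sequence files")
    config = KmerConfig(params.kmer_size, params.canonical)
    sketch = Sketch(params)
    buffer: list[bytes] = []
    n_records = 0
    try:
        with _open_text(path) as handle:
            fmt = _detect_format(handle)
            for record in SeqIO.parse(handle, fmt):
                n_records += 1
                buffer.extend(canonical_kmers(str(record.seq), config))
                if len(buffer) >= _CHUNK_KMERS:
                    sketch = merge(sketch, _sketch_chunk(buffer, params))
                    buffer.clear()
    except SketchFormatError:
        raise
    except (OSError, ValueError) as exc:
        raise SketchFormatError(
            f"failed to read {path!s} (record {n_records}): {exc}"
        ) from exc
    if buffer:
        sketch = merge(sketch, _sketch_chunk(buffer, params))
    logger.info(
        "sketched %s: %d records, %d k-mers, sample size %d",
        path,
        n_records,
        sketch.n_stream,
        sketch.sample_size(),
    )
    return sketch


def _sketch_chunk(kmers: list[bytes], params: SketchParams) -> Sketch:
    arr = np.array(kmers, dtype=f"S{params.kmer_size}")
    from .hashing import hash64_array

    return DistinctHashes(hash64_array(arr, params.seed)).sketch(params)


# -- sketch v1 text format ------------------------------------------------


def _float_repr(x: float) -> str:
    return repr(float(x))


def _header(params) -> str:
    if isinstance(params, SketchParams):
        if params.variant == "mgh":
            algo, parameter = "mgh", f"b={params.b}"
        else:
            algo, parameter = "amgh", f"alpha={_float_repr(params.alpha)}"
        gamma = params.gamma
    else:
        if params.algo == "minhash":
            algo, parameter = "minhash", f"k_top={params.k_top}"
        else:
            algo, parameter = "fracminhash", f"scale={_float_repr(params.scale)}"
        gamma = 1.0
    k = params.kmer_size if params.kmer_size is not None else 0
    return (
        f"#kmersketch v1 algo={algo} {parameter} gamma={_float_repr(gamma)} "
        f"seed={params.seed} hash={HASH_NAME} k={k} "
        f"canonical={1 if params.canonical else 0}"
    )


def write_sketch(sketch, path) -> None:
    """Serialize a sketch (MGH/alpha-MGH or baseline) canonically.

    Equal sketches always produce byte-identical files: entries are emitted
    bucket-ascending then suffix-descending with fixed number formatting.
    """
    lines = [_header(sketch.params)]
    if isinstance(sketch, Sketch):
        for i, entry in sketch.entries():
            lines.append(f"{i}\t{entry.h:016x}\t{entry.freq}")
    else:
        for h in sorted(sketch.entries, reverse=True):
            lines.append(f"0\t{h:016x}\t{sketch.entries[h]}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_header(line: str):
    tokens = line.strip().split()
    if len(tokens) < 2 or tokens[0] != "#kmersketch" or tokens[1] != "v1":
        raise SketchFormatError(f"not a kmersketch v1 file: {line.strip()!r}")
    fields = {}
    for tok in tokens[2:]:
        if "=" not in tok:
            raise SketchFormatError(f"malformed header token {tok!r}")
        key, _, value = tok.partition("=")
        fields[key] = value
    try:
        algo = fields["algo"]
        seed = int(fields["seed"])
        k = int(fields["k"])
        canonical = fields["canonical"] == "1"
        hash_name = fields["hash"]
    except KeyError as exc:
        raise SketchFormatError(f"header missing field {exc}") from exc
    if hash_name != HASH_NAME:
        raise SketchFormatError(
            f"sketch built with hash {hash_name!r}; this build supports {HASH_NAME!r}"
        )
    kmer_size = k if k > 0 else None
    try:
        if algo == "mgh":
            return SketchParams(
                "mgh", b=int(fields["b"]), gamma=float(fields["gamma"]),
                seed=seed, kmer_size=kmer_size, canonical=canonical,
            )
        if algo == "amgh":
            return SketchParams(
                "alpha_mgh", alpha=float(fields["alpha"]),
                gamma=float(fields["gamma"]), seed=seed,
                kmer_size=kmer_size, canonical=canonical,
            )
        if algo == "minhash":
            return BaselineParams(
                "minhash", k_top=int(fields["k_top"]), seed=seed,
                kmer_size=kmer_size, canonical=canonical,
            )
        if algo == "fracminhash":
            return BaselineParams(
                "fracminhash", scale=float(fields["scale"]), seed=seed,
                kmer_size=kmer_size, canonical=canonical,
            )
    except (KeyError, ValueError) as exc:
        raise SketchFormatError(f"malformed header for algo={algo!r}: {exc}") from exc
    raise SketchFormatError(f"unknown algo {algo!r} in header")


def read_sketch(path):
    """Parse a sketch v1 file (gzip transparent) back into a sketch object.

    Validates the entry grammar, bucket/hash consistency, capacity bounds
    and hash uniqueness; errors name the offending line.
    Round-trip laws: ``read(write(S)) == S`` and re-writing a read file is
    byte-identical.
    """
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise SketchFormatError(f"{path!s}: empty file")
    params = _parse_header(lines[0])
    is_geometric = isinstance(params, SketchParams)
    sketch = Sketch(params) if is_geometric else BaselineSketch(params)
    seen: set[int] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise SketchFormatError(f"{path!s}:{lineno}: expected 3 tab-separated fields")
        try:
            bucket = int(parts[0])
            if len(parts[1]) != 16 or parts[1] != parts[1].lower():
                raise ValueError("hash must be 16 lowercase hex digits")
            h = int(parts[1], 16)
            count = int(parts[2])
        except ValueError as exc:
            raise SketchFormatError(f"{path!s}:{lineno}: {exc}") from exc
        if count < 1:
            raise SketchFormatError(f"{path!s}:{lineno}: count must be >= 1")
        if h in seen:
            raise SketchFormatError(f"{path!s}:{lineno}: duplicate hash {parts[1]}")
        seen.add(h)
        if is_geometric:
            d = decompose(h)
            if d.i != bucket:
                raise SketchFormatError(
                    f"{path!s}:{lineno}: hash belongs to bucket {d.i}, not {bucket}"
                )
            bucket_map = sketch.buckets.setdefault(bucket, {})
            if len(bucket_map) >= capacity(bucket, params):
                raise SketchFormatError(
                    f"{path!s}:{lineno}: bucket {bucket} exceeds its capacity"
                )
            bucket_map[h] = BucketEntry(h, d.h_prime, count)
        else:
            if bucket != 0:
                raise SketchFormatError(
                    f"{path!s}:{lineno}: baseline sketches use bucket 0"
                )
            sketch.entries[h] = count
    if is_geometric:
        sketch._R = max(sketch.buckets) if sketch.buckets else 0
    elif params.algo == "minhash":
        if len(sketch.entries) > params.k_top:
            raise SketchFormatError(f"{path!s}: more than k_top entries")
        import heapq

        sketch._heap = [-h for h in sketch.entries]
        heapq.heapify(sketch._heap)
    else:
        bad = [h for h in sketch.entries if h > params.threshold]
        if bad:
            raise SketchFormatError(
                f"{path!s}: hash above the fracminhash retention threshold"
            )
    return sketch
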