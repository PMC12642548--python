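"""Similarity estimation from a pair of sketches.

Two sketches S = MGH(A) and T = MGH(B) built under the same hash seed cannot
be compared by naive set operations: S ∪ T is not a random sample of A ∪ B.
The refinement step restores that property bucket by bucket: U_i is the
capacity-i truncation of S_i ∪ T_i (keeping the largest suffixes), so that
U = ⋃ U_i is a uniform random sample of A ∪ B, and V = U ∩ S ∩ T equals
A ∩ B ∩ U.  |V|/|U| is then an unbiased estimator of the Jaccard index, and
the restricted counts |U ∩ S|, |U ∩ T| play the roles of |A| and |B| within
the sample, from which containment, Sørensen–Dice, cosine and the Kulczynski
coefficients follow.

Note V is *not* the raw bucket intersection S_i ∩ T_i: a shared element may
be pushed out of U_i by larger union suffixes, and only the U-restricted
intersection keeps the estimator unbiased.

Jaccard estimates can be converted to a genome-wide average mutation rate
(one minus average nucleotide identity) under a simple independent-site
mutation model at k-mer length k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sketch_core import Sketch, SketchParams, _check_compatible, capacity

__all__ = [
    "MEASURES",
    "UndefinedSimilarityError",
    "RefinedComparison",
    "SimilarityReport",
    "refine",
    "estimate",
    "jaccard",
    "mutation_rate_from_jaccard",
    "distance_matrix",
    "write_comparisons_tsv",
]

MEASURES = (
    "jaccard",
    "containment_ab",
    "containment_ba",
    "sorensen_dice",
    "cosine",
    "kulczynski1",
    "kulczynski2",
)


class UndefinedSimilarityError(ValueError):
    """Raised when a similarity measure is undefined (e.g. empty refined union)."""


@dataclass
class RefinedComparison:
    """Counts from the refined union of two sketches.

    u_size = |U| (refined union sample), v_size = |V| (in both sketches),
    a_restricted = |U ∩ S|, b_restricted = |U ∩ T|.  Every refined element
    came from at least one sketch, so
    ``a_restricted + b_restricted - v_size == u_size``.
    """

    u_size: int
    v_size: int
    a_restricted: int
    b_restricted: int
    params: SketchParams
    per_bucket: dict[int, dict] | None = None


@dataclass
class SimilarityReport:
    measure: str
    estimate: float
    u_size: int
    v_size: int
    params: SketchParams


def refine(s: Sketch, t: Sketch, *, per_bucket: bool = False) -> RefinedComparison:
    """Refine two compatible sketches into the counts (|U|, |V|, |U∩S|, |U∩T|).

    Per bucket i, U_i holds the capacity(i) entries of S_i ∪ T_i with the
    largest suffix; V_i = U_i ∩ S_i ∩ T_i.  With ``per_bucket=True`` the
    result also records, per bucket, the U_i member hashes and counts.
    """
    _check_compatible(s.params, t.params)
    u = v = a = b = 0
    detail: dict[int, dict] | None = {} if per_bucket else None
    for i in sorted(set(s.buckets) | set(t.buckets)):
        sb = s.buckets.get(i, {})
        tb = t.buckets.get(i, {})
        union: dict[int, int] = {h: e.h_prime for h, e in sb.items()}
        for h, e in tb.items():
            union.setdefault(h, e.h_prime)
        cap = capacity(i, s.params)
        if len(union) > cap:
            members = sorted(union, key=union.__getitem__, reverse=True)[:cap]
        else:
            members = sorted(union, key=union.__getitem__, reverse=True)
        u_i = len(members)
        v_i = a_i = b_i = 0
        for h in members:
            in_s = h in sb
            in_t = h in tb
            a_i += in_s
            b_i += in_t
            v_i += in_s and in_t
        u += u_i
        v += v_i
        a += a_i
        b += b_i
        if detail is not None:
            detail[i] = {"u_hashes": members, "u": u_i, "v": v_i, "a": a_i, "b": b_i}
    return RefinedComparison(u, v, a, b, s.params, detail)


def estimate(rc: RefinedComparison, measure: str = "jaccard") -> SimilarityReport:
    """Evaluate a similarity measure on refined counts.

    With u = |U|, v = |V|, a = |U∩S|, b = |U∩T|:
    jaccard = v/u, containment_ab = v/a, containment_ba = v/b,
    sorensen_dice = 2v/(a+b), cosine = v/sqrt(a*b),
    kulczynski1 = min(1, v/(u-v)) (1 when v == u),
    kulczynski2 = (v/2)(1/a + 1/b).
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    u, v, a, b = rc.u_size, rc.v_size, rc.a_restricted, rc.b_restricted
    if u == 0:
        raise UndefinedSimilarityError(
            "refined union is empty (two empty sketches); similarity undefined"
        )
    if measure == "jaccard":
        value = v / u
    elif measure == "containment_ab":
        if a == 0:
            raise UndefinedSimilarityError("containment_ab undefined: |U ∩ S| = 0")
        value = v / a
    elif measure == "containment_ba":
        if b == 0:
            raise UndefinedSimilarityError("containment_ba undefined: |U ∩ T| = 0")
        value = v / b
    elif measure == "sorensen_dice":
        value = 2 * v / (a + b)
    elif measure == "cosine":
        if a == 0 or b == 0:
            raise UndefinedSimilarityError("cosine undefined: a restricted count is 0")
        value = v / math.sqrt(a * b)
    elif measure == "kulczynski1":
        value = 1.0 if v == u else min(1.0, v / (u - v))
    else:  # kulczynski2
        if a == 0 or b == 0:
            raise UndefinedSimilarityError(
                "kulczynski2 undefined: a restricted count is 0"
            )
        value = 0.5 * v * (1.0 / a + 1.0 / b)
    return SimilarityReport(measure, value, u, v, rc.params)


def jaccard(s: Sketch, t: Sketch) -> float:
    """Unbiased Jaccard estimate |V|/|U| from two compatible sketches."""
    return estimate(refine(s, t), "jaccard").estimate


def mutation_rate_from_jaccard(j: float, k: int) -> float:
    """Genome-wide average mutation rate from a k-mer Jaccard index.

    Under a simple independent-site mutation model, two genomes at per-site
    mutation rate r share a fraction (1-r)^k of their k-mers, giving
    ``r = 1 - (2j/(1+j))**(1/k)``; ANI = 1 - r.
    """
    if not 0.0 <= j <= 1.0:
        raise ValueError(f"Jaccard index must lie in [0, 1], got {j}")
    if k < 1:
        raise ValueError("k must be a positive integer")
    return 1.0 - (2.0 * j / (1.0 + j)) ** (1.0 / k) if j > 0 else 1.0


def distance_matrix(sketches: list[Sketch], k: int) -> np.ndarray:
    """Pairwise mutation-rate distances from k-mer sketches.

    ``d[p, q] = mutation_rate_from_jaccard(jaccard(p, q), k)``; symmetric
    with a zero diagonal.
    """
    m = len(sketches)
    d = np.zeros((m, m), dtype=float)
    for p in range(m):
        for q in range(p + 1, m):
            d[p, q] = d[q, p] = mutation_rate_from_jaccard(
                jaccard(sketches[p], sketches[q]), k
            )
    return d


def write_comparisons_tsv(path, rows) -> None:
    """Write comparison rows as TSV with columns
    name_a, name_b, measure, estimate, u_size, v_size."""
    with open(path, "w") as fh:
        fh.write("name_a\tname_b\tmeasure\testimate\tu_size\tv_size\n")
        for name_a, name_b, measure, value, u, v in rows:
            fh.write(f"{name_a}\t{name_b}\t{measure}\t{value:.10g}\t{u}\t{v}\n")
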