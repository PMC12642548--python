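"""Refined-union similarity estimation and the mutation-rate conversion."""

import numpy as np
import pytest

from kmersketch.hashing import hash64
from kmersketch.sketch_core import (
    IncompatibleSketchError,
    Sketch,
    SketchParams,
    build_sketch,
    merge,
)
from kmersketch.similarity import (
    MEASURES,
    UndefinedSimilarityError,
    distance_matrix,
    estimate,
    jaccard,
    mutation_rate_from_jaccard,
    refine,
)

from conftest import random_stream


def _bucket1(suffix: int) -> int:
    """Hash landing in bucket 1 with the given suffix."""
    return (1 << 63) + suffix


def _sketch_with(params, hashes):
    sk = Sketch(params)
    for h in hashes:
        sk.insert_hash(h)
    return sk


class TestRefine:
    def test_self_comparison(self, rng, mgh_params):
        sk = build_sketch(random_stream(rng, 100), mgh_params)
        rc = refine(sk, sk)
        n = sk.sample_size()
        assert (rc.u_size, rc.v_size, rc.a_restricted, rc.b_restricted) == (n, n, n, n)

    def test_disjoint_sets_have_empty_intersection(self, rng, mgh_params):
        a = build_sketch([b"A%d" % i for i in range(200)], mgh_params)
        b = build_sketch([b"B%d" % i for i in range(200)], mgh_params)
        assert refine(a, b).v_size == 0

    def test_shared_element_pushed_out_of_refined_union(self):
        """b=2, one bucket: A suffixes {10, 5}, B suffixes {8, 5} with the
        suffix-5 element shared.  U = {10, 8}, so V is empty even though the
        raw bucket intersection is not."""
        params = SketchParams("mgh", b=2)
        a = _sketch_with(params, [_bucket1(10), _bucket1(5)])
        b = _sketch_with(params, [_bucket1(8), _bucket1(5)])
        rc = refine(a, b, per_bucket=True)
        assert rc.u_size == 2 and rc.v_size == 0
        assert rc.a_restricted == 1 and rc.b_restricted == 1
        assert rc.per_bucket[1]["u_hashes"] == [_bucket1(10), _bucket1(8)]
        assert estimate(rc, "jaccard").estimate == 0.0

    def test_counts_are_consistent(self, rng, mgh_params):
        stream = random_stream(rng, 400)
        a = build_sketch(stream[:350], mgh_params)
        b = build_sketch(stream[200:], mgh_params)
        rc = refine(a, b)
        assert rc.v_size <= min(rc.a_restricted, rc.b_restricted) <= rc.u_size
        assert rc.a_restricted + rc.b_restricted - rc.v_size == rc.u_size

    def test_union_identity(self, rng, mgh_params):
        """The refined union U equals, bucket for bucket, both merge(S, T)
        and the direct sketch of A ∪ B built under the same seed."""
        items_a = [b"a%04d" % i for i in range(600)]
        items_b = [b"b%04d" % i for i in range(300)] + items_a[:300]
        a = build_sketch(items_a, mgh_params)
        b = build_sketch(items_b, mgh_params)
        rc = refine(a, b, per_bucket=True)
        u_content = {i: set(d["u_hashes"]) for i, d in rc.per_bucket.items() if d["u"]}
        merged = merge(a, b)
        direct = build_sketch(sorted(set(items_a) | set(items_b)), mgh_params)
        assert u_content == {i: set(bk) for i, bk in merged.buckets.items() if bk}
        assert u_content == {i: set(bk) for i, bk in direct.buckets.items() if bk}

    def test_incompatible_rejected(self):
        a = Sketch(SketchParams("mgh", b=2, seed=1))
        b = Sketch(SketchParams("mgh", b=3, seed=1))
        with pytest.raises(IncompatibleSketchError):
            refine(a, b)

    def test_refined_union_is_uniform_sample(self):
        """For a fixed 200-element union and b=5, every element's inclusion
        frequency in U over 2000 hash seeds matches the common inclusion
        probability within 5 standard errors."""
        items = [b"elem%03d" % i for i in range(200)]
        a_items, b_items = items[:120], items[80:]
        trials = 2000
        counts = {item: 0 for item in items}
        for seed in range(trials):
            params = SketchParams("mgh", b=5, seed=seed)
            rc = refine(
                build_sketch(a_items, params),
                build_sketch(b_items, params),
                per_bucket=True,
            )
            member_hashes = set().union(
                *(d["u_hashes"] for d in rc.per_bucket.values())
            )
            for item in items:
                if hash64(item, seed) in member_hashes:
                    counts[item] += 1
        freqs = np.array([counts[item] / trials for item in items])
        p = freqs.mean()
        se = np.sqrt(p * (1 - p) / trials)
        assert np.all(np.abs(freqs - p) <= 5 * se)


class TestEstimate:
    def test_identical_sketches_are_maximally_similar(self, rng, mgh_params):
        sk = build_sketch(random_stream(rng, 100), mgh_params)
        rc = refine(sk, sk)
        for measure in MEASURES:
            assert estimate(rc, measure).estimate == pytest.approx(1.0)

    def test_formulas_on_fixed_counts(self):
        from kmersketch.similarity import RefinedComparison

        rc = RefinedComparison(10, 4, 7, 7, SketchParams("mgh", b=5))
        assert estimate(rc, "jaccard").estimate == pytest.approx(0.4)
        assert estimate(rc, "containment_ab").estimate == pytest.approx(4 / 7)
        assert estimate(rc, "sorensen_dice").estimate == pytest.approx(8 / 14)
        assert estimate(rc, "cosine").estimate == pytest.approx(4 / 7)
        assert estimate(rc, "kulczynski1").estimate == pytest.approx(4 / 6)
        assert estimate(rc, "kulczynski2").estimate == pytest.approx(4 / 7)

    def test_subset_containment_is_one(self):
        params = SketchParams("mgh", b=8, seed=4)
        universe = [b"u%03d" % i for i in range(300)]
        a = build_sketch(universe[:100], params)
        b = build_sketch(universe, params)
        assert estimate(refine(a, b), "containment_ab").estimate == pytest.approx(1.0)

    def test_symmetry_and_range(self, rng, mgh_params):
        stream = random_stream(rng, 300)
        a = build_sketch(stream[:250], mgh_params)
        b = build_sketch(stream[100:], mgh_params)
        assert jaccard(a, b) == jaccard(b, a)
        rc = refine(a, b)
        for measure in MEASURES:
            assert 0.0 <= estimate(rc, measure).estimate <= 1.0

    def test_empty_comparison_raises(self, mgh_params):
        rc = refine(Sketch(mgh_params), Sketch(mgh_params))
        with pytest.raises(UndefinedSimilarityError):
            estimate(rc, "jaccard")

    def test_unknown_measure_rejected(self, rng, mgh_params):
        sk = build_sketch(random_stream(rng, 10), mgh_params)
        with pytest.raises(ValueError):
            estimate(refine(sk, sk), "dice")


class TestMutationRate:
    def test_boundaries(self):
        assert mutation_rate_from_jaccard(1.0, 31) == pytest.approx(0.0)
        assert mutation_rate_from_jaccard(0.0, 31) == pytest.approx(1.0)

    def test_halfway_value(self):
        assert mutation_rate_from_jaccard(0.5, 31) == pytest.approx(0.01300, abs=5e-5)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            mutation_rate_from_jaccard(1.5, 31)
        with pytest.raises(ValueError):
            mutation_rate_from_jaccard(-0.1, 31)


class TestDistanceMatrix:
    def test_single_sketch(self, rng, mgh_params):
        sk = build_sketch(random_stream(rng, 50), mgh_params)
        np.testing.assert_array_equal(distance_matrix([sk], 31), np.zeros((1, 1)))

    def test_duplicate_sketches_have_zero_distance(self, rng, mgh_params):
        sk = build_sketch(random_stream(rng, 200), mgh_params)
        d = distance_matrix([sk, sk.copy()], 31)
        assert d[0, 1] == pytest.approx(0.0)

    def test_matches_exact_jaccard_on_known_overlaps(self):
        """Three synthetic sets with known pairwise overlaps: sketch-based
        distances match the brute-force exact Jaccard converted through the
        same model, within estimator noise."""
        params = SketchParams("mgh", b=60, seed=9)
        universe = [b"w%05d" % i for i in range(3000)]
        sets = [universe[:2000], universe[1000:2800], universe[1500:3000]]
        sketches = [build_sketch(s, params) for s in sets]
        d = distance_matrix(sketches, 31)
        for p in range(3):
            for q in range(p + 1, 3):
                sp, sq = set(sets[p]), set(sets[q])
                exact = mutation_rate_from_jaccard(
                    len(sp & sq) / len(sp | sq), 31
                )
                assert d[p, q] == pytest.approx(exact, abs=2e-3)
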