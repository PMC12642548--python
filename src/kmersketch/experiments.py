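"""Synthetic-data generators and the simulation suite.

Three Monte Carlo experiments validate the samplers against theory, plus a
small phylogenetic pipeline:

* :func:`size_experiment` -- empirical sample sizes vs the theoretical size
  laws, over a grid of n and parameter settings, 50 hash seeds each.
* :func:`jaccard_sweep` -- Jaccard estimation quality over the full [0, 1]
  similarity range, summarized as a per-setting coefficient of
  determination R^2 about the identity line (the realized Jaccard of each
  generated pair is the truth; R^2 = 1 - SS_res / SS_tot).
* :func:`mse_experiment` -- mean squared error of the Jaccard estimate at a
  fixed true similarity, across MinHash / FracMinHash / MGH / alpha-MGH and
  a grid of set sizes.
* :func:`upgma_newick` and :func:`tree_experiment` -- UPGMA similarity trees
  from pairwise mutation-rate distances, exercised on synthetic genomes
  mutated from a common root sequence.

Synthetic sets are distinct alphanumeric strings of length 10; a pair with
target Jaccard j shares ``round(2*n*j/(1+j))`` of its elements, so the
realized Jaccard ``shared / (2n - shared)`` differs from the target only by
rounding.  Every experiment is fully determined by its arguments and master
seed; internal hash seeds are drawn below 2^31 from a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baselines import BaselineParams, baseline_sketch_from_hashes, baseline_jaccard
from .hashing import hash64_array
from .similarity import distance_matrix, estimate, refine
from .sketch_core import (
    DistinctHashes,
    SketchParams,
    expected_size_alpha,
    expected_size_mgh,
)

__all__ = [
    "ALPHANUMERIC",
    "PairSpec",
    "ExperimentResult",
    "random_string_set",
    "pair_with_jaccard",
    "size_experiment",
    "jaccard_sweep",
    "mse_experiment",
    "upgma_newick",
    "random_dna",
    "mutate_sequence",
    "tree_experiment",
]

ALPHANUMERIC = (
    b"ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)
_STRING_LENGTH = 10
_SEED_BOUND = 2**31


@dataclass(frozen=True)
class PairSpec:
    """A generated set pair: sizes, target and realized Jaccard."""

    n: int
    j_target: float
    seed: int
    shared: int

    @property
    def realized_jaccard(self) -> float:
        if self.n == 0:
            return 1.0
        return self.shared / (2 * self.n - self.shared)


@dataclass
class ExperimentResult:
    """Per-trial records (``data``), aggregated ``summary`` and the config."""

    data: pd.DataFrame
    summary: pd.DataFrame
    config: dict


def random_string_set(n: int, seed: int, length: int = _STRING_LENGTH) -> np.ndarray:
    """Exactly ``n`` distinct alphanumeric byte strings of the given length.

    Returns a numpy ``S<length>`` array (sorted); deterministic per seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(ALPHANUMERIC, dtype=np.uint8)
    out = np.empty(0, dtype=f"S{length}")
    while out.size < n:
        need = n - out.size
        draw = alphabet[rng.integers(0, alphabet.size, size=(need, length))]
        chunk = np.frombuffer(draw.tobytes(), dtype=f"S{length}")
        out = np.unique(np.concatenate([out, chunk]))
    return out[:n]


def pair_with_jaccard(n: int, j_target: float, seed: int):
    """Generate a pair of n-element sets with a prescribed Jaccard index.

    Returns ``(A, B, spec)`` where A and B are ``S10`` arrays sharing
    ``spec.shared`` elements; the realized Jaccard is within one rounding
    step of the target.
    """
    if not 0.0 <= j_target <= 1.0:
        raise ValueError("j_target must lie in [0, 1]")
    shared = int(np.floor(2 * n * j_target / (1 + j_target) + 0.5))
    total = 2 * n - shared
    strings = random_string_set(total, seed)
    a = strings[:n]
    b = strings[total - n :]
    return a, b, PairSpec(n, j_target, seed, shared)


def _geometric_settings(mgh_b, alpha_values):
    settings = []
    for b in mgh_b:
        settings.append((f"mgh_b{b}", "mgh", {"b": int(b)}))
    for alpha in alpha_values:
        settings.append((f"amgh_a{alpha:g}", "alpha_mgh", {"alpha": float(alpha)}))
    return settings


def size_experiment(
    n_values=(10_000, 100_000),
    mgh_b=(70, 80, 90, 100),
    alpha_values=(0.4, 0.45, 0.5),
    trials: int = 50,
    seed: int = 0,
) -> ExperimentResult:
    """Empirical sample sizes vs the theoretical size laws.

    For each set size n, one fixed random set is sketched under ``trials``
    independent hash seeds for every parameter setting; the summary reports
    the mean and SD of the sample size next to the theory value
    (``b*lg(n/b)+b`` for MGH, the exact leading coefficient times ``n**alpha``
    for alpha-MGH, lower-order terms omitted).
    """
    rng = np.random.default_rng(seed)
    settings = _geometric_settings(mgh_b, alpha_values)
    records = []
    for n in n_values:
        strings = random_string_set(int(n), int(rng.integers(_SEED_BOUND)))
        hash_seeds = rng.integers(_SEED_BOUND, size=trials)
        for trial, hseed in enumerate(hash_seeds):
            pool = DistinctHashes(hash64_array(strings, int(hseed)))
            for name, variant, kw in settings:
                params = SketchParams(variant, seed=int(hseed), **kw)
                records.append(
                    {
                        "setting": name,
                        "n": int(n),
                        "trial": trial,
                        "hash_seed": int(hseed),
                        "size": pool.size(params),
                    }
                )
    data = pd.DataFrame.from_records(records)
    summary = (
        data.groupby(["setting", "n"], as_index=False)["size"]
        .agg(mean_size="mean", sd_size="std")
    )
    summary["expected_size"] = [
        (
            expected_size_mgh(row.n, int(row.setting.split("_b")[1]))
            if row.setting.startswith("mgh")
            else expected_size_alpha(row.n, float(row.setting.split("_a")[1]))
        )
        for row in summary.itertuples()
    ]
    config = {
        "n_values": list(map(int, n_values)),
        "mgh_b": list(map(int, mgh_b)),
        "alpha_values": list(map(float, alpha_values)),
        "trials": trials,
        "seed": seed,
    }
    return ExperimentResult(data, summary, config)


def jaccard_sweep(
    pairs: int = 200,
    n: int = 100_000,
    mgh_b=(70, 80, 90, 100),
    alpha_values=(0.4, 0.45, 0.5),
    seed: int = 0,
) -> ExperimentResult:
    """Jaccard estimation across the full similarity range.

    Generates ``pairs`` set pairs with target Jaccard uniform on [0, 1],
    sketches both sets of each pair under every parameter setting with a
    shared hash seed, and estimates Jaccard through the refined union.  The
    summary gives, per setting, R^2 about the identity line with the
    realized Jaccard as truth.
    """
    rng = np.random.default_rng(seed)
    settings = _geometric_settings(mgh_b, alpha_values)
    records = []
    for pair_idx in range(pairs):
        j_target = float(rng.uniform())
        pair_seed = int(rng.integers(_SEED_BOUND))
        hash_seed = int(rng.integers(_SEED_BOUND))
        shared = int(np.floor(2 * n * j_target / (1 + j_target) + 0.5))
        total = 2 * n - shared
        spec = PairSpec(n, j_target, pair_seed, shared)
        strings = random_string_set(total, pair_seed)
        hashes = hash64_array(strings, hash_seed)
        pool_a = DistinctHashes(hashes[:n])
        pool_b = DistinctHashes(hashes[total - n :])
        for name, variant, kw in settings:
            params = SketchParams(variant, seed=hash_seed, **kw)
            rc = refine(pool_a.sketch(params), pool_b.sketch(params))
            records.append(
                {
                    "setting": name,
                    "pair": pair_idx,
                    "true_jaccard": spec.realized_jaccard,
                    "estimate": estimate(rc, "jaccard").estimate,
                    "u_size": rc.u_size,
                }
            )
    data = pd.DataFrame.from_records(records)
    rows = []
    for name, grp in data.groupby("setting"):
        truth = grp["true_jaccard"].to_numpy()
        est = grp["estimate"].to_numpy()
        ss_res = float(np.sum((est - truth) ** 2))
        ss_tot = float(np.sum((truth - truth.mean()) ** 2))
        rows.append({"setting": name, "r2": 1.0 - ss_res / ss_tot, "pairs": len(grp)})
    summary = pd.DataFrame(rows)
    config = {
        "pairs": pairs,
        "n": n,
        "mgh_b": list(map(int, mgh_b)),
        "alpha_values": list(map(float, alpha_values)),
        "seed": seed,
    }
    return ExperimentResult(data, summary, config)


def mse_experiment(
    n_values=(1_000, 10_000, 100_000),
    trials: int = 50,
    j_true: float = 0.5,
    minhash_k: int = 1000,
    frac_scale: float = 0.001,
    mgh_b: int = 90,
    alpha: float = 0.45,
    seed: int = 0,
) -> ExperimentResult:
    """MSE of the Jaccard estimate at fixed true similarity, four samplers.

    For each n, one fixed pair at the target Jaccard is sketched under
    ``trials`` hash seeds by bottom-k MinHash, FracMinHash, MGH and
    alpha-MGH.  FracMinHash comparisons whose retained union is empty (an
    event with appreciable probability only when ``n * scale`` is of order
    one) are recorded as undefined and excluded from the MSE average; the
    summary reports how many trials were defined.
    """
    rng = np.random.default_rng(seed)
    records = []
    for n in n_values:
        pair_seed = int(rng.integers(_SEED_BOUND))
        shared = int(np.floor(2 * int(n) * j_true / (1 + j_true) + 0.5))
        total = 2 * int(n) - shared
        strings = random_string_set(total, pair_seed)
        truth = PairSpec(int(n), j_true, pair_seed, shared).realized_jaccard
        hash_seeds = rng.integers(_SEED_BOUND, size=trials)
        for trial, hseed in enumerate(hash_seeds):
            hseed = int(hseed)
            hashes = hash64_array(strings, hseed)
            ha, hb = hashes[: int(n)], hashes[total - int(n) :]
            pool_a, pool_b = DistinctHashes(ha), DistinctHashes(hb)
            for algo, est, size in _mse_trial(
                pool_a, pool_b, ha, hb, hseed, minhash_k, frac_scale, mgh_b, alpha
            ):
                records.append(
                    {
                        "algo": algo,
                        "n": int(n),
                        "trial": trial,
                        "estimate": est,
                        "sq_error": (est - truth) ** 2 if est == est else np.nan,
                        "size": size,
                    }
                )
    data = pd.DataFrame.from_records(records)
    summary = (
        data.groupby(["algo", "n"], as_index=False)
        .agg(
            mse=("sq_error", "mean"),
            se_mse=("sq_error", lambda s: s.std() / np.sqrt(s.notna().sum())),
            mean_size=("size", "mean"),
            defined=("sq_error", lambda s: int(s.notna().sum())),
        )
    )
    config = {
        "n_values": list(map(int, n_values)),
        "trials": trials,
        "j_true": j_true,
        "minhash_k": minhash_k,
        "frac_scale": frac_scale,
        "mgh_b": mgh_b,
        "alpha": alpha,
        "seed": seed,
    }
    return ExperimentResult(data, summary, config)


def _mse_trial(pool_a, pool_b, ha, hb, hseed, minhash_k, frac_scale, mgh_b, alpha):
    mh = BaselineParams("minhash", k_top=minhash_k, seed=hseed)
    fm = BaselineParams("fracminhash", scale=frac_scale, seed=hseed)
    sa_mh = baseline_sketch_from_hashes(ha, mh)
    sb_mh = baseline_sketch_from_hashes(hb, mh)
    yield "minhash", baseline_jaccard(sa_mh, sb_mh), sa_mh.sample_size()
    sa_fm = baseline_sketch_from_hashes(ha, fm)
    sb_fm = baseline_sketch_from_hashes(hb, fm)
    try:
        est_fm = baseline_jaccard(sa_fm, sb_fm)
    except ValueError:
        est_fm = float("nan")
    yield "fracminhash", est_fm, sa_fm.sample_size()
    for name, params in (
        (f"mgh_b{mgh_b}", SketchParams("mgh", b=mgh_b, seed=hseed)),
        (f"amgh_a{alpha:g}", SketchParams("alpha_mgh", alpha=alpha, seed=hseed)),
    ):
        sk_a = pool_a.sketch(params)
        sk_b = pool_b.sketch(params)
        rc = refine(sk_a, sk_b)
        yield name, estimate(rc, "jaccard").estimate, sk_a.sample_size()


# -- UPGMA similarity trees -----------------------------------------------


def upgma_newick(d, labels) -> str:
    """UPGMA clustering of a distance matrix, serialized as rooted Newick.

    Cluster distances are arithmetic means over leaf pairs (sizes weight the
    update).  The tree is ultrametric: every leaf sits at the same height,
    and each branch length is half the merge distance minus the child's
    height.  Tie-break: among pairs at the minimum distance, the pair whose
    (lexicographically sorted) representative labels are smallest is merged,
    and the smaller-labelled child is written first.
    """
    d = np.asarray(d, dtype=float)
    m = d.shape[0]
    if d.shape != (m, m) or m != len(labels):
        raise ValueError("distance matrix must be square and match labels")
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must be symmetric with a zero diagonal")
    if m == 1:
        return f"{labels[0]};"
    # cluster state: key (smallest leaf label), newick, height, size
    clusters = {
        idx: {"key": str(lab), "newick": str(lab), "height": 0.0, "size": 1}
        for idx, lab in enumerate(labels)
    }
    dist = {(p, q): float(d[p, q]) for p in range(m) for q in range(p + 1, m)}
    next_id = m
    while len(clusters) > 1:
        dmin = min(dist.values())
        best = min(
            (pair for pair, val in dist.items() if val == dmin),
            key=lambda pair: tuple(
                sorted((clusters[pair[0]]["key"], clusters[pair[1]]["key"]))
            ),
        )
        p, q = best
        cp, cq = clusters.pop(p), clusters.pop(q)
        if cq["key"] < cp["key"]:  # smaller-labelled child written first
            p, q, cp, cq = q, p, cq, cp
        height = dmin / 2.0
        newick = (
            f"({cp['newick']}:{height - cp['height']:.12g},"
            f"{cq['newick']}:{height - cq['height']:.12g})"
        )
        merged = {
            "key": min(cp["key"], cq["key"]),
            "newick": newick,
            "height": height,
            "size": cp["size"] + cq["size"],
        }
        new_dist = {}
        for r in clusters:
            dp = dist[(min(p, r), max(p, r))]
            dq = dist[(min(q, r), max(q, r))]
            new_dist[r] = (cp["size"] * dp + cq["size"] * dq) / merged["size"]
        dist = {
            pair: val
            for pair, val in dist.items()
            if p not in pair and q not in pair
        }
        for r, val in new_dist.items():
            dist[(min(r, next_id), max(r, next_id))] = val
        clusters[next_id] = merged
        next_id += 1
    (root,) = clusters.values()
    return root["newick"] + ";"


# -- synthetic genomes for the tree pipeline ------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(length: int, rng) -> bytes:
    """A uniform random A/C/G/T sequence."""
    return _BASES[rng.integers(0, 4, size=length)].tobytes()


def mutate_sequence(seq: bytes, rate: float, rng) -> bytes:
    """Independently substitute each site with probability ``rate``
    (always to a different base)."""
    arr = np.frombuffer(seq, dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    idx = np.flatnonzero(hit)
    if idx.size:
        base_idx = np.searchsorted(_BASES, arr[idx])
        arr[idx] = _BASES[(base_idx + rng.integers(1, 4, size=idx.size)) % 4]
    return arr.tobytes()


def tree_experiment(
    rates=(0.01, 0.01, 0.05, 0.20, 0.20),
    length: int = 20_000,
    b: int = 90,
    k: int = 31,
    seed: int = 0,
):
    """Synthetic-genome similarity tree.

    Mutates one random root sequence at the given per-site rates (one leaf
    per rate), sketches the canonical k-mers of each leaf with MGH, converts
    pairwise Jaccard estimates to mutation-rate distances and clusters by
    UPGMA.  Returns ``(newick, labels, distance_matrix)``; leaves are
    labelled s1, s2, ... in rate order.
    """
    from .seqio import KmerConfig, canonical_kmers

    rng = np.random.default_rng(seed)
    root = random_dna(length, rng)
    config = KmerConfig(k=k, canonical=True)
    hash_seed = int(rng.integers(_SEED_BOUND))
    params = SketchParams("mgh", b=b, seed=hash_seed, kmer_size=k, canonical=True)
    sketches = []
    labels = []
    for idx, rate in enumerate(rates):
        seq = mutate_sequence(root, rate, rng)
        kmers = np.array(list(canonical_kmers(seq, config)), dtype=f"S{k}")
        sketches.append(
            DistinctHashes(hash64_array(kmers, hash_seed)).sketch(params)
        )
        labels.append(f"s{idx + 1}")
    dmat = distance_matrix(sketches, k)
    return upgma_newick(dmat, labels), labels, dmat
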