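# Methods

## The samplers

All four samplers in this package share one mechanism: each stream item is
hashed once with a seeded 64-bit hash, and every keep/evict decision is a
deterministic function of hash values. This is what makes the samples
uniform random subsets of the distinct elements, order-independent,
mergeable and dependable (exact frequency counts for retained elements).

**MaxGeomHash (MGH).** The hash `h` is split at its leftmost set bit: with
`zpl(h)` leading zeros, the item is routed to bucket `i = zpl(h) + 1` and
ranked within the bucket by the suffix `h′` (the bits strictly after the
leftmost 1). Bucket `i` keeps at most `b` entries, evicting the smallest
suffix when a larger one arrives. Since all hashes in a bucket share their
zero-prefix length, ranking by `h′` coincides with ranking by `h`, and ties
between distinct keys are impossible. The bucket index is geometric with
parameter ½, so buckets with `i ≲ lg(n/b)` saturate at `b` while deeper
buckets hold everything routed to them; the expected sample size is
`b·lg(n/b) + b + ε(n, b)` with `V[S] = O(1)`. The error term is bounded by
the constant `E_b = Σ_{m=0}^{b−1} (b−m) e^{−b} b^m / m!`, exposed as
`eb_constant` (evaluated through the Poisson pmf for stability) but used by
no estimator.

**α-MGH.** Identical flow, but bucket `i` has capacity `γ·2^{βi}` with
`β = α/(1−α)` (default `γ = 1`), giving expected size
`(2^{1/(1−α)} − 1)/(2^β − 1) · n^α + O(log n)` and variance `Θ(n^α)`.
The real-valued capacity is rounded half-away-from-zero and floored at 1; the
rounding direction only affects the first few buckets and is absorbed by the
`O(log n)` term. The analytic size formula `expected_size_alpha` reports the
exact leading coefficient; at `α = 0.45` it evaluates to `3.3103·n^0.45`,
agreeing with its asymptotic series `(1−α)/(α ln 2) + 3/2 + α ln 2/(12(1−α))`
to better than 0.01%.

**Baselines.** Bottom-k MinHash keeps the `k_top` smallest distinct hashes
of a single hash function (the convention of the common genomic tools; k
independent hash functions are deliberately not implemented). FracMinHash
keeps every distinct hash `h ≤ floor(s·2^64)`. Default comparison
parameters follow common tool defaults: `k_top = 1000`, `s = 0.001`.

**Degenerate inputs.** `h = 0` (probability `2^{−64}`) has, by convention,
a zero-prefix spanning the whole word and lands in bucket 65 with `h′ = 0`;
it is handled, not special-cased away. Empty streams give empty sketches;
comparing two empty sketches raises an error rather than returning a 0/0
sentinel, because silent conventions corrupt downstream distance matrices.

## The hash

`smx64` is this package's seeded, portable 64-bit hash: a chain of
splitmix64 finalizer rounds over little-endian 8-byte blocks, with the item
length folded into the initial state (so zero-padding of the last block is
unambiguous) and the seed XORed in. It has identical scalar and
numpy-vectorized implementations, verified bit-for-bit against each other in
the tests, and its bucket-index distribution is checked against the
geometric(½) law. Sketches record the hash name in their file header and
refuse to load under a different hash; sketches are only comparable under
the identical hash function and seed.

## Similarity estimation

For sketches S = MGH(A), T = MGH(B) under one seed, the per-bucket union
`S_i ∪ T_i` truncated back to capacity (largest suffixes kept) gives `U_i`;
`U = ⋃ U_i` is a uniform random sample of A ∪ B — element content identical
to `merge(S, T)` and to the direct sketch of A ∪ B, an exact identity the
tests verify. The intersection sample is computed as `V = U ∩ S ∩ T`, *not*
as the raw `S_i ∩ T_i`: a shared element can be displaced from `U_i` by
larger union suffixes, and a two-element example in the tests shows the raw
intersection would differ and bias the estimator. All measures are
evaluated on the refined counts `u = |U|`, `v = |V|`, `a = |U ∩ S|`,
`b = |U ∩ T|`, which are the within-sample analogues of |A∪B|, |A∩B|, |A|,
|B|: Jaccard `v/u`, containment `v/a` and `v/b`, Sørensen–Dice `2v/(a+b)`,
cosine `v/√(ab)`, Kulczynski-2 `(v/2)(1/a + 1/b)`, and Kulczynski-1
`v/(u−v)` clipped to [0, 1] (defined as 1 when `v = u`). Jaccard,
containment, Sørensen–Dice and Kulczynski-2 are unbiased; cosine and
Kulczynski-1 carry `O(E[1/|U|])` bias. The correlation coefficient is
omitted: it needs the universe cardinality, which sketches do not carry.

Mutation-rate conversion assumes independent point mutations at per-site
rate `r`, under which two genomes share a `(1−r)^k` fraction of k-mers,
giving `r = 1 − (2j/(1+j))^{1/k}` from Jaccard `j` at k-mer length `k`
(ANI = 1 − r). This ignores repeats, indels and compositional bias; it is a
proxy adequate for topology-level comparison, not a substitution model.

## Sequence front end

Sequences are uppercased; windows of length k (default 31) containing any
character outside A/C/G/T are skipped; canonicalization takes the
lexicographic minimum of the window and its reverse complement under
A<C<G<T byte order. One sketch per input file (genome-level); k-mers are
buffered and folded in vectorized chunks of 2^20, with chunk sketches
merged — exact, because retention is a global property of the hash and
per-chunk counts of retained elements sum to the true frequencies. Sketch
files are canonical plain text (header with algorithm, parameters, seed,
hash name, k-mer settings; one line per entry, bucket ascending then suffix
descending, 16-digit lowercase hex hashes), so equal sketches serialize
byte-identically and files diff cleanly; gzip is transparent on read. The
header's parameter slot is `b=`/`alpha=` for the geometric samplers and
`k_top=`/`scale=` for the baselines, which share the format with a single
pseudo-bucket 0.

## Synthetic data and what it does (not) show

The generators emulate the simulation conditions the samplers are analyzed
under: sets of distinct length-10 alphanumeric strings (uniform over a
62-character alphabet), and set pairs sharing `round(2nj/(1+j))` elements so
the realized Jaccard `shared/(2n − shared)` is within one rounding step of
the target. Realized — not target — Jaccard is always the truth in error
metrics. These are idealized inputs: real k-mer sets have skewed abundances,
shared repeats and correlated content. Because every sampler decision
depends only on hash values, the distribution of sketch *sizes* and
estimator *errors* is insensitive to the item distribution given the number
of distinct elements, so the Monte Carlo results transfer; what the
synthetic tests cannot show is robustness to biological artifacts upstream
of hashing (sequencing errors inflating n, abundance-weighted similarity —
frequencies are carried in sketches but unused by the estimators).

Synthetic genomes for the tree pipeline are i.i.d. uniform DNA with
independent substitutions at prescribed per-site rates (no indels, no rate
heterogeneity); five leaves at rates (0.01, 0.01, 0.05, 0.20, 0.20) from a
20 kb root are enough for the topology check that the two least-mutated
leaves cluster together.

## Problem sizes and numerical choices

Monte Carlo scales were chosen for a desk-scale validation that still sits
in each estimator's asymptotic regime: size laws at n = 10^5 with 50 hash
seeds (2% band for MGH with CV < 2%; 10% band for α-MGH, absorbing its
`O(log n)` term and capacity rounding); estimation quality over 200 pairs of
10^5-element sets per parameter setting (seven settings, minimum R^2
compared against 0.9932, with R^2 computed about the identity line —
`1 − SS_res/SS_tot` with realized Jaccard as truth — not as a squared
correlation of a refitted line); unbiasedness at one pair, true J = 0.5,
n = 10^4, 200 seeds, 3-standard-error bands; MSE trends over
n ∈ {10^3, 10^4, 10^5} with 50 seeds. At n·s of order one, a FracMinHash
comparison can retain an empty union; such trials are recorded as undefined
and excluded from the MSE average, with the defined-trial count reported.

UPGMA is implemented directly (size-weighted arithmetic-mean linkage) with a
deterministic tie-break — among minimum-distance pairs, merge the pair whose
lexicographically smallest leaf labels sort first, smaller label written
first — so tree output is reproducible to the byte; merge heights are
cross-checked against scipy's average-linkage on tie-free matrices. Branch
lengths are written with 12 significant digits, enough to keep the tree
ultrametric to 1e-9 under round-trip parsing.

## Known limitations

- Element identity is the full 64-bit hash; collisions (~n²/2^65) are
  accepted as negligible, as in the reference tools. Optional payload
  retention exists for debugging only and does not survive serialization.
- Merging sketches of *overlapping* streams is exact in element content but
  double-counts frequencies on the overlap; counts are exact for disjoint
  partitions (the parallel-construction case).
- Abundance-aware (weighted) similarity, ModHash, Affirmative and Reservoir
  sampling, and interoperability with external sketch file formats are out
  of scope.
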