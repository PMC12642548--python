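# kmersketch

Variable-size random sampling of distinct elements for scalable sequence
comparison.

Comparing large k-mer sets — genomes, metagenomes, read sets — is usually done
through *sketches*: compact random samples of the distinct k-mers from which
similarity can be estimated. The two workhorse designs sit at opposite ends of
a trade-off: bottom-k MinHash keeps a **constant** number of hashes (cheap but
inaccurate for large or unequally sized sets), while FracMinHash keeps a fixed
**fraction** of them (accurate but linear in the data). `kmersketch`
implements a family of samplers in between:

- **MaxGeomHash (MGH)** — expected sample size `b·lg(n/b) + b + ε` for `n`
  distinct elements, with O(1) variance;
- **α-MaxGeomHash** — expected sample size
  `(2^{1/(1−α)} − 1)/(2^{α/(1−α)} − 1) · n^α`, for a chosen `α ∈ (0, 1)`.

Both hash each item to 64 bits, route it to bucket `i = zpl(h) + 1` (one plus
the number of leading zero bits — geometric with parameter ½), and keep per
bucket only the entries with the largest suffix `h′` (the bits after the
leftmost 1): at most `b` of them for MGH, up to `γ·2^{βi}` with
`β = α/(1−α)` for α-MGH. Because every decision depends only on the hash,
the samples are

- **order-independent** — any permutation of the stream gives the identical
  sketch;
- **mergeable** — sketches of stream parts combine (union + re-prune) into
  exactly the sketch of the whole stream, enabling parallel and incremental
  construction;
- **dependable** — membership is decided at an element's first occurrence and
  evicted elements never return, so retained frequency counts are exact.

Given two sketches built under the same seed, a per-bucket *refinement*
(truncate the bucket union back to its capacity) yields a uniform random
sample **U** of A ∪ B and its subset **V** = A ∩ B ∩ U; `|V|/|U|` is an
unbiased Jaccard estimator, and the same counts give containment,
Sørensen–Dice, cosine and Kulczynski measures. Jaccard values convert to
genome-wide mutation-rate distances `r = 1 − (2j/(1+j))^{1/k}` (one minus
ANI) under a simple mutation model, from which UPGMA similarity trees are
built. Bottom-k MinHash and FracMinHash are included as baselines, and a
FASTA/FASTQ front end streams canonical k-mers (default k = 31) into any of
the samplers.

## Worked example

```python
import numpy as np
from kmersketch import SketchParams, build_sketch, refine, estimate
from kmersketch.experiments import random_string_set

universe = random_string_set(150_000, seed=4)   # distinct 10-char strings
A, B = universe[:100_000], universe[50_000:]    # true Jaccard = 1/3

params = SketchParams("mgh", b=90, seed=7)
sa, sb = build_sketch(A, params), build_sketch(B, params)
print(sa.sample_size())                          # 990

rc = refine(sa, sb)
print(rc.u_size, rc.v_size)                      # 1038 338
print(round(estimate(rc, "jaccard").estimate, 4))        # 0.3256
print(round(estimate(rc, "containment_ab").estimate, 4)) # 0.4913
```

The sketch of 100,000 distinct items holds 990 entries — against a
theoretical expectation `90·lg(100000/90) + 90 ≈ 1000.6` — and the refined
union of the two sketches (1038 elements, 338 shared) estimates Jaccard
0.3256 and containment 0.4913 against true values 1/3 and 1/2, each within
the expected sampling error of about `1/√|U| ≈ 0.03`.

The same operations are available from the shell:

```sh
kmersketch sketch --algo mgh -b 90 --kmer-size 31 --seed 9 -o cow.sketch cow.fa
kmersketch compare --measure jaccard --output cmp.tsv *.sketch
kmersketch tree -o tree.nwk *.sketch
kmersketch simulate mse --config mse.yml --out-prefix mse
```

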