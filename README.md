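# pairplan

Exact-once subset designs for parallelizing all-pairs comparison problems,
with a worked identity-by-descent (IBD) calling demonstration.

## The problem

Many genomics analyses compare **every pair** of individuals — detecting IBD
segments, building relatedness matrices, clustering — and therefore scale as
O(n²). Splitting the genome helps only so much: every genomic window still
needs all n(n−1)/2 pairs, and sub-chromosomal windows force error-prone
segment stitching. The alternative is to split the **sample**: find a family
of subsets such that every unordered pair of individuals co-occurs in
*exactly one* subset. Then each subset can be processed independently on any
cluster, no pair is compared twice or missed, and the gather step is plain
concatenation.

## The construction

Let *p* be the smallest prime with *p*² ≥ *n*. Write 1…*p*² column-wise into
a *p*×*p* matrix *P* (values > *n* are null padding). The design's
*p*² + *p* subsets are:

1. the *p* columns of *P*,
2. the *p* rows of *P*,
3. for each shift level *k* = 1…*p*−1, the *p* rows of *P_k*, where column
   *i* of *P_k* is column *i* of *P* cyclically shifted by
   *r*(*i*, *k*) = ((*i*−1)·*k*) mod *p* rows.

These are the lines of an affine plane of order *p*: each individual lies in
exactly *p* + 1 subsets, every pair of individuals co-occurs in exactly one
subset, and the total comparison count Σ m(m−1)/2 over subsets equals the
naive (n² − n)/2 exactly. Primality of *p* is essential — composite shift
strides collide and break the exact-once property (the test suite carries
this negative control). Self-comparisons, when wanted, attach to the first
*p* subsets only, where each individual appears exactly once.

For a sample of 435,187 individuals this gives *p* = 661 and 437,582 subsets
of ≤ 661 individuals — small enough that each subset is a cheap independent
job, and 437,582 × 22 autosomes ≈ 9.6M caller runs in total.

The package verifies the exact-once property computationally with a
brute-force oracle (it is independent of the construction and consumes only
the emitted member lists), emits per-subset keep-files and batched job
manifests for external callers such as GERMLINE or hap-IBD, merges
per-subset result tables, and ships a synthetic phased-haplotype simulator
plus a small deterministic IBD caller that together demonstrate the central
property end to end: **merged per-subset calls are bit-identical to a
full-sample run**.

## Worked example

```python
>>> import pairplan as pp
>>> design = pp.enumerate_subsets(25)
>>> print(design.summary())
n = 25
p = 5 (smallest prime with p^2 >= n)
subsets = 30 (p^2 + p)
subset sizes: min 5, max 5
memberships per individual = 6 (p + 1)
pairwise comparisons = 300 (naive (n^2-n)/2 = 300)
with self-comparisons = 325
>>> print(pp.pair_coverage(design))
n=25 p=5: EXACT COVER [t=1: 300]
```

Every one of the 300 unordered pairs of the 25 individuals co-occurs in
exactly one of the 30 subsets (`t=1: 300`), and the 30 × C(5,2) = 300
within-subset comparisons equal the naive total exactly.

The same from the shell, including the scatter-gather demonstration:

```bash
pairplan plan --n 435187          # p = 661, 437,582 subsets
pairplan verify --n 2000          # brute-force exact-once check, exit 0
pairplan manifest --n 25 --batch-size 1000 --out-dir design/   # keep-files + YAML manifest
pairplan equivalence --n 50 --seed 1   # simulate, call per subset, merge, compare
```

The `equivalence` command simulates a phased panel with planted IBD
segments, calls segments on the full sample and per subset, merges, and
prints e.g.:

```
EQUIVALENT: 10 segments, full-sample and merged subset calls are identical
```

meaning the scatter-gather pipeline reproduced the full-sample analysis
record for record. `--drop-subset <id>` deletes one subset first and shows
the resulting missing-pair diff (exit code 1).

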