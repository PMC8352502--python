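# Methods

## The partition design

Given `n >= 4` individuals, the design prime `p` is the smallest prime with
`p**2 >= n`, found by a deterministic primality test (sympy's, exact far
beyond any sample size of interest) over ascending candidates starting at
`ceil(sqrt(n))`. The integers `1..p**2` fill a `p x p` matrix `P`
column-wise: cell `(j, i)` (1-based) holds `(i-1)*p + j`. Values above `n`
are null padding, dropped from every subset.

Subsets are emitted in a fixed, documented order — columns of `P`, rows of
`P`, then rows of `P_k` for `k = 1..p-1` — and `subset_id` is simply the
position. The shifted matrix obeys

```
P_k[j, i] = P[((j - 1 + r(i, k)) mod p) + 1, i],   r(i, k) = ((i-1) * k) mod p
```

i.e. the column contents rotate downward, conveyor-belt style; the identity
`P_1[p, 2] == P[1, 2]` pins the direction and is asserted in the tests.
The construction is fully deterministic — no randomness anywhere — so the
design is bit-identical across runs and machines.

**Why prime?** Rows of `P_k` pick one element from each column with column
offsets forming an arithmetic progression with stride `k` modulo `p`. When
`p` is prime, distinct `(k, row)` choices intersect any fixed column pair in
exactly one way, which is what makes every pair of cells co-occur exactly
once. With composite `p` the strides that share a factor with `p` collide:
some pairs co-occur twice, others never. No formal proof is shipped;
instead the property is verified computationally (below), and composite
"primes" are kept as a negative control documenting the failure mode.

**Degenerate subsets.** When `p**2 > n`, null padding can shrink subsets;
with large padding (e.g. `n = 435,187`, `p = 661`, 1734 nulls) the last
whole columns of `P` can empty out entirely. Such subsets stay in the design
so that the arithmetic (`p**2 + p` subsets, `p + 1` memberships) remains
literal, but they are skipped — with a logged notice — when emitting
keep-files and job manifests, since they carry no pairwise work.

## The coverage oracle

`pairplan.coverage` verifies the exact-once property by brute force,
independently of the construction: it consumes only the emitted member
lists. For each individual `i` it walks the subsets containing `i` (an
inverted index built from the member lists alone) and tallies every
co-member `j > i` in an `n`-sized count buffer; reading the buffer off
yields the co-occurrence count `t` of every pair `(i, j)`. This visits each
within-subset pair exactly once with a cache-resident working set, so an
exhaustive sweep of `n = 4..2000` takes tens of seconds and a single
`n ~ 100,000` (~5e9 pairs) runs in about a minute on one CPU; these are the
sweep sizes the tests and the acceptance script use. Counts saturate at 255
(a valid design never exceeds 1). The primary output is the full histogram
`t -> #pairs`, not a boolean, so violations are diagnosable; offending pairs
are reported up to a cap (default 100) to bound output.

## Keep-files, manifests, merging

Keep-files are one-sample-ID-per-line text (the single-column dialect that
PLINK `--keep`-style options accept), one file per emitted subset, in member
order. Job manifests batch subsets into jobs of `batch_size` (default 1000)
in stable `subset_id` order and serialize as YAML. Segment results travel as
a fixed-header TSV (`SEGMENT_COLUMNS`), with marker spans half-open and bp
spans inclusive of the first/last matching marker; records are canonicalized
on read (endpoints ordered lexicographically by `(id, haplotype)`) and
genetic lengths stored at the TSV's 1e-6 cM precision so records survive
write/read round trips bit-identically. Because the design covers each pair
exactly once, merging is concatenation + sort; an exact duplicate row in a
merge is logged as a coverage-violation warning and kept once.

## The synthetic panel

The simulator emulates a phased SNP-array chromosome just realistically
enough to exercise exact-match IBD machinery:

* markers are independent (no background linkage disequilibrium), biallelic,
  with per-marker allele frequencies uniform in `maf_range`
  (default 0.1–0.5);
* marker gaps are uniform in 25–75 kb (mean 50 kb, roughly array density),
  and the genetic map is uniform at 1 cM/Mb, so the default `m = 2000`
  markers span ~100 Mb ≈ 100 cM;
* IBD is planted by copying a contiguous allele stretch of the requested
  genetic length (the shortest marker span reaching it) from one haplotype
  onto another at a seeded random location, recording the span as ground
  truth; self-IBD (one individual's two haplotypes) is allowed so the
  self-comparison rule can be exercised;
* genotyping error is independent allele flipping at rate `< 0.05`.

What passing tests on these panels do **not** show: performance on real data
with LD (which inflates chance matches at short lengths), realistic
recombination/IBD length distributions, phasing errors, or error-tolerant
calling. The panels are sufficient for what they are used for — proving the
scatter-gather bookkeeping exact — because that property depends only on the
caller being deterministic and pairwise-local, not on the data's realism.

## The toy IBD caller

`call_ibd` partitions markers into consecutive windows of `window_markers`
(default 75), groups haplotypes by identical window content via hashing,
and for each within-group pair extends maximal runs of consecutive shared
windows marker-by-marker at both ends, emitting spans whose genetic length
reaches `min_length_cM` (default 3.5 cM — with the 75-marker window these
mirror widely used hash-based IBD-caller settings for array data). The final
partial window participates in extension but never seeds. Matching is exact:
no error tolerance, no heuristics, so output for a pair depends only on that
pair's haplotypes and the configuration (asserted as the pairwise-locality
test). Planted segments at least one window longer than the threshold
(~3.5 + 3.75 cM here) are guaranteed to contain an aligned seeding window
and are always recalled at zero error rate; the equivalence demos plant
8–12 cM segments for this reason.

**Equivalence.** `equivalence_check` runs the caller on the full sample and
once per design subset (self-comparisons, if enabled, only on the
column-of-`P` subsets), merges, and compares record lists for exact
equality. Because the caller is pairwise-local and deterministic and the
design covers each pair exactly once, the two outputs must be identical —
including under injected genotyping error, which fragments segments
identically on both routes. This equivalence, not caller quality, is the
property the package exists to establish.

## Numerical and design choices

* Individuals are 1-based `1..n` internally, keeping the worked matrix
  identities literal; external ID lists map line `l` to individual `l`.
* `n < 4` is rejected outright rather than special-cased.
* All simulation randomness flows through seeded `numpy` generators;
  fixtures and CLI commands pin seeds, so every result in the tests and
  README is reproducible bit-for-bit.
* Problem sizes used by the verification sweeps (exhaustive `n = 4..2000`,
  20 random `n <= 1e5`, equivalence panels `n in {16, 25, 49, 50, 100}`
  with `m = 2000` markers) were chosen as desk-scale analogues that
  exercise every structural regime: `n = p**2` exactly, `p**2 > n` with
  padding, padding that empties whole subsets, and sizes spanning three
  orders of magnitude.

## Known limitations

* No formal proof of the exact-once property is attempted; verification is
  computational, at the sweep sizes above.
* The construction requires prime `p`; prime-power orders (Galois-field
  affine planes) would also work in principle but are not implemented.
* The toy caller is not a production IBD caller (no error tolerance, no
  phasing, no population-scale performance work); production use should
  emit keep-files and run an external caller per subset.
* No scheduler integration: manifests are plain YAML for the user's
  submission tooling.
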