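# Methods

## Data model

A haplotype panel is an *M* × *N* binary matrix: *M* phased haplotypes
(two per diploid sample), *N* biallelic loci, allele 0 = reference,
1 = alternate. No missing data and no multiallelic codes are admitted; the
VCF reader either rejects such sites (strict mode) or drops them with a
logged count (lenient mode). Internally loci are 0-based column indices;
VCF `POS` is carried only as metadata; all reported intervals are 0-based
half-open.

## Sequential construction

The PBWT state at locus *k* is the pair (*a_k*, *d_k*):

* *a_k* — permutation of haplotype ids in non-decreasing colexicographic
  order of the reverse prefixes (alleles over [0, *k*), compared from
  locus *k*−1 backwards); exactly the order of a column-wise stable radix
  sort of the first *k* columns.
* *d_k* — *d_k*[i] is the smallest *j* with agreement of the haplotypes at
  sorted positions *i*, *i*−1 over [*j*, *k*); *d_k*[0] = *k* (no
  predecessor, empty match).

One step *k* → *k*+1 partitions *a_k* stably into the 0-class followed by
the 1-class of column *k* and derives *d_{k+1}* from two running maxima
(one per class) that start at *k*+1 and reset to 0 after each emitted
entry. The implementation computes the step with vectorised segmented
maxima (`np.maximum.reduceat` over the inter-entry windows), which is
algebraically identical to the scalar scan; all arrays are int64 and no
floating point appears anywhere in the package.

**Tie rule.** Haplotypes identical over [0, *k*) keep their input order
(stability of the partition, identity start order). Any fixed
deterministic rule would work; stability is chosen because it makes the
sequential and chunked paths agree without extra bookkeeping: a group of
chunk-identical haplotypes appears in identity order in every chunk, and
the correction step rewrites it to the previous boundary's relative order,
which is inductively the input order for haplotypes identical from locus 0.

`check_state` is the package's own brute-force oracle: it re-sorts reverse
prefixes and re-derives divergences by direct suffix comparison in
quadratic time, and is used only in tests.

## Chunked construction and correction

`plan_chunks(N, T)` partitions [0, *N*) into *T* contiguous chunks whose
sizes differ by at most one (the remainder of *N*/*T* goes one locus at a
time to the leading chunks). Each chunk [*k−b*, *k*) is built from
identity order and the sentinel divergence array filled with *k−b*. Two
facts drive the correction:

* every divergence that ends above the sentinel is already exact, and
  every index outside a *candidate group* — a maximal run of
  sentinel-valued divergences together with the entry directly before it —
  already holds its true *a* and *d* values;
* inside a candidate group only the *order* of members and the sentinel
  divergences are unresolved, because the members are indistinguishable
  within the chunk.

Correction of one group sorts the members' positions in the previous
boundary's prefix array (via the inverse permutation), writes them back in
that order, and sets each member's divergence to the maximum of the
previous divergence array over the half-open window between consecutive
sorted previous positions — the same quantity the sequential running
maxima would have accumulated. The group's first entry keeps its
divergence (it refers to the haplotype before the group, which never
moves). Chunk 0 needs no correction: its sentinel array equals *d_0*.

Corrections run strictly left to right, each against its predecessor's
*corrected* state, so *T*−1 cheap sequential steps restore exactness at
every boundary. Per correction call the summed group sizes are ≤ *M*
(groups are disjoint), giving the O(*M* log *M*) sort bound, and within
one group the scan windows tile the span between its sorted previous
positions, bounding that group's divergence lookups by *M*. Note the
*summed* scan over all groups of one call may exceed *M*: windows of
different groups can overlap in the previous ordering. Both counters (per
group and summed) are recorded in `CorrectionStats` and asserted in the
test-suite at their provable bounds.

`sentinel_groups` exposes the candidate groups of an uncorrected chunk
build directly: each is a set of haplotypes identical across the whole
chunk, usable as a deduplication by-product.

## Matching

Both reporters run inside one sweep that maintains (*a_k*, *d_k*) and
reports a match at the locus where it terminates — the first locus where
the pair disagrees, or the panel end. Termination-time reporting makes
chunk outputs disjoint: a match belongs to the chunk containing its end
locus, matches still open at *k* = *N* belong to the final chunk, and the
union over chunks equals the single-sweep output exactly.

* **Long matches (≥ L, inclusive).** At locus *k*, positions with
  *d* > *k*−*L* split the sorted order into blocks; within a block every
  pair matches over ≥ *L* loci ending at *k*, and the pairs with opposite
  alleles at *k* (all pairs, at the end-of-panel flush) terminate there.
  A pair's match start is the maximum of *d* between its positions,
  accumulated with a running maximum, so reporting is O(1) per emitted
  match. The classic biobank use maps to *L* = 2000; the bound is
  implemented inclusively (a match of exactly *L* loci is reported) and
  exposed as a parameter.
* **Set-maximal matches.** For the haplotype at sorted position *i* the
  longest current matches start at min(*d*[i], *d*[i+1]) and sit among its
  sorted neighbours. The sweep scans outward over every neighbour matching
  from that locus; if any shares *i*'s allele at *k* the match extends and
  nothing is set-maximal for *i* at *k*, otherwise all terminating
  neighbour matches on the minimal side(s) are reported (ties on both
  sides included).

The observable contracts — exactly the maximal matches ≥ *L*; exactly the
not-strictly-contained matches per haplotype — are pinned by quadratic
brute-force oracles (`brute_force_long_matches`, `brute_force_set_maximal`)
that enumerate all pairs directly, and the suite asserts set equality
against them across hundreds of seeded panels.

## Concurrency model

Chunk builds are pure functions of (column slice, chunk start); matching
sweeps are pure functions of (column slice, seed state). Any scheduler
respecting the correction order is conformant; the default is a serial
in-process loop (`workers=1`), and `workers>1` uses a process pool with
each task shipped only its own column slice. Results are independent of
worker count and scheduling by construction, and match TSVs are written in
canonical (start, hap_i, hap_j) order so files are byte-identical for any
thread count.

## Synthetic panels

`generate_panel` draws background haplotypes i.i.d. per site with
frequencies uniform in [0.05, 0.5] by default — avoiding monomorphic
columns while keeping diversity low enough for realistic short shared
runs — and plants *duplicate groups*: blocks of haplotypes copied from a
template, exactly identical over a chosen span and flipped at a given rate
outside it. Groups whose spans straddle chunk boundaries are the stressor
for the correction path. `random_panel` wraps this with seeded sampling of
M, N, group sizes and spans at a target duplicate rate. These panels have
no linkage disequilibrium or genealogy; since the algorithms are exact and
combinatorial, passing on them demonstrates correctness for arbitrary 0/1
panels, but performance characteristics on real data (where long shared
haplotypes are common) are not represented.

## Problem sizes and tolerances

Everything asserted is exact integer equality (states elementwise, match
sets as sets); there are no numeric tolerances. The test-suite exercises
300 seeded panels (M ≤ 64, N ≤ 256, duplicate rates 0/0.2/0.8, T ∈
{1, 2, 3, 5, 8}) for construction and 200 panels (M ≤ 48, N ≤ 200,
L ∈ {1, 2, 5, 20}) for matching; `scripts/acceptance.py` re-runs scaled
versions (60 and 40 panels) plus a timing comparison on an M = 400,
N = 40 000 panel. The wall-clock comparison in the suite (M = 1000,
N = 100 000, T = 4 vs T = 1) asserts a qualitative speedup and holds only
when genuinely concurrent cores are available; on a single CPU the chunked
run pays process overhead on identical total work and the comparison
fails by design rather than being gated.

## Limitations

* Biallelic, fully phased, no missing data; no imputation or multiallelic
  splitting.
* No query-versus-panel matching of external haplotypes and no
  PBWT-based compression codec.
* Single-node only; no distributed or GPU execution.
* Checkpoints store full int64 a/d arrays (16·M bytes plus a fixed
  header); no compressed checkpoint format.
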