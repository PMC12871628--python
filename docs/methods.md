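# Methods

## Data model and coordinates

The dictionary is built over a spectrum-preserving string set (SPSS): a
set 𝒮 of strings over {A,C,G,T}, each of length ≥ k, jointly containing
every k-mer of the underlying collection exactly once.  Build rejects
inputs violating either condition, naming both occurrences of a duplicated
k-mer; in canonical mode the duplicate check compares canonical forms
(a k-mer and its reverse complement are the same key there).  All public
coordinates are 1-based with half-open windows [q .. q+k), matching the
standard notation for this structure; internal 0-based arithmetic is
hidden.  Bases are coded A=0, C=1, G=2, T=3 with position 1 in the
least-significant 2-bit pair, so complementation is `3 − code` and reverse
complementation is cheap; k is capped at 63 (126-bit codes).  Non-ACGT
symbols are a hard error in SPSS input, while query windows containing
them are answered ⊥ without a lookup.

## Minimizer scheme

A scheme is (m, k, 𝒪) with m < k.  The order 𝒪 is either *lexicographic*
(used by the small worked examples and useful for debugging) or *random*:
a seeded splitmix64 hash of the m-mer code, with the code itself as a
deterministic tie key so the order is total.  The canonical minimizer
compares MINI(x) and MINI(x̄) under the same order; when both strands
yield the *same* m-mer value, the forward-strand position is stored and
the displacement function compensates by emitting all four candidates.

Super-k-mer boundaries are placed where the minimizer **occurrence
position** changes, not merely its value.  The locate sets store
occurrence positions, and every k-mer must be reachable from its stored
occurrence; the occurrence-based rule is the stricter reading that keeps
the ≤ k−m+1 span bound and the locate-set reachability property valid
when a minimizer value recurs within a window run.

Window-by-window minimizers are maintained incrementally with two
monotone deques over the rolling m-mer codes (one per strand; the reverse
strand prefers the rightmost minimal occurrence, which is the leftmost in
the reverse complement), giving amortized O(1) work per window.  Property
tests assert exact agreement with the from-scratch definition on both
strands.

## Locate sets, displacements, and the three-type layout

With loc(ϕ) holding minimizer occurrence positions, a regular-mode lookup
computes q = j − pos(MINI(x), x) + 1 per stored j; canonical mode derives
2–4 (position, orientation) candidates through the mirror identity
pos(ϕ̄, x̄) = k − m − pos(ϕ, x) + 2, dropping out-of-range ones.  Every
candidate is bounds-checked against the string offsets P (one Elias-Fano
successor query) so that no reported window crosses a string boundary.

Minimizers are typed by occurrence count z: singleton (z = 1, position
inlined in the tag), light (2 ≤ z ≤ 2^l, sets grouped by size in L with a
directory G), heavy (z > 2^l, sets in H plus a skew index).  Tag words are
⌈log₂N⌉+1 bits — operationally `N.bit_length() + 1`, since positions run
up to N — with layout, least-significant first: singleton `[0 | j]`,
light `[1 0 | z−2 (l bits) | group index]`, heavy `[1 1 | partition id
(3 bits) | offset o]`.  When the group-index or offset field cannot
address its store (a tiny-N corner), the whole tag word widens by the
minimal amount and the widening is recorded; tests cover the corner.

Defaults: **l = 6** (light sets up to 64 positions; the value used in the
skew-hashing literature for human-scale inputs) and **r = l + 7 = 13**, so
the partition id always fits 3 bits.  Partition i holds the k-mers of
minimizers with 2^i < z ≤ min(2^{i+1}, max), clamped to r; V_i entries
are 0-based indices into the owning locate set, logically i+1 bits wide
(⌈log₂ max⌉ for i = r).  In canonical mode the skew keys are canonical
k-mer codes (min of code and rc-code), so both strands address the same
V_i slot.

On the negative path, minimizer presence ("found") is decided by probing
the m-mer at a stored position.  For singleton and light tags the probed
position is owned by the tag's minimizer, so a mismatch proves the query
minimizer foreign.  For heavy tags the probed element depends on the
query k-mer through f_i and can go astray for foreign k-mers even when
the minimizer is present; the implementation then consults the first
element of the stored set (H[o]) before declaring the minimizer absent.
This keeps the found flag a pure function of the minimizer — the property
the streaming negative-skip rule relies on — while the positive-path
probe counts stay at the contracted one read of H plus one of V_i.

## Minimal perfect hashing

Bucket-placement construction: keys are hashed into buckets of ~3 keys on
average; buckets are processed largest-first, each searching (in
vectorized batches) for a pilot under which its keys occupy distinct free
slots of the global table; size-1 buckets take the remaining free slots
directly, with the slot encoded in the pilot word.  Evaluation is two
hashes and one pilot fetch.  Keys wider than 64 bits are folded
deterministically first; a fold collision triggers a re-salt (attempted
up to 16 times before reporting failure with seed advice).  The pilot
storage lands at a few bits per key — above the log₂(e) ≈ 1.443
information bound, as any MPHF must be; the average bucket size trades
construction speed against pilot compactness, and the chosen default
favours fast, reliable pure-Python construction.  Foreign keys evaluate
to arbitrary in-range values by design; membership is always verified
against the text downstream.

## Elias-Fano sequences

Low ℓ = max(0, ⌊log₂(U/n)⌋) bits per element in a fixed-width array, high
parts in a unary bit vector; the logical payload is within the classic
n·log₂(U/n) + 3n bits and is what `size_bits()` reports.  Position arrays
for select are kept alongside as an acceleration and their cost reported
separately (`select_overhead_bits()`).  Successor is select-then-scan and
returns the leftmost qualifying index; duplicates are legal.  A query
above the maximum element is a caller error, per the structure's
contract.

## Streaming lookup

The stream state is (start, found, h, i, o, q, minimizer pair, budget).
Per window: attempt an extension when a previous match exists and budget
remains — even when minimizers change through the stream; otherwise skip
the lookup entirely when the minimizer pair is unchanged and the last
seed established its absence; otherwise seed with a full lookup and reset
the budget.  Extension compares the full shifted window (comparing only
the one new base would be an equivalent optimization) and requires the
shifted window to stay inside the matched string.  A successful extension
does not set found: minimizer presence is only established by seeding.

The **budget resets to 32 at every seed** by default.  The reference
description leaves the reset value open; a fixed constant bounds the
wasted comparisons after a divergence while allowing long extension runs,
and the knob is exposed (`--budget`) for extension-rate studies.  Forcing
budget = 0 degenerates to a per-window lookup; the equivalence suite
checks both settings produce identical output, category counts
(extensions + seeds + skipped = windows) and the closed-form stats on
error-free reads.

## Synthetic data

The SPSS generator emulates the *shape* of eulertig/unitig inputs — G
total bases split into strings of length ≥ k, no duplicated canonical
k-mer (enforced during generation by per-base rejection with bounded
retries; an over-saturated spec, e.g. G close to 4^k/2, fails with a
clear error).  It does **not** emulate genomic repeat structure or
composition bias, so passing tests demonstrate correctness of the
dictionary contracts, not space/speed on real pangenomes.  Minimizer
skew on random strings is milder than on real genomes; the heavy/skew
machinery is therefore exercised with deliberately small m and l in the
tests rather than by data volume.

The read generator samples windows from the SPSS, reverse-complements
half, applies i.i.d. substitutions, and mixes in uniformly random
foreign reads; every window carries a present/absent truth label.  With
substitution rate p, a window of k bases survives error-free with
probability (1−p)^k — at k = 31 a rate of 1% yields ≈ 73% present
windows, so the "high-hit" workload tests (where > 75% of windows should
be present) use p = 0.5% (expectation ≈ 85.6%); equivalence tests keep
1%-error reads, since correctness does not depend on the hit rate.

## Problem sizes in the test suite

The study-scale suites run on synthetic SPSSs of 100 kb (50 strings,
k = 31, m = 15, both modalities, three seeds) for the bijection/order
properties, 50 kb for negative soundness (10⁵ oracle-verified absent
k-mers), and 20 kb with 10⁴ mixed 80 bp reads for streaming equivalence;
minimizer-density checks use 100 kb random strings (k = 31, m = 13,
three seeds, ±10% of the 2/(k−m+2)·(N−m+1) expectation).  These sizes
exercise every code path (including multi-partition skew indexes via
small-m fixtures) and are the package's chosen desk-scale study
conditions.

## Known limitations

* Single-threaded, in-memory construction only; the index is static
  (no insert/delete) and carries no abundance/color payloads.
* Pure-Python throughput is orders of magnitude below the C++
  implementations of this design; the value here is the reference
  semantics, the contracts, and the space accounting, not wall-clock
  speed.
* Space accounting is *logical* (bit widths as designed); the in-memory
  Python objects are larger, and the serialized file adds headers and
  byte alignment.
* Mod-minimizers, syncmers and sequence-specific orders are out of
  scope, as is building the SPSS itself (unitig/eulertig construction is
  upstream).
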