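# sshash

An order-preserving dictionary for the k-mers of a DNA sequence collection,
based on **sparse and skew hashing** (SSHash), with refined displacement
functions, a cache-conscious three-type locate layout, and a budget-based
streaming lookup algorithm.

## The problem

Representing a set of *n* distinct k-mers (DNA substrings of fixed length
k ≤ 63) so that

* `LOOKUP(x)` returns a unique handle *h* ∈ [1..n] if x is in the set, or ⊥
  otherwise — with x and its reverse complement x̄ treated as the same k-mer;
* `ACCESS(h)` returns the k-mer with handle *h* (or ε);
* `LOOKUP(s)` answers all |s| − k + 1 window queries of a read *s*, fast,

is a core primitive behind colored/positional de Bruijn graph indexes and
pseudoalignment.  The dictionary here is **order-preserving**: k-mers that
overlap by k−1 characters receive consecutive handles, which makes
satellite data (abundances, color sets) stored by handle highly
compressible.

## The method

The input is a *spectrum-preserving string set* (SPSS, e.g. unitigs or
eulertigs): strings of length ≥ k containing every k-mer exactly once,
concatenated into a 2-bit packed string S[1..N] with string offsets P kept
in an Elias-Fano sequence.  A minimizer scheme (m, k, 𝒪) samples each
k-mer x at its minimizer ϕ = MINI(x) (or the canonical CMINI(x) =
min{MINI(x), MINI(x̄)}), and the *locate set*

    loc(ϕ) = { pos(x, S) + pos(ϕ, x) − 1 : x ∈ spect_k(S), Φ(x) = ϕ }

stores minimizer *occurrence* positions, so that a stored j turns into a
candidate k-mer start directly, q = j − pos(ϕ, x) + 1, with no search
inside super-k-mers (canonical mode checks 2–4 mirrored candidates, using
pos(ϕ̄, x̄) = k − m − pos(ϕ, x) + 2).  A minimal perfect hash function f
over the minimizer set ℳ indexes an array of (⌈log₂N⌉+1)-bit *tags* that
dispatch each minimizer to one of three stores by its occurrence count z:

* **singleton** (z = 1): the position is inlined in the tag — no extra read;
* **light** (2 ≤ z ≤ 2^l): positions grouped by size in an array L;
* **heavy** (z > 2^l): positions in an array H, resolved in a single probe
  through a *skew index* — per size class K_i (2^i < z ≤ 2^{i+1}, at most 8
  classes), an MPHF f_i and a compact vector V_i give
  j = H[o + V_i[f_i(x)]].

The returned handle is h = q − (i−1)(k−1), where i is the query's string —
a bijection of the indexed k-mers onto [1..n], consecutive along each
string.  Streaming lookup keeps the last match (h, i, o, q) and, while an
integer *budget* lasts, extends it by comparing the next window against
S[q+o .. q+o+k) before ever touching the hash path, re-seeding with a full
lookup when extension fails.

## Worked example

```python
from sshash import SsHashIndex, SyntheticSpssSpec, gen_spss, stream_lookup

data = gen_spss(SyntheticSpssSpec(total_bases=20_000, n_strings=10, k=31, seed=1))
idx = SsHashIndex.build(data.strings, k=31, m=15, mode="canonical", seed=1)
print(f"indexed {idx.n} k-mers, {idx.M} minimizers")

kmer = data.strings[0][100:131]
res = idx.lookup(kmer)
print(f"lookup: handle={res.handle} string={res.string_id} "
      f"orientation={res.orientation:+d} position={res.position}")
print("access:", idx.access(res.handle) == kmer)

run = stream_lookup(idx, data.strings[0][100:250])
st = run.stats
print(f"stream: {st.windows} windows, {st.positives} hits, "
      f"{st.seeds} seeds, {st.extensions} extensions "
      f"(rate {st.extension_rate:.3f})")
print(f"space: {idx.space_report()['bits_per_kmer']:.2f} bits/k-mer")
```

prints

```
indexed 19700 k-mers, 2187 minimizers
lookup: handle=101 string=1 orientation=+1 position=101
access: True
stream: 120 windows, 120 hits, 4 seeds, 116 extensions (rate 0.967)
space: 4.25 bits/k-mer
```

The k-mer starting at position 101 of string 1 receives handle 101
(handles run consecutively along a string), `access` inverts the lookup,
and streaming over a 150 bp error-free slice needs only 4 full lookups —
the remaining 116 windows are resolved by extension (the default budget of
32 forces a periodic re-seed).  The same index is reachable from a shell:
`sshash build -i spss.fa -k 31 -m 15 --mode canonical -o index.ssh`, then
`sshash query`, `sshash access`, `sshash stats`, `sshash gen`.

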