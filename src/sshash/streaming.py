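"""Budget-based streaming LOOKUP over reads.

Consecutive k-mers of a read overlap by k-1 characters, so after a match at
position q in S the next window very likely sits at q+1 (forward strand) or
q-1 (reverse strand).  The streaming state carries the last match (handle,
string id, orientation, position), the per-window minimizer pair maintained
incrementally, a *found* flag recording whether the last seeded minimizer
exists in S at all, and an integer *budget*.

Per window, in order:

1. if there is a previous match and budget > 0, attempt an *extension*:
   compare the window against the shifted position on the matched strand
   (staying inside the same SPSS string); on success emit handle +/- 1 and
   decrement the budget — extensions are attempted even when the minimizer
   changes through the stream;
2. otherwise, if the last seeded minimizer pair is unchanged and was not
   found in S, emit a negative answer without any lookup;
3. otherwise *Seed*: run the full lookup, store its state, reset the budget.

Windows containing non-ACGT symbols emit a negative answer and restart the
state.  The output is window-for-window identical to issuing independent
lookups; the streaming machinery only changes the work done per window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .index import LookupResult, SsHashIndex, _MISS
from .kmer import _ENC, codes_to_int, rc_code
from .minimizer import streaming_minimizer_pairs

DEFAULT_BUDGET = 32


@dataclass
class StreamStats:
    windows: int = 0
    positives: int = 0
    extensions: int = 0
    seeds: int = 0
    skipped: int = 0  # negative answers emitted without a lookup

    @property
    def extension_rate(self) -> float:
        return self.extensions / self.windows if self.windows else 0.0

    def as_tuple(self) -> tuple:
        return (self.windows, self.positives, self.extensions, self.seeds,
                self.extension_rate)


@dataclass
class StreamRun:
    """Results of one streaming pass, one LookupResult per k-window."""

    results: list[LookupResult] = field(default_factory=list)
    stats: StreamStats = field(default_factory=StreamStats)

    def __iter__(self):
        return iter(self.results)

    def __len__(self):
        return len(self.results)

    def __getitem__(self, i):
        return self.results[i]


def stream_stats(run: StreamRun) -> tuple:
    """(total windows, positive hits, extensions, seeds, extension rate)."""
    return run.stats.as_tuple()


def _segments(seq: str, k: int):
    """Maximal ACGT runs of seq as (start0, codes); shorter-than-k runs are
    kept so the caller can count their (zero) windows uniformly."""
    codes: list[int] = []
    start = 0
    for idx, ch in enumerate(seq.upper()):
        c = _ENC.get(ch)
        if c is None:
            if codes:
                yield start, np.asarray(codes, dtype=np.uint8)
                codes = []
            start = idx + 1
        else:
            if not codes:
                start = idx
            codes.append(c)
    if codes:
        yield start, np.asarray(codes, dtype=np.uint8)


def stream_lookup(
    index: SsHashIndex, seq: str, budget: int = DEFAULT_BUDGET
) -> StreamRun:
    """LOOKUP(s): one result per k-window of ``seq``, left to right."""
    k = index.k
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    run = StreamRun()
    stats = run.stats
    total_windows = len(seq) - k + 1
    covered = np.zeros(total_windows, dtype=bool)
    window_results: dict[int, LookupResult] = {}

    for seg_start, codes in _segments(seq, k):
        if len(codes) < k:
            continue
        _stream_segment(index, codes, seg_start, budget, window_results, stats)
        nwin = len(codes) - k + 1
        covered[seg_start : seg_start + nwin] = True

    for w in range(total_windows):
        if covered[w]:
            run.results.append(window_results[w])
        else:
            run.results.append(_MISS)
            stats.skipped += 1
    stats.windows = total_windows
    stats.positives = sum(1 for r in run.results if r.is_hit)
    return run


def _stream_segment(index, codes, seg_start, budget, out, stats):
    k = index.k
    packed = index.spss.packed
    starts = index.spss.starts
    kmask = (1 << (2 * k)) - 1
    kshift = 2 * (k - 1)

    # rolling forward / reverse-complement codes of the current window
    fcode = codes_to_int(codes[:k])
    rcode = rc_code(fcode, k)

    start = True
    h = None
    i = 0
    o = 0
    q = 0
    found = False
    budget_left = 0
    last_pair = None

    pair_gen = streaming_minimizer_pairs(codes, index.scheme)
    for w, pair in enumerate(pair_gen):
        if w > 0:
            b = int(codes[w + k - 1])
            fcode = ((fcode >> 2) | (b << kshift)) & kmask
            rcode = ((rcode << 2) | (3 - b)) & kmask
        mini_pair = (pair[0], pair[2])  # fwd m-mer code, reverse m-mer code

        # (1) extension
        if not start and budget_left > 0 and h is not None:
            q_new = q + o
            p_i, p_next = int(starts[i - 1]), int(starts[i])
            if p_i <= q_new <= p_next - k:
                want = fcode if o > 0 else rcode
                if packed.window_int(q_new, k) == want:
                    q = q_new
                    h = h + o
                    budget_left -= 1
                    out[seg_start + w] = LookupResult(h, i, o, q, found)
                    stats.extensions += 1
                    last_pair = mini_pair
                    start = False
                    continue

        # (2) negative skip
        if not start and not found and h is None and mini_pair == last_pair:
            out[seg_start + w] = _MISS
            stats.skipped += 1
            continue

        # (3) seed
        res = index.lookup_code(fcode)
        out[seg_start + w] = res
        stats.seeds += 1
        h = res.handle
        i = res.string_id
        o = res.orientation
        q = res.position
        found = res.found
        budget_left = budget
        last_pair = mini_pair
        start = False
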