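"""Back-splice (head-to-tail) junction calling from single-end reads.

Strategy: split each read into a head anchor (first ``anchor_len`` bases)
and a tail anchor (last ``anchor_len`` bases) and place both exactly
(0 mismatches) with a k-mer index of the genome.  A read is a junction
candidate when both anchors place uniquely on the same chromosome and
strand in *reversed* genomic order (the tail anchor upstream of the head
anchor on the transcript strand).  Both anchors are then extended
maximally toward the breakpoint; the call is made only when exactly one
breakpoint is consistent with the read and flanked by the canonical
splice signal — AG immediately upstream of the acceptor and GT
immediately downstream of the donor, on the transcript strand.
Reads with multiple signal-consistent breakpoints are rejected as
ambiguous rather than guessed.

Calls are collapsed per (chrom, strand, acceptor, donor); support is the
number of *distinct read sequences* and junctions under
``min_unique_reads`` (default 2) are dropped.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from ._util import revcomp
from .core_io import CircCandidate, Genome

DEFAULT_ANCHOR_LEN = 20
DEFAULT_MIN_UNIQUE_READS = 2
DEFAULT_MAX_SPAN = 100_000


class KmerIndex:
    """Exact-match index of all genomic k-mers (forward strand stored;
    reverse-complement hits are resolved at query time)."""

    def __init__(self, genome: Genome, k: int):
        if k < 1:
            raise ValueError("k must be positive")
        self.k = k
        self.genome = genome
        index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in genome.items():
            for pos in range(len(seq) - k + 1):
                index[seq[pos:pos + k]].append((chrom, pos))
        self._index = dict(index)

    def lookup(self, query: str) -> list[tuple[str, int, str]]:
        """All (chrom, pos, strand) occurrences of ``query``.

        A '-' hit at forward position p means the query matches the
        reverse complement of genome[p:p+k].
        """
        if len(query) != self.k:
            raise ValueError(f"query length {len(query)} != k={self.k}")
        hits = [(c, p, "+") for c, p in self._index.get(query, ())]
        hits += [(c, p, "-") for c, p in self._index.get(revcomp(query), ())]
        return hits


def build_index(genome: Genome, k: int) -> KmerIndex:
    return KmerIndex(genome, k)


def extract_anchors(seq: str, anchor_len: int = DEFAULT_ANCHOR_LEN) -> tuple[str, str] | None:
    """(head, tail) anchors, or None when the read is too short."""
    if len(seq) < 2 * anchor_len:
        return None
    return seq[:anchor_len], seq[-anchor_len:]


@dataclass(frozen=True)
class JunctionCall:
    """One read's back-splice call: genomic span [start, end) and strand.

    ``start`` is the acceptor position (first base of the circle) and
    ``end`` the donor position (one past its last base) in forward
    genomic coordinates, regardless of strand.
    """

    chrom: str
    strand: str
    start: int
    end: int
    read_id: str
    read_seq: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("acceptor must precede donor")


def _consistent_breakpoints(work_seq: str, read: str, head_pos: int, tail_pos: int,
                            anchor_len: int) -> list[int]:
    """Breakpoints b (read index) splitting the read into a donor suffix
    match at head_pos and an acceptor prefix match ending at the tail
    anchor, each flanked by the GT / AG signal in ``work_seq``."""
    L = len(read)
    k = anchor_len
    n = len(work_seq)
    # extend head anchor rightwards along the genome
    e1 = 0
    while (k + e1 < L and head_pos + k + e1 < n
           and read[k + e1] == work_seq[head_pos + k + e1]):
        e1 += 1
    # extend tail anchor leftwards
    e2 = 0
    while (k + e2 < L and tail_pos - e2 - 1 >= 0
           and read[L - k - e2 - 1] == work_seq[tail_pos - e2 - 1]):
        e2 += 1
    lo = max(k, L - k - e2)
    hi = min(L - k, k + e1)
    valid = []
    for b in range(lo, hi + 1):
        donor_end = head_pos + b                      # one past donor exon
        acceptor = tail_pos - (L - k) + b             # first base of acceptor exon
        if acceptor < 2 or donor_end + 2 > n:
            continue
        if acceptor >= donor_end:
            continue
        if work_seq[donor_end:donor_end + 2] == "GT" and \
           work_seq[acceptor - 2:acceptor] == "AG":
            valid.append(b)
    return valid


def call_junction(read_id: str, seq: str, index: KmerIndex, genome: Genome,
                  anchor_len: int = DEFAULT_ANCHOR_LEN,
                  max_span: int = DEFAULT_MAX_SPAN,
                  tally: Counter | None = None) -> JunctionCall | None:
    """Call a head-to-tail junction from a single read, or None.

    ``tally`` (optional Counter) accumulates per-read outcomes:
    too_short, anchor_not_unique, strand_or_chrom_mismatch, colinear,
    span_exceeded, no_signal, ambiguous_breakpoint, called.
    """
    t = tally if tally is not None else Counter()
    anchors = extract_anchors(seq, anchor_len)
    if anchors is None:
        t["too_short"] += 1
        return None
    head, tail = anchors
    head_hits = index.lookup(head)
    tail_hits = index.lookup(tail)
    if len(head_hits) != 1 or len(tail_hits) != 1:
        t["anchor_not_unique"] += 1
        return None
    (hc, hp, hs), (tc, tp, ts) = head_hits[0], tail_hits[0]
    if hc != tc or hs != ts:
        t["strand_or_chrom_mismatch"] += 1
        return None
    chrom, strand = hc, hs
    fwd = genome[chrom]
    L = len(fwd)
    k = anchor_len
    if strand == "+":
        work_seq, wh, wt = fwd, hp, tp
    else:
        # move to reverse-complement coordinates so '+' logic applies
        work_seq = revcomp(fwd)
        wh = L - hp - k
        wt = L - tp - k
    if wt + k > wh:
        t["colinear"] += 1
        return None
    valid = _consistent_breakpoints(work_seq, seq, wh, wt, k)
    if not valid:
        t["no_signal"] += 1
        return None
    if len(valid) > 1:
        t["ambiguous_breakpoint"] += 1
        return None
    b = valid[0]
    donor_end = wh + b
    acceptor = wt - (len(seq) - k) + b
    if donor_end - acceptor > max_span:
        t["span_exceeded"] += 1
        return None
    if strand == "+":
        start, end = acceptor, donor_end
    else:
        start, end = L - donor_end, L - acceptor
    t["called"] += 1
    return JunctionCall(chrom, strand, start, end, read_id, seq)


def detect_reads(reads: Iterable[tuple[str, str]], genome: Genome,
                 anchor_len: int = DEFAULT_ANCHOR_LEN,
                 max_span: int = DEFAULT_MAX_SPAN,
                 index: KmerIndex | None = None,
                 ) -> tuple[list[JunctionCall], Counter]:
    """Run the junction caller over a read set."""
    if index is None:
        index = build_index(genome, anchor_len)
    elif index.k != anchor_len:
        raise ValueError("index k does not match anchor_len")
    tally: Counter = Counter()
    calls = []
    for read_id, seq in reads:
        call = call_junction(read_id, seq.upper(), index, genome,
                             anchor_len=anchor_len, max_span=max_span, tally=tally)
        if call is not None:
            calls.append(call)
    return calls, tally


def collapse_and_filter(calls: Sequence[JunctionCall],
                        min_unique_reads: int = DEFAULT_MIN_UNIQUE_READS,
                        ) -> list[CircCandidate]:
    """Group calls per junction and keep those with enough unique support.

    Support is the number of distinct read *sequences* ("unique reads");
    identical duplicate reads count once.  Output order is deterministic
    (chrom, start, end, strand) and independent of input order.
    """
    groups: dict[tuple[str, str, int, int], list[JunctionCall]] = defaultdict(list)
    for call in calls:
        groups[(call.chrom, call.strand, call.start, call.end)].append(call)
    out = []
    for (chrom, strand, start, end), members in groups.items():
        unique = len({m.read_seq for m in members})
        if unique < min_unique_reads:
            continue
        out.append(CircCandidate(
            chrom, start, end, strand,
            junction_read_count=unique,
            unique_read_ids=tuple(sorted(m.read_id for m in members))))
    out.sort(key=lambda c: (c.chrom, c.start, c.end, c.strand))
    return out
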