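"""Host assignment and annotation categories for circRNA candidates.

Each candidate receives exactly one of five categories:
coding_exon, antisense, intronic, noncoding_gene, intergenic.

Priority when several features overlap a candidate:

1. both junction boundaries coincide (within ``boundary_tol`` nt) with
   exon boundaries of a same-strand transcript -> coding_exon when that
   transcript has a CDS (UTR exons included), else noncoding_gene;
2. candidate lies entirely within one intron of a same-strand
   transcript -> intronic;
3. candidate overlaps a same-strand transcript without exon-bounded
   junctions -> classified by the transcript's coding flag (host kept,
   spliced length unknown);
4. overlap only on the opposite strand -> antisense;
5. no overlap -> intergenic.

When several same-strand transcripts are exon-bounded the host is the one
minimizing spliced length, tie-broken lexicographically by transcript id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .core_io import CATEGORIES, CircCandidate, Transcript

log = logging.getLogger(__name__)

DEFAULT_BOUNDARY_TOL = 2


@dataclass(frozen=True)
class AnnotationResult:
    circ_id: str
    host_transcript_id: str | None
    orientation: str  # sense | antisense
    category: str
    genomic_length: int
    spliced_length: int | None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "intergenic" and self.host_transcript_id is not None:
            raise ValueError("intergenic candidates have no host")
        if self.genomic_length <= 0:
            raise ValueError("genomic_length must be positive")


def _overlaps(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def spliced_length(candidate: CircCandidate, host: Transcript) -> int:
    """Sum of host exon lengths intersected with the circle span."""
    return sum(max(0, min(b, candidate.end) - max(a, candidate.start))
               for a, b in host.exons)


def _exon_bounded(cand: CircCandidate, tx: Transcript, tol: int) -> bool:
    starts = [a for a, _ in tx.exons]
    ends = [b for _, b in tx.exons]
    i = next((idx for idx, s in enumerate(starts) if abs(s - cand.start) <= tol), None)
    j = next((idx for idx, e in enumerate(ends) if abs(e - cand.end) <= tol), None)
    return i is not None and j is not None and i <= j


def classify_candidate(candidate: CircCandidate, transcripts: Sequence[Transcript],
                       boundary_tol: int = DEFAULT_BOUNDARY_TOL) -> AnnotationResult:
    """Assign host, orientation, category and lengths to one candidate."""
    same, anti = [], []
    for tx in transcripts:
        if tx.chrom != candidate.chrom:
            continue
        if not _overlaps(candidate.start, candidate.end, tx.start, tx.end):
            continue
        (same if tx.strand == candidate.strand else anti).append(tx)

    glen = candidate.genomic_length

    # rule 1: exon-bounded on a same-strand transcript
    bounded = [tx for tx in same if _exon_bounded(candidate, tx, boundary_tol)]
    if bounded:
        host = min(bounded, key=lambda tx: (spliced_length(candidate, tx),
                                            tx.transcript_id))
        category = "coding_exon" if host.coding else "noncoding_gene"
        return AnnotationResult(candidate.circ_id, host.transcript_id, "sense",
                                category, glen, spliced_length(candidate, host))

    # rule 2: fully intronic in a same-strand transcript
    for tx in sorted(same, key=lambda t: t.transcript_id):
        for ia, ib in tx.introns():
            if ia <= candidate.start and candidate.end <= ib:
                return AnnotationResult(candidate.circ_id, tx.transcript_id,
                                        "sense", "intronic", glen, None)

    # rule 3: other same-strand overlap, classified by host coding status
    if same:
        host = min(same, key=lambda t: t.transcript_id)
        category = "coding_exon" if host.coding else "noncoding_gene"
        return AnnotationResult(candidate.circ_id, host.transcript_id, "sense",
                                category, glen, None)

    # rule 4: overlap only on the opposite strand
    if anti:
        host = min(anti, key=lambda t: t.transcript_id)
        return AnnotationResult(candidate.circ_id, host.transcript_id,
                                "antisense", "antisense", glen, None)

    # rule 5: intergenic
    return AnnotationResult(candidate.circ_id, None, "sense", "intergenic",
                            glen, None)


def annotate_candidates(candidates: Sequence[CircCandidate],
                        transcripts: Sequence[Transcript],
                        boundary_tol: int = DEFAULT_BOUNDARY_TOL,
                        ) -> list[CircCandidate]:
    """Return annotated copies of the candidates (order preserved)."""
    out = []
    for cand in candidates:
        res = classify_candidate(cand, transcripts, boundary_tol)
        out.append(replace(cand, host_transcript_id=res.host_transcript_id,
                           orientation=res.orientation, category=res.category,
                           spliced_length=res.spliced_length))
    return out


def catalog_summary(annotated: Sequence[CircCandidate | AnnotationResult],
                    ) -> pd.DataFrame:
    """Counts and percentage shares per annotation category."""
    if not annotated:
        log.warning("empty catalog; summary has no rows")
        return pd.DataFrame(columns=["category", "count", "share_pct"])
    counts = {cat: 0 for cat in CATEGORIES}
    for item in annotated:
        if item.category is None:
            raise ValueError("unannotated candidate in summary input")
        counts[item.category] += 1
    total = sum(counts.values())
    return pd.DataFrame([
        {"category": cat, "count": n, "share_pct": 100.0 * n / total}
        for cat, n in counts.items() if n > 0
    ])
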