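"""Junction / linear boundary read counting, CLR and host-gene TPM.

The circular-to-linear ratio of a candidate is

    CLR = reads_circular / max(reads_linear_5p, reads_linear_3p)

with the denominator replaced by a pseudocount of 1 only when *both*
linear counts are zero.  Report columns are rounded half-up to one
decimal; full precision is kept internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import round_half_up
from .core_io import CircCandidate
from .simulate import parse_truth_tag

PLACEMENT_COLUMNS = ["read_id", "kind", "circ_id", "donor_site", "acceptor_site"]
DEFAULT_BOUNDARY_FLANK = 5


@dataclass(frozen=True)
class QuantRecord:
    circ_id: str
    reads_circular: int
    reads_linear_5p: int
    reads_linear_3p: int
    clr: float
    clr_rounded: float
    host_tpm: float | None = None

    def __post_init__(self):
        for n in (self.reads_circular, self.reads_linear_5p, self.reads_linear_3p):
            if n < 0:
                raise ValueError("read counts must be non-negative")
        if self.clr < 0:
            raise ValueError("CLR must be non-negative")


def clr(reads_circular: int, reads_linear_5p: int, reads_linear_3p: int) -> float:
    """Circular-to-linear ratio at full precision."""
    if min(reads_circular, reads_linear_5p, reads_linear_3p) < 0:
        raise ValueError("read counts must be non-negative")
    denom = max(reads_linear_5p, reads_linear_3p)
    if denom == 0:
        denom = 1  # pseudocount: no linearly spliced reads detected
    return reads_circular / denom


def clr_rounded(reads_circular: int, reads_linear_5p: int, reads_linear_3p: int) -> float:
    """CLR rounded half-up to one decimal (printed-table convention)."""
    return round_half_up(clr(reads_circular, reads_linear_5p, reads_linear_3p), 1)


# ---------------------------------------------------------------------------
# Read placements

def placements_from_truth(reads: Iterable[tuple[str, str]]) -> pd.DataFrame:
    """Build a read-placement table from simulator truth tags.

    One row per junction-spanning circular read (kind='junction') and one
    row per linear splice crossing (kind='linear'); a read crossing two
    boundaries yields two rows.
    """
    rows = []
    for name, _seq in reads:
        tag = parse_truth_tag(name)
        if tag["kind"] == "circ":
            if tag["junction"]:
                rows.append({"read_id": tag["read_id"], "kind": "junction",
                             "circ_id": tag["circ_id"],
                             "donor_site": -1, "acceptor_site": -1})
        else:
            for d, a in tag["crossings"]:
                rows.append({"read_id": tag["read_id"], "kind": "linear",
                             "circ_id": "-", "donor_site": d, "acceptor_site": a})
    return pd.DataFrame(rows, columns=PLACEMENT_COLUMNS)


def count_boundary_reads(placements: pd.DataFrame,
                         candidate: CircCandidate) -> tuple[int, int]:
    """(reads_linear_5p, reads_linear_3p) for one candidate.

    A linear placement crossing the candidate's acceptor-side splice site
    increments the 5' count; one crossing the donor-side site increments
    the 3' count.  A read crossing both increments both.
    """
    lin = placements[placements["kind"] == "linear"]
    n5 = int((lin["acceptor_site"] == candidate.acceptor_site).sum())
    n3 = int((lin["donor_site"] == candidate.donor_site).sum())
    return n5, n3


def quantify_candidates(candidates: Sequence[CircCandidate],
                        placements: pd.DataFrame,
                        junction_from: str = "candidate",
                        ) -> dict[str, QuantRecord]:
    """QuantRecord per candidate.

    ``junction_from='candidate'`` takes reads_circular from the detector's
    unique-read support; ``'placements'`` counts junction placements
    (e.g. simulator truth) instead.
    """
    if junction_from not in ("candidate", "placements"):
        raise ValueError(f"bad junction_from {junction_from!r}")
    jcounts = None
    if junction_from == "placements":
        jc = placements[placements["kind"] == "junction"]
        jcounts = jc.groupby("circ_id").size().to_dict()
    out = {}
    for cand in candidates:
        n5, n3 = count_boundary_reads(placements, cand)
        nc = (cand.junction_read_count if jcounts is None
              else int(jcounts.get(cand.circ_id, 0)))
        out[cand.circ_id] = QuantRecord(
            cand.circ_id, nc, n5, n3,
            clr=clr(nc, n5, n3), clr_rounded=clr_rounded(nc, n5, n3))
    return out


def host_tpm(gene_counts: Mapping[str, int],
             gene_spliced_lengths: Mapping[str, int]) -> dict[str, float]:
    """Transcripts-per-million from read counts and spliced lengths."""
    rates = {}
    for gene, count in gene_counts.items():
        length = gene_spliced_lengths.get(gene)
        if length is None or length <= 0:
            raise ValueError(f"zero or missing spliced length for gene {gene!r}")
        if count < 0:
            raise ValueError(f"negative count for gene {gene!r}")
        rates[gene] = count / length
    total = sum(rates.values())
    if total == 0:
        return {g: 0.0 for g in rates}
    return {g: 1e6 * r / total for g, r in rates.items()}
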