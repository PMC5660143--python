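"""Junction-spanning ORFs and tryptic peptides from circular sequences.

The spliced circle is treated as a ring whose position 0 is the first
base of the acceptor exon on the transcript strand, so the head-to-tail
junction sits between the last and first base of the ring.  ORFs are
enumerated on the doubled sequence (ring + ring): an AUG-initiated,
stop-terminated reading frame is reported iff its codon span crosses the
junction (index ring_length on the doubled string).  Frames without an
in-ring stop are truncated at ``max_loops`` times the ring length and
flagged, consistent with ignoring rolling-circle concatemers.

Peptides come from an in-silico tryptic digest (cleave after K/R, not
before P); only peptides whose encoding codons overlap the junction are
kept for the search database.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

from ._util import revcomp
from .core_io import CircCandidate, Genome, Transcript

DEFAULT_MIN_PEP_LEN = 7
DEFAULT_MAX_PEP_LEN = 35


@dataclass(frozen=True)
class CircularSequence:
    circ_id: str
    ring: str
    junction_index: int = 0  # position 0 = first base of the acceptor exon

    def __post_init__(self):
        if not self.ring:
            raise ValueError("empty ring sequence")
        bad = set(self.ring) - set("ACGT")
        if bad:
            raise ValueError(f"invalid ring characters: {sorted(bad)}")


@dataclass(frozen=True)
class JunctionOrf:
    """An ORF on the doubled ring whose codons cross the junction.

    ``start`` is the nt offset of the AUG on the doubled sequence
    (0 <= start < ring length); ``frame`` = start % 3.
    """

    circ_id: str
    frame: int
    start: int
    aa_seq: str
    stop_found: bool
    crosses_junction: bool = True

    @property
    def no_stop_in_circle(self) -> bool:
        return not self.stop_found

    @property
    def end_nt(self) -> int:
        """One past the ORF's codon span on the doubled sequence
        (includes the stop codon when one was found)."""
        return self.start + 3 * len(self.aa_seq) + (3 if self.stop_found else 0)


@dataclass(frozen=True)
class JunctionPeptide:
    circ_id: str
    peptide: str
    orf_start: int
    start_nt: int  # codon span on the doubled sequence
    end_nt: int
    junction_offset_aa: int  # index of the residue whose codon contains/follows the junction


def circular_sequence(candidate: CircCandidate, host: Transcript,
                      genome: Genome) -> CircularSequence:
    """Spliced ring of an exon-bounded candidate (5'->3' on the transcript strand)."""
    if candidate.category not in (None, "coding_exon", "noncoding_gene"):
        raise ValueError(f"{candidate.circ_id}: no spliced model for "
                         f"{candidate.category} candidates")
    if host.chrom != candidate.chrom:
        raise ValueError("host transcript on a different chromosome")
    parts = [genome[host.chrom][max(a, candidate.start):min(b, candidate.end)]
             for a, b in host.exons
             if min(b, candidate.end) > max(a, candidate.start)]
    if not parts:
        raise ValueError(f"{candidate.circ_id}: no exonic overlap with host")
    seq = "".join(parts)
    if host.strand == "-":
        seq = revcomp(seq)
    return CircularSequence(candidate.circ_id, seq)


def _translate(nt: str) -> str:
    # truncate to whole codons; '*' marks stops
    usable = len(nt) - len(nt) % 3
    return str(Seq(nt[:usable]).translate())


def find_junction_orfs(ring: CircularSequence | str, max_loops: int = 1,
                       circ_id: str = "ring") -> list[JunctionOrf]:
    """Maximal AUG-to-stop ORFs on the doubled ring that cross the junction.

    A start is maximal when no upstream in-frame AUG shares its open
    stretch (no stop codon in between).  Starts are restricted to
    [0, ring length): any ORF starting later is a rotation duplicate.
    """
    if isinstance(ring, CircularSequence):
        seq, circ_id = ring.ring, ring.circ_id
    else:
        seq = ring
    n = len(seq)
    doubled = seq + seq
    limit_nt = 3 * ((max_loops * n) // 3)
    orfs = []
    for s in range(n):
        if doubled[s:s + 3] != "ATG":
            continue
        # maximality: walk back in frame until a stop codon or sequence start
        maximal = True
        p = s - 3
        while p >= 0:
            codon = doubled[p:p + 3]
            if codon in ("TAA", "TAG", "TGA"):
                break
            if codon == "ATG":
                maximal = False
                break
            p -= 3
        if not maximal:
            continue
        aa = _translate(doubled[s:s + limit_nt])
        stop_at = aa.find("*")
        stop_found = stop_at != -1
        aa_seq = aa[:stop_at] if stop_found else aa
        end_nt = s + 3 * len(aa_seq) + (3 if stop_found else 0)
        if not (s < n < end_nt):
            continue  # does not cross the junction
        orfs.append(JunctionOrf(circ_id, s % 3, s, aa_seq, stop_found))
    return orfs


def tryptic_peptides(aa_seq: str, missed_cleavages: int = 0) -> list[tuple[int, str]]:
    """(start_index, peptide) fragments of a tryptic digest.

    Cleaves C-terminally of K/R except before proline; adjacent fragments
    are merged for up to ``missed_cleavages`` skipped sites.
    """
    if not aa_seq:
        return []
    cuts = [i + 1 for i, aa in enumerate(aa_seq[:-1])
            if aa in "KR" and aa_seq[i + 1] != "P"]
    bounds = [0] + cuts + [len(aa_seq)]
    base = [(bounds[i], aa_seq[bounds[i]:bounds[i + 1]])
            for i in range(len(bounds) - 1)]
    out = []
    for i in range(len(base)):
        for mc in range(missed_cleavages + 1):
            if i + mc >= len(base):
                break
            start = base[i][0]
            pep = "".join(p for _, p in base[i:i + mc + 1])
            out.append((start, pep))
    return out


def junction_peptides(orfs: Sequence[JunctionOrf], ring: CircularSequence | str,
                      min_len: int = DEFAULT_MIN_PEP_LEN,
                      max_len: int = DEFAULT_MAX_PEP_LEN,
                      missed_cleavages: int = 0) -> list[JunctionPeptide]:
    """Tryptic peptides from junction ORFs whose codons overlap the junction."""
    n = len(ring.ring) if isinstance(ring, CircularSequence) else len(ring)
    out = []
    seen = set()
    for orf in orfs:
        for aa_start, pep in tryptic_peptides(orf.aa_seq, missed_cleavages):
            if not min_len <= len(pep) <= max_len:
                continue
            start_nt = orf.start + 3 * aa_start
            end_nt = start_nt + 3 * len(pep)
            if not (start_nt < n < end_nt):
                continue  # codons do not straddle the junction
            key = (orf.circ_id, orf.start, start_nt, pep)
            if key in seen:
                continue
            seen.add(key)
            out.append(JunctionPeptide(orf.circ_id, pep, orf.start, start_nt,
                                       end_nt, (n - start_nt) // 3))
    return out


def write_peptide_fasta(peptides: Sequence[JunctionPeptide], path: str | Path) -> None:
    """FASTA database of junction peptides; headers carry circ_id, the ORF
    frame offset and the junction position within the peptide."""
    with open(path, "w") as fh:
        for i, p in enumerate(peptides, 1):
            fh.write(f">pep{i:05d} circ_id={p.circ_id} orf_start={p.orf_start} "
                     f"junction_aa={p.junction_offset_aa}\n{p.peptide}\n")


def filter_hits(observed: Iterable[str],
                db: Sequence[JunctionPeptide]) -> list[dict]:
    """Match observed peptide strings against the junction-peptide database.

    Verdicts: 'junction-spanning match' for exact hits, 'non-junction'
    otherwise (the class of peptides that match a host protein but not
    the back-splice junction).
    """
    db_index: dict[str, list[JunctionPeptide]] = {}
    for p in db:
        db_index.setdefault(p.peptide, []).append(p)
    report = []
    for pep in observed:
        hits = db_index.get(pep, [])
        report.append({
            "peptide": pep,
            "verdict": "junction-spanning match" if hits else "non-junction",
            "circ_ids": sorted({h.circ_id for h in hits}),
        })
    return report
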