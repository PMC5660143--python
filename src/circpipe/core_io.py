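"""Core domain types and file I/O.

All coordinates are 0-based, half-open, on the forward genomic strand.
GTF (1-based inclusive) is converted on read and write; BED12 is native.

The circRNA catalog TSV mirrors a circBase-style record: genomic span,
strand, junction/linear read support, circular-to-linear ratio, host
transcript, orientation, annotation category and genomic/spliced lengths.
Catalog ``start`` is the first base of the circle's 5'-most exon and
``end`` is one past the last base of its 3'-most exon (a strand-independent
genomic span; strand is carried separately).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")
CATEGORIES = ("coding_exon", "antisense", "intronic", "noncoding_gene", "intergenic")

CATALOG_COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand",
    "circ_id",
    "junction_reads",
    "linear_5p_reads",
    "linear_3p_reads",
    "CLR",
    "host_transcript",
    "orientation",
    "category",
    "genomic_length",
    "spliced_length",
]


class Genome:
    """Chromosome name -> uppercase A/C/G/T/N sequence.

    Names must be unique and sequences non-empty; enforced at construction.
    """

    def __init__(self, sequences: Mapping[str, str]):
        seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            if name in seqs:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            s = str(seq).upper()
            if not s:
                raise ValueError(f"empty sequence for chromosome {name!r}")
            bad = set(s) - VALID_ALPHABET
            if bad:
                raise ValueError(f"invalid characters in {name!r}: {sorted(bad)}")
            seqs[name] = s
        self._seqs = seqs

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __iter__(self):
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self._seqs == other._seqs

    def items(self):
        return self._seqs.items()

    def length(self, name: str) -> int:
        return len(self._seqs[name])


@dataclass(frozen=True)
class Transcript:
    """A transcript: ordered exon intervals on one chromosome.

    Exons are 0-based half-open intervals sorted by genomic start and
    non-overlapping.  ``exon_index_tx(i)`` maps a 5'->3' transcript-order
    index to the genomic-order index (identity on '+', reversed on '-').
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    coding: bool = False
    cds: tuple[int, int] | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript must have at least one exon")
        exons = tuple(sorted((int(a), int(b)) for a, b in self.exons))
        for a, b in exons:
            if not a < b:
                raise ValueError(f"degenerate exon [{a},{b})")
        for (_, b1), (a2, _) in zip(exons, exons[1:]):
            if a2 < b1:
                raise ValueError("overlapping exons")
        object.__setattr__(self, "exons", exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    def exon_index_tx(self, tx_order_index: int) -> int:
        """Genomic-order exon index for a 5'->3' transcript-order index."""
        n = len(self.exons)
        if not 0 <= tx_order_index < n:
            raise IndexError(tx_order_index)
        return tx_order_index if self.strand == "+" else n - 1 - tx_order_index

    def introns(self) -> list[tuple[int, int]]:
        return [(b1, a2) for (_, b1), (a2, _) in zip(self.exons, self.exons[1:])]

    def spliced_sequence(self, genome: Genome) -> str:
        from ._util import revcomp

        seq = "".join(genome[self.chrom][a:b] for a, b in self.exons)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass
class CircCandidate:
    """A called head-to-tail junction with optional annotation fields.

    ``start``/``end`` delimit the genomic extent of the circle
    (0-based half-open); ``junction_read_count`` holds the number of
    distinct read sequences supporting the back-splice.
    """

    chrom: str
    start: int
    end: int
    strand: str
    junction_read_count: int = 0
    unique_read_ids: tuple[str, ...] = ()
    host_transcript_id: str | None = None
    orientation: str = "sense"
    category: str | None = None
    spliced_length: int | None = None

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"start must be < end ({self.start}, {self.end})")
        if self.junction_read_count < 0:
            raise ValueError("negative junction_read_count")
        if self.category is not None and self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def genomic_length(self) -> int:
        return self.end - self.start

    @property
    def circ_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @property
    def acceptor_site(self) -> int:
        """Genomic coordinate of the 5' (acceptor) boundary on the transcript strand."""
        return self.start if self.strand == "+" else self.end

    @property
    def donor_site(self) -> int:
        """Genomic coordinate of the 3' (donor) boundary on the transcript strand."""
        return self.end if self.strand == "+" else self.start


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> Genome:
    """Read a FASTA file into a :class:`Genome` (case folded to uppercase)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA record: {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(seqs)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# FASTQ (4-line records, Phred+33; qualities are not interpreted)

def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Return [(read_name, sequence), ...] from a plain 4-line FASTQ."""
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ near {header!r}")
            if len(seq) != len(qual):
                raise ValueError(f"sequence/quality length mismatch for {header!r}")
            reads.append((header[1:].rstrip("\n").split(" ")[0], seq.upper()))
    return reads


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


# ---------------------------------------------------------------------------
# Gene models (GTF 2.2 and BED12)

def read_gene_models(path: str | Path, format: str = "gtf",
                     genome: Genome | None = None) -> list[Transcript]:
    """Read transcripts from GTF or BED12 into 0-based half-open intervals.

    If ``genome`` is given, exons are checked against chromosome bounds
    (hard error when outside).  Unsorted exon input is sorted with a
    logged warning.
    """
    if format == "gtf":
        txs = _read_gtf(path)
    elif format == "bed12":
        txs = _read_bed12(path)
    else:
        raise ValueError(f"unknown gene-model format {format!r}")
    if genome is not None:
        for tx in txs:
            if tx.chrom not in genome:
                raise ValueError(f"{tx.transcript_id}: unknown chromosome {tx.chrom!r}")
            clen = genome.length(tx.chrom)
            for a, b in tx.exons:
                if a < 0 or b > clen:
                    raise ValueError(
                        f"{tx.transcript_id}: exon [{a},{b}) outside chromosome "
                        f"{tx.chrom} (length {clen})")
    return txs


def _parse_gtf_attrs(attr_field: str) -> dict[str, str]:
    attrs = {}
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def _read_gtf(path: str | Path) -> list[Transcript]:
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, chrom, strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attr = fields[:9]
            if feature not in ("exon", "CDS"):
                continue
            attrs = _parse_gtf_attrs(attr)
            tx_id = attrs["transcript_id"]
            iv = (int(start) - 1, int(end))  # GTF is 1-based inclusive
            prev = meta.setdefault(tx_id, (attrs.get("gene_id", tx_id), chrom, strand))
            if (prev[1], prev[2]) != (chrom, strand):
                raise ValueError(f"{tx_id}: inconsistent chrom/strand")
            (exons if feature == "exon" else cds).setdefault(tx_id, []).append(iv)
    txs = []
    for tx_id, (gene_id, chrom, strand) in meta.items():
        ivs = exons.get(tx_id)
        if not ivs:
            raise ValueError(f"{tx_id}: no exon features")
        if ivs != sorted(ivs):
            log.warning("%s: exons not sorted in input; sorting", tx_id)
        cds_ivs = cds.get(tx_id)
        cds_span = None
        if cds_ivs:
            cds_span = (min(a for a, _ in cds_ivs), max(b for _, b in cds_ivs))
        txs.append(Transcript(tx_id, gene_id, chrom, strand, tuple(sorted(ivs)),
                              coding=cds_ivs is not None, cds=cds_span))
    txs.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return txs


def _read_bed12(path: str | Path) -> list[Transcript]:
    txs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, chrom_start = f[0], int(f[1])
            name, strand = f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((chrom_start + s, chrom_start + s + sz)
                          for s, sz in zip(starts, sizes))
            coding = thick_end > thick_start
            txs.append(Transcript(name, name, chrom, strand, exons, coding=coding,
                                  cds=(thick_start, thick_end) if coding else None))
    txs.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return txs


def write_gene_models(transcripts: Sequence[Transcript], path: str | Path,
                      format: str = "gtf", source: str = "circpipe") -> None:
    if format == "gtf":
        with open(path, "w") as fh:
            for tx in transcripts:
                attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
                for a, b in tx.exons:
                    fh.write(f"{tx.chrom}\t{source}\texon\t{a + 1}\t{b}\t.\t"
                             f"{tx.strand}\t.\t{attrs}\n")
                if tx.coding and tx.cds is not None:
                    ca, cb = tx.cds
                    # emit CDS pieces clipped to exons so every CDS feature is exonic
                    for a, b in tx.exons:
                        lo, hi = max(a, ca), min(b, cb)
                        if lo < hi:
                            fh.write(f"{tx.chrom}\t{source}\tCDS\t{lo + 1}\t{hi}\t.\t"
                                     f"{tx.strand}\t0\t{attrs}\n")
    elif format == "bed12":
        with open(path, "w") as fh:
            for tx in transcripts:
                start, end = tx.start, tx.end
                sizes = ",".join(str(b - a) for a, b in tx.exons)
                offs = ",".join(str(a - start) for a, _ in tx.exons)
                thick = tx.cds if (tx.coding and tx.cds) else (start, start)
                fh.write("\t".join(map(str, [
                    tx.chrom, start, end, tx.transcript_id, 0, tx.strand,
                    thick[0], thick[1], "0,0,0", tx.n_exons, sizes, offs])) + "\n")
    else:
        raise ValueError(f"unknown gene-model format {format!r}")


# ---------------------------------------------------------------------------
# Catalog TSV

_CATALOG_HEADER_COMMENT = (
    "# circRNA catalog; coordinates are 0-based half-open genomic spans "
    "(start = first base of the 5'-most exon, end = one past the 3'-most exon); "
    "circ_id = chrom:start-end:strand\n"
)


def write_catalog(candidates: Sequence[CircCandidate],
                  quant: Mapping[str, "QuantLike"],
                  path: str | Path) -> None:
    """Write the annotated, quantified catalog as a 14-column TSV.

    ``quant`` maps circ_id to any object with ``reads_circular``,
    ``reads_linear_5p``, ``reads_linear_3p`` and ``clr`` attributes.
    A candidate without quantification is a hard error.
    """
    rows = []
    for cand in sorted(candidates, key=lambda c: (c.chrom, c.start, c.end, c.strand)):
        q = quant.get(cand.circ_id)
        if q is None:
            raise ValueError(f"missing quantification for {cand.circ_id}")
        rows.append({
            "chrom": cand.chrom,
            "start": cand.start,
            "end": cand.end,
            "strand": cand.strand,
            "circ_id": cand.circ_id,
            "junction_reads": q.reads_circular,
            "linear_5p_reads": q.reads_linear_5p,
            "linear_3p_reads": q.reads_linear_3p,
            "CLR": q.clr,
            "host_transcript": cand.host_transcript_id or "NA",
            "orientation": cand.orientation,
            "category": cand.category or "NA",
            "genomic_length": cand.genomic_length,
            "spliced_length": cand.spliced_length if cand.spliced_length is not None else "NA",
        })
    df = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    with open(path, "w") as fh:
        fh.write(_CATALOG_HEADER_COMMENT)
        df.to_csv(fh, sep="\t", index=False)


def read_catalog(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False,
                     na_values=[],
                     dtype={"chrom": str, "host_transcript": str,
                            "spliced_length": str})
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"catalog {path} missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# BED6 candidate emission (detector output)

def write_candidates_bed(candidates: Sequence[CircCandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in sorted(candidates, key=lambda c: (c.chrom, c.start, c.end, c.strand)):
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.circ_id}\t"
                     f"{c.junction_read_count}\t{c.strand}\n")


def read_candidates_bed(path: str | Path) -> list[CircCandidate]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, _name, score, strand = line.rstrip("\n").split("\t")[:6]
            out.append(CircCandidate(chrom, int(start), int(end), strand,
                                     junction_read_count=int(score)))
    return out
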