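"""Synthetic data with known ground truth.

Generates toy genomes with multi-exon genes (canonical GT/AG introns on the
transcript strand), plants back-spliced circles on a subset of transcripts,
simulates single-end reads from a mixture of linear and circular fragments,
models RNase R digestion as differential read survival, and produces qPCR
Ct tables with spike-in / housekeeper channels and planted group effects.

Truth is carried in read names as ``|``-delimited fields::

    <read_id>|lin|<transcript_id>|-|x=<crossings or ->
    <read_id>|circ|<transcript_id>|<circ_id>|jun=<0|1>

where a linear crossing ``d<donor_site>a<acceptor_site>`` records that the
read spans that exon-exon splice with at least ``boundary_flank`` bases on
each side.  Circular reads sample the spliced ring with a uniform start;
``jun=1`` marks reads that wrap past the head-to-tail junction.  Rotations
beyond one full circle (rolling-circle concatemers) are not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import revcomp
from .core_io import CircCandidate, Genome, Transcript

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Knobs for the synthetic genome / library generator."""

    seed: int
    n_genes: int = 10
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_length: tuple[int, int] = (150, 300)
    intron_length: tuple[int, int] = (80, 200)
    intergenic_gap: tuple[int, int] = (300, 600)
    read_length: int = 100
    depth: int = 500  # fragments per locus
    circular_fraction: float = 0.5
    error_rate: float = 0.0
    rnase_r_linear_survival: float = 1.0
    rnase_r_circular_survival: float = 1.0
    anchor_len: int = 20
    boundary_flank: int = 5
    minus_strand_prob: float = 0.5
    coding_prob: float = 1.0
    chrom_name: str = "chrS"

    def __post_init__(self):
        for name in ("circular_fraction", "error_rate", "rnase_r_linear_survival",
                     "rnase_r_circular_survival", "minus_strand_prob", "coding_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.read_length < 2 * self.anchor_len:
            raise ValueError("read_length must be >= 2 x anchor_len")
        if self.exon_length[0] < self.read_length:
            raise ValueError("minimum exon length must be >= read_length "
                             "(reads may not span a whole exon)")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


@dataclass(frozen=True)
class CircTruth:
    """A planted circle: exon block, genomic span and expected ring sequence.

    ``acceptor_exon``/``donor_exon`` are 5'->3' transcript-order indices
    with acceptor_exon <= donor_exon (the circle spans a contiguous block).
    ``ring_seq`` starts at the first base of the acceptor exon on the
    transcript strand.
    """

    transcript_id: str
    chrom: str
    strand: str
    acceptor_exon: int
    donor_exon: int
    start: int  # genomic span, 0-based half-open
    end: int
    circular_fraction: float
    ring_seq: str

    def __post_init__(self):
        if self.acceptor_exon > self.donor_exon:
            raise ValueError("acceptor exon must not be downstream of donor exon")
        if not 0.0 <= self.circular_fraction <= 1.0:
            raise ValueError("circular_fraction must be in [0,1]")

    @property
    def circ_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @property
    def acceptor_site(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def donor_site(self) -> int:
        return self.end if self.strand == "+" else self.start

    def as_candidate(self, junction_read_count: int = 0) -> CircCandidate:
        return CircCandidate(self.chrom, self.start, self.end, self.strand,
                             junction_read_count=junction_read_count)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def make_genome_and_genes(config: SimConfig) -> tuple[Genome, list[Transcript]]:
    """Build one synthetic chromosome with non-overlapping multi-exon genes.

    Every intron begins GT and ends AG *on the transcript strand*; for
    '-' strand genes the genomic intron therefore begins CT and ends AC.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    pieces: list[str] = []
    pos = 0
    transcripts: list[Transcript] = []
    for gi in range(config.n_genes):
        gap = int(rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1))
        pieces.append(_random_seq(rng, gap))
        pos += gap
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        strand = "-" if rng.random() < config.minus_strand_prob else "+"
        exons: list[tuple[int, int]] = []
        for ei in range(n_exons):
            if ei > 0:
                ilen = int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
                intron = list(_random_seq(rng, max(ilen, 4)))
                if strand == "+":
                    intron[0:2] = "GT"
                    intron[-2:] = "AG"
                else:  # transcript-strand GT..AG reads CT..AC on the forward genome
                    intron[0:2] = "CT"
                    intron[-2:] = "AC"
                pieces.append("".join(intron))
                pos += len(intron)
            elen = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            pieces.append(_random_seq(rng, elen))
            exons.append((pos, pos + elen))
            pos += elen
        coding = bool(rng.random() < config.coding_prob)
        cds = exons[0] if coding else None
        tid = f"tx{gi + 1:03d}"
        transcripts.append(Transcript(tid, f"gene{gi + 1:03d}", config.chrom_name,
                                      strand, tuple(exons), coding=coding, cds=cds))
    pieces.append(_random_seq(rng, 200))
    chrom = list("".join(pieces))
    # Stamp a canonical splice signal at *every* exon boundary on the
    # transcript strand (AG upstream of each exon start, GT downstream of
    # each exon end).  Intron-internal boundaries already satisfy this;
    # stamping the outermost boundaries too makes every contiguous exon
    # block a back-splice-compatible circle.
    for tx in transcripts:
        for a, b in tx.exons:
            if tx.strand == "+":
                chrom[a - 2:a] = "AG"
                chrom[b:b + 2] = "GT"
            else:
                chrom[a - 2:a] = "AC"
                chrom[b:b + 2] = "CT"
    genome = Genome({config.chrom_name: "".join(chrom)})
    return genome, transcripts


def _block_ring_seq(genome: Genome, tx: Transcript, acc_tx: int, don_tx: int) -> str:
    """Spliced ring sequence for a circle over transcript-order exons [acc, don]."""
    gidx = sorted(tx.exon_index_tx(i) for i in range(acc_tx, don_tx + 1))
    seq = "".join(genome[tx.chrom][a:b] for a, b in (tx.exons[i] for i in gidx))
    return revcomp(seq) if tx.strand == "-" else seq


def plant_circles(genome: Genome, transcripts: Sequence[Transcript], n_circles: int,
                  circular_fraction: float, seed: int,
                  min_ring_length: int = 0) -> list[CircTruth]:
    """Choose transcripts and contiguous exon blocks to act as circles."""
    if n_circles > len(transcripts):
        raise ValueError(f"cannot plant {n_circles} circles on "
                         f"{len(transcripts)} transcripts")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(transcripts))
    truths: list[CircTruth] = []
    for idx in order:
        if len(truths) == n_circles:
            break
        tx = transcripts[idx]
        n = tx.n_exons
        acc = int(rng.integers(0, n))
        don = int(rng.integers(acc, n))
        ring = _block_ring_seq(genome, tx, acc, don)
        if len(ring) < min_ring_length:
            don = n - 1
            acc = 0
            ring = _block_ring_seq(genome, tx, acc, don)
            if len(ring) < min_ring_length:
                continue
        gidx = sorted(tx.exon_index_tx(i) for i in (acc, don))
        start = tx.exons[gidx[0]][0]
        end = tx.exons[gidx[-1]][1]
        truths.append(CircTruth(tx.transcript_id, tx.chrom, tx.strand, acc, don,
                                start, end, circular_fraction, ring))
    if len(truths) < n_circles:
        raise ValueError("not enough transcripts satisfy min_ring_length")
    truths.sort(key=lambda t: (t.chrom, t.start, t.end))
    return truths


# ---------------------------------------------------------------------------
# Read simulation

def _linear_crossings(tx: Transcript, start: int, read_len: int, flank: int) -> str:
    """Splice junctions crossed linearly (with >= flank nt each side) by a
    read at spliced-coordinate ``start`` of the transcript."""
    # cumulative exon ends in transcript 5'->3' order
    sites = []
    cum = 0
    for i in range(tx.n_exons - 1):
        gi = tx.exon_index_tx(i)
        a, b = tx.exons[gi]
        cum += b - a
        # transcript-order junction i|i+1 at spliced coordinate `cum`
        don_gi = tx.exon_index_tx(i)
        acc_gi = tx.exon_index_tx(i + 1)
        donor_site = tx.exons[don_gi][1] if tx.strand == "+" else tx.exons[don_gi][0]
        acceptor_site = (tx.exons[acc_gi][0] if tx.strand == "+"
                         else tx.exons[acc_gi][1])
        sites.append((cum, donor_site, acceptor_site))
    crossed = [f"d{d}a{a}" for cum, d, a in sites
               if start <= cum - flank and start + read_len >= cum + flank]
    return ",".join(crossed) if crossed else "-"


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        current = arr[i].decode()
        choices = [b for b in "ACGT" if b != current]
        arr[i] = choices[int(rng.integers(0, 3))]
    return arr.tobytes().decode()


def simulate_reads(genome: Genome, transcripts: Sequence[Transcript],
                   circ_truth: Sequence[CircTruth], config: SimConfig,
                   ) -> list[tuple[str, str]]:
    """Simulate single-end reads with truth-tagged names.

    Per locus, ``config.depth`` fragments are drawn; at a circle-bearing
    locus each fragment is circular with probability
    ``truth.circular_fraction``.  Linear fragments sample the spliced
    linear transcript uniformly; circular fragments sample the ring with a
    uniform start so a read wraps the junction with probability
    (read_length - 1) / ring_length.
    """
    rng = np.random.default_rng(config.seed + 1)
    by_tx: dict[str, CircTruth] = {t.transcript_id: t for t in circ_truth}
    L = config.read_length
    reads: list[tuple[str, str]] = []
    ridx = 0
    for tx in transcripts:
        spliced = tx.spliced_sequence(genome)
        if len(spliced) < L:
            raise ValueError(f"{tx.transcript_id}: spliced transcript shorter than read")
        truth = by_tx.get(tx.transcript_id)
        ring = truth.ring_seq if truth else ""
        doubled = ring + ring
        for _ in range(config.depth):
            is_circ = truth is not None and rng.random() < truth.circular_fraction
            if is_circ:
                if len(ring) < L:
                    raise ValueError(f"{truth.circ_id}: ring shorter than read length")
                s = int(rng.integers(0, len(ring)))
                seq = doubled[s:s + L]
                jun = int(s + L > len(ring))
                name = f"r{ridx:07d}|circ|{tx.transcript_id}|{truth.circ_id}|jun={jun}"
            else:
                s = int(rng.integers(0, len(spliced) - L + 1))
                seq = spliced[s:s + L]
                x = _linear_crossings(tx, s, L, config.boundary_flank)
                name = f"r{ridx:07d}|lin|{tx.transcript_id}|-|x={x}"
            reads.append((name, _apply_errors(rng, seq, config.error_rate)))
            ridx += 1
    return reads


def parse_truth_tag(read_name: str) -> dict:
    """Decode the truth fields embedded in a simulated read name."""
    parts = read_name.split("|")
    if len(parts) != 5 or parts[1] not in ("lin", "circ"):
        raise ValueError(f"not a truth-tagged read name: {read_name!r}")
    rid, kind, tx_id, circ_id, extra = parts
    out = {"read_id": rid, "kind": kind, "transcript_id": tx_id,
           "circ_id": None if circ_id == "-" else circ_id,
           "junction": False, "crossings": []}
    key, _, value = extra.partition("=")
    if kind == "circ":
        out["junction"] = value == "1"
    elif value != "-":
        for token in value.split(","):
            d, _, a = token[1:].partition("a")
            out["crossings"].append((int(d), int(a)))
    return out


def simulate_rnase_r(reads: Sequence[tuple[str, str]], config: SimConfig,
                     seed: int) -> list[tuple[str, str]]:
    """Differential read survival: linear reads are preferentially lost.

    Each linear-tagged read is retained with probability
    ``rnase_r_linear_survival`` and each circular-tagged read with
    ``rnase_r_circular_survival``.
    """
    rng = np.random.default_rng(seed)
    kept = []
    for name, seq in reads:
        kind = parse_truth_tag(name)["kind"]
        p = (config.rnase_r_linear_survival if kind == "lin"
             else config.rnase_r_circular_survival)
        if rng.random() < p:
            kept.append((name, seq))
    return kept


def truth_counts(reads: Iterable[tuple[str, str]],
                 circ_truth: Sequence[CircTruth]) -> pd.DataFrame:
    """Per-circle junction and linear boundary-read counts from truth tags.

    This is the ground-truth table the quantification stage must reproduce.
    """
    rows = {t.circ_id: {"circ_id": t.circ_id, "junction_reads": 0,
                        "linear_5p_reads": 0, "linear_3p_reads": 0}
            for t in circ_truth}
    acc_of = {t.circ_id: t.acceptor_site for t in circ_truth}
    don_of = {t.circ_id: t.donor_site for t in circ_truth}
    for name, _ in reads:
        tag = parse_truth_tag(name)
        if tag["kind"] == "circ":
            if tag["junction"] and tag["circ_id"] in rows:
                rows[tag["circ_id"]]["junction_reads"] += 1
        else:
            for d, a in tag["crossings"]:
                for cid in rows:
                    if a == acc_of[cid]:
                        rows[cid]["linear_5p_reads"] += 1
                    if d == don_of[cid]:
                        rows[cid]["linear_3p_reads"] += 1
    return pd.DataFrame(list(rows.values()))


def write_truth_manifest(circ_truth: Sequence[CircTruth], path) -> None:
    pd.DataFrame([{
        "circ_id": t.circ_id, "transcript_id": t.transcript_id, "chrom": t.chrom,
        "strand": t.strand, "start": t.start, "end": t.end,
        "acceptor_exon": t.acceptor_exon, "donor_exon": t.donor_exon,
        "circular_fraction": t.circular_fraction, "ring_length": len(t.ring_seq),
        "ring_seq": t.ring_seq,
    } for t in circ_truth]).to_csv(path, sep="\t", index=False)


def read_truth_manifest(path) -> list[CircTruth]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [CircTruth(r.transcript_id, r.chrom, r.strand, int(r.acceptor_exon),
                      int(r.donor_exon), int(r.start), int(r.end),
                      float(r.circular_fraction), r.ring_seq)
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# Ct table simulation

ROLES = ("spike_in", "housekeeper", "reference_rRNA", "assay")


def simulate_ct_table(samples: Mapping[str, str], targets: Mapping[str, str],
                      effects: Mapping[str, Mapping[str, float]] | None,
                      noise_sd: float, seed: int, replicates: int = 2,
                      baseline: Mapping[str, float] | None = None,
                      sample_shift_sd: float = 0.0) -> pd.DataFrame:
    """Simulate a qPCR Ct table.

    ``samples`` maps sample name -> group label; ``targets`` maps target
    name -> role (spike_in / housekeeper / reference_rRNA / assay).
    ``effects[target][group]`` is a linear fold change applied to an assay
    target in that group; a fold change f lowers Ct by log2(f).  Control
    targets (spike-in, housekeepers, rRNA) must carry no effect.  Optional
    per-sample Ct shifts model loading differences and cancel under any
    normalizer.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for t, role in targets.items():
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r} for target {t!r}")
    effects = effects or {}
    for t in effects:
        if targets.get(t) != "assay":
            raise ValueError(f"group effect on non-assay target {t!r}")
    if not any(r == "spike_in" for r in targets.values()):
        raise ValueError("design must include a spike-in target")
    if not any(r in ("housekeeper", "reference_rRNA") for r in targets.values()):
        raise ValueError("design must include a housekeeper or rRNA target")
    rng = np.random.default_rng(seed)
    base = dict(baseline) if baseline else {
        t: float(18 + 12 * rng.random()) for t in targets}
    rows = []
    for sample, group in samples.items():
        shift = float(rng.normal(0.0, sample_shift_sd)) if sample_shift_sd > 0 else 0.0
        for target, role in targets.items():
            fold = float(effects.get(target, {}).get(group, 1.0))
            delta = -np.log2(fold)
            for rep in range(1, replicates + 1):
                noise = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
                rows.append({"sample": sample, "group": group, "target": target,
                             "role": role, "replicate": rep,
                             "ct": base[target] + shift + delta + noise})
    return pd.DataFrame(rows)
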