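from collections import Counter

import numpy as np
import pytest

from circpipe._util import revcomp
from circpipe.core_io import Genome
from circpipe.detect import (
    JunctionCall,
    build_index,
    call_junction,
    collapse_and_filter,
    detect_reads,
    extract_anchors,
)
from circpipe.simulate import (
    SimConfig,
    make_genome_and_genes,
    parse_truth_tag,
    plant_circles,
    simulate_reads,
)


# ---------------------------------------------------------------------------
# k-mer index

class TestKmerIndex:
    def test_absent_kmer(self):
        idx = build_index(Genome({"c1": "ACGTACGTAC"}), 4)
        assert idx.lookup("TTTT") == []

    def test_palindromic_kmer_once_per_pos_and_strand(self):
        # ACGCGT is its own reverse complement
        idx = build_index(Genome({"c1": "TTACGCGTTT"}), 6)
        hits = idx.lookup("ACGCGT")
        assert sorted(hits) == [("c1", 2, "+"), ("c1", 2, "-")]

    def test_agrees_with_naive_scan(self):
        rng = np.random.default_rng(42)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)])
        genome = Genome({"c1": seq})
        k = 8
        idx = build_index(genome, k)
        for pos in range(len(seq) - k + 1):
            query = seq[pos:pos + k]
            expected = [("c1", p, "+") for p in range(len(seq) - k + 1)
                        if seq[p:p + k] == query]
            rc = revcomp(query)
            expected += [("c1", p, "-") for p in range(len(seq) - k + 1)
                         if seq[p:p + k] == rc]
            assert sorted(idx.lookup(query)) == sorted(expected)


class TestExtractAnchors:
    def test_exact_split(self):
        seq = "A" * 20 + "C" * 20
        head, tail = extract_anchors(seq, 20)
        assert head == "A" * 20 and tail == "C" * 20

    def test_short_read_skipped(self):
        assert extract_anchors("A" * 39, 20) is None

    def test_short_read_tallied(self, small_sim):
        _, genome, _, _ = small_sim
        idx = build_index(genome, 20)
        tally = Counter()
        assert call_junction("r", "A" * 30, idx, genome, tally=tally) is None
        assert tally["too_short"] == 1


# ---------------------------------------------------------------------------
# junction calling on constructed reads

def _junction_read(genome, truth, donor_flank=45, acceptor_flank=55):
    """suffix(donor side) + prefix(acceptor side) of the truth ring."""
    ring = truth.ring_seq
    return ring[-donor_flank:] + ring[:acceptor_flank]


class TestCallJunction:
    def test_planted_circle_exact_coordinates(self, small_sim):
        _, genome, txs, truths = small_sim
        idx = build_index(genome, 20)
        for truth in truths:
            read = _junction_read(genome, truth)
            call = call_junction("r1", read, idx, genome)
            assert call is not None
            assert (call.chrom, call.strand, call.start, call.end) == \
                (truth.chrom, truth.strand, truth.start, truth.end)

    def test_mutated_splice_signal_blocks_call(self, small_sim):
        _, genome, txs, truths = small_sim
        truth = truths[0]
        read = _junction_read(genome, truth)
        # rebuild the genome with the acceptor-side AG mutated to AC
        chrom = list(genome[truth.chrom])
        if truth.strand == "+":
            assert "".join(chrom[truth.start - 2:truth.start]) == "AG"
            chrom[truth.start - 1] = "C"
        else:
            assert "".join(chrom[truth.end:truth.end + 2]) == "CT"
            chrom[truth.end] = "G"
        mutated = Genome({truth.chrom: "".join(chrom)})
        idx = build_index(mutated, 20)
        tally = Counter()
        assert call_junction("r1", read, idx, mutated, tally=tally) is None
        assert tally["no_signal"] == 1

    def test_linear_read_is_colinear_no_call(self, small_sim):
        _, genome, txs, _ = small_sim
        tx = txs[0]
        spliced = tx.spliced_sequence(genome)
        read = spliced[10:110]
        idx = build_index(genome, 20)
        tally = Counter()
        assert call_junction("r1", read, idx, genome, tally=tally) is None
        assert tally["colinear"] + tally["anchor_not_unique"] == 1

    def test_max_span_gate(self, small_sim):
        _, genome, txs, truths = small_sim
        truth = truths[0]
        read = _junction_read(genome, truth)
        idx = build_index(genome, 20)
        tally = Counter()
        assert call_junction("r1", read, idx, genome, max_span=10, tally=tally) is None
        assert tally["span_exceeded"] == 1


def _oracle_split_points(read, genome, anchor_len=20):
    """Exhaustive oracle: every split point of the read, every genomic
    placement of both parts (string scan on both strands), GT/AG check."""
    results = set()
    for chrom, fwd in genome.items():
        for strand, seq in (("+", fwd), ("-", revcomp(fwd))):
            L = len(seq)
            for b in range(anchor_len, len(read) - anchor_len + 1):
                donor_part, acceptor_part = read[:b], read[b:]
                d_hits, a_hits = [], []
                start = seq.find(donor_part)
                while start != -1:
                    d_hits.append(start)
                    start = seq.find(donor_part, start + 1)
                start = seq.find(acceptor_part)
                while start != -1:
                    a_hits.append(start)
                    start = seq.find(acceptor_part, start + 1)
                for dh in d_hits:
                    donor_end = dh + b
                    for ah in a_hits:
                        if ah >= donor_end:
                            continue
                        if ah < 2 or donor_end + 2 > L:
                            continue
                        if seq[donor_end:donor_end + 2] == "GT" and \
                           seq[ah - 2:ah] == "AG":
                            if strand == "+":
                                results.add((chrom, strand, ah, donor_end))
                            else:
                                results.add((chrom, strand, L - donor_end, L - ah))
    return results


class TestAgainstSplitPointOracle:
    def test_error_free_junction_reads_match_oracle_and_truth(self):
        cfg = SimConfig(seed=33, n_genes=6, depth=400)
        genome, txs = make_genome_and_genes(cfg)
        truths = plant_circles(genome, txs, 4, 0.6, seed=33,
                               min_ring_length=cfg.read_length)
        reads = simulate_reads(genome, txs, truths, cfg)
        jreads = [(n, s) for n, s in reads if parse_truth_tag(n)["junction"]][:200]
        assert len(jreads) >= 100
        idx = build_index(genome, 20)
        truth_by_id = {t.circ_id: t for t in truths}
        n_called = 0
        for name, seq in jreads:
            call = call_junction(name, seq, idx, genome)
            oracle = _oracle_split_points(seq, genome)
            if call is not None:
                n_called += 1
                truth = truth_by_id[parse_truth_tag(name)["circ_id"]]
                assert (call.start, call.end) == (truth.start, truth.end)
                assert (call.chrom, call.strand, call.start, call.end) in oracle
            else:
                # detector must only stay silent when the oracle finds no
                # unique breakpoint reachable with intact anchors
                assert len(oracle) != 1 or not _anchors_unique(seq, idx)
        assert n_called >= 50

    def test_linear_library_has_zero_calls(self):
        cfg = SimConfig(seed=34, n_genes=6, depth=300, circular_fraction=0.0)
        genome, txs = make_genome_and_genes(cfg)
        reads = simulate_reads(genome, txs, [], cfg)
        calls, _ = detect_reads(reads, genome)
        assert calls == []


def _anchors_unique(seq, idx):
    head, tail = seq[:20], seq[-20:]
    return len(idx.lookup(head)) == 1 and len(idx.lookup(tail)) == 1


# ---------------------------------------------------------------------------
# collapse & filter

def _call(read_id, read_seq, start=100, end=400):
    return JunctionCall("c1", "+", start, end, read_id, read_seq)


class TestCollapseAndFilter:
    def test_single_read_dropped(self):
        assert collapse_and_filter([_call("r1", "ACGT")]) == []

    def test_two_distinct_reads_kept(self):
        cands = collapse_and_filter([_call("r1", "ACGT"), _call("r2", "ACGA")])
        assert len(cands) == 1
        assert cands[0].junction_read_count == 2
        assert cands[0].unique_read_ids == ("r1", "r2")

    def test_duplicate_sequences_count_once(self):
        calls = [_call(f"r{i}", "ACGT") for i in range(5)]
        assert collapse_and_filter(calls) == []

    def test_threshold_configurable(self):
        calls = [_call("r1", "ACGT")]
        assert len(collapse_and_filter(calls, min_unique_reads=1)) == 1

    def test_input_order_invariance(self):
        calls = [_call("r1", "AAAA"), _call("r2", "CCCC"),
                 _call("r3", "GGGG", 500, 900), _call("r4", "TTTT", 500, 900)]
        a = collapse_and_filter(calls)
        b = collapse_and_filter(calls[::-1])
        assert a == b
        assert [c.start for c in a] == [100, 500]


class TestDetectEndToEnd:
    def test_recall_on_planted_circles(self, small_sim):
        cfg, genome, txs, truths = small_sim
        reads = simulate_reads(genome, txs, truths, cfg)
        calls, _ = detect_reads(reads, genome)
        cands = collapse_and_filter(calls)
        found = {(c.chrom, c.start, c.end, c.strand) for c in cands}
        expected = {(t.chrom, t.start, t.end, t.strand) for t in truths}
        assert found == expected

    def test_read_order_invariance(self, small_sim):
        cfg, genome, txs, truths = small_sim
        reads = simulate_reads(genome, txs, truths, cfg)
        calls_fwd, _ = detect_reads(reads, genome)
        calls_rev, _ = detect_reads(reads[::-1], genome)
        assert collapse_and_filter(calls_fwd) == collapse_and_filter(calls_rev)
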