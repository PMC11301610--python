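"""Clustering, consensus, realignment and junction annotation."""

import numpy as np
import pytest

from iesweave.consensus import consensus
from iesweave.io_align import AlignedSegmentView, InsertEvidence, ReferenceGenome
from iesweave.milraa import (
    cluster_inserts,
    detect_pointer,
    detect_ta,
    extract_flanked_segments,
    filter_clusters,
    left_normalize,
    read_records,
    realign_consensus,
    split_mixed_length_clusters,
    write_gff3,
    write_ies_fasta,
)

from conftest import random_seq
from oracles import closure_partition, shift_equivalents


def _ev(junction, read_id="r", seq="ACGTACGTACGT", qs=0):
    return InsertEvidence(read_id, "c1", junction, seq, qs)


class TestClustering:
    def test_nearby_junctions_form_one_cluster(self):
        evs = [_ev(98, "a"), _ev(100, "b"), _ev(102, "c")]
        clusters = cluster_inserts(evs, 5)
        assert len(clusters) == 1
        assert clusters[0].mode_junction == 98  # all unique -> leftmost

    def test_distant_junctions_split(self):
        clusters = cluster_inserts([_ev(100, "a"), _ev(120, "b")], 5)
        assert [c.span for c in clusters] == [(100, 100), (120, 120)]

    def test_mode_junction_prefers_most_frequent(self):
        evs = [_ev(100, "a"), _ev(102, "b"), _ev(102, "c")]
        assert cluster_inserts(evs, 5)[0].mode_junction == 102

    def test_duplicate_read_collapsed_to_longest(self):
        evs = [_ev(100, "a", "ACGTACGTAC"), _ev(101, "a", "ACGTACGTACGTACGT")]
        cluster = cluster_inserts(evs, 5)[0]
        assert cluster.n_reads == 1
        assert cluster.members[0].insert_seq == "ACGTACGTACGTACGT"

    def test_min_coverage_counts_distinct_reads(self):
        evs = [_ev(100, f"r{i}") for i in range(5)] + [_ev(101, "r0")]
        clusters = cluster_inserts(evs, 5)
        assert filter_clusters(clusters, 5) == clusters
        assert filter_clusters(clusters, 6) == []

    def test_empty_input(self):
        assert cluster_inserts([], 5) == []

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(99)
        for trial in range(20):
            n = int(rng.integers(2, 60))
            positions = sorted(int(x) for x in rng.integers(0, 400, size=n))
            d = int(rng.integers(1, 15))
            evs = [_ev(p, f"r{i}") for i, p in enumerate(positions)]
            got = sorted(
                tuple(sorted(m.junction for m in c.members))
                for c in cluster_inserts(evs, d)
            )
            assert got == closure_partition(positions, d)

    def test_mixed_length_cluster_split(self):
        short = [_ev(100, f"s{i}", "A" * 30) for i in range(5)]
        long = [_ev(102, f"l{i}", "A" * 90) for i in range(5)]
        clusters = cluster_inserts(short + long, 5)
        assert len(clusters) == 1
        split = split_mixed_length_clusters(clusters)
        assert sorted(c.n_reads for c in split) == [5, 5]


class TestFlankedSegments:
    def test_full_flanks(self):
        rng = np.random.default_rng(3)
        read = random_seq(rng, 400)
        ev = InsertEvidence("r1", "c1", 500, read[150:190], 150)
        seg = AlignedSegmentView("r1", "c1", 350, [(0, 150), (1, 40), (0, 210)], read)
        cluster = cluster_inserts([ev], 5)[0]
        out = extract_flanked_segments(cluster, {"r1": seg}, flank_len=100)
        assert out[0].seq == read[50:290]

    def test_flank_truncated_at_read_start(self):
        rng = np.random.default_rng(4)
        read = random_seq(rng, 300)
        ev = InsertEvidence("r1", "c1", 500, read[20:60], 20)
        seg = AlignedSegmentView("r1", "c1", 480, [(0, 20), (1, 40), (0, 240)], read)
        cluster = cluster_inserts([ev], 5)[0]
        out = extract_flanked_segments(cluster, {"r1": seg}, flank_len=100)
        assert out[0].seq == read[0:160]

    def test_missing_read_named_in_error(self):
        cluster = cluster_inserts([_ev(100, "ghost")], 5)[0]
        with pytest.raises(KeyError, match="ghost"):
            extract_flanked_segments(cluster, {})


class TestConsensus:
    def test_identical_sequences(self):
        assert consensus(["ACGTACGT"] * 5) == "ACGTACGT"

    def test_singleton_returned_verbatim(self):
        assert consensus(["ACGT"]) == "ACGT"

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            consensus([])

    def test_majority_fixes_isolated_substitutions(self):
        rng = np.random.default_rng(8)
        s = random_seq(rng, 120)
        copies = []
        for pos in (10, 60, 110):
            c = list(s)
            c[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[c[pos]]
            copies.append("".join(c))
        assert consensus(copies) == s

    def test_majority_fixes_indels(self):
        rng = np.random.default_rng(9)
        s = random_seq(rng, 150)
        variants = [s, s[:40] + s[41:], s[:90] + "T" + s[90:], s, s]
        assert consensus(variants) == s


class TestRealign:
    def test_planted_insert_recovered_exactly(self, flat_ref):
        refseq = flat_ref["c1"]
        rng = np.random.default_rng(10)
        ins = random_seq(rng, 60)
        cons = refseq[300:400] + ins + refseq[400:500]
        got = realign_consensus(cons, flat_ref, "c1", (250, 550))
        assert got == (400, ins)

    def test_reference_like_consensus_rejected(self, flat_ref):
        cons = flat_ref["c1"][300:500]
        assert realign_consensus(cons, flat_ref, "c1", (250, 550)) is None

    def test_noisy_flanks_land_within_2bp(self, flat_ref):
        """Junctions survive ~2% substitution noise in the anchoring flanks
        (compared after left-normalizing both call and truth)."""
        refseq = flat_ref["c1"]
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(100):
            ins = random_seq(rng, 50)
            true_j, _ = left_normalize(ins, refseq, 400)
            left, right = list(refseq[300:400]), list(refseq[400:500])
            for side in (left, right):  # ~2% substitution noise
                for pos in rng.integers(0, 100, size=2):
                    side[pos] = "ACGT"[rng.integers(0, 4)]
            cons = "".join(left) + ins + "".join(right)
            got = realign_consensus(cons, flat_ref, "c1", (250, 550))
            if got is None:
                continue
            norm_j, _ = left_normalize(got[1], refseq, got[0])
            if abs(norm_j - true_j) <= 2:
                hits += 1
        # a substitution landing immediately at the junction can shift the
        # alignment optimum itself; everything else must stay within 2 bp
        assert hits >= 98


class TestPointerAnnotation:
    def test_two_base_pointer(self):
        ref = ReferenceGenome({"c1": "AAAAGTAGGGG"})
        # insertion before ref position 5 ("TAGGGG" follows): insert TACCCCC
        pointer, j, seq = detect_pointer("TACCCCC", ref, "c1", 5)
        assert (pointer, j, seq) == ("TA", 5, "TACCCCC")

    def test_no_pointer(self):
        ref = ReferenceGenome({"c1": "AAAATTTTAAAA"})
        pointer, _, _ = detect_pointer("GGGG", ref, "c1", 4)
        assert pointer == ""

    def test_left_normalization_shifts_to_leftmost(self):
        ref = ReferenceGenome({"c1": "AAAACGCGTTTT"})
        # insert "GCG" after "AAAACG" is shift-equivalent to "CGC" before it
        j, seq = left_normalize("GCG", ref["c1"], 6)
        expect_j, expect_seq = shift_equivalents(ref["c1"], 6, "GCG")[0]
        assert (j, seq) == (expect_j, expect_seq)

    def test_normalization_preserves_implied_mic(self, flat_ref):
        """Any shift-equivalent placement reinserts to the same sequence."""
        rng = np.random.default_rng(12)
        refseq = flat_ref["c1"]
        for _ in range(100):
            j = int(rng.integers(10, 900))
            ies = random_seq(rng, int(rng.integers(5, 40)))
            _, nj, nseq = detect_pointer(ies, flat_ref, "c1", j)
            raw = refseq[:j] + ies + refseq[j:]
            normalized = refseq[:nj] + nseq + refseq[nj:]
            assert raw == normalized

    @pytest.mark.parametrize(
        "pointer,expected",
        [("TA", True), ("TTAA", False), ("", False)],
    )
    def test_ta_boundary(self, pointer, expected):
        seq = pointer + "CCCC" if pointer else "CCCC"
        assert detect_ta(seq, pointer) is expected


class TestGffRoundTrip:
    def _records(self):
        from iesweave.milraa import IESRecord

        return [
            IESRecord("c1", 110, "TACCGTTAGG", "TA", True, 12, 20, 0.6,
                      "subread", "IES_00001_c1_111"),
            IESRecord("c1", 500, "GGGGCCCC", "", False, 7, 7, 1.0,
                      "subread", "IES_00002_c1_501"),
        ]

    def test_junction_converts_to_one_based(self, tmp_path):
        path = tmp_path / "ies.gff3"
        write_gff3(self._records(), path)
        line = [l for l in path.read_text().splitlines() if not l.startswith("#")][0]
        fields = line.split("\t")
        assert (fields[3], fields[4]) == ("111", "111")

    def test_round_trip_recovers_fields(self, tmp_path):
        gff = tmp_path / "ies.gff3"
        fasta = tmp_path / "ies.fasta"
        records = self._records()
        write_gff3(records, gff)
        write_ies_fasta(records, fasta)
        back = read_records(gff, fasta)
        for orig, rec in zip(records, back):
            assert rec.contig == orig.contig
            assert rec.junction == orig.junction
            assert rec.ies_seq == orig.ies_seq
            assert rec.pointer == orig.pointer
            assert rec.ta_bounded == orig.ta_bounded
            assert rec.support == orig.support
            assert rec.spanning_total == orig.spanning_total
            assert rec.retention_score == pytest.approx(orig.retention_score)

    def test_empty_record_list_is_valid_gff(self, tmp_path):
        path = tmp_path / "empty.gff3"
        write_gff3([], path)
        assert path.read_text().startswith("##gff-version 3")
        assert read_records(path) == []


def test_ccs_and_subread_modes_agree_on_accurate_reads(tmp_path):
    """On CCS-grade (0.5% error) reads both calling paths find the same
    junctions."""
    from iesweave.milraa import call_iess
    from iesweave.simdata import SimParams, make_genomes, simulate_reads

    params = SimParams(seed=71, n_contigs=1, contig_len=50_000, n_iess=10,
                       err_sub=0.002, err_ins=0.002, err_del=0.001)
    mac, mic, truth = make_genomes(params)
    _, bam = simulate_reads(mac, mic, truth, params, tmp_path)
    ccs, _ = call_iess(bam, mac, mode="ccs")
    subread, _ = call_iess(bam, mac, mode="subread")
    assert [(r.contig, r.junction) for r in ccs] == [
        (r.contig, r.junction) for r in subread
    ]


def test_identical_inputs_give_byte_identical_outputs(small_sim, tmp_path):
    """The whole calling path is deterministic: rerunning on the same BAM
    writes byte-identical GFF3 and FASTA."""
    from iesweave.milraa import call_iess

    outputs = []
    for run in ("a", "b"):
        records, _ = call_iess(small_sim["bam"], small_sim["mac"], mode="subread")
        gff = tmp_path / f"{run}.gff3"
        fasta = tmp_path / f"{run}.fasta"
        write_gff3(records, gff)
        write_ies_fasta(records, fasta)
        outputs.append(gff.read_bytes() + fasta.read_bytes())
    assert outputs[0] == outputs[1]
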