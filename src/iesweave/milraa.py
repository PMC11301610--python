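"""De novo reconstruction of internally eliminated sequences (IESs).

MIC-derived reads mapped to the somatic (MAC) assembly show IESs as
insertions.  Calling proceeds per contig:

1. insertion evidence is clustered by single linkage on junction distance;
2. clusters below the minimum distinct-read coverage are dropped;
3. the insert sequence is polished to a consensus — directly from the
   member inserts for accurate (CCS-grade) reads, or from insert + flanking
   read sequence followed by realignment to the reference for noisy
   subreads, where the flanks anchor the consensus and the realignment
   recovers the true junction;
4. the insertion is left-normalized to its leftmost shift-equivalent
   position, and the pointer (tandem repeat at the junction, one copy
   retained in the MAC) and TA boundary are annotated;
5. a per-site retention score is computed from spanning reads.
"""

from __future__ import annotations

import logging
import os
from collections import Counter
from dataclasses import dataclass, field

import pysam
from Bio import Align

from . import gff as gff_io
from .consensus import consensus
from .io_align import (
    DEFAULT_MIN_INSERT_LEN,
    DEFAULT_MIN_MAPQ,
    AlignedSegmentView,
    InsertEvidence,
    ReferenceGenome,
    SpanStatus,
    extract_insert_evidence,
    iter_alignments,
    spans_junction,
    validate_contigs,
)

logger = logging.getLogger(__name__)

DEFAULT_MAX_CLUSTER_DIST = {"ccs": 3, "subread": 10}
DEFAULT_MIN_COVERAGE = 5
DEFAULT_FLANK_LEN = 100
DEFAULT_BUFFER = 15
#: extra reference sequence beyond flanks when realigning a consensus
REALIGN_SLACK = 50
GFF_FEATURE_TYPE = "internal_eliminated_sequence_junction"


@dataclass
class EvidenceCluster:
    """Co-located insertion evidence; the unit of IES calling.

    Members are unique per read (a read contributing several inserts keeps
    only the longest) and sorted by junction.
    """

    contig: str
    members: list[InsertEvidence]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty cluster")
        self.members.sort(key=lambda e: (e.junction, e.read_id))

    @property
    def span(self) -> tuple[int, int]:
        return (self.members[0].junction, self.members[-1].junction)

    @property
    def mode_junction(self) -> int:
        counts = Counter(e.junction for e in self.members)
        best = max(counts.values())
        return min(j for j, c in counts.items() if c == best)

    @property
    def n_reads(self) -> int:
        return len({e.read_id for e in self.members})


@dataclass(frozen=True)
class FlankedSegment:
    """Insert plus up to ``flank_len`` bp of read sequence on each side."""

    read_id: str
    seq: str


@dataclass
class IESRecord:
    """One called IES at a left-normalized junction."""

    contig: str
    junction: int
    ies_seq: str
    pointer: str
    ta_bounded: bool
    support: int
    spanning_total: int
    retention_score: float
    mode: str
    ies_id: str = ""

    @property
    def length(self) -> int:
        return len(self.ies_seq)


def _dedup_members(members: list[InsertEvidence]) -> list[InsertEvidence]:
    best: dict[str, InsertEvidence] = {}
    for ev in members:
        prev = best.get(ev.read_id)
        if prev is None or len(ev.insert_seq) > len(prev.insert_seq):
            best[ev.read_id] = ev
    return list(best.values())


def cluster_inserts(
    evidence: list[InsertEvidence], max_cluster_dist: int
) -> list[EvidenceCluster]:
    """Single-linkage clustering of insertion evidence on one contig.

    A new cluster starts whenever the junction gap to the previous piece of
    evidence exceeds ``max_cluster_dist``; this equals the transitive
    closure of the "within distance" relation on sorted junctions.
    """
    if not evidence:
        return []
    contigs = {e.contig for e in evidence}
    if len(contigs) > 1:
        raise ValueError(f"evidence spans several contigs: {sorted(contigs)}")
    evidence = sorted(evidence, key=lambda e: (e.junction, e.read_id))
    clusters: list[EvidenceCluster] = []
    current = [evidence[0]]
    for ev in evidence[1:]:
        if ev.junction - current[-1].junction > max_cluster_dist:
            clusters.append(EvidenceCluster(ev.contig, _dedup_members(current)))
            current = [ev]
        else:
            current.append(ev)
    clusters.append(EvidenceCluster(current[0].contig, _dedup_members(current)))
    return clusters


def split_mixed_length_clusters(
    clusters: list[EvidenceCluster], ratio: float = 2.0
) -> list[EvidenceCluster]:
    """Split clusters whose member insert lengths are multimodal.

    Two distinct IESs can share a junction neighborhood; building one
    consensus across both would be chimeric.  Members are grouped by insert
    length, breaking wherever consecutive sorted lengths differ by more
    than ``ratio``-fold.
    """
    out: list[EvidenceCluster] = []
    for cluster in clusters:
        members = sorted(cluster.members, key=lambda e: len(e.insert_seq))
        groups: list[list[InsertEvidence]] = [[members[0]]]
        for ev in members[1:]:
            if len(ev.insert_seq) > ratio * len(groups[-1][-1].insert_seq):
                groups.append([ev])
            else:
                groups[-1].append(ev)
        if len(groups) == 1:
            out.append(cluster)
        else:
            out.extend(EvidenceCluster(cluster.contig, g) for g in groups)
    out.sort(key=lambda c: c.span)
    return out


def filter_clusters(
    clusters: list[EvidenceCluster], min_coverage: int
) -> list[EvidenceCluster]:
    """Keep clusters supported by at least ``min_coverage`` distinct reads."""
    return [c for c in clusters if c.n_reads >= min_coverage]


def extract_flanked_segments(
    cluster: EvidenceCluster,
    segments: dict[str, AlignedSegmentView],
    flank_len: int = DEFAULT_FLANK_LEN,
) -> list[FlankedSegment]:
    """Slice insert plus flanking read sequence for every cluster member.

    Flanks are truncated (never padded) at read ends.
    """
    out = []
    for ev in cluster.members:
        seg = segments.get(ev.read_id)
        if seg is None:
            raise KeyError(f"read {ev.read_id!r} missing from alignment segments")
        qs = ev.query_start
        left = min(flank_len, qs)
        end = qs + len(ev.insert_seq)
        right = min(flank_len, len(seg.query_seq) - end)
        out.append(FlankedSegment(ev.read_id, seg.query_seq[qs - left : end + right]))
    return out


def _make_aligner(
    match: int, mismatch: int, gap_open: int, gap_extend: int
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # first gap base costs open + extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    # reference-window overhangs beyond the consensus are free
    aligner.end_deletion_score = 0.0
    return aligner


def realign_consensus(
    cons: str,
    ref: ReferenceGenome,
    contig: str,
    window: tuple[int, int],
    min_insert_len: int = DEFAULT_MIN_INSERT_LEN,
    match: int = 2,
    mismatch: int = -4,
    gap_open: int = 4,
    gap_extend: int = 2,
) -> tuple[int, str] | None:
    """Anchor a flanked consensus in the reference and read off the insert.

    The consensus is aligned globally (affine gaps, free reference end
    overhangs) against the reference window; the longest consensus-only run
    in the traceback is the insert, its reference coordinate the junction.
    Returns ``None`` when no insertion run reaches ``min_insert_len`` —
    the cluster is rejected, not fatal.
    """
    if not cons:
        raise ValueError("empty consensus")
    start = max(0, window[0])
    end = min(ref.length(contig), window[1])
    refwin = ref[contig][start:end]
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(refwin, cons)[0]
    tblocks, qblocks = aln.aligned

    runs: list[tuple[int, int, int]] = []  # (length, ref_pos, query_start)
    if len(qblocks) and qblocks[0][0] > 0:
        runs.append((int(qblocks[0][0]), int(tblocks[0][0]), 0))
    for i in range(len(tblocks) - 1):
        q_gap = int(qblocks[i + 1][0] - qblocks[i][1])
        if q_gap > 0:
            runs.append((q_gap, int(tblocks[i][1]), int(qblocks[i][1])))
    if len(qblocks) and qblocks[-1][1] < len(cons):
        runs.append(
            (len(cons) - int(qblocks[-1][1]), int(tblocks[-1][1]), int(qblocks[-1][1]))
        )
    if not runs:
        return None
    best_len, ref_pos, q_start = max(runs, key=lambda r: (r[0], -r[1]))
    if best_len < min_insert_len:
        return None
    return start + ref_pos, cons[q_start : q_start + best_len]


def left_normalize(
    ies_seq: str, refseq: str, junction: int
) -> tuple[int, str]:
    """Shift an insertion to its leftmost shift-equivalent position.

    While the last inserted base equals the reference base preceding the
    junction, the insertion can slide one base left without changing the
    implied germline (MIC) sequence; the leftmost position is canonical.
    """
    while junction > 0 and ies_seq[-1] == refseq[junction - 1]:
        ies_seq = ies_seq[-1] + ies_seq[:-1]
        junction -= 1
    return junction, ies_seq


def detect_pointer(
    ies_seq: str, ref: ReferenceGenome, contig: str, junction: int
) -> tuple[str, int, str]:
    """Annotate the pointer repeat after left-normalizing the insertion.

    The pointer is the longest prefix of the (normalized) insert that also
    follows the junction in the reference: the tandem repeat whose second
    copy stays in the MAC after excision.  Returns (pointer,
    normalized_junction, normalized_seq); the pointer may be empty.
    """
    refseq = ref[contig]
    junction, ies_seq = left_normalize(ies_seq, refseq, junction)
    k = 0
    while (
        k < len(ies_seq)
        and junction + k < len(refseq)
        and ies_seq[k] == refseq[junction + k]
    ):
        k += 1
    return ies_seq[:k], junction, ies_seq


def detect_ta(ies_seq: str, pointer: str) -> bool:
    """True iff the element is TA-bounded: the pointer is exactly "TA"."""
    return pointer == "TA" and ies_seq.startswith("TA")


def count_spanners(
    bam: pysam.AlignmentFile,
    contig: str,
    junction: int,
    buffer: int,
    min_insert_len: int,
    min_mapq: int,
) -> tuple[int, int]:
    """(retained, excised) spanning-read counts at one junction."""
    retained = excised = 0
    start = max(0, junction - buffer)
    for rec in bam.fetch(contig, start, junction + buffer):
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        if rec.mapping_quality < min_mapq:
            continue
        view = AlignedSegmentView(
            read_id=rec.query_name,
            contig=contig,
            ref_start=rec.reference_start,
            cigar=list(rec.cigartuples),
            query_seq="",
            mapq=rec.mapping_quality,
        )
        status = spans_junction(view, contig, junction, buffer, min_insert_len)
        if status is SpanStatus.RETAINED:
            retained += 1
        elif status is SpanStatus.EXCISED:
            excised += 1
    return retained, excised


def call_iess(
    bam_path: str | os.PathLike,
    ref: ReferenceGenome,
    mode: str = "subread",
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    max_cluster_dist: int | None = None,
    flank_len: int = DEFAULT_FLANK_LEN,
    min_insert_len: int = DEFAULT_MIN_INSERT_LEN,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    buffer: int = DEFAULT_BUFFER,
    contig: str | None = None,
) -> tuple[list[IESRecord], list[dict]]:
    """Run the full IES calling pipeline over a mapped long-read BAM.

    Returns the called records sorted by (contig, junction) and a
    per-cluster report including rejected clusters with reasons.
    """
    if mode not in ("ccs", "subread"):
        raise ValueError(f"unknown mode {mode!r}")
    if max_cluster_dist is None:
        max_cluster_dist = DEFAULT_MAX_CLUSTER_DIST[mode]
    validate_contigs(bam_path, ref)

    evidence_by_contig: dict[str, list[InsertEvidence]] = {}
    views: dict[str, AlignedSegmentView] = {}
    region = contig if contig else None
    for seg in iter_alignments(bam_path, region=region, min_mapq=min_mapq):
        evs = extract_insert_evidence(seg, min_insert_len)
        if evs:
            evidence_by_contig.setdefault(seg.contig, []).extend(evs)
            if mode == "subread":
                views[seg.read_id] = seg

    records: list[IESRecord] = []
    report: list[dict] = []
    with pysam.AlignmentFile(os.fspath(bam_path), "rb") as bam:
        for ctg in sorted(evidence_by_contig):
            clusters = cluster_inserts(evidence_by_contig[ctg], max_cluster_dist)
            clusters = split_mixed_length_clusters(clusters)
            for cluster in clusters:
                row = {
                    "contig": ctg,
                    "span_start": cluster.span[0],
                    "span_end": cluster.span[1],
                    "n_reads": cluster.n_reads,
                }
                if cluster.n_reads < min_coverage:
                    row.update(status="rejected", reason="below_min_coverage")
                    report.append(row)
                    continue
                called = _call_cluster(
                    cluster, views, ref, bam, mode, flank_len, min_insert_len,
                    min_mapq, buffer,
                )
                if called is None:
                    row.update(status="rejected", reason="no_insertion_in_realignment")
                    logger.debug(
                        "cluster %s:%d-%d rejected: realignment found no insertion",
                        ctg, *cluster.span,
                    )
                else:
                    records.append(called)
                    row.update(
                        status="called", reason="", junction=called.junction,
                        ies_length=called.length,
                    )
                report.append(row)

    records.sort(key=lambda r: (r.contig, r.junction))
    for idx, rec in enumerate(records, 1):
        rec.ies_id = f"IES_{idx:05d}_{rec.contig}_{rec.junction + 1}"
    return records, report


def _call_cluster(
    cluster: EvidenceCluster,
    views: dict[str, AlignedSegmentView],
    ref: ReferenceGenome,
    bam: pysam.AlignmentFile,
    mode: str,
    flank_len: int,
    min_insert_len: int,
    min_mapq: int,
    buffer: int,
) -> IESRecord | None:
    ctg = cluster.contig
    if mode == "ccs":
        cons = consensus([e.insert_seq for e in cluster.members])
        junction, ies_seq = cluster.mode_junction, cons
    else:
        flanked = extract_flanked_segments(cluster, views, flank_len)
        cons = consensus([f.seq for f in flanked])
        span = cluster.span
        window = (
            span[0] - flank_len - REALIGN_SLACK,
            span[1] + flank_len + REALIGN_SLACK,
        )
        result = realign_consensus(
            cons, ref, ctg, window, min_insert_len=min_insert_len
        )
        if result is None:
            return None
        junction, ies_seq = result

    pointer, junction, ies_seq = detect_pointer(ies_seq, ref, ctg, junction)
    support = cluster.n_reads
    _retained, excised = count_spanners(
        bam, ctg, junction, buffer, min_insert_len, min_mapq
    )
    spanning_total = support + excised
    return IESRecord(
        contig=ctg,
        junction=junction,
        ies_seq=ies_seq,
        pointer=pointer,
        ta_bounded=detect_ta(ies_seq, pointer),
        support=support,
        spanning_total=spanning_total,
        retention_score=support / spanning_total if spanning_total else 0.0,
        mode=mode,
    )


def write_gff3(
    records: list[IESRecord],
    path: str | os.PathLike,
    provenance: dict | None = None,
) -> None:
    """Write called IESs as zero-width GFF3 junction features (1-based,
    start == end == junction + 1)."""
    rows = []
    for rec in records:
        attrs = {
            "ID": rec.ies_id,
            "IES_length": rec.length,
            "pointer": rec.pointer,
            "ta_bound": str(rec.ta_bounded).lower(),
            "support": rec.support,
            "spanning_total": rec.spanning_total,
            "retention_score": f"{rec.retention_score:.4f}",
        }
        rows.append(
            (
                rec.contig,
                "iesweave_milraa",
                GFF_FEATURE_TYPE,
                rec.junction + 1,
                rec.junction + 1,
                f"{rec.retention_score:.4f}",
                ".",
                ".",
                attrs,
            )
        )
    gff_io.write_gff3(rows, path, provenance)


def write_ies_fasta(records: list[IESRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.ies_id}\n{rec.ies_seq}\n")


def read_records(
    gff_path: str | os.PathLike, fasta_path: str | os.PathLike | None = None
) -> list[IESRecord]:
    """Load called IESs back from GFF3 (and optionally the insert FASTA)."""
    seqs: dict[str, str] = {}
    if fasta_path is not None:
        with pysam.FastxFile(os.fspath(fasta_path)) as fh:
            seqs = {rec.name: rec.sequence for rec in fh}
    out = []
    df = gff_io.read_gff3(gff_path)
    for _, row in df.iterrows():
        attrs = row["attr"]
        ies_id = attrs.get("ID", "")
        seq = seqs.get(ies_id, "N" * int(attrs.get("IES_length", 1)))
        out.append(
            IESRecord(
                contig=row["seqid"],
                junction=int(row["start"]) - 1,
                ies_seq=seq,
                pointer=attrs.get("pointer", ""),
                ta_bounded=attrs.get("ta_bound") == "true",
                support=int(attrs.get("support", 0)),
                spanning_total=int(attrs.get("spanning_total", 0)),
                retention_score=float(attrs.get("retention_score", 0.0)),
                mode="unknown",
                ies_id=ies_id,
            )
        )
    return out
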