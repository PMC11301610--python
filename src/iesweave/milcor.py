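"""IES retention scoring and read binning.

Given an IES junction annotation, every primary read spanning a junction
is classified as carrying the insert (retained) or not (excised).  Scores
are reported per site — the classic retention score, the fraction of
spanning reads that retain the IES — and per read, the fraction of
annotated sites spanned by that read at which the IES is not excised.
Long reads span many sites, so the per-read score separates germline-like
(MIC) molecules from somatic-like (MAC) ones and can be used to bin reads
for partial germline-genome assembly.

Both scores share one definition of "spanning" (the ±buffer rule of
``io_align.spans_junction``), so the per-read and per-site tallies are
exactly consistent on the same BAM.

Unlike de novo evidence extraction — where short spurious insertions are
absorbed by clustering and coverage cutoffs downstream — retention
classification has no later filter, so its insert-length threshold defaults
to 20 bp: comfortably above the indel runs produced by noisy subreads, and
below the shortest IESs (26 bp) this regime targets.
"""

from __future__ import annotations

import logging
import os
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from enum import Enum

import pysam

from .io_align import (
    DEFAULT_MIN_MAPQ,
    AlignedSegmentView,
    SpanStatus,
    insert_positions,
    spans_junction,
)

logger = logging.getLogger(__name__)

DEFAULT_BUFFER = 15
#: minimum insert length to call a spanning read "retained" at an annotated
#: site; stricter than evidence extraction (see module docstring)
DEFAULT_RETENTION_MIN_INSERT = 20
DEFAULT_HI = 0.9
DEFAULT_LO = 0.1


@dataclass
class RetentionSiteStats:
    """Spanning-read tally at one annotated junction.

    ``score`` is None when no read spans the site.
    """

    contig: str
    junction: int
    ies_plus: int
    ies_minus: int

    @property
    def score(self) -> float | None:
        total = self.ies_plus + self.ies_minus
        return self.ies_plus / total if total else None


class ReadBin(str, Enum):
    MIC_LIKE = "mic_like"
    MAC_LIKE = "mac_like"
    AMBIGUOUS = "ambiguous"
    UNSCORED = "unscored"


@dataclass
class ReadRetentionRecord:
    read_id: str
    sites_spanned: int
    sites_retained: int

    @property
    def per_read_score(self) -> float | None:
        if self.sites_spanned == 0:
            return None
        return self.sites_retained / self.sites_spanned

    def bin(self, hi: float = DEFAULT_HI, lo: float = DEFAULT_LO) -> ReadBin:
        score = self.per_read_score
        if score is None:
            return ReadBin.UNSCORED
        if score >= hi:
            return ReadBin.MIC_LIKE
        if score <= lo:
            return ReadBin.MAC_LIKE
        return ReadBin.AMBIGUOUS


def _check_annotation(
    bam: pysam.AlignmentFile, annotation: list[tuple[str, int]]
) -> None:
    bam_contigs = set(bam.references)
    missing = {c for c, _ in annotation} - bam_contigs
    if missing:
        raise ValueError(
            "annotation contigs absent from BAM header: "
            + ", ".join(sorted(missing)[:5])
        )


def site_retention(
    bam_path: str | os.PathLike,
    annotation: list[tuple[str, int]],
    buffer: int = DEFAULT_BUFFER,
    min_insert_len: int = DEFAULT_RETENTION_MIN_INSERT,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> list[RetentionSiteStats]:
    """Per-site retention score at every annotated junction."""
    out = []
    with pysam.AlignmentFile(os.fspath(bam_path), "rb") as bam:
        _check_annotation(bam, annotation)
        for contig, junction in annotation:
            plus = minus = 0
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
                    plus += 1
                elif status is SpanStatus.EXCISED:
                    minus += 1
            out.append(RetentionSiteStats(contig, junction, plus, minus))
    return out


def read_retention(
    bam_path: str | os.PathLike,
    annotation: list[tuple[str, int]],
    buffer: int = DEFAULT_BUFFER,
    min_insert_len: int = DEFAULT_RETENTION_MIN_INSERT,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> list[ReadRetentionRecord]:
    """Per-read retention score over all annotated junctions.

    Classification at each site is identical to ``site_retention``; reads
    spanning zero sites come back unscored.
    """
    junctions: dict[str, list[int]] = {}
    for contig, junction in annotation:
        junctions.setdefault(contig, []).append(junction)
    for lst in junctions.values():
        lst.sort()

    out = []
    with pysam.AlignmentFile(os.fspath(bam_path), "rb") as bam:
        _check_annotation(bam, annotation)
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            sites = junctions.get(rec.reference_name, [])
            ref_start, ref_end = rec.reference_start, rec.reference_end
            lo_i = bisect_left(sites, ref_start + 1)
            hi_i = bisect_right(sites, ref_end)
            spanned = retained = 0
            if lo_i < hi_i:
                view = AlignedSegmentView(
                    read_id=rec.query_name,
                    contig=rec.reference_name,
                    ref_start=ref_start,
                    cigar=list(rec.cigartuples),
                    query_seq="",
                    mapq=rec.mapping_quality,
                )
                inserts = insert_positions(view, min_insert_len)
                for junction in sites[lo_i:hi_i]:
                    if ref_start > junction - buffer or view.ref_end < junction + buffer:
                        continue
                    spanned += 1
                    if any(abs(p - junction) <= buffer for p, _ in inserts):
                        retained += 1
            out.append(ReadRetentionRecord(rec.query_name, spanned, retained))
    return out


def bin_reads(
    records: list[ReadRetentionRecord],
    reads_path: str | os.PathLike,
    out_prefix: str | os.PathLike,
    hi: float = DEFAULT_HI,
    lo: float = DEFAULT_LO,
) -> dict[str, str]:
    """Split a read library into MIC-like / MAC-like / ambiguous files.

    Thresholds are inclusive outward: score >= ``hi`` is MIC-like, score <=
    ``lo`` MAC-like.  Unscored reads are omitted (count logged).  Output
    format (FASTA/FASTQ) follows the input.  A scored read missing from the
    sequence source is an error.
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    bins = {r.read_id: r.bin(hi, lo) for r in records}
    n_unscored = sum(1 for b in bins.values() if b is ReadBin.UNSCORED)
    if n_unscored:
        logger.info("omitting %d unscored reads from binning", n_unscored)

    out_paths = {}
    handles = {}
    seen: set[str] = set()
    try:
        with pysam.FastxFile(os.fspath(reads_path)) as fh:
            for rec in fh:
                bin_ = bins.get(rec.name)
                if bin_ is None or bin_ is ReadBin.UNSCORED:
                    continue
                seen.add(rec.name)
                if bin_ not in handles:
                    ext = "fastq" if rec.quality is not None else "fasta"
                    path = f"{os.fspath(out_prefix)}.{bin_.value}.{ext}"
                    handles[bin_] = open(path, "w")
                    out_paths[bin_.value] = path
                if rec.quality is not None:
                    handles[bin_].write(f"@{rec.name}\n{rec.sequence}\n+\n{rec.quality}\n")
                else:
                    handles[bin_].write(f">{rec.name}\n{rec.sequence}\n")
    finally:
        for h in handles.values():
            h.close()
    missing = {
        rid for rid, b in bins.items() if b is not ReadBin.UNSCORED
    } - seen
    if missing:
        raise ValueError(
            f"{len(missing)} scored reads absent from {reads_path}, e.g. "
            + sorted(missing)[0]
        )
    return out_paths
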