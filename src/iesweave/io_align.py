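"""Reference and alignment input layer.

Loads the somatic (MAC) reference genome and decomposes mapped long reads
into insertion / soft-clip evidence in a single 0-based, half-open
coordinate frame.  An insertion is a zero-width junction indexed by the
first reference base *after* the inserted sequence; this matches the native
BAM frame so that all downstream modules share one convention.

Only primary alignments contribute evidence: secondary and supplementary
records describe the same molecule again and would double-count support.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

import pysam

logger = logging.getLogger(__name__)

# CIGAR operation codes as stored in BAM
_CIGAR_OPS = "MIDNSHP=X"
M, I, D, N, S, H, P, EQ, X = range(9)

#: ops that consume the reference
REF_CONSUMING = {M, D, N, EQ, X}
#: ops that consume the query (read) sequence
QUERY_CONSUMING = {M, I, S, EQ, X}

_VALID_BASES = set("ACGTN")

DEFAULT_MIN_MAPQ = 1
DEFAULT_MIN_INSERT_LEN = 10


@dataclass(frozen=True)
class ReferenceGenome:
    """Named contigs with uppercase A/C/G/T/N sequences."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not name:
                raise ValueError("empty contig name")
            if not seq:
                raise ValueError(f"contig {name!r} has an empty sequence")

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def length(self, name: str) -> int:
        return len(self.contigs[name])

    @property
    def names(self) -> list[str]:
        return list(self.contigs)


@dataclass
class AlignedSegmentView:
    """Lightweight view of one primary alignment record.

    ``query_seq`` is the read sequence as stored in the BAM record, i.e.
    already in reference orientation and including soft-clipped bases.
    """

    read_id: str
    contig: str
    ref_start: int
    cigar: list[tuple[int, int]]
    query_seq: str
    mapq: int = 60
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.ref_start < 0:
            raise ValueError("ref_start must be >= 0")
        if not self.cigar:
            raise ValueError("empty CIGAR")
        if self.query_seq:
            qlen = sum(n for op, n in self.cigar if op in QUERY_CONSUMING)
            if qlen != len(self.query_seq):
                raise ValueError(
                    f"{self.read_id}: CIGAR consumes {qlen} query bases but "
                    f"sequence has {len(self.query_seq)}"
                )

    @property
    def ref_end(self) -> int:
        """End of the aligned reference interval (half-open)."""
        return self.ref_start + sum(n for op, n in self.cigar if op in REF_CONSUMING)


@dataclass(frozen=True)
class InsertEvidence:
    """One read's insertion observation at a reference junction.

    The insertion sits between reference bases ``junction - 1`` and
    ``junction``; ``query_start`` indexes the first inserted base in
    ``query_seq`` of the originating segment.
    """

    read_id: str
    contig: str
    junction: int
    insert_seq: str
    query_start: int

    def __post_init__(self) -> None:
        if not self.insert_seq:
            raise ValueError("empty insert sequence")
        if self.junction < 0:
            raise ValueError("negative junction")


class ClipSide(str, Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class ClipEvidence:
    """A soft-clipped read terminus at a reference breakpoint."""

    read_id: str
    contig: str
    breakpoint: int
    side: ClipSide
    clip_seq: str

    def __post_init__(self) -> None:
        if not self.clip_seq:
            raise ValueError("empty clip sequence")


class SpanStatus(str, Enum):
    RETAINED = "retained"
    EXCISED = "excised"
    NOT_SPANNING = "not_spanning"


def read_reference(path: str | os.PathLike) -> ReferenceGenome:
    """Load a FASTA reference, normalizing case and ambiguity codes.

    Lowercase is uppercased; IUPAC ambiguity codes other than N are mapped
    to N with a warning.  Duplicate contig names and empty files are hard
    errors.
    """
    contigs: dict[str, str] = {}
    n_ambiguous = 0
    with pysam.FastxFile(os.fspath(path)) as fh:
        for rec in fh:
            if rec.name in contigs:
                raise ValueError(f"duplicate contig name {rec.name!r} in {path}")
            seq = rec.sequence.upper()
            if not set(seq) <= _VALID_BASES:
                cleaned = "".join(b if b in _VALID_BASES else "N" for b in seq)
                n_ambiguous += sum(1 for a, b in zip(seq, cleaned) if a != b)
                seq = cleaned
            contigs[rec.name] = seq
    if n_ambiguous:
        logger.warning(
            "replaced %d non-ACGTN ambiguity bases with N while reading %s",
            n_ambiguous,
            path,
        )
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return ReferenceGenome(contigs)


def validate_contigs(bam_path: str | os.PathLike, ref: ReferenceGenome) -> None:
    """Fail fast if the BAM header and reference disagree on contig names."""
    with pysam.AlignmentFile(os.fspath(bam_path), "rb") as bam:
        bam_names = set(bam.references)
    missing = bam_names - set(ref.contigs)
    if missing:
        raise ValueError(
            "BAM contigs absent from reference FASTA: "
            + ", ".join(sorted(missing)[:5])
        )


def _view_from_pysam(rec: pysam.AlignedSegment) -> AlignedSegmentView:
    return AlignedSegmentView(
        read_id=rec.query_name,
        contig=rec.reference_name,
        ref_start=rec.reference_start,
        cigar=list(rec.cigartuples),
        query_seq=rec.query_sequence or "",
        mapq=rec.mapping_quality,
        is_primary=not (rec.is_secondary or rec.is_supplementary),
    )


def iter_alignments(
    path: str | os.PathLike,
    region: str | None = None,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> Iterator[AlignedSegmentView]:
    """Yield primary alignment views from a BAM, optionally within a region.

    Unmapped, secondary and supplementary records are skipped, as are
    records below ``min_mapq``.  A region query on an unindexed BAM is a
    hard error with a remediation hint.
    """
    with pysam.AlignmentFile(os.fspath(path), "rb") as bam:
        if region is not None:
            if not bam.has_index():
                raise ValueError(
                    f"{path} has no index but a region was requested; "
                    "run 'samtools index' (or pysam.index) first"
                )
            records = bam.fetch(region=region)
        else:
            records = bam.fetch(until_eof=True)
        for rec in records:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            if not rec.cigartuples:
                continue
            yield _view_from_pysam(rec)


def extract_insert_evidence(
    seg: AlignedSegmentView, min_insert_len: int = DEFAULT_MIN_INSERT_LEN
) -> list[InsertEvidence]:
    """All insertions of at least ``min_insert_len`` bases in one alignment.

    The junction of an I op equals ``ref_start`` plus the reference length
    consumed before it; the inserted sequence is sliced from the query by
    the corresponding query-consumed prefix.
    """
    out: list[InsertEvidence] = []
    rpos = seg.ref_start
    qpos = 0
    for op, n in seg.cigar:
        if op == I and n >= min_insert_len:
            if seg.query_seq and qpos + n > len(seg.query_seq):
                raise ValueError(
                    f"{seg.read_id}: I op at query offset {qpos} overruns sequence"
                )
            out.append(
                InsertEvidence(
                    read_id=seg.read_id,
                    contig=seg.contig,
                    junction=rpos,
                    insert_seq=seg.query_seq[qpos : qpos + n],
                    query_start=qpos,
                )
            )
        if op in REF_CONSUMING:
            rpos += n
        if op in QUERY_CONSUMING:
            qpos += n
    return out


def extract_clip_evidence(
    seg: AlignedSegmentView, min_clip_len: int
) -> list[ClipEvidence]:
    """Soft-clip evidence at either end of one alignment.

    A left clip breaks at ``ref_start``; a right clip at the end of the
    aligned reference interval.  Hard clips carry no sequence and are
    ignored.
    """
    out: list[ClipEvidence] = []
    first_op, first_n = seg.cigar[0]
    if first_op == S and first_n >= min_clip_len:
        out.append(
            ClipEvidence(
                read_id=seg.read_id,
                contig=seg.contig,
                breakpoint=seg.ref_start,
                side=ClipSide.LEFT,
                clip_seq=seg.query_seq[:first_n],
            )
        )
    last_op, last_n = seg.cigar[-1]
    if last_op == S and last_n >= min_clip_len and len(seg.cigar) > 1:
        out.append(
            ClipEvidence(
                read_id=seg.read_id,
                contig=seg.contig,
                breakpoint=seg.ref_end,
                side=ClipSide.RIGHT,
                clip_seq=seg.query_seq[len(seg.query_seq) - last_n :],
            )
        )
    return out


def insert_positions(
    seg: AlignedSegmentView, min_insert_len: int
) -> list[tuple[int, int]]:
    """(junction, length) of every I op of at least ``min_insert_len``."""
    out = []
    rpos = seg.ref_start
    for op, n in seg.cigar:
        if op == I and n >= min_insert_len:
            out.append((rpos, n))
        if op in REF_CONSUMING:
            rpos += n
    return out


def spans_junction(
    seg: AlignedSegmentView,
    contig: str,
    junction: int,
    buffer: int = 15,
    min_insert_len: int = DEFAULT_MIN_INSERT_LEN,
) -> SpanStatus:
    """Classify a read against one annotated IES junction.

    A read spans the junction if its aligned reference interval covers
    ``[junction - buffer, junction + buffer]``.  A spanning read is
    ``retained`` if it carries an insertion of at least ``min_insert_len``
    within ``buffer`` bp of the junction, else ``excised``.  Reads clipped
    inside the insert do not cover both flanks and are ``not_spanning``.
    """
    if buffer < 1:
        raise ValueError("buffer must be >= 1")
    if seg.contig != contig:
        return SpanStatus.NOT_SPANNING
    if seg.ref_start > junction - buffer or seg.ref_end < junction + buffer:
        return SpanStatus.NOT_SPANNING
    for pos, _n in insert_positions(seg, min_insert_len):
        if abs(pos - junction) <= buffer:
            return SpanStatus.RETAINED
    return SpanStatus.EXCISED
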