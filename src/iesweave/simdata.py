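"""Synthetic paired MAC/MIC genomes, long reads, and truth-based evaluation.

The generator emulates a *Paramecium*-like setting: a somatic (MAC)
reference; a germline-like (MIC) variant carrying short internally
eliminated sequences (IESs) with pointer/TA junction structure; and noisy
long reads drawn from both genomes.  Reads are emitted together with their
error-aware true alignment to the MAC reference (planted IESs appear as I
ops, telomeric tails and IES overhangs as soft clips), so the whole calling
pipeline is testable hermetically, without an external mapper.

Defaults describe the regime the toolkit targets: IESs of 26-100 bp
(mostly-TA-bounded, AT-rich genome), PacBio-subread-like ~10% error reads
at 20x coverage of each genome.  The error model is i.i.d. per base with
geometric insertion lengths — simpler than a chemistry-specific HMM, but
the detection logic responds to rates, not to error autocorrelation, and
all rates are configurable.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
import pysam

from .io_align import ReferenceGenome

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {b: i for i, b in enumerate("ACGT")}

# CIGAR op codes (BAM numeric)
_I, _D, _S, _EQ, _X = 1, 2, 4, 7, 8
_REF_OPS = {0, _D, 3, _EQ, _X}

IES_TRUTH_COLUMNS = [
    "ies_id",
    "contig",
    "mac_junction",
    "ies_seq",
    "pointer",
    "ta_bounded",
]


@dataclass(frozen=True)
class SimParams:
    """Simulation conditions; defaults are the target study regime."""

    seed: int = 1
    n_contigs: int = 2
    contig_len: int = 250_000
    gc: float = 0.28
    n_iess: int = 100
    ies_len_dist: tuple[int, int] = (26, 100)
    pointer_len_dist: tuple[int, int] = (0, 8)
    ta_fraction: float = 1.0
    read_len_dist: tuple[float, float, int] = (8000.0, 3000.0, 500)
    coverage_mac: float = 20.0
    coverage_mic: float = 20.0
    err_sub: float = 0.03
    err_ins: float = 0.04
    err_del: float = 0.03

    def __post_init__(self) -> None:
        for name in ("gc", "ta_fraction", "err_sub", "err_ins", "err_del"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.err_sub + self.err_ins + self.err_del >= 0.5:
            raise ValueError("total error rate must be < 0.5")
        if self.ies_len_dist[0] < 2 or self.ies_len_dist[0] > self.ies_len_dist[1]:
            raise ValueError("invalid IES length range")
        if self.coverage_mac < 0 or self.coverage_mic < 0:
            raise ValueError("coverages must be >= 0")


@dataclass
class TruthTable:
    """Ground truth for one simulation.

    ``ies`` has one row per planted IES; inserting each ``ies_seq`` at its
    ``mac_junction`` reproduces the MIC contig exactly.  ``reads`` (filled
    by ``simulate_reads``) labels each read with its genome of origin and
    true MAC alignment interval.
    """

    ies: pd.DataFrame
    reads: pd.DataFrame | None = None

    def verify(self, mac: ReferenceGenome, mic: ReferenceGenome) -> None:
        """Check the reinsertion invariant; raises on any mismatch."""
        for contig in mac.names:
            rows = self.ies[self.ies["contig"] == contig].sort_values(
                "mac_junction"
            )
            pieces = []
            prev = 0
            for _, row in rows.iterrows():
                j = int(row["mac_junction"])
                pieces.append(mac[contig][prev:j])
                pieces.append(row["ies_seq"])
                prev = j
            pieces.append(mac[contig][prev:])
            if "".join(pieces) != mic[contig]:
                raise AssertionError(
                    f"reinsertion of planted IESs does not reproduce MIC {contig}"
                )

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.ies.to_csv(path, sep="\t", index=False, columns=IES_TRUTH_COLUMNS)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", dtype={"ies_seq": str, "pointer": str})
        df["pointer"] = df["pointer"].fillna("")
        df["ta_bounded"] = df["ta_bounded"].astype(bool)
        return cls(ies=df)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _random_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    return rng.choice(4, size=n, p=[at, gc / 2.0, gc / 2.0, at]).astype(np.uint8)


def _sample_junctions(
    rng: np.random.Generator, contig_len: int, n: int, margin: int, min_gap: int
) -> np.ndarray:
    """Sorted junction positions with pairwise spacing >= min_gap."""
    if n == 0:
        return np.array([], dtype=int)
    span = contig_len - 2 * margin - (n - 1) * min_gap
    if span <= 0:
        raise ValueError(
            f"cannot place {n} IESs with {min_gap} bp spacing on a "
            f"{contig_len} bp contig; reduce n_iess"
        )
    # stars-and-bars: uniform positions in the reduced space, then re-expand
    raw = np.sort(rng.integers(0, span, size=n))
    return raw + margin + min_gap * np.arange(n)


def _pick_base(rng: np.random.Generator, forbidden: set[int]) -> int:
    choices = [b for b in range(4) if b not in forbidden]
    return int(choices[rng.integers(0, len(choices))])


def make_genomes(
    params: SimParams,
) -> tuple[ReferenceGenome, ReferenceGenome, TruthTable]:
    """Build paired MAC / MIC genomes with planted IESs.

    Each IES is pointer + random core; TA-bounded elements start with "TA"
    with one TA copy carried by the MAC junction.  Planted insertions are
    left-normalized by construction (the last inserted base differs from
    the base preceding the junction) and their pointer is exact (the base
    after the pointer differs between insert and reference), so truth
    junctions and pointers are unambiguous.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    margin = 600
    min_gap = 500

    # largest-remainder allocation of IESs across equal-length contigs
    per = [params.n_iess // params.n_contigs] * params.n_contigs
    for i in range(params.n_iess - sum(per)):
        per[i] += 1

    mac_contigs: dict[str, str] = {}
    mic_contigs: dict[str, str] = {}
    rows = []
    idx = 0
    for ci in range(params.n_contigs):
        name = f"ctg{ci + 1:03d}"
        mac = _random_codes(rng, params.contig_len, params.gc)
        junctions = _sample_junctions(rng, params.contig_len, per[ci], margin, min_gap)
        contig_ies: list[tuple[int, np.ndarray]] = []
        for j in junctions:
            j = int(j)
            ta = bool(rng.random() < params.ta_fraction)
            if ta:
                pointer = np.array([_CODE["T"], _CODE["A"]], dtype=np.uint8)
            else:
                k = int(rng.integers(params.pointer_len_dist[0],
                                     params.pointer_len_dist[1] + 1))
                pointer = _random_codes(rng, k, params.gc)
            k = len(pointer)
            mac[j : j + k] = pointer
            ies_len = int(rng.integers(params.ies_len_dist[0],
                                       params.ies_len_dist[1] + 1))
            core_len = max(1, ies_len - k)
            core = _random_codes(rng, core_len, params.gc)
            # pointer must not extend: first core base differs from reference
            # after the pointer copy
            if core_len == 1:
                core[0] = _pick_base(rng, {int(mac[j + k]), int(mac[j - 1])})
            else:
                if core[0] == mac[j + k]:
                    core[0] = _pick_base(rng, {int(mac[j + k])})
                # keep the insertion left-normalized
                if core[-1] == mac[j - 1]:
                    core[-1] = _pick_base(rng, {int(mac[j - 1])})
            ies = np.concatenate([pointer, core])
            contig_ies.append((j, ies))
            rows.append(
                {
                    "ies_id": f"TRUE_{idx + 1:05d}",
                    "contig": name,
                    "mac_junction": j,
                    "ies_seq": _decode(ies),
                    "pointer": _decode(pointer),
                    "ta_bounded": ta and _decode(pointer) == "TA",
                }
            )
            idx += 1
        pieces = []
        prev = 0
        for j, ies in contig_ies:
            pieces.append(mac[prev:j])
            pieces.append(ies)
            prev = j
        pieces.append(mac[prev:])
        mac_contigs[name] = _decode(mac)
        mic_contigs[name] = _decode(np.concatenate(pieces) if pieces else mac)

    truth = TruthTable(
        ies=pd.DataFrame(rows, columns=IES_TRUTH_COLUMNS)
    )
    mac_genome = ReferenceGenome(mac_contigs)
    mic_genome = ReferenceGenome(mic_contigs)
    truth.verify(mac_genome, mic_genome)
    return mac_genome, mic_genome, truth


def _rle(arr: np.ndarray) -> list[tuple[int, int]]:
    if arr.size == 0:
        return []
    change = np.flatnonzero(np.diff(arr))
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [arr.size]])
    return [(int(arr[s]), int(e - s)) for s, e in zip(starts, ends)]


def _merge_ops(ops: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for op, n in ops:
        if n == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def _make_read(
    tmpl: np.ndarray,
    unaligned: np.ndarray,
    rng: np.random.Generator,
    err_sub: float,
    err_ins: float,
    err_del: float,
) -> tuple[str, list[tuple[int, int]], int, int, dict] | None:
    """Apply the error model to a template and build the true CIGAR.

    ``unaligned`` marks template positions that do not exist in the MAC
    reference (IES bases, telomeric tails); surviving copies of them become
    I ops, converted to soft clips at read ends.  Returns (sequence, cigar,
    leading_ref_trim, ref_consumed, error-event stats), or None when no
    template base aligns (read is unmapped).
    """
    L = tmpl.size
    r = rng.random(L)
    del_mask = r < err_del
    sub_mask = (r >= err_del) & (r < err_del + err_sub)
    kept = ~del_mask
    ins_mask = rng.random(L) < err_ins
    ins_pos = np.flatnonzero(ins_mask)
    ins_lens = rng.geometric(0.5, size=ins_pos.size) if ins_pos.size else np.array([], dtype=int)

    bases = tmpl.copy()
    n_sub = int(np.count_nonzero(sub_mask & kept))
    if n_sub:
        where = sub_mask & kept
        bases[where] = (bases[where] + rng.integers(1, 4, size=n_sub).astype(np.uint8)) % 4

    ins_len_full = np.zeros(L, dtype=np.int64)
    ins_len_full[ins_pos] = ins_lens
    contrib = kept.astype(np.int64) + ins_len_full
    off = np.cumsum(contrib) - contrib
    total = int(contrib.sum())
    seq = np.empty(total, dtype=np.uint8)
    seq[off[kept]] = bases[kept]
    for p, g in zip(ins_pos, ins_lens):
        o = int(off[p] + kept[p])
        seq[o : o + int(g)] = rng.integers(0, 4, size=int(g)).astype(np.uint8)

    opc = np.empty(L, dtype=np.int8)
    opc[unaligned & kept] = _I
    opc[unaligned & ~kept] = -1  # deleted insert base: no op at all
    aligned = ~unaligned
    opc[aligned & ~kept] = _D
    opc[aligned & kept & sub_mask] = _X
    opc[aligned & kept & ~sub_mask] = _EQ

    ops: list[tuple[int, int]] = []
    prev = 0
    for p, g in zip(ins_pos, ins_lens):
        seg = opc[prev : p + 1]
        ops.extend(_rle(seg[seg >= 0]))
        ops.append((_I, int(g)))
        prev = p + 1
    seg = opc[prev:]
    ops.extend(_rle(seg[seg >= 0]))
    ops = _merge_ops(ops)

    # Trim read ends: an alignment must start and end on an aligned base.
    # Leading/trailing D runs are dropped (the reference trim is recorded);
    # leading/trailing I runs, including planted-insert overhangs, become
    # soft clips.
    if not any(op in (_EQ, _X) for op, _ in ops):
        return None
    lead_trim = lead_clip = 0
    while ops[0][0] not in (_EQ, _X):
        op, n = ops.pop(0)
        if op == _D:
            lead_trim += n
        else:
            lead_clip += n
    tail_clip = 0
    while ops[-1][0] not in (_EQ, _X):
        op, n = ops.pop()
        if op != _D:
            tail_clip += n
    if lead_clip:
        ops.insert(0, (_S, lead_clip))
    if tail_clip:
        ops.append((_S, tail_clip))
    ref_consumed = sum(n for op, n in ops if op in _REF_OPS)
    stats = {
        "n_sub": n_sub,
        "n_del": int(np.count_nonzero(del_mask)),
        "n_ins_events": int(ins_pos.size),
        "template_len": L,
    }
    return _decode(seq), ops, lead_trim, ref_consumed, stats


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


class _BamBuilder:
    """Collects alignment records, then writes a sorted, indexed BAM."""

    def __init__(self, ref: ReferenceGenome, out_bam: str):
        self.header = pysam.AlignmentHeader.from_references(
            ref.names, [ref.length(n) for n in ref.names]
        )
        self.tids = {n: i for i, n in enumerate(ref.names)}
        self.records: list[pysam.AlignedSegment] = []
        self.out_bam = out_bam

    def add(self, name, contig, start, cigar, seq, reverse):
        rec = pysam.AlignedSegment(self.header)
        rec.query_name = name
        rec.flag = 16 if reverse else 0
        rec.reference_id = self.tids[contig]
        rec.reference_start = start
        rec.mapping_quality = 60
        rec.cigartuples = cigar
        rec.query_sequence = seq
        self.records.append(rec)

    def write(self) -> None:
        tmp = self.out_bam + ".unsorted.bam"
        with pysam.AlignmentFile(tmp, "wb", header=self.header) as fh:
            for rec in self.records:
                fh.write(rec)
        pysam.sort("--no-PG", "-o", self.out_bam, tmp)
        pysam.index(self.out_bam)
        os.remove(tmp)


def _mic_coordinate_maps(
    mac: ReferenceGenome, truth: TruthTable
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per MIC contig: (is_ies mask, exclusive prefix count of IES bases)."""
    maps = {}
    for contig in mac.names:
        rows = truth.ies[truth.ies["contig"] == contig].sort_values("mac_junction")
        mic_len = mac.length(contig) + int(rows["ies_seq"].str.len().sum())
        is_ies = np.zeros(mic_len, dtype=bool)
        offset = 0
        for _, row in rows.iterrows():
            start = int(row["mac_junction"]) + offset
            ln = len(row["ies_seq"])
            is_ies[start : start + ln] = True
            offset += ln
        prefix = np.cumsum(is_ies) - is_ies
        maps[contig] = (is_ies, prefix)
    return maps


def simulate_reads(
    mac: ReferenceGenome,
    mic: ReferenceGenome,
    truth: TruthTable,
    params: SimParams,
    out_dir: str | os.PathLike,
) -> tuple[str, str]:
    """Draw noisy reads from both genomes, with their true MAC alignments.

    Writes ``reads.fastq`` (reverse-strand reads reverse-complemented) and
    a coordinate-sorted, indexed ``truth.bam`` under ``out_dir``; fills
    ``truth.reads`` with per-read origin labels, true alignment intervals
    and error-event counts.  Reads lying entirely within an IES are emitted
    to the FASTQ only.
    """
    os.makedirs(out_dir, exist_ok=True)
    fastq_path = os.path.join(os.fspath(out_dir), "reads.fastq")
    bam_path = os.path.join(os.fspath(out_dir), "truth.bam")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))

    mac_codes = {n: np.frombuffer(mac[n].encode(), np.uint8) for n in mac.names}
    mic_codes = {n: np.frombuffer(mic[n].encode(), np.uint8) for n in mic.names}
    for d in (mac_codes, mic_codes):
        for n, arr in d.items():
            codes = np.zeros(arr.size, dtype=np.uint8)
            for b, i in _CODE.items():
                codes[arr == ord(b)] = i
            d[n] = codes
    mic_maps = _mic_coordinate_maps(mac, truth)

    builder = _BamBuilder(mac, bam_path)
    mean_len, sd_len, min_len = params.read_len_dist
    read_rows = []
    counter = 0
    with open(fastq_path, "w") as fq:
        for origin, coverage, codes_by_ctg in (
            ("mac", params.coverage_mac, mac_codes),
            ("mic", params.coverage_mic, mic_codes),
        ):
            if coverage <= 0:
                continue
            names = list(codes_by_ctg)
            lens = np.array([codes_by_ctg[n].size for n in names], dtype=float)
            weights = lens / lens.sum()
            target = coverage * lens.sum()
            emitted = 0.0
            while emitted < target:
                contig = names[int(rng.choice(len(names), p=weights))]
                src = codes_by_ctg[contig]
                L = int(np.clip(rng.normal(mean_len, sd_len), min_len, src.size))
                start = int(rng.integers(0, src.size - L + 1))
                tmpl = src[start : start + L]
                if origin == "mic":
                    is_ies, prefix = mic_maps[contig]
                    unaligned = is_ies[start : start + L]
                else:
                    unaligned = np.zeros(L, dtype=bool)
                emitted += L
                counter += 1
                name = f"{origin}_{counter:06d}"
                made = _make_read(
                    tmpl, unaligned, rng, params.err_sub, params.err_ins,
                    params.err_del,
                )
                reverse = bool(rng.random() < 0.5)
                if made is None:
                    seq = _decode(tmpl)  # fully unaligned: emit raw template
                    made_stats = {"n_sub": 0, "n_del": 0, "n_ins_events": 0,
                                  "template_len": L}
                    mac_start = mac_end = -1
                else:
                    seq, cigar, lead_trim, ref_consumed, made_stats = made
                    if origin == "mic":
                        aligned_idx = np.flatnonzero(~unaligned)
                        first = int(start + aligned_idx[0])
                        mac_start = first - int(prefix[first]) + lead_trim
                    else:
                        mac_start = start + lead_trim
                    mac_end = mac_start + ref_consumed
                    builder.add(name, contig, mac_start, cigar, seq, reverse)
                out_seq = _revcomp(seq) if reverse else seq
                fq.write(f"@{name}\n{out_seq}\n+\n{'I' * len(out_seq)}\n")
                read_rows.append(
                    {
                        "read_id": name,
                        "origin": origin,
                        "contig": contig,
                        "mac_start": mac_start,
                        "mac_end": mac_end,
                        "strand": "-" if reverse else "+",
                        **made_stats,
                    }
                )
    builder.write()
    truth.reads = pd.DataFrame(read_rows)
    return fastq_path, bam_path


def simulate_breakage_reads(
    mac: ReferenceGenome,
    breaks: list[tuple[str, int, str]],
    out_bam: str | os.PathLike,
    n_reads: int = 10,
    telomere_len: int = 120,
    motif: str = "TTGGGG",
    aligned_len: int = 2000,
    err_sub: float = 0.03,
    err_ins: float = 0.04,
    err_del: float = 0.03,
    seed: int = 1,
) -> None:
    """Reads crossing planted chromosome breakage sites with telomere tails.

    ``breaks`` holds (contig, position, side) where ``side`` is the clipped
    side of the resulting alignments: "right" means the retained fragment
    lies left of the break and reads run into the appended telomere.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    tail = (motif * (telomere_len // len(motif) + 1))[:telomere_len]
    tail_codes = np.array([_CODE[b] for b in tail], dtype=np.uint8)
    builder = _BamBuilder(mac, os.fspath(out_bam))
    counter = 0
    for contig, position, side in breaks:
        codes = np.array([_CODE.get(b, 0) for b in mac[contig]], dtype=np.uint8)
        for _ in range(n_reads):
            span = int(rng.integers(aligned_len // 2, aligned_len + 1))
            if side == "right":
                s = max(0, position - span)
                tmpl = np.concatenate([codes[s:position], tail_codes])
                unaligned = np.zeros(tmpl.size, dtype=bool)
                unaligned[position - s :] = True
                ref_anchor = s
            elif side == "left":
                e = min(mac.length(contig), position + span)
                tmpl = np.concatenate([tail_codes, codes[position:e]])
                unaligned = np.zeros(tmpl.size, dtype=bool)
                unaligned[: tail_codes.size] = True
                ref_anchor = position
            else:
                raise ValueError(f"unknown side {side!r}")
            made = _make_read(tmpl, unaligned, rng, err_sub, err_ins, err_del)
            if made is None:
                continue
            seq, cigar, lead_trim, _ref_consumed, _stats = made
            counter += 1
            builder.add(
                f"brk_{counter:05d}", contig, ref_anchor + lead_trim, cigar,
                seq, bool(rng.random() < 0.5),
            )
    builder.write()


def evaluate(
    predicted: list,
    truth: TruthTable,
    tol_bp: int = 5,
) -> dict:
    """Match predictions to planted IESs and score recovery.

    One-to-one greedy matching by junction distance (closest pairs first,
    ties toward the leftmost truth junction); ``recall`` and ``precision``
    follow, and matched pairs are scored for sequence accuracy by global
    edit alignment: exact reconstructions, and reconstructions with at most
    1 mismatch and 1 indel base.
    """
    truth_sites = [
        (row["contig"], int(row["mac_junction"]), row["ies_seq"])
        for _, row in truth.ies.iterrows()
    ]
    pairs = []
    for pi, rec in enumerate(predicted):
        for ti, (contig, junction, _seq) in enumerate(truth_sites):
            if rec.contig == contig and abs(rec.junction - junction) <= tol_bp:
                pairs.append((abs(rec.junction - junction), junction, pi, ti))
    pairs.sort()
    matched_pred: set[int] = set()
    matched_truth: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _d, _j, pi, ti in pairs:
        if pi in matched_pred or ti in matched_truth:
            continue
        matched_pred.add(pi)
        matched_truth.add(ti)
        matches.append((pi, ti))

    n_exact = n_near = 0
    for pi, ti in matches:
        pred_seq = predicted[pi].ies_seq
        true_seq = truth_sites[ti][2]
        if pred_seq == true_seq:
            n_exact += 1
            n_near += 1
            continue
        res = edlib.align(pred_seq, true_seq, mode="NW", task="path")
        mm = indel = 0
        for m in re.finditer(r"(\d+)([=XID])", res["cigar"]):
            n, op = int(m.group(1)), m.group(2)
            if op == "X":
                mm += n
            elif op in "ID":
                indel += n
        if mm <= 1 and indel <= 1:
            n_near += 1

    n_truth = len(truth_sites)
    n_pred = len(predicted)
    n_matched = len(matches)
    return {
        "n_truth": n_truth,
        "n_pred": n_pred,
        "n_matched": n_matched,
        "recall": n_matched / n_truth if n_truth else 0.0,
        "precision": n_matched / n_pred if n_pred else 0.0,
        "n_exact_seq": n_exact,
        "n_seq_1mm1indel": n_near,
    }
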