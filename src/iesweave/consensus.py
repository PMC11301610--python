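"""Consensus calling for clustered insert (plus flank) sequences.

The consensus is built by iterative backbone polishing: the member whose
length is closest to the cluster median seeds the backbone, every member is
globally aligned to it with edlib, and per-column majority voting over
substitutions, deletions and inserted runs rewrites the backbone.  Two
rounds are enough in practice — the first round removes nearly all
backbone-private errors, the second converges.  Tie-breaks are fixed
(lexicographic base order, first-seen insertion strings) so the result is a
deterministic function of the input list and its order.
"""

from __future__ import annotations

from collections import Counter
import re

import edlib
import numpy as np

_CIG_RE = re.compile(r"(\d+)([=XIDM])")
_BASE_IDX = {b: i for i, b in enumerate("ACGTN")}
#: vote index 5 is "deleted"
_DEL = 5


def _pick_backbone(seqs: list[str]) -> str:
    lens = sorted(len(s) for s in seqs)
    median = lens[len(lens) // 2]
    return min(seqs, key=lambda s: (abs(len(s) - median), seqs.index(s)))


def _polish(backbone: str, seqs: list[str]) -> str:
    n = len(backbone)
    votes = np.zeros((n, 6), dtype=np.int32)
    # inserted sequence immediately *before* backbone position p (p == n
    # appends at the end)
    inserts: dict[int, Counter] = {}
    has_insert: Counter = Counter()

    for seq in seqs:
        res = edlib.align(seq, backbone, mode="NW", task="path")
        bpos = 0  # backbone (target) position
        qpos = 0
        for m in _CIG_RE.finditer(res["cigar"]):
            length, op = int(m.group(1)), m.group(2)
            if op in "=XM":
                for k in range(length):
                    votes[bpos + k, _BASE_IDX.get(seq[qpos + k], 4)] += 1
                bpos += length
                qpos += length
            elif op == "D":  # gap in query: backbone bases deleted
                votes[bpos : bpos + length, _DEL] += 1
                bpos += length
            elif op == "I":  # extra query bases before backbone position
                run = seq[qpos : qpos + length]
                inserts.setdefault(bpos, Counter())[run] += 1
                has_insert[bpos] += 1
                qpos += length

    half = len(seqs) / 2.0
    out: list[str] = []
    for p in range(n + 1):
        if has_insert.get(p, 0) > half:
            run, _cnt = max(inserts[p].items(), key=lambda kv: (kv[1], kv[0]))
            out.append(run)
        if p == n:
            break
        col = votes[p]
        best = int(np.argmax(col))  # ties resolve in ACGTN<del order
        if best != _DEL:
            out.append("ACGTN"[best])
    return "".join(out)


def consensus(seqs: list[str], rounds: int = 2) -> str:
    """Majority consensus of a list of similar sequences.

    A single sequence is returned verbatim; an empty list is an error.
    """
    if not seqs:
        raise ValueError("cannot build a consensus from zero sequences")
    if len(seqs) == 1:
        return seqs[0]
    backbone = _pick_backbone(seqs)
    for _ in range(rounds):
        new = _polish(backbone, seqs)
        if new == backbone:
            break
        backbone = new
    return backbone
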