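"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a quantity by the most literal method available —
per-base walks, transitive closures, exhaustive shift enumeration — and is
deliberately kept free of any code from the package's own fast paths.
"""

from __future__ import annotations

import numpy as np

# BAM numeric op codes
M, I, D, N, S, H, P, EQ, X = range(9)
REF_OPS = {M, D, N, EQ, X}
QUERY_OPS = {M, I, S, EQ, X}


def expand_cigar(cigar: list[tuple[int, int]]) -> list[int]:
    out: list[int] = []
    for op, n in cigar:
        out.extend([op] * n)
    return out


def naive_insert_evidence(
    ref_start: int, cigar: list[tuple[int, int]], query_seq: str, min_len: int
) -> list[tuple[int, int, str]]:
    """(junction, query_start, seq) of every long-enough I run, found by
    stepping one base at a time through the expanded CIGAR."""
    ops = expand_cigar(cigar)
    out = []
    rpos, qpos = ref_start, 0
    i = 0
    while i < len(ops):
        if ops[i] == I:
            j = i
            while j < len(ops) and ops[j] == I:
                j += 1
            run = j - i
            if run >= min_len:
                out.append((rpos, qpos, query_seq[qpos : qpos + run]))
            qpos += run
            i = j
            continue
        if ops[i] in REF_OPS:
            rpos += 1
        if ops[i] in QUERY_OPS:
            qpos += 1
        i += 1
    return out


def naive_clip_evidence(
    ref_start: int, cigar: list[tuple[int, int]], query_seq: str, min_len: int
) -> list[tuple[str, int, str]]:
    """(side, breakpoint, seq) for soft clips, from the expanded CIGAR."""
    ops = expand_cigar(cigar)
    out = []
    n_left = 0
    while n_left < len(ops) and ops[n_left] == S:
        n_left += 1
    if 0 < n_left < len(ops) and n_left >= min_len:
        out.append(("left", ref_start, query_seq[:n_left]))
    n_right = 0
    while n_right < len(ops) and ops[len(ops) - 1 - n_right] == S:
        n_right += 1
    if 0 < n_right < len(ops) - n_left and n_right >= min_len:
        ref_len = sum(1 for op in ops if op in REF_OPS)
        out.append(("right", ref_start + ref_len, query_seq[len(query_seq) - n_right :]))
    return out


def closure_partition(positions: list[int], max_dist: int) -> list[tuple[int, ...]]:
    """Connected components of the "within max_dist" relation, by repeated
    transitive closure over all pairs (O(n^2))."""
    n = len(positions)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(n):
        for b in range(a + 1, n):
            if abs(positions[a] - positions[b]) <= max_dist:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(positions[i])
    return sorted(tuple(sorted(g)) for g in groups.values())


def shift_equivalents(
    refseq: str, junction: int, ies_seq: str
) -> list[tuple[int, str]]:
    """Every (junction, insert) placement implying the same MIC sequence,
    found by exhaustive single-base shifts in both directions."""
    seen = {(junction, ies_seq)}
    j, s = junction, ies_seq
    while j > 0 and s[-1] == refseq[j - 1]:
        s = s[-1] + s[:-1]
        j -= 1
        seen.add((j, s))
    j, s = junction, ies_seq
    while j < len(refseq) and s[0] == refseq[j]:
        s = s[1:] + s[0]
        j += 1
        seen.add((j, s))
    return sorted(seen)


def pointer_by_shift_enumeration(
    refseq: str, junction: int, ies_seq: str
) -> tuple[str, int, str]:
    """Canonical (pointer, junction, insert) via the leftmost equivalent
    placement and a literal prefix comparison."""
    j, s = shift_equivalents(refseq, junction, ies_seq)[0]
    k = 0
    while k < len(s) and j + k < len(refseq) and s[k] == refseq[j + k]:
        k += 1
    return s[:k], j, s


def naive_motif_coverage(seq: str, variants: set[str]) -> float:
    """Per-position coverage scan: position i is covered if any variant
    occurrence [a, a+m) contains i."""
    covered = np.zeros(len(seq), dtype=bool)
    for a in range(len(seq)):
        for v in variants:
            if seq[a : a + len(v)] == v:
                covered[a : a + len(v)] = True
    return covered.sum() / len(seq)


def optimal_matching_size(
    preds: list[int], truths: list[int], tol: int
) -> int:
    """Maximum bipartite matching size by exhaustive recursion (small n)."""
    best = 0

    def rec(pi: int, used: set[int], count: int) -> None:
        nonlocal best
        best = max(best, count)
        if pi == len(preds):
            return
        rec(pi + 1, used, count)
        for ti, t in enumerate(truths):
            if ti not in used and abs(preds[pi] - t) <= tol:
                used.add(ti)
                rec(pi + 1, used, count + 1)
                used.remove(ti)

    rec(0, set(), 0)
    return best
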