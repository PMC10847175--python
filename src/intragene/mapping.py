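"""Deterministic short-read mapping for desk-scale references.

A k-mer seed index over the reference plus edlib infix alignment of candidate
placements, with the best-scoring contiguous alignment segment extracted from
the CIGAR (match +1, mismatch/indel -1). This soft-clips junction-spanning read
ends, so a read half inside the vector still maps to the vector with its
genomic tail trimmed. Intended for references up to a few megabases; it is the
mapping contract behind both insertion-caller steps, not a general aligner.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

import edlib

from .seqs import revcomp

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


@dataclass(frozen=True)
class Alignment:
    """Best local placement of a query on a reference collection.

    ``ref_start``/``ref_end`` are 0-based half-open on the reference forward
    strand; ``identity`` is matches over aligned columns of the retained
    segment; ``aligned_frac`` is the fraction of query bases in that segment.
    ``n_best`` counts distinct equally-scoring placements (ambiguity flag).
    """

    query_id: str
    ref_id: str
    ref_start: int
    ref_end: int
    strand: str
    identity: float
    aligned_frac: float
    matches: int
    n_best: int = 1


class ReferenceIndex:
    """Exact k-mer index over a reference collection (forward strand)."""

    def __init__(self, refs: dict[str, str], k: int = 21):
        if not refs or all(len(s) == 0 for s in refs.values()):
            raise ValueError("empty reference")
        self.k = k
        self.names = sorted(refs)
        self.seqs = {n: refs[n].upper() for n in self.names}
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ri, name in enumerate(self.names):
            seq = self.seqs[name]
            for pos in range(0, len(seq) - k + 1):
                kmer = seq[pos:pos + k]
                if "N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((ri, pos))


_MISMATCH_PENALTY = 3
_END_ANCHOR = 4  # segment ends must sit on a run of >= this many consecutive matches


def _best_segment(cigar: str) -> tuple[int, int, int, int, int, int]:
    """Maximum-scoring contiguous stretch of CIGAR runs (match +1, else -3),
    with both ends trimmed back to a run of >= 4 consecutive matches.

    The penalty stops greedy extension over low-identity tails (e.g. the
    vector half of a junction-spanning read drifting across unrelated
    reference bases) and the end anchoring removes isolated chance matches at
    the segment edges; both trims only ever shorten the segment, never shift
    it. Returns (score, matches, q_off, q_len, t_off, t_len) with offsets
    relative to the alignment start.
    """
    runs = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    # run-level prefix coordinates and scores
    q_off = [0]
    t_off = [0]
    for n, op in runs:
        q_off.append(q_off[-1] + (n if op in "=XI" else 0))
        t_off.append(t_off[-1] + (n if op in "=XD" else 0))
    scores = [n if op == "=" else -_MISMATCH_PENALTY * n for n, op in runs]

    best = (0, -1, -1)  # (score, first run, last run)
    cur, cur_start = 0, 0
    for i, s in enumerate(scores):
        if cur <= 0:
            cur, cur_start = s, i
        else:
            cur += s
        if cur > best[0]:
            best = (cur, cur_start, i)
    _, i0, i1 = best
    if i0 < 0:
        return (0, 0, 0, 0, 0, 0)
    while i0 <= i1 and not (runs[i0][1] == "=" and runs[i0][0] >= _END_ANCHOR):
        i0 += 1
    while i1 >= i0 and not (runs[i1][1] == "=" and runs[i1][0] >= _END_ANCHOR):
        i1 -= 1
    if i1 < i0:
        return (0, 0, 0, 0, 0, 0)
    score = sum(scores[i0:i1 + 1])
    matches = sum(n for n, op in runs[i0:i1 + 1] if op == "=")
    return (score, matches, q_off[i0], q_off[i1 + 1] - q_off[i0],
            t_off[i0], t_off[i1 + 1] - t_off[i0])


def map_to_reference(queries: Iterable[tuple[str, str]],
                     index: ReferenceIndex | dict[str, str],
                     min_identity: float = 0.9,
                     min_aligned_frac: float = 0.5,
                     seed_stride: int = 10,
                     pad: int = 30) -> dict[str, Optional[Alignment]]:
    """Best placement per query, or None when no placement meets the thresholds.

    Deterministic: ties are broken by (lowest ref id, leftmost position, plus
    strand first); the tie count is recorded in ``n_best`` so callers can drop
    ambiguous placements.
    """
    if isinstance(index, dict):
        index = ReferenceIndex(index)
    out: dict[str, Optional[Alignment]] = {}
    for qid, seq in queries:
        out[qid] = _map_one(qid, seq.upper(), index, min_identity,
                            min_aligned_frac, seed_stride, pad)
    return out


def _candidates(seq: str, index: ReferenceIndex, seed_stride: int) -> list[tuple[int, int]]:
    k = index.k
    if len(seq) < k:
        return []
    votes: dict[tuple[int, int], int] = {}
    offsets = list(range(0, len(seq) - k + 1, seed_stride))
    if offsets[-1] != len(seq) - k:
        offsets.append(len(seq) - k)
    for qo in offsets:
        for ri, pos in index.index.get(seq[qo:qo + k], ()):
            votes[(ri, pos - qo)] = votes.get((ri, pos - qo), 0) + 1
    # merge diagonals within 6 bp (small indels), keep representative with most votes
    merged: list[tuple[int, int, int]] = []  # (ri, diag, votes)
    for (ri, diag) in sorted(votes):
        v = votes[(ri, diag)]
        if merged and merged[-1][0] == ri and diag - merged[-1][1] <= 6:
            if v > merged[-1][2]:
                merged[-1] = (ri, diag, v)
        else:
            merged.append((ri, diag, v))
    merged.sort(key=lambda m: (-m[2], m[0], m[1]))
    return [(ri, diag) for ri, diag, _ in merged[:20]]


def _map_one(qid: str, seq: str, index: ReferenceIndex, min_identity: float,
             min_aligned_frac: float, seed_stride: int, pad: int) -> Optional[Alignment]:
    qlen = len(seq)
    results: list[tuple] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for ri, diag in _candidates(s, index, seed_stride):
            ref_name = index.names[ri]
            ref = index.seqs[ref_name]
            w0 = max(0, diag - pad)
            w1 = min(len(ref), diag + qlen + pad)
            if w1 - w0 < index.k:
                continue
            aln = edlib.align(s, ref[w0:w1], mode="HW", task="path")
            if aln["editDistance"] < 0 or not aln.get("cigar"):
                continue
            t_start = aln["locations"][0][0]
            score, matches, q0, qseg, t0, tseg = _best_segment(aln["cigar"])
            if qseg == 0:
                continue
            cols = max(qseg, tseg)
            identity = matches / cols
            aligned_frac = qseg / qlen
            if identity < min_identity or aligned_frac < min_aligned_frac:
                continue
            rs = w0 + t_start + t0
            results.append((-score, ri, rs, 0 if strand == "+" else 1,
                            matches, identity, aligned_frac, rs + tseg, strand, ref_name))
    if not results:
        return None
    results.sort()
    best = results[0]
    # count distinct placements achieving the best score (> 10 bp apart)
    n_best, seen = 0, []
    for r in results:
        if r[0] != best[0]:
            break
        key = (r[1], r[3])
        if any(k == key and abs(p - r[2]) <= 10 for k, p in seen):
            continue
        seen.append((key, r[2]))
        n_best += 1
    _, _, rs, _, matches, identity, aligned_frac, re_, strand, ref_name = best
    return Alignment(qid, ref_name, rs, re_, strand, identity, aligned_frac,
                     matches, n_best)
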