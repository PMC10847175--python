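"""Vector-anchored paired-end insertion-site calling.

Two-step discordant-pair strategy: first keep only read pairs with exactly one
mate mapping to the transformation vector (the anchor), classifying the anchor
as T-DNA or bacterial backbone; then map each retained pair's other (informative)
mate to the host reference genome and cluster those placements into insertion
calls with strand-partitioned support. A backbone-anchored count doubles as the
vector-backbone integration screen: zero backbone anchors at adequate coverage
certifies a backbone-free event.

Because an intragenic vector is built from host DNA, wild-type reads sampled
from the fragments' native loci also anchor to the vector; calls there reflect
the donor loci, not an integration. ``call_insertions`` therefore accepts an
exclusion mask (by default derived from the construct's provenance) so that
only novel loci are reported, mirroring a wild-type-vs-transformed comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .construct import ConstructMap
from .mapping import Alignment, ReferenceIndex, map_to_reference

VECTOR_REF_NAME = "vector"


@dataclass(frozen=True)
class ReadPair:
    pair_id: str
    mate1: tuple[str, str]  # (sequence, quality)
    mate2: tuple[str, str]

    def __post_init__(self):
        for i, (seq, qual) in enumerate((self.mate1, self.mate2), start=1):
            if not seq:
                raise ValueError(f"pair {self.pair_id}: mate {i} empty")
            if len(seq) != len(qual):
                raise ValueError(f"pair {self.pair_id}: mate {i} sequence/quality length differ")


@dataclass(frozen=True)
class AnchoredMate:
    """A pair with exactly one vector-mapped mate."""

    pair_id: str
    anchored_mate: int  # 1 or 2
    vector_interval: tuple[int, int]  # 0-based half-open on the vector
    vector_segment: str  # "tdna" | "backbone"
    anchor_strand: str
    informative_sequence: str
    informative_orientation: str  # expected FR orientation of the informative mate


@dataclass(frozen=True)
class InsertionCall:
    """A clustered genomic locus supported by vector-anchored mates.

    ``interval`` is 1-based closed. When both orientations support the call the
    interval is narrowed to the gap between the forward-mate cluster's right
    edge and the reverse-mate cluster's left edge — the breakpoint window.
    """

    dest_ref: str
    interval: tuple[int, int]
    support_fwd: int
    support_rev: int

    @property
    def support(self) -> int:
        return self.support_fwd + self.support_rev


def _classify(construct: ConstructMap, interval: tuple[int, int]) -> str:
    mid = (interval[0] + interval[1]) // 2
    tdna = construct.features_by_role("tdna_region")
    if tdna and tdna[0].start <= mid < tdna[0].end:
        return "tdna"
    return "backbone"


def anchor_filter(pairs: Sequence[ReadPair], vector: ConstructMap,
                  min_identity: float = 0.9, min_aligned_frac: float = 0.5,
                  ) -> list[AnchoredMate]:
    """Pairs with exactly one vector-mapped mate; both- and neither-mapped pairs drop."""
    index = ReferenceIndex({VECTOR_REF_NAME: vector.sequence})
    queries = []
    for p in pairs:
        queries.append((f"{p.pair_id}/1", p.mate1[0]))
        queries.append((f"{p.pair_id}/2", p.mate2[0]))
    hits = map_to_reference(queries, index, min_identity, min_aligned_frac)
    out: list[AnchoredMate] = []
    for p in pairs:
        a1 = hits.get(f"{p.pair_id}/1")
        a2 = hits.get(f"{p.pair_id}/2")
        if (a1 is None) == (a2 is None):
            continue  # neither or both mates on vector
        mate_no, aln = (1, a1) if a1 is not None else (2, a2)
        informative = p.mate2[0] if mate_no == 1 else p.mate1[0]
        out.append(AnchoredMate(
            pair_id=p.pair_id,
            anchored_mate=mate_no,
            vector_interval=(aln.ref_start, aln.ref_end),
            vector_segment=_classify(vector, (aln.ref_start, aln.ref_end)),
            anchor_strand=aln.strand,
            informative_sequence=informative,
            informative_orientation="-" if aln.strand == "+" else "+",
        ))
    return out


def provenance_mask(construct: ConstructMap, margin: int = 500,
                    ) -> list[tuple[str, int, int]]:
    """Native genomic loci of the construct's host-derived fragments (1-based
    closed, padded by ``margin``) — the default call-exclusion mask."""
    mask = []
    for frag, _ in construct.provenance:
        if frag.role == "backbone" or frag.source_ref.startswith("synthetic"):
            continue
        lo, hi = frag.source_interval
        mask.append((frag.source_ref, max(1, lo - margin), hi + margin))
    return mask


def _overlaps_mask(ref: str, interval: tuple[int, int],
                   mask: Iterable[tuple[str, int, int]]) -> bool:
    return any(r == ref and interval[0] <= hi and lo <= interval[1]
               for r, lo, hi in mask)


def call_insertions(anchored: Sequence[AnchoredMate], genome: dict[str, str],
                    cluster_gap: int = 700, min_support: int = 3,
                    exclude: Optional[Iterable[tuple[str, int, int]]] = None,
                    min_identity: float = 0.9, min_aligned_frac: float = 0.5,
                    ) -> list[InsertionCall]:
    """Cluster T-DNA-anchored informative mates on the genome into insertion calls.

    Single-linkage clustering on mate start positions with gap <= ``cluster_gap``
    (default ~2x the library insert size); clusters need >= ``min_support`` mates.
    Mates with multiple equally good genome placements are dropped as ambiguous.
    Calls overlapping ``exclude`` intervals (1-based closed) are suppressed.
    """
    tdna = [a for a in anchored if a.vector_segment == "tdna"]
    if not tdna:
        return []
    index = ReferenceIndex(genome)
    hits = map_to_reference(
        [(a.pair_id, a.informative_sequence) for a in tdna],
        index, min_identity, min_aligned_frac)
    placements: list[Alignment] = [
        h for h in hits.values() if h is not None and h.n_best == 1]
    placements.sort(key=lambda h: (h.ref_id, h.ref_start, h.ref_end, h.strand))
    exclude = list(exclude) if exclude is not None else []

    calls: list[InsertionCall] = []
    cluster: list[Alignment] = []

    def _flush():
        if len(cluster) < min_support:
            return
        fwd = [h for h in cluster if h.strand == "+"]
        rev = [h for h in cluster if h.strand == "-"]
        lo = min(h.ref_start for h in cluster) + 1
        hi = max(h.ref_end for h in cluster)
        if fwd and rev:
            bp_lo = max(h.ref_end for h in fwd)       # 1-based last fwd base
            bp_hi = min(h.ref_start for h in rev) + 1  # 1-based first rev base
            if bp_lo <= bp_hi:
                lo, hi = bp_lo, bp_hi
        ref = cluster[0].ref_id
        if not _overlaps_mask(ref, (lo, hi), exclude):
            calls.append(InsertionCall(ref, (lo, hi), len(fwd), len(rev)))

    for h in placements:
        if cluster and (h.ref_id != cluster[-1].ref_id
                        or h.ref_start - cluster[-1].ref_start > cluster_gap):
            _flush()
            cluster = []
        cluster.append(h)
    if cluster:
        _flush()
    calls.sort(key=lambda c: (c.dest_ref, c.interval))
    return calls


def backbone_screen(pairs: Sequence[ReadPair], vector: ConstructMap,
                    min_identity: float = 0.9, min_aligned_frac: float = 0.5) -> int:
    """Number of pairs whose anchor lies in the vector backbone (0 = clean event)."""
    anchored = anchor_filter(pairs, vector, min_identity, min_aligned_frac)
    return sum(1 for a in anchored if a.vector_segment == "backbone")


def write_calls_gff3(path, calls: Sequence[InsertionCall],
                     source: str = "intragene") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(calls, start=1):
            attrs = (f"ID=insertion_{i};support_fwd={c.support_fwd};"
                     f"support_rev={c.support_rev}")
            fh.write("\t".join([
                c.dest_ref, source, "insertion_site", str(c.interval[0]),
                str(c.interval[1]), str(c.support), ".", ".", attrs,
            ]) + "\n")


def read_calls_gff3(path) -> list[InsertionCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            calls.append(InsertionCall(
                dest_ref=cols[0],
                interval=(int(cols[3]), int(cols[4])),
                support_fwd=int(attrs["support_fwd"]),
                support_rev=int(attrs["support_rev"]),
            ))
    return calls
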