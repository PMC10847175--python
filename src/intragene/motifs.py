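"""Degenerate T-DNA border motif scanning and border assembly from sequence pairs.

Agrobacterium T-DNA borders are ~24 bp direct repeats summarised by the degenerate
consensus 5'-GRCAGGATATATNNNNNKGTMAWS-3' (IUPAC codes). Host genomes and transcript
collections contain near-matches to the two conserved halves of this consensus,
5'-GRCAGGATATAT-3' and 5'-KGTMAWS-3', which flank a five-nucleotide spacer. A full
border can therefore be engineered by adjoining a consensus prefix found in one host
sequence to a compatible suffix found in another. This module provides exact
IUPAC-degenerate scanning over FASTA collections and the combinatorial adjoining
search that yields such two-source border candidates.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .seqs import revcomp

#: Concrete base set for every IUPAC nucleotide code (used by expand_motif).
IUPAC_BASES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

#: Base set used when matching a subject sequence. A subject `N` (masked base) is
#: matched only by a pattern `N`, never by an informative pattern code.
_MATCH_BASES: dict[str, str] = {**IUPAC_BASES, "N": "ACGTN"}

#: The 24-bp T-DNA border consensus and its two conserved sub-motifs.
BORDER_CONSENSUS = "GRCAGGATATATNNNNNKGTMAWS"
BORDER_PREFIX_MOTIF = "GRCAGGATATAT"
BORDER_SUFFIX_MOTIF = "KGTMAWS"


@dataclass(frozen=True)
class DegenerateMotif:
    """An IUPAC-coded nucleotide pattern."""

    name: str
    pattern: str

    def __post_init__(self):
        validate_iupac(self.pattern)

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def degeneracy(self) -> int:
        return degeneracy(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    """One window of a subject sequence compatible with a motif.

    Coordinates are 0-based half-open on the forward strand of the subject.
    ``matched`` is the motif-oriented concrete sequence (reverse-complemented for
    minus-strand hits), so it is always compatible with the pattern position by
    position.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    matched: str
    motif_name: str


@dataclass(frozen=True)
class BorderCandidate:
    """A full 24-bp border assembled from parts of one or two source sequences.

    ``junction_offset`` is the position within the 24-mer where the upstream
    source ends and the downstream source begins (None for single-source hits).
    """

    upstream_source: tuple[str, tuple[int, int]]
    downstream_source: Optional[tuple[str, tuple[int, int]]]
    junction_offset: Optional[int]
    assembled: str
    border_side: str = "unassigned"


def validate_iupac(pattern: str) -> None:
    """Reject patterns containing non-IUPAC characters, reporting the first offender."""
    if not pattern:
        raise ValueError("empty motif pattern")
    for i, c in enumerate(pattern):
        if c.upper() not in IUPAC_BASES:
            raise ValueError(f"invalid IUPAC code {c!r} at position {i}")


def degeneracy(pattern: str) -> int:
    validate_iupac(pattern)
    d = 1
    for c in pattern.upper():
        d *= len(IUPAC_BASES[c])
    return d


def expand_motif(motif: DegenerateMotif | str) -> set[str]:
    """All concrete ACGT strings compatible with the pattern.

    The size of the returned set equals the analytic degeneracy product.
    """
    pattern = motif.pattern if isinstance(motif, DegenerateMotif) else motif
    validate_iupac(pattern)
    sets = [IUPAC_BASES[c] for c in pattern.upper()]
    return {"".join(p) for p in itertools.product(*sets)}


def _compiled(pattern: str) -> re.Pattern:
    # Lookahead so overlapping windows are all reported.
    body = "".join(f"[{_MATCH_BASES[c.upper()]}]" for c in pattern)
    return re.compile(f"(?=({body}))")


def matches_pattern(window: str, pattern: str) -> bool:
    """IUPAC compatibility predicate: every subject base in the pattern code's set."""
    if len(window) != len(pattern):
        return False
    return all(b in _MATCH_BASES[c.upper()] for b, c in zip(window.upper(), pattern))


def scan_sequence(seq: str, seq_id: str, motif: DegenerateMotif | str,
                  both_strands: bool = True) -> list[MotifHit]:
    """All windows of ``seq`` compatible with ``motif``, sorted by (start, strand).

    Minus-strand hits are reported in forward-strand coordinates with ``matched``
    reverse-complemented into motif orientation. Overlapping hits are all kept.
    """
    if isinstance(motif, str):
        motif = DegenerateMotif("motif", motif)
    seq = seq.upper()
    hits: list[MotifHit] = []
    m = len(motif.pattern)
    for mo in _compiled(motif.pattern).finditer(seq):
        s = mo.start()
        hits.append(MotifHit(seq_id, s, s + m, "+", seq[s:s + m], motif.name))
    if both_strands:
        for mo in _compiled(revcomp(motif.pattern)).finditer(seq):
            s = mo.start()
            hits.append(MotifHit(seq_id, s, s + m, "-", revcomp(seq[s:s + m]), motif.name))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def assemble_border_candidates(seq_a: tuple[str, str], seq_b: tuple[str, str],
                               consensus: DegenerateMotif | str = BORDER_CONSENSUS,
                               ) -> list[BorderCandidate]:
    """Enumerate borders formed by adjoining a piece of A to a piece of B.

    Every (window-in-A matching a consensus prefix, window-in-B matching the
    complementary suffix, cut point) triple is reported, scanning the forward
    strand of both sources. Candidates are deduplicated on (assembled sequence,
    cut point, source intervals).
    """
    if isinstance(consensus, str):
        consensus = DegenerateMotif("border_consensus", consensus)
    pattern = consensus.pattern
    id_a, a = seq_a[0], seq_a[1].upper()
    id_b, b = seq_b[0], seq_b[1].upper()
    out: dict[tuple, BorderCandidate] = {}
    for offset in range(1, len(pattern)):
        pre, suf = pattern[:offset], pattern[offset:]
        pre_hits = [(mo.start(), mo.start() + offset)
                    for mo in _compiled(pre).finditer(a)]
        if not pre_hits:
            continue
        suf_hits = [(mo.start(), mo.start() + len(suf))
                    for mo in _compiled(suf).finditer(b)]
        for (a0, a1) in pre_hits:
            for (b0, b1) in suf_hits:
                assembled = a[a0:a1] + b[b0:b1]
                key = (assembled, offset, (id_a, a0, a1), (id_b, b0, b1))
                if key not in out:
                    out[key] = BorderCandidate(
                        upstream_source=(id_a, (a0, a1)),
                        downstream_source=(id_b, (b0, b1)),
                        junction_offset=offset,
                        assembled=assembled,
                    )
    return list(out.values())


def find_border_pairs(collection: Sequence[tuple[str, str]] | dict[str, str],
                      consensus: DegenerateMotif | str = BORDER_CONSENSUS,
                      ) -> list[BorderCandidate]:
    """Batch driver: two-source candidates over all ordered sequence pairs, plus
    single-source candidates where one sequence alone contains a full consensus match."""
    if isinstance(consensus, str):
        consensus = DegenerateMotif("border_consensus", consensus)
    items = list(collection.items()) if isinstance(collection, dict) else list(collection)
    out: list[BorderCandidate] = []
    for sid, seq in items:
        for hit in scan_sequence(seq, sid, consensus, both_strands=False):
            out.append(BorderCandidate(
                upstream_source=(sid, (hit.start, hit.end)),
                downstream_source=None,
                junction_offset=None,
                assembled=hit.matched,
            ))
    for (ida, sa), (idb, sb) in itertools.permutations(items, 2):
        out.extend(assemble_border_candidates((ida, sa), (idb, sb), consensus))
    return out


def motif_hits_table(hits: Iterable[MotifHit]):
    """MotifHit list as a DataFrame (1-based closed coordinates for reporting)."""
    import pandas as pd

    return pd.DataFrame(
        [(h.seq_id, h.start + 1, h.end, h.strand, h.matched, h.motif_name) for h in hits],
        columns=["seq_id", "start", "end", "strand", "matched", "motif"],
    )
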