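"""In-silico model of an intragenic binary vector.

A ConstructMap carries the (usually circular) vector sequence, its features
(borders, gene cassette, backbone, T-DNA region) and per-fragment provenance:
which host chromosome interval each piece of the construct was taken from.
On top of it sit three operations used throughout the pipeline:

* restriction-ligation assembly of an insert into a backbone (``digest_and_ligate``),
* exact-match in-silico PCR (``in_silico_pcr``), and
* the micro-translocation table (``translocation_table``), which decomposes a
  transferred construct interval into the host fragments it originated from —
  the tabular equivalent of a translocation Circos plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .seqs import check_dna, revcomp

#: SalI recognition site; cut after position 1 (G^TCGAC, 5' overhang TCGA).
SALI_SITE = "GTCGAC"
_CUT_OFFSET = 1  # cut position within the recognition site


@dataclass(frozen=True)
class SourceFragment:
    """A host-derived piece of the construct with its source coordinates.

    ``source_interval`` is 1-based closed on ``source_ref``; ``sequence`` is the
    fragment as it appears in the construct.
    """

    label: str
    source_ref: str
    source_interval: tuple[int, int]
    sequence: str
    role: str = "other"  # left_border_part | right_border_part | gene | backbone | other

    def __post_init__(self):
        lo, hi = self.source_interval
        if not self.sequence:
            raise ValueError(f"fragment {self.label}: empty sequence")
        if hi - lo + 1 != len(self.sequence):
            raise ValueError(
                f"fragment {self.label}: interval span {hi - lo + 1} != "
                f"sequence length {len(self.sequence)}")


@dataclass(frozen=True)
class Feature:
    """Annotated interval on the construct (0-based half-open, forward strand)."""

    name: str
    start: int
    end: int
    strand: str = "+"
    role: str = "other"


@dataclass
class ConstructMap:
    """Annotated vector sequence with provenance.

    ``provenance`` is an ordered list of (SourceFragment, (start, end)) with the
    interval 0-based half-open on the construct; the intervals must tile the
    construct without overlap when provenance is supplied.
    """

    sequence: str
    is_circular: bool = True
    features: list[Feature] = field(default_factory=list)
    provenance: list[tuple[SourceFragment, tuple[int, int]]] = field(default_factory=list)

    def __post_init__(self):
        check_dna(self.sequence, context="construct sequence")
        n = len(self.sequence)
        for f in self.features:
            if not (0 <= f.start <= f.end <= n):
                raise ValueError(f"feature {f.name} [{f.start},{f.end}) outside construct")
        if self.provenance:
            pos = 0
            for frag, (s, e) in self.provenance:
                if s != pos:
                    raise ValueError(
                        f"provenance does not tile construct: gap/overlap at {s} (expected {pos})")
                if e - s != len(frag.sequence):
                    raise ValueError(f"provenance interval for {frag.label} != fragment length")
                pos = e
            if pos != n:
                raise ValueError("provenance does not cover construct end")
        borders = {r: [f for f in self.features if f.role == r]
                   for r in ("left_border", "right_border", "tdna_region")}
        if borders["tdna_region"]:
            if len(borders["left_border"]) != 1 or len(borders["right_border"]) != 1:
                raise ValueError("an annotated tdna_region requires exactly one left and "
                                 "one right border feature")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, role: str) -> Feature:
        hits = [f for f in self.features if f.role == role]
        if len(hits) != 1:
            raise ValueError(f"expected exactly one {role} feature, found {len(hits)}")
        return hits[0]

    def features_by_role(self, role: str) -> list[Feature]:
        return [f for f in self.features if f.role == role]

    def reverse_complement(self) -> "ConstructMap":
        """The same construct read on the opposite strand.

        Feature intervals are remapped and strands flipped; border roles are
        physical identities and stay attached to the same sequence.
        """
        n = len(self.sequence)
        feats = [Feature(f.name, n - f.end, n - f.start,
                         "-" if f.strand == "+" else "+", f.role)
                 for f in self.features]
        prov = [(replace(frag, sequence=revcomp(frag.sequence)), (n - e, n - s))
                for frag, (s, e) in reversed(self.provenance)]
        return ConstructMap(revcomp(self.sequence), self.is_circular, feats, prov)


@dataclass(frozen=True)
class TranslocationRecord:
    """One host fragment's contribution to a transferred (integrated) interval."""

    source_ref: str
    source_interval: tuple[int, int]  # 1-based closed on the source
    dest_ref: str
    dest_position: int  # 1-based position of this piece's first base at destination
    transferred_length: int

    def __post_init__(self):
        lo, hi = self.source_interval
        if self.transferred_length < 0 or hi - lo + 1 != self.transferred_length:
            raise ValueError("transferred_length must equal the source interval span")


class AssemblyError(ValueError):
    """Restriction-ligation assembly rejected (site count wrong, etc.)."""


def digest_and_ligate(insert_seq: str, backbone_seq: str,
                      site: str = SALI_SITE) -> tuple[ConstructMap, ConstructMap]:
    """Clone a site-flanked insert into a one-site backbone; both orientations.

    The insert must contain exactly two occurrences of the recognition site (its
    flanks); the backbone exactly one (treated as circular and opened there).
    Both ligation junctions regenerate the site. Returns the two possible insert
    orientations as circular ConstructMaps; the caller selects one.
    """
    insert_seq, backbone_seq, site = insert_seq.upper(), backbone_seq.upper(), site.upper()
    check_dna(insert_seq, context="insert")
    check_dna(backbone_seq, context="backbone")
    ins_sites = _find_sites(insert_seq, site, circular=False)
    if len(ins_sites) != 2:
        raise AssemblyError(
            f"insert must be flanked by exactly 2 {site} sites, found {len(ins_sites)}")
    bb_sites = _find_sites(backbone_seq, site, circular=True)
    if len(bb_sites) != 1:
        raise AssemblyError(
            f"backbone must contain exactly 1 {site} site, found {len(bb_sites)}")
    cut_a = ins_sites[0] + _CUT_OFFSET
    cut_b = ins_sites[1] + _CUT_OFFSET
    middle = insert_seq[cut_a:cut_b]  # sticky-end fragment: TCGAC ... G for SalI
    bb_cut = (bb_sites[0] + _CUT_OFFSET) % len(backbone_seq)
    opened = backbone_seq[bb_cut:] + backbone_seq[:bb_cut]
    # flipping the physical fragment keeps the sticky ends in place and
    # reverse-complements only the interior between the half-sites
    k1 = len(site) - _CUT_OFFSET
    flipped = site[_CUT_OFFSET:] + revcomp(middle[k1:len(middle) - _CUT_OFFSET]) \
        + site[:_CUT_OFFSET]

    def _make(mid: str) -> ConstructMap:
        seq = opened + mid
        feats = [
            Feature("backbone", 0, len(opened), "+", "backbone"),
            Feature("insert", len(opened), len(seq), "+", "tdna_insert"),
        ]
        return ConstructMap(seq, is_circular=True, features=feats)

    return _make(middle), _make(flipped)


def digest(construct: ConstructMap | str, site: str = SALI_SITE) -> list[str]:
    """Fragments released by cutting at every site occurrence."""
    seq = construct.sequence if isinstance(construct, ConstructMap) else construct
    circular = construct.is_circular if isinstance(construct, ConstructMap) else False
    seq, site = seq.upper(), site.upper()
    cuts = [(p + _CUT_OFFSET) % len(seq) for p in _find_sites(seq, site, circular)]
    if not cuts:
        return [seq]
    cuts.sort()
    if circular:
        frags = [seq[cuts[i]:cuts[i + 1]] for i in range(len(cuts) - 1)]
        frags.append(seq[cuts[-1]:] + seq[:cuts[0]])
    else:
        edges = [0] + cuts + [len(seq)]
        frags = [seq[edges[i]:edges[i + 1]] for i in range(len(edges) - 1)]
    return [f for f in frags if f]


def _find_sites(seq: str, site: str, circular: bool) -> list[int]:
    search = seq + seq[:len(site) - 1] if circular else seq
    out, i = [], search.find(site)
    while i != -1:
        if i < len(seq):
            out.append(i)
        i = search.find(site, i + 1)
    return out


def in_silico_pcr(template: ConstructMap | str, fwd_primer: str, rev_primer: str,
                  max_len: int = 5000) -> list[tuple[int, tuple[int, int]]]:
    """Exact-match PCR product prediction.

    One product per (forward-primer match on the plus strand, reverse-primer
    binding site downstream within ``max_len``); product length counts both
    primers. Circular templates are scanned across the origin; products are
    reported with 0-based half-open intervals on the given linear representation
    (the end may exceed the template length for origin-spanning products).
    """
    if isinstance(template, ConstructMap):
        seq, circular = template.sequence, template.is_circular
    else:
        seq, circular = template.upper(), False
        check_dna(seq, context="template")
    fwd_primer, rev_primer = fwd_primer.upper(), rev_primer.upper()
    for name, p in (("forward", fwd_primer), ("reverse", rev_primer)):
        if len(p) < 15:
            raise ValueError(f"{name} primer shorter than 15 nt")
        if set(p) - set("ACGT"):
            raise ValueError(f"{name} primer contains degenerate codes "
                             "(exact-match dialect accepts ACGT only)")
    n = len(seq)
    search = seq + seq[:max_len] if circular else seq
    rev_site = revcomp(rev_primer)
    fwd_pos = _all_occurrences(search, fwd_primer)
    rev_pos = _all_occurrences(search, rev_site)
    limit = min(max_len, n) if circular else max_len
    products: list[tuple[int, tuple[int, int]]] = []
    for f in fwd_pos:
        if f >= n:  # duplicate of an origin-wrapped scan
            continue
        for r in rev_pos:
            if r < f:
                continue
            end = r + len(rev_site)
            length = end - f
            if length <= limit:
                products.append((length, (f, end)))
    products.sort(key=lambda p: (p[1][0], p[0]))
    return products


def _all_occurrences(hay: str, needle: str) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def translocation_table(construct: ConstructMap, transferred_interval: tuple[int, int],
                        dest_ref: str, dest_position: int) -> list[TranslocationRecord]:
    """Decompose a transferred construct interval into per-source records.

    ``transferred_interval`` is 0-based half-open on the construct;
    ``dest_position`` is the 1-based position of the interval's first base at the
    destination. Record lengths are clipped to the intersection with each
    provenance fragment and always sum to the interval span.
    """
    s, e = transferred_interval
    if not (0 <= s <= e <= len(construct.sequence)):
        raise ValueError(f"transferred interval [{s},{e}) outside construct "
                         f"[0,{len(construct.sequence)})")
    if not construct.provenance:
        raise ValueError("construct has no provenance to decompose against")
    records: list[TranslocationRecord] = []
    for frag, (fs, fe) in construct.provenance:
        lo, hi = max(s, fs), min(e, fe)
        if lo >= hi:
            continue
        src_lo = frag.source_interval[0] + (lo - fs)
        records.append(TranslocationRecord(
            source_ref=frag.source_ref,
            source_interval=(src_lo, src_lo + (hi - lo) - 1),
            dest_ref=dest_ref,
            dest_position=dest_position + (lo - s),
            transferred_length=hi - lo,
        ))
    return records


def translocation_frame(records: Sequence[TranslocationRecord]):
    """TranslocationRecord list as the standard tabular output."""
    import pandas as pd

    return pd.DataFrame(
        [(r.source_ref, r.source_interval[0], r.source_interval[1],
          r.dest_ref, r.dest_position, r.transferred_length) for r in records],
        columns=["source_ref", "source_start", "source_end",
                 "dest_ref", "dest_pos", "length"],
    )
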