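"""Synthetic study generator: genome, intragenic vector, integration event, reads, progeny.

Every pipeline input can be generated here with full ground truth, so each
downstream stage (border discovery, construct assembly, insertion calling,
junction calling, segregation testing) is testable without external data.
Everything is a pure function of (parameters, seed).

The default event emulates a single-copy intragenic integration: a
multi-chromosome host genome; a circular binary vector whose T-DNA is tiled
from five host fragments (two per border plus an AHAS-like cassette) with
24-bp borders matching the degenerate consensus; integration on chromosome 5
with 3 right-border bases transferred, the left border lost plus 7 bp of
adjacent T-DNA, and a 20 bp target-site deletion; 150 bp read pairs from
~350 bp inserts with substitution errors; and progeny counts drawn from 3:1
(selfed hemizygote) or 1:1 (backcross) single-locus expectations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .construct import (SALI_SITE, ConstructMap, Feature, SourceFragment,
                        digest_and_ligate)
from .insertions import ReadPair
from .motifs import BORDER_CONSENSUS
from .segregation import SegregationRecord
from .seqs import revcomp

#: Concrete border instances used by the default construct; both match the
#: 24-bp degenerate border consensus but differ so left/right parts cannot
#: cross-assemble.
LEFT_BORDER_SEQ = "GGCAGGATATATCAATCTGTCATG"
RIGHT_BORDER_SEQ = "GACAGGATATATTGGCGGGTAAAC"

DEFAULT_CHROM_LENGTHS = {
    "chr2": 6_000, "chr4": 6_000, "chr5": 100_000, "chr19": 6_000, "scaffold": 8_000,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class BorderPartPlan:
    """One host fragment of the construct: where it comes from and which slice
    of a border (if any) is written into it."""

    label: str
    source_ref: str
    start: int          # 1-based start on the source chromosome
    length: int
    role: str
    border_slice: Optional[tuple[int, int]] = None  # slice of the border 24-mer
    border_at: Optional[int] = None                 # offset within the fragment
    border_side: Optional[str] = None               # "left" | "right"


def default_fragment_spec() -> list[BorderPartPlan]:
    """Five host fragments mirroring a realistic intragenic T-DNA tiling:
    two left-border donors, an AHAS-like cassette, and two right-border donors."""
    return [
        BorderPartPlan("LB_donor_a", "chr2", 1001, 32, "left_border_part",
                       (0, 12), 20, "left"),
        BorderPartPlan("LB_donor_b", "chr4", 2001, 84, "left_border_part",
                       (12, 24), 0, "left"),
        BorderPartPlan("AHAS_cassette", "scaffold", 1001, 3386, "gene"),
        BorderPartPlan("RB_donor_a", "chr19", 1501, 56, "right_border_part",
                       (0, 15), 41, "right"),
        BorderPartPlan("RB_donor_b", "chr2", 3001, 29, "right_border_part",
                       (15, 24), 0, "right"),
    ]


@dataclass
class ConstructTruth:
    """Design truth emitted alongside a generated construct."""

    construct: ConstructMap
    genome: dict[str, str]              # host genome with donor loci patched in
    est_collection: dict[str, str]      # EST-like donor sequences for border discovery
    primers: dict[str, tuple[str, str, int]]  # assay -> (fwd, rev, expected bp)
    tdna_interval: tuple[int, int]
    seed: int


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated integration event."""

    genome: dict[str, str]
    construct: ConstructMap
    insertion_site: tuple[str, int]     # (chromosome, 1-based last retained base)
    rb_transferred: int
    lb_truncation: int
    lb_border_retained: int
    deletion_len: int
    microhomology_len: int
    backbone_cointegrated: bool
    transferred_interval: tuple[int, int]
    transferred_length: int
    seed: int
    transferred_segment: str = ""

    def canonical_summary(self):
        """Event geometry after genome-side assignment of chance junction homology.

        When integrated bases adjacent to a junction happen to equal the
        reference bases they replaced, the breakpoint is ambiguous by that many
        positions; the junction caller resolves the ambiguity toward the genome
        side. This returns the IntegrationSummary a perfect caller following
        that convention reports, which differs from the nominal parameters by
        exactly those chance-homology shifts (and equals them when there are
        none).
        """
        from .junctions import IntegrationSummary

        if self.backbone_cointegrated:
            raise ValueError("canonical summary undefined for backbone read-through")
        chrom, pos = self.insertion_site
        ref = self.genome[chrom]
        d = self.deletion_len
        m = self.microhomology_len
        seg = self.transferred_segment[m:]
        a = self.transferred_interval[0] + m
        b = self.transferred_interval[1]
        k_l = 0
        while k_l < len(seg) and pos + k_l < len(ref) and seg[k_l] == ref[pos + k_l]:
            k_l += 1
        k_r = 0
        while (k_r < len(seg) - k_l and pos + d - 1 - k_r >= 0
               and seg[-1 - k_r] == ref[pos + d - 1 - k_r]):
            k_r += 1
        a2, b2 = a + k_l, b - k_r
        lb = self.construct.feature("left_border")
        rb = self.construct.feature("right_border")

        def overlap(f):
            return max(0, min(b2, f.end) - max(a2, f.start))

        lb_ret = overlap(lb)
        if lb_ret:
            lb_trunc = 0
        else:
            lb_trunc = a2 - lb.end if a2 >= lb.end else lb.start - b2
        return IntegrationSummary(
            rb_transferred=overlap(rb), lb_truncation=lb_trunc,
            deletion_len=d - k_l - k_r, transferred_length=b2 - a2,
            lb_border_retained=lb_ret)

    @property
    def canonical_insertion_site(self) -> tuple[str, int]:
        """Insertion site shifted right across any chance homology.

        When the first k integrated bases equal the k reference bases that
        follow the site, the same transformed allele is produced by inserting
        after ``site + k``; breakpoint evidence (read ends) lands on that
        shifted coordinate. Analogous to left-/right-alignment of indels.
        """
        chrom, pos = self.insertion_site
        ref, seg = self.genome[chrom], self.transferred_segment
        k = 0
        while k < len(seg) and pos + k < len(ref) and seg[k] == ref[pos + k]:
            k += 1
        return chrom, pos + k

    def __post_init__(self):
        chrom, pos = self.insertion_site
        if chrom not in self.genome or not (1 <= pos <= len(self.genome[chrom])):
            raise ValueError("insertion site outside genome bounds")
        for name in ("rb_transferred", "lb_truncation", "lb_border_retained",
                     "deletion_len", "microhomology_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def make_genome(lengths: dict[str, int] | Sequence[int] | None = None,
                gc: float = 0.4, seed: int = 0,
                n_chroms: Optional[int] = None) -> dict[str, str]:
    """Random multi-chromosome genome with the requested base composition.

    ``lengths`` maps chromosome names to lengths; a bare sequence of lengths (or
    ``n_chroms`` with a single default length) auto-names chromosomes chr1..chrN.
    """
    if lengths is None:
        lengths = dict(DEFAULT_CHROM_LENGTHS) if n_chroms is None else \
            {f"chr{i + 1}": 100_000 for i in range(n_chroms)}
    if not isinstance(lengths, dict):
        lengths = {f"chr{i + 1}": int(n) for i, n in enumerate(lengths)}
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    for name, n in lengths.items():
        if n <= 0:
            raise ValueError(f"chromosome {name}: non-positive length {n}")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {name: rng.choice(_BASES, size=n, p=p).tobytes().decode()
            for name, n in lengths.items()}


def _patch(genome: dict[str, str], ref: str, pos0: int, piece: str) -> None:
    s = genome[ref]
    genome[ref] = s[:pos0] + piece + s[pos0 + len(piece):]


def build_construct(genome: dict[str, str],
                    fragment_spec: Optional[Sequence[BorderPartPlan]] = None,
                    consensus: str = BORDER_CONSENSUS,
                    seed: int = 0,
                    backbone_len: int = 7998,
                    est_context: int = 60) -> ConstructTruth:
    """Assemble the intragenic vector and patch its donor loci into the genome.

    Border 24-mers (concrete instances of ``consensus``) are written into the
    donor fragments' edges, the corresponding genome loci are patched to match
    (the donors are genuine host loci), restriction sites inside donors are
    scrubbed, and the insert is cloned into a synthetic bacterial backbone by
    in-silico SalI restriction-ligation. The returned truth carries the patched
    genome, an EST-like collection of the donor sequences (for border
    discovery), and diagnostic primer pairs designed across the left-border/
    promoter junction (422 bp product) and within the backbone (210 bp product)
    — synthetic stand-ins for a real vector's diagnostic assay, with the
    conventional 422/210 bp product sizes as the design truth.
    """
    spec = list(fragment_spec) if fragment_spec is not None else default_fragment_spec()
    genome = dict(genome)
    borders = {"left": LEFT_BORDER_SEQ, "right": RIGHT_BORDER_SEQ}
    for plan in spec:
        if plan.source_ref not in genome:
            raise ValueError(f"fragment {plan.label}: unknown source {plan.source_ref}")
        if plan.start < 1 or plan.start - 1 + plan.length > len(genome[plan.source_ref]):
            raise ValueError(f"fragment {plan.label}: interval outside source")
        if plan.border_slice is not None:
            lo, hi = plan.border_slice
            if plan.length < (hi - lo) or plan.border_at + (hi - lo) > plan.length:
                raise ValueError(f"fragment {plan.label}: too short to host its "
                                 "border part")
            piece = borders[plan.border_side][lo:hi]
            _patch(genome, plan.source_ref, plan.start - 1 + plan.border_at, piece)

    # scrub restriction sites from donor loci (and re-check after each edit, since
    # an edit can create a new site); border bases are never touched.
    border_zones = [(p.source_ref, p.start - 1 + p.border_at,
                     p.start - 1 + p.border_at + (p.border_slice[1] - p.border_slice[0]))
                    for p in spec if p.border_slice is not None]

    def _in_border(ref: str, pos: int) -> bool:
        return any(r == ref and a <= pos < b for r, a, b in border_zones)

    changed = True
    while changed:
        changed = False
        for plan in spec:
            s0 = plan.start - 1
            frag = genome[plan.source_ref][s0:s0 + plan.length]
            i = frag.find(SALI_SITE)
            if i >= 0:
                for q in range(i, i + len(SALI_SITE)):
                    if not _in_border(plan.source_ref, s0 + q):
                        base = genome[plan.source_ref][s0 + q]
                        _patch(genome, plan.source_ref, s0 + q,
                               "A" if base != "A" else "G")
                        changed = True
                        break

    fragments = [
        SourceFragment(p.label, p.source_ref, (p.start, p.start + p.length - 1),
                       genome[p.source_ref][p.start - 1:p.start - 1 + p.length], p.role)
        for p in spec
    ]
    core = "".join(f.sequence for f in fragments)
    # cross-fragment boundaries could still spell a site; scrub deterministically
    guard = 0
    while SALI_SITE in core and guard < 50:
        i = core.index(SALI_SITE)
        pos = 0
        done = False
        for fi, f in enumerate(fragments):
            if pos <= i < pos + len(f.sequence) or pos <= i + 5 < pos + len(f.sequence):
                for q in range(max(i, pos), min(i + 6, pos + len(f.sequence))):
                    src_pos = fragments[fi].source_interval[0] - 1 + (q - pos)
                    if not _in_border(f.source_ref, src_pos):
                        base = genome[f.source_ref][src_pos]
                        _patch(genome, f.source_ref, src_pos, "A" if base != "A" else "G")
                        s0 = fragments[fi].source_interval[0] - 1
                        fragments[fi] = SourceFragment(
                            f.label, f.source_ref, f.source_interval,
                            genome[f.source_ref][s0:s0 + len(f.sequence)], f.role)
                        done = True
                        break
            if done:
                break
            pos += len(f.sequence)
        core = "".join(f.sequence for f in fragments)
        guard += 1

    rng = np.random.default_rng(seed)
    if backbone_len:
        backbone = rng.choice(_BASES, size=backbone_len).tobytes().decode()
        while SALI_SITE in backbone:
            backbone = backbone.replace(SALI_SITE, "GACGAC")
        bb_cut_site = min(3000, backbone_len - len(SALI_SITE))
        backbone = (backbone[:bb_cut_site] + SALI_SITE
                    + backbone[bb_cut_site + len(SALI_SITE):])
        insert = SALI_SITE + core + SALI_SITE
        fwd, _rev = digest_and_ligate(insert, backbone, SALI_SITE)
        sequence = fwd.sequence
        opened_len = backbone_len
    else:
        sequence = core
        opened_len = 0

    # feature layout (all offsets relative to the start of the donor core)
    off = opened_len + (5 if backbone_len else 0)  # skip the TCGAC linker
    sizes = [len(f.sequence) for f in fragments]
    cum = np.concatenate([[0], np.cumsum(sizes)])
    lb_plan = [p for p in spec if p.border_side == "left"]
    rb_plan = [p for p in spec if p.border_side == "right"]
    if not lb_plan or not rb_plan:
        raise ValueError("fragment spec must provide left and right border parts")

    def _border_start(plans) -> int:
        p = min(plans, key=lambda q: q.border_slice[0])
        fi = spec.index(p)
        return off + int(cum[fi]) + p.border_at - p.border_slice[0]

    lb0 = _border_start(lb_plan)
    rb0 = _border_start(rb_plan)
    gene_idx = next(i for i, p in enumerate(spec) if p.role == "gene")
    g0 = off + int(cum[gene_idx])
    g1 = off + int(cum[gene_idx + 1])
    features = [
        Feature("left_border", lb0, lb0 + 24, "+", "left_border"),
        Feature("promoter", g0, g0 + 1000, "+", "promoter"),
        Feature("AHAS", g0 + 1000, g1 - 300, "+", "gene"),
        Feature("terminator", g1 - 300, g1, "+", "terminator"),
        Feature("right_border", rb0, rb0 + 24, "+", "right_border"),
        Feature("tdna_region", lb0, rb0 + 24, "+", "tdna_region"),
        Feature("backbone", 0, opened_len, "+", "backbone"),
    ]

    provenance: list[tuple[SourceFragment, tuple[int, int]]] = []
    pos = 0
    if backbone_len:
        opened = sequence[:opened_len]
        provenance.append((SourceFragment("binary_backbone", "synthetic_backbone",
                                          (1, opened_len), opened, "backbone"),
                           (0, opened_len)))
        provenance.append((SourceFragment("sali_linker_a", "synthetic_linker",
                                          (1, 5), "TCGAC", "other"),
                           (opened_len, opened_len + 5)))
        pos = opened_len + 5
    for f in fragments:
        provenance.append((f, (pos, pos + len(f.sequence))))
        pos += len(f.sequence)
    if backbone_len:
        provenance.append((SourceFragment("sali_linker_b", "synthetic_linker",
                                          (1, 1), sequence[pos:pos + 1], "other"),
                           (pos, pos + 1)))

    construct = ConstructMap(sequence, is_circular=True, features=features,
                             provenance=provenance)

    primers: dict[str, tuple[str, str, int]] = {}
    amp = 422  # across the left-border donor / promoter junction
    primers["tdna"] = (sequence[off:off + 20],
                       revcomp(sequence[off + amp - 20:off + amp]), amp)
    if backbone_len:
        primers["backbone"] = (sequence[100:120], revcomp(sequence[290:310]), 210)

    ests = {}
    for p, f in zip(spec, fragments):
        ref = genome[p.source_ref]
        a = max(0, p.start - 1 - est_context)
        b = min(len(ref), p.start - 1 + p.length + est_context)
        ests[f"EST_{p.label}"] = ref[a:b]

    return ConstructTruth(construct=construct, genome=genome, est_collection=ests,
                          primers=primers, tdna_interval=(lb0, rb0 + 24), seed=seed)


def integrate_tdna(genome: dict[str, str], construct: ConstructMap,
                   site: tuple[str, int] = ("chr5", 50_000),
                   rb_transferred: int = 3, lb_truncation: int = 7,
                   lb_border_retained: int = 0, deletion_len: int = 20,
                   microhomology_len: int = 0,
                   backbone_cointegrated: bool = False, backbone_bp: int = 2000,
                   seed: int = 0) -> tuple[dict[str, str], SyntheticTruth]:
    """Insert a (possibly truncated) T-DNA into the genome at ``site``.

    The integrated segment runs from the left-border side to the right-border
    side of the T-DNA region: it begins ``lb_truncation`` bp after the left
    border's inner edge (or inside the border when ``lb_border_retained`` > 0)
    and ends ``rb_transferred`` bp into the right border. ``deletion_len``
    reference bases following ``site`` (the 1-based last retained base) are
    removed. With ``microhomology_len`` m > 0 the m reference bases ending at
    ``site`` are rewritten to equal the segment start and only the remainder
    of the segment is inserted, so the shared tract appears once in the allele
    and is genuinely attributable to either side of the junction. Returns
    (transformed genome, truth); the truth carries the (possibly
    microhomology-patched) reference genome.
    """
    chrom, pos = site
    if chrom not in genome:
        raise ValueError(f"unknown chromosome {chrom}")
    ref = genome[chrom]
    if not (deletion_len <= pos and pos + deletion_len <= len(ref)):
        raise ValueError("site out of bounds (must be >= deletion_len from both ends)")
    if lb_truncation and lb_border_retained:
        raise ValueError("lb_truncation and lb_border_retained are mutually exclusive")
    lb = construct.feature("left_border")
    rb = construct.feature("right_border")
    a = lb.end + lb_truncation - lb_border_retained
    b = rb.start + rb_transferred
    if not (0 <= a < b <= len(construct.sequence)):
        raise ValueError("truncation parameters leave no transferable segment")
    if backbone_cointegrated:
        segment = construct.sequence[a:] + construct.sequence[:backbone_bp]
        b = len(construct.sequence) + backbone_bp
    else:
        segment = construct.sequence[a:b]

    reference = dict(genome)
    m = microhomology_len
    if m:
        if m > pos or m >= len(segment):
            raise ValueError("microhomology longer than flank or segment")
        _patch(reference, chrom, pos - m, segment[:m])
        ref = reference[chrom]
    transformed = dict(reference)
    transformed[chrom] = ref[:pos] + segment[m:] + ref[pos + deletion_len:]

    truth = SyntheticTruth(
        genome=reference, construct=construct, insertion_site=site,
        rb_transferred=rb_transferred, lb_truncation=lb_truncation,
        lb_border_retained=lb_border_retained, deletion_len=deletion_len,
        microhomology_len=microhomology_len,
        backbone_cointegrated=backbone_cointegrated,
        transferred_interval=(a, b), transferred_length=len(segment), seed=seed,
        transferred_segment=segment,
    )
    return transformed, truth


def junction_sequences(transformed: dict[str, str], truth: SyntheticTruth,
                       flank: int = 300) -> dict[str, str]:
    """Extract +/- ``flank`` nt around each integration junction.

    The "left" junction reads genome-then-vector (the left-border-truncated end
    of the segment); the "right" junction reads vector-then-genome (the
    right-border end).
    """
    chrom, pos = truth.insertion_site
    seq = transformed[chrom]
    tl = truth.transferred_length
    if pos - flank < 0 or pos + tl + flank > len(seq):
        raise ValueError("flank extends beyond the transformed chromosome")
    return {
        "left": seq[pos - flank:pos + flank],
        "right": seq[pos + tl - flank:pos + tl + flank],
    }


def simulate_reads(genome: dict[str, str], coverage: float, read_len: int = 150,
                   insert_mean: int = 350, insert_sd: float = 35,
                   error_rate: float = 0.01, seed: int = 0,
                   ) -> tuple[list[ReadPair], list[tuple[str, str, int, int]]]:
    """Paired-end shotgun reads with substitution errors.

    Pair count = round(coverage * genome_len / (2 * read_len)); inserts are
    drawn from a normal truncated below at max(2*read_len - 50, read_len);
    mate 2 is the reverse complement of the fragment end. Returns the pairs and
    the truth placements (pair_id, chromosome, 0-based fragment start, insert).
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if insert_mean < 2 * read_len:
        warnings.warn("insert_mean < 2 x read_len: mates will overlap", stacklevel=2)
    rng = np.random.default_rng(seed)
    names = sorted(genome)
    lens = np.array([len(genome[n]) for n in names], dtype=np.int64)
    total = int(lens.sum())
    n_pairs = int(round(coverage * total / (2 * read_len)))
    min_insert = max(2 * read_len - 50, read_len)
    chrom_idx = rng.choice(len(names), size=n_pairs, p=lens / total)
    inserts = np.maximum(
        np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)), min_insert
    ).astype(np.int64)
    np.minimum(inserts, lens[chrom_idx], out=inserts)
    starts = (rng.random(n_pairs) * (lens[chrom_idx] - inserts + 1)).astype(np.int64)

    qual = "I" * read_len
    pairs: list[ReadPair] = []
    placements: list[tuple[str, str, int, int]] = []
    for i in range(n_pairs):
        name = names[chrom_idx[i]]
        s, ins = int(starts[i]), int(inserts[i])
        frag = genome[name][s:s + ins]
        m1 = _mutate(frag[:read_len], error_rate, rng)
        m2 = _mutate(revcomp(frag[-read_len:]), error_rate, rng)
        pid = f"sim{i}"
        pairs.append(ReadPair(pid, (m1, qual), (m2, qual)))
        placements.append((pid, name, s, ins))
    return pairs, placements


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_progeny(cross: str, n: int, seed: int = 0,
                     line: str = "intragenic-1") -> SegregationRecord:
    """Progeny resistance counts under single dominant locus expectations.

    ``self_het``: hemizygote selfed, resistant ~ Binomial(n, 3/4), tested 3:1;
    ``backcross``: hemizygote x wild type, Binomial(n, 1/2), tested 1:1;
    ``control``: wild type x wild type, all susceptible, untested.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if cross == "self_het":
        r = int(rng.binomial(n, 0.75))
        return SegregationRecord(line, line, r, n - r, (3, 1))
    if cross == "backcross":
        r = int(rng.binomial(n, 0.5))
        return SegregationRecord("Wild-type", line, r, n - r, (1, 1))
    if cross == "control":
        return SegregationRecord("Wild-type", "Wild-type", 0, n, None)
    raise ValueError(f"unknown cross {cross!r} (self_het | backcross | control)")


@dataclass
class EventSim:
    """A fully simulated integration study: references, event, and reads."""

    reference: dict[str, str]
    transformed: dict[str, str]
    construct: ConstructMap
    construct_truth: ConstructTruth
    truth: SyntheticTruth
    pairs: list[ReadPair] = field(default_factory=list)
    placements: list = field(default_factory=list)


def simulate_event(seed: int = 0,
                   chrom_lengths: Optional[dict[str, int]] = None,
                   gc: float = 0.4, coverage: float = 20.0,
                   read_len: int = 150, insert_mean: int = 350,
                   insert_sd: float = 35, error_rate: float = 0.01,
                   site: Optional[tuple[str, int]] = None,
                   rb_transferred: int = 3, lb_truncation: int = 7,
                   lb_border_retained: int = 0, deletion_len: int = 20,
                   microhomology_len: int = 0,
                   backbone_cointegrated: bool = False,
                   wild_type: bool = False,
                   with_reads: bool = True) -> EventSim:
    """One-call study generator: genome -> construct -> integration -> reads.

    ``wild_type`` samples reads from the untransformed reference instead of the
    transformed genome (the event truth is still recorded). Sub-seeds for each
    stage are derived from ``seed``; the whole object is reproducible from it.
    """
    ss = np.random.SeedSequence(seed)
    s_gen, s_con, s_int, s_reads = (int(x) for x in ss.generate_state(4) >> 1)
    genome = make_genome(chrom_lengths or dict(DEFAULT_CHROM_LENGTHS), gc, s_gen)
    ctruth = build_construct(genome, seed=s_con)
    if site is None:
        chrom = "chr5" if "chr5" in ctruth.genome else sorted(ctruth.genome)[0]
        site = (chrom, len(ctruth.genome[chrom]) // 2)
    transformed, truth = integrate_tdna(
        ctruth.genome, ctruth.construct, site,
        rb_transferred=rb_transferred, lb_truncation=lb_truncation,
        lb_border_retained=lb_border_retained, deletion_len=deletion_len,
        microhomology_len=microhomology_len,
        backbone_cointegrated=backbone_cointegrated, seed=s_int)
    sim = EventSim(reference=truth.genome, transformed=transformed,
                   construct=ctruth.construct, construct_truth=ctruth, truth=truth)
    if with_reads:
        source = sim.reference if wild_type else sim.transformed
        sim.pairs, sim.placements = simulate_reads(
            source, coverage, read_len, insert_mean, insert_sd, error_rate, s_reads)
    return sim
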