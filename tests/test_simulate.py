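"""Synthetic-data generator: determinism, composition, bookkeeping, calibration."""

import io
import warnings

import numpy as np
import pytest

from intragene import simulate
from intragene.construct import SALI_SITE
from intragene.motifs import BORDER_CONSENSUS, scan_sequence
from intragene.segregation import chisq_gof
from intragene.seqs import revcomp, write_fastq
from intragene.simulate import (build_construct, integrate_tdna, make_genome,
                                simulate_progeny, simulate_reads)


# ------------------------------------------------------------------ make_genome

def test_genome_deterministic():
    a = make_genome({"c1": 100_000, "c2": 100_000}, gc=0.4, seed=7)
    b = make_genome({"c1": 100_000, "c2": 100_000}, gc=0.4, seed=7)
    assert a == b
    c = make_genome({"c1": 100_000, "c2": 100_000}, gc=0.4, seed=8)
    assert a != c


def test_genome_gc_concentration():
    g = make_genome({"c1": 100_000}, gc=0.5, seed=1)["c1"]
    gc = (g.count("G") + g.count("C")) / len(g)
    assert 0.48 <= gc <= 0.52
    g2 = make_genome({"c1": 50_000}, gc=0.4, seed=2)["c1"]
    gc2 = (g2.count("G") + g2.count("C")) / len(g2)
    assert 0.38 <= gc2 <= 0.42


def test_genome_rejects_bad_lengths():
    with pytest.raises(ValueError, match="non-positive"):
        make_genome({"c1": 0})
    with pytest.raises(ValueError):
        make_genome({"c1": 1000}, gc=1.5)


# -------------------------------------------------------------- build_construct

def test_construct_borders_rescan_as_consensus(event):
    c = event.construct
    hits = scan_sequence(c.sequence, "vec", BORDER_CONSENSUS, both_strands=False)
    starts = {h.start for h in hits}
    lb = c.feature("left_border")
    rb = c.feature("right_border")
    assert lb.start in starts and rb.start in starts
    assert lb.end - lb.start == rb.end - rb.start == 24


def test_construct_deterministic():
    g = make_genome(seed=3)
    a = build_construct(g, seed=4)
    b = build_construct(g, seed=4)
    assert a.construct.sequence == b.construct.sequence
    assert a.genome == b.genome
    assert a.primers == b.primers


def test_construct_restriction_sites_regenerated(event):
    c = event.construct.sequence
    # circular construct carries exactly the two regenerated ligation sites
    assert (c + c[:len(SALI_SITE) - 1]).count(SALI_SITE) == 2


def test_construct_provenance_tiles_and_is_host_derived(event):
    c = event.construct
    pos = 0
    for frag, (s, e) in c.provenance:
        assert s == pos
        assert c.sequence[s:e] == frag.sequence
        pos = e
    assert pos == len(c.sequence)
    genome = event.construct_truth.genome
    for frag, _ in c.provenance:
        if frag.source_ref in genome:  # host-derived fragments match their loci
            lo, hi = frag.source_interval
            assert genome[frag.source_ref][lo - 1:hi] == frag.sequence


def test_construct_without_backbone():
    g = make_genome(seed=9)
    t = build_construct(g, seed=9, backbone_len=0)
    bb = t.construct.feature("backbone")
    assert bb.start == bb.end == 0
    assert "backbone" not in t.primers


def test_construct_rejects_short_border_fragment():
    from intragene.simulate import BorderPartPlan, default_fragment_spec
    g = make_genome(seed=1)
    spec = default_fragment_spec()
    spec[0] = BorderPartPlan("LB_donor_a", "chr2", 1001, 8, "left_border_part",
                             (0, 12), 0, "left")
    with pytest.raises(ValueError, match="too short"):
        build_construct(g, fragment_spec=spec)


# --------------------------------------------------------------- integrate_tdna

def test_integration_length_bookkeeping(event):
    t = event.truth
    chrom = t.insertion_site[0]
    ref_len = len(event.reference[chrom])
    assert len(event.transformed[chrom]) == ref_len - t.deletion_len + t.transferred_length
    assert t.transferred_length == 3495


def test_full_tdna_blunt_insertion_verbatim():
    g = make_genome(seed=11)
    ct = build_construct(g, seed=11)
    tdna = ct.construct.sequence[ct.tdna_interval[0]:ct.tdna_interval[1]]
    transformed, truth = integrate_tdna(
        ct.genome, ct.construct, ("chr5", 40_000), rb_transferred=24,
        lb_truncation=0, lb_border_retained=24, deletion_len=0)
    assert tdna in transformed["chr5"]
    assert truth.transferred_length == len(tdna)


def test_integration_site_bounds_checked(event):
    ct = event.construct_truth
    with pytest.raises(ValueError, match="out of bounds"):
        integrate_tdna(ct.genome, ct.construct, ("chr5", 10))
    with pytest.raises(ValueError, match="unknown chromosome"):
        integrate_tdna(ct.genome, ct.construct, ("chrX", 500))
    with pytest.raises(ValueError, match="mutually exclusive"):
        integrate_tdna(ct.genome, ct.construct, ("chr5", 50_000),
                       lb_truncation=7, lb_border_retained=5)


def test_microhomology_shared_tract_appears_once():
    from intragene.junctions import call_breakpoint

    g = make_genome(seed=13)
    ct = build_construct(g, seed=13)
    transformed, truth = integrate_tdna(ct.genome, ct.construct, ("chr5", 50_000),
                                        microhomology_len=6)
    chrom, pos = truth.insertion_site
    ref = truth.genome[chrom]
    seg = truth.transferred_segment
    # the flank end replicates the segment start, and only the remainder of the
    # segment is inserted after it
    assert ref[pos - 6:pos] == seg[:6]
    assert transformed[chrom][pos:pos + 20] == seg[6:26]
    junction = transformed[chrom][pos - 300:pos + 300]
    call = call_breakpoint(junction, ref, ct.construct.sequence, "left", chrom)
    assert call.microhomology_len >= 6
    assert call.genome_breakpoint == pos  # homology assigned to the genome side


# --------------------------------------------------------------- simulate_reads

def test_read_pair_count_formula():
    g = make_genome({"c1": 100_000}, seed=1)
    pairs, _ = simulate_reads(g, coverage=20, read_len=150, seed=1)
    assert len(pairs) == round(20 * 100_000 / (2 * 150))  # 6667


def test_error_free_reads_are_genome_substrings():
    g = make_genome({"c1": 30_000}, seed=2)
    pairs, placements = simulate_reads(g, coverage=3, error_rate=0.0, seed=2)
    seq = g["c1"]
    for p, (pid, chrom, start, ins) in zip(pairs, placements):
        assert p.mate1[0] == seq[start:start + 150]
        assert p.mate2[0] == revcomp(seq[start + ins - 150:start + ins])


def test_fastq_byte_identical_for_same_seed():
    g = make_genome({"c1": 20_000}, seed=3)

    def dump(seed):
        pairs, _ = simulate_reads(g, coverage=2, seed=seed)
        buf = io.StringIO()
        for p in pairs:
            buf.write(f"@{p.pair_id}\n{p.mate1[0]}\n+\n{p.mate1[1]}\n")
        return buf.getvalue()

    assert dump(5) == dump(5)
    assert dump(5) != dump(6)


def test_reads_reject_bad_coverage_and_warn_on_overlap():
    g = make_genome({"c1": 10_000}, seed=4)
    with pytest.raises(ValueError, match="coverage"):
        simulate_reads(g, coverage=0)
    with pytest.warns(UserWarning, match="overlap"):
        simulate_reads(g, coverage=1, insert_mean=200, read_len=150, seed=4)


# ------------------------------------------------------------- simulate_progeny

def test_progeny_control_all_susceptible():
    rec = simulate_progeny("control", 188, seed=1)
    assert (rec.n_resistant, rec.n_susceptible) == (0, 188)
    assert rec.expected_ratio is None


def test_progeny_selfing_fraction_concentrates():
    rec = simulate_progeny("self_het", 10_000, seed=2)
    assert 0.73 <= rec.n_resistant / rec.total <= 0.77
    assert rec.expected_ratio == (3, 1)


def test_progeny_backcross_ratio():
    rec = simulate_progeny("backcross", 10_000, seed=3)
    assert 0.48 <= rec.n_resistant / rec.total <= 0.52
    assert rec.expected_ratio == (1, 1)


def test_progeny_errors():
    with pytest.raises(ValueError, match="n must be"):
        simulate_progeny("self_het", 0)
    with pytest.raises(ValueError, match="unknown cross"):
        simulate_progeny("outcross", 10)


def test_chisq_calibration_on_null_progeny():
    """Under true 3:1 segregation the test should reject ~5% of the time."""
    n_reps, n_progeny, alpha = 1000, 100, 0.05
    rejections = 0
    for seed in range(n_reps):
        rec = simulate_progeny("self_het", n_progeny, seed=seed)
        _, _, p = chisq_gof(rec)
        rejections += p < alpha
    assert 0.03 <= rejections / n_reps <= 0.07


# ------------------------------------------------------------------ full events

def test_event_fully_deterministic():
    a = simulate.simulate_event(seed=21, coverage=2)
    b = simulate.simulate_event(seed=21, coverage=2)
    assert a.construct.sequence == b.construct.sequence
    assert a.transformed == b.transformed
    assert [(p.pair_id, p.mate1, p.mate2) for p in a.pairs] == \
        [(p.pair_id, p.mate1, p.mate2) for p in b.pairs]
    assert a.truth.transferred_interval == b.truth.transferred_interval
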