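"""Breakpoint calling and integration-summary geometry."""

import numpy as np
import pytest

from intragene import simulate
from intragene.junctions import (AmbiguousJunctionError, NoJunctionError,
                                 call_breakpoint, summarize_integration)
from intragene.simulate import junction_sequences
from intragene.seqs import revcomp


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


# -------------------------------------------------------------- call_breakpoint

def test_constructed_junction_exact_breakpoints():
    rng = np.random.default_rng(0)
    genome = _rand(rng, 1000)
    vector = _rand(rng, 1200)
    junction = genome[0:200] + vector[500:700]
    call = call_breakpoint(junction, genome, vector, side="left")
    assert call.genome_first
    assert call.genome_breakpoint == 200   # 1-based last retained base
    assert call.vector_breakpoint == 500   # 0-based start of integrated sequence
    assert call.microhomology_len == 0 or call.microhomology_len <= 2  # chance only
    assert call.filler == ""


def test_vector_first_layout_autodetected():
    rng = np.random.default_rng(1)
    genome = _rand(rng, 900)
    vector = _rand(rng, 900)
    junction = vector[100:280] + genome[600:800]
    call = call_breakpoint(junction, genome, vector, side="right")
    assert not call.genome_first
    assert call.genome_breakpoint == 601   # first retained base after the insert
    assert call.vector_breakpoint == 280   # integrated sequence ends here


def test_all_genomic_junction_is_no_junction():
    rng = np.random.default_rng(2)
    genome = _rand(rng, 800)
    vector = _rand(rng, 800)
    with pytest.raises(NoJunctionError):
        call_breakpoint(genome[100:500], genome, vector)
    with pytest.raises(NoJunctionError):
        call_breakpoint(vector[100:500], genome, vector)


def test_unrelated_sequence_is_ambiguous_not_no_junction():
    rng = np.random.default_rng(3)
    genome = _rand(rng, 800)
    vector = _rand(rng, 800)
    foreign = _rand(rng, 400)
    with pytest.raises((AmbiguousJunctionError, NoJunctionError)) as exc:
        call_breakpoint(foreign, genome, vector)
    # a sequence matching neither reference must not be reported as "all one side"
    assert exc.type is AmbiguousJunctionError


def test_short_junction_rejected():
    with pytest.raises(NoJunctionError, match="shorter"):
        call_breakpoint("ACGT" * 5, "ACGT" * 100, "TTAA" * 100)


def test_microhomology_assigned_to_genome_side():
    rng = np.random.default_rng(4)
    genome = _rand(rng, 600)
    vector = _rand(rng, 600)
    homology = "ACGTA"  # 5 bp shared by the flank end and the vector bases
    genome_mod = genome[:195] + homology + genome[200:]
    vector_mod = vector[:300] + homology + vector[305:]
    # the shared tract appears once in the junction (switch anywhere within it
    # yields the same sequence)
    junction = genome_mod[50:200] + vector_mod[305:450]
    call = call_breakpoint(junction, genome_mod, vector_mod, side="left")
    assert call.microhomology_len >= 5
    # genome side keeps the shared bases: breakpoint at/after the homology end
    assert call.genome_breakpoint == 200
    assert call.vector_breakpoint == 305


def test_filler_reported_and_exclusive():
    rng = np.random.default_rng(5)
    genome = _rand(rng, 600)
    vector = _rand(rng, 600)
    filler = "TTTTT"
    junction = genome[100:260] + filler + vector[300:460]
    call = call_breakpoint(junction, genome, vector, side="left")
    if call.filler:  # filler bases may by chance extend a reference match
        assert call.microhomology_len == 0
        assert set(call.filler) == {"T"}
        # conservation: genome extension + reported filler + vector extension
        # account for exactly the five inserted bases
        g_ext = call.genome_breakpoint - 260
        v_ext = 300 - call.vector_breakpoint
        assert g_ext >= 0 and v_ext >= 0
        assert g_ext + len(call.filler) + v_ext == 5


# ------------------------------------------------ exhaustive oracle equivalence

from _oracles import oracle_split  # noqa: E402  (independent brute-force scorer)


@pytest.mark.parametrize("seed", range(12))
def test_caller_equals_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    genome = _rand(rng, 320)
    vector = _rand(rng, 320)
    micro = int(rng.integers(0, 9))
    filler = _rand(rng, int(rng.integers(0, 6))) if micro == 0 else ""
    g_end = int(rng.integers(60, 120))
    v_start = int(rng.integers(60, 180))
    if micro:
        # vector bases just before v_start replicate the genome flank end, so
        # the switch is ambiguous over `micro` positions
        shared = genome[g_end - micro:g_end]
        vector = vector[:v_start - micro] + shared + vector[v_start:]
    junction = genome[g_end - 60:g_end] + filler + vector[v_start:v_start + 60]
    call = call_breakpoint(junction, genome, vector, side="left")
    M, s_star = oracle_split(junction, genome, vector, genome_is_prefix=True)
    assert call.genome_first
    assert call.score == M
    # oracle split position equals the caller's (breakpoint before filler trim)
    assert call.genome_breakpoint <= s_star + (g_end - 60)
    assert call.genome_breakpoint + len(call.filler) + call.microhomology_len >= g_end


@pytest.mark.parametrize("seed", range(6))
def test_error_free_random_truths_recovered(seed):
    rng = np.random.default_rng(100 + seed)
    genome = _rand(rng, 500)
    vector = _rand(rng, 500)
    g_end = int(rng.integers(100, 400))
    v_start = int(rng.integers(50, 300))
    junction = genome[g_end - 80:g_end] + vector[v_start:v_start + 80]
    call = call_breakpoint(junction, genome, vector, side="left")
    # exact recovery modulo chance microhomology at the switch
    m = call.microhomology_len
    assert g_end <= call.genome_breakpoint <= g_end + m
    assert v_start <= call.vector_breakpoint <= v_start + m


# --------------------------------------------------------- summarize_integration

def test_summary_recovers_default_truth(clean_event):
    sim = clean_event
    juncs = junction_sequences(sim.transformed, sim.truth)
    chrom = sim.truth.insertion_site[0]
    left = call_breakpoint(juncs["left"], sim.reference[chrom],
                           sim.construct.sequence, "left", chrom)
    right = call_breakpoint(juncs["right"], sim.reference[chrom],
                            sim.construct.sequence, "right", chrom)
    s = summarize_integration(left, right, sim.construct)
    assert (s.rb_transferred, s.lb_truncation, s.deletion_len) == (3, 7, 20)
    assert s.transferred_length == sim.truth.transferred_length == 3495
    assert s.lb_border_retained == 0


def test_summary_blunt_full_tdna():
    sim = simulate.simulate_event(seed=3, with_reads=False, error_rate=0.0,
                                  rb_transferred=24, lb_truncation=0,
                                  lb_border_retained=24, deletion_len=0)
    juncs = junction_sequences(sim.transformed, sim.truth)
    chrom = sim.truth.insertion_site[0]
    left = call_breakpoint(juncs["left"], sim.reference[chrom],
                           sim.construct.sequence, "left", chrom)
    right = call_breakpoint(juncs["right"], sim.reference[chrom],
                            sim.construct.sequence, "right", chrom)
    s = summarize_integration(left, right, sim.construct)
    assert s.rb_transferred == 24
    assert s.lb_border_retained == 24
    assert s.lb_truncation == 0
    assert s.deletion_len == 0
    lb, rb = sim.construct.feature("left_border"), sim.construct.feature("right_border")
    assert s.transferred_length == rb.end - lb.start  # complete T-DNA region


SMALL_GENOME = {"chr2": 6000, "chr4": 6000, "chr5": 20_000, "chr19": 6000,
                "scaffold": 8000}


@pytest.mark.parametrize("seed", range(10))
def test_randomized_truths_recovered(seed):
    rng = np.random.default_rng(200 + seed)
    sim = simulate.simulate_event(
        seed=300 + seed, with_reads=False, error_rate=0.0,
        chrom_lengths=SMALL_GENOME,
        rb_transferred=int(rng.integers(1, 25)),
        lb_truncation=int(rng.integers(0, 40)),
        deletion_len=int(rng.integers(10, 60)))
    juncs = junction_sequences(sim.transformed, sim.truth)
    chrom = sim.truth.insertion_site[0]
    left = call_breakpoint(juncs["left"], sim.reference[chrom],
                           sim.construct.sequence, "left", chrom)
    right = call_breakpoint(juncs["right"], sim.reference[chrom],
                            sim.construct.sequence, "right", chrom)
    s = summarize_integration(left, right, sim.construct)
    # exact recovery of the canonical geometry (chance homology at a junction
    # is resolved to the genome side by both the caller and the truth)
    c = sim.truth.canonical_summary()
    assert (s.rb_transferred, s.lb_truncation, s.deletion_len,
            s.transferred_length, s.lb_border_retained) == \
        (c.rb_transferred, c.lb_truncation, c.deletion_len,
         c.transferred_length, c.lb_border_retained)
    t = sim.truth
    if left.microhomology_len == right.microhomology_len == 0:
        assert (s.rb_transferred, s.lb_truncation, s.deletion_len) == \
            (t.rb_transferred, t.lb_truncation, t.deletion_len)


def test_summary_symmetry_under_reverse_complement(clean_event):
    sim = clean_event
    juncs = junction_sequences(sim.transformed, sim.truth)
    chrom = sim.truth.insertion_site[0]
    gen = sim.reference[chrom]
    left = call_breakpoint(juncs["left"], gen, sim.construct.sequence, "left", chrom)
    right = call_breakpoint(juncs["right"], gen, sim.construct.sequence, "right", chrom)
    s = summarize_integration(left, right, sim.construct)

    rc_construct = sim.construct.reverse_complement()
    rc_gen = revcomp(gen)
    rc_left = call_breakpoint(revcomp(juncs["right"]), rc_gen,
                              rc_construct.sequence, "left", chrom)
    rc_right = call_breakpoint(revcomp(juncs["left"]), rc_gen,
                               rc_construct.sequence, "right", chrom)
    s_rc = summarize_integration(rc_left, rc_right, rc_construct)
    assert (s_rc.rb_transferred, s_rc.lb_truncation, s_rc.deletion_len,
            s_rc.transferred_length) == \
        (s.rb_transferred, s.lb_truncation, s.deletion_len, s.transferred_length)


def test_summary_rejects_mismatched_references(clean_event):
    sim = clean_event
    juncs = junction_sequences(sim.transformed, sim.truth)
    chrom = sim.truth.insertion_site[0]
    left = call_breakpoint(juncs["left"], sim.reference[chrom],
                           sim.construct.sequence, "left", chrom)
    right = call_breakpoint(juncs["right"], sim.reference[chrom],
                            sim.construct.sequence, "right", "other_chrom")
    with pytest.raises(ValueError, match="different genome references"):
        summarize_integration(left, right, sim.construct)
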