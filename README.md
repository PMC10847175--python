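# intragene

Analysis toolkit for **intragenic plant transformation** — *Agrobacterium*-mediated
gene transfer in which the entire T-DNA (borders, promoter, gene, terminator) is
assembled from the host species' own genome, so the transformed plant carries no
foreign DNA. A successful intragenic event is genetically equivalent to a
micro-translocation: a few host fragments relocated to a new chromosomal site.

The package implements the full desk-scale computational workflow around a
single-copy intragenic integration event, for researchers designing intragenic
vectors or characterising transformed lines:

1. **Border discovery** (`intragene.motifs`) — exact IUPAC-degenerate scanning of
   sequence collections (ESTs, genomes) for the 24-bp T-DNA border consensus
   `5'-GRCAGGATATATNNNNNKGTMAWS-3'` and enumeration of full borders formed by
   adjoining a consensus prefix from one host sequence to a compatible suffix
   from another.
2. **Construct modelling** (`intragene.construct`) — an annotated circular vector
   with per-fragment host provenance; in-silico SalI restriction-ligation
   assembly, exact-match in-silico PCR, and the micro-translocation table
   decomposing a transferred interval into its donor fragments.
3. **Insertion-site calling** (`intragene.insertions` + `intragene.mapping`) —
   the two-step discordant-pair strategy: keep read pairs with exactly one mate
   mapping to the vector, classify the anchor as T-DNA or bacterial backbone,
   map the other mate to the host genome and cluster into strand-partitioned
   insertion calls. The backbone-anchored count doubles as the vector-backbone
   integration screen.
4. **Junction characterisation** (`intragene.junctions`) — single-switch
   breakpoint calling on junction amplicons by exhaustive split scoring, with
   microhomology and non-templated filler; two junction calls combine into the
   event geometry: right-border bases transferred, truncation short of the left
   border, target-site deletion, total transferred length.
5. **Segregation statistics** (`intragene.segregation`) — Pearson chi-square
   goodness-of-fit (1 df, no continuity correction) of progeny resistance
   counts against 3:1 (selfed hemizygote) and 1:1 (backcross) single-locus
   expectations.
6. **Synthetic data** (`intragene.simulate`) — a generator producing every
   pipeline input with ground truth: multi-chromosome genome, host-derived
   vector, truncated integration with target-site deletion, paired-end reads
   with substitution errors, and binomially sampled progeny counts.

## Worked example

Simulate a complete study and run the analysis back over it:

```python
from intragene import simulate
from intragene.insertions import anchor_filter, call_insertions, \
    provenance_mask, backbone_screen
from intragene.junctions import call_breakpoint, summarize_integration
from intragene.simulate import junction_sequences

sim = simulate.simulate_event(seed=1)          # genome -> vector -> event -> reads

anchored = anchor_filter(sim.pairs, sim.construct)
calls = call_insertions(anchored, sim.reference,
                        exclude=provenance_mask(sim.construct))
for c in calls:
    print(f"insertion: {c.dest_ref}:{c.interval[0]}-{c.interval[1]} "
          f"support +{c.support_fwd}/-{c.support_rev}")
print("backbone-anchored pairs:", backbone_screen(sim.pairs, sim.construct))

j = junction_sequences(sim.transformed, sim.truth)
left = call_breakpoint(j["left"], sim.reference["chr5"],
                       sim.construct.sequence, "left", "chr5")
right = call_breakpoint(j["right"], sim.reference["chr5"],
                        sim.construct.sequence, "right", "chr5")
s = summarize_integration(left, right, sim.construct)
print(f"rb_transferred={s.rb_transferred} lb_truncation={s.lb_truncation} "
      f"deletion={s.deletion_len} transferred={s.transferred_length}")
```

prints

```
insertion: chr5:50000-50021 support +17/-17
backbone-anchored pairs: 0
rb_transferred=3 lb_truncation=7 deletion=20 transferred=3495
```

The single call sits exactly on the simulated integration site (the interval is
the breakpoint window between the forward- and reverse-oriented read clusters),
no read pair anchors to the bacterial backbone (a "clean" event), and the
junction caller recovers the event geometry exactly: only the first 3 bases of
the right border transferred, the integrated sequence ends 7 bp short of the
left border, and 20 bp of the target site were deleted — 3495 bp of host DNA
moved to chromosome 5.

Segregation testing of progeny counts:

```python
from intragene.segregation import EXAMPLE_PROGENY_TABLE, records_frame
print(records_frame(EXAMPLE_PROGENY_TABLE).head(4).to_string(index=False))
```

```
ovule_parent pollen_parent  n_resistant  n_susceptible ratio     chi2        p    verdict
    021401-1      021401-1           54             15   3:1 0.391304 0.531615 consistent
    021401-4      021401-4           67             18   3:1 0.662745 0.415592 consistent
    021401-4      021401-4           74             23   3:1 0.085911 0.769442 consistent
   Wild-type      021401-1           28             26   1:1 0.074074 0.785495 consistent
```

Every testable cross is consistent with a single dominant resistance locus.

A `click` CLI mirrors the library (`intragene scan-borders`, `assemble`, `pcr`,
`call-insertions`, `call-junctions`, `segregation`, `simulate ...`).

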