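"""Independent brute-force oracles shared by the unit and acceptance tests.

These re-derive expected results directly from definitions with explicit
loops; they share no code path with the implementations they check.
"""


def oracle_split(junction, pre_ref, suf_ref, genome_is_prefix, min_segment=20):
    """Exhaustive single-switch scorer over every split x every window.

    Score of a split = best gapless match count of the 5' part over all
    pre_ref windows plus the same for the 3' part over suf_ref. Conventions
    mirror the caller's contract: homology ties resolve to the genome side
    (maximal split when the genome is the 5' part, minimal otherwise).
    Returns (max score, chosen split).
    """
    L = len(junction)
    best_pre = [0] * (L + 1)
    for o in range(len(pre_ref)):
        c = 0
        for i in range(min(L, len(pre_ref) - o)):
            if junction[i] == pre_ref[o + i]:
                c += 1
            if c > best_pre[i + 1]:
                best_pre[i + 1] = c
    best_suf = [0] * (L + 1)  # best_suf[t]: suffix of length t
    rj = junction[::-1]
    rr = suf_ref[::-1]
    for o in range(len(rr)):
        c = 0
        for i in range(min(L, len(rr) - o)):
            if rj[i] == rr[o + i]:
                c += 1
            if c > best_suf[i + 1]:
                best_suf[i + 1] = c
    scores = {s: best_pre[s] + best_suf[L - s]
              for s in range(min_segment, L - min_segment + 1)}
    m = max(scores.values())
    ties = [s for s, v in scores.items() if v == m]
    return m, (max(ties) if genome_is_prefix else min(ties))


def oracle_scan(seq, pattern, match_bases, both_strands, revcomp):
    """Window-by-window IUPAC scan: every offset tested against the code sets."""
    out = []
    m = len(pattern)
    for s in range(len(seq) - m + 1):
        win = seq[s:s + m]
        if all(b in match_bases[c] for b, c in zip(win, pattern)):
            out.append((s, "+"))
        if both_strands:
            rc = revcomp(win)
            if all(b in match_bases[c] for b, c in zip(rc, pattern)):
                out.append((s, "-"))
    return sorted(out)
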