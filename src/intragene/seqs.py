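"""Small shared sequence helpers (alphabet checks, reverse complement, FASTA/FASTQ I/O)."""

from __future__ import annotations

from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def revcomp(seq: str) -> str:
    """Reverse complement; IUPAC degeneracy codes are complemented correctly."""
    return seq.translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, *, context: str = "sequence") -> None:
    bad = set(seq.upper()) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{context} contains non-ACGTN characters: {sorted(bad)}")


def read_fasta(path) -> dict[str, str]:
    """Read a (multi-)FASTA into an ordered {id: uppercase sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, seqs: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(path, reads: Iterable[tuple[str, str, str]]) -> None:
    """Write (name, sequence, quality) triples as plain FASTQ."""
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq).upper(), qual))
    return out
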