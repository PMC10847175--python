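"""Minimal flat GFF3 reading/writing for construct features and insertion calls.

Only the subset of GFF3 this package emits is handled: one feature per line,
``key=value`` attributes, no hierarchy. Feature coordinates convert between the
package's internal 0-based half-open intervals and GFF3's 1-based closed ones.
"""

from __future__ import annotations

from urllib.parse import quote, unquote

from .construct import ConstructMap, Feature


def write_features_gff3(path, seq_id: str, features: list[Feature],
                        source: str = "intragene") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={quote(f.name)};role={quote(f.role)}"
            fh.write("\t".join([
                seq_id, source, "region", str(f.start + 1), str(f.end),
                ".", f.strand, ".", attrs,
            ]) + "\n")


def read_features_gff3(path) -> tuple[str, list[Feature]]:
    seq_id, feats = "", []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            seq_id = cols[0]
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            feats.append(Feature(
                name=unquote(attrs.get("ID", "")),
                start=int(cols[3]) - 1,
                end=int(cols[4]),
                strand=cols[6],
                role=unquote(attrs.get("role", "other")),
            ))
    return seq_id, feats


def load_construct(fasta_path, gff3_path) -> ConstructMap:
    """Assemble a ConstructMap from its FASTA + GFF3 representation (no provenance)."""
    from .seqs import read_fasta

    seqs = read_fasta(fasta_path)
    if len(seqs) != 1:
        raise ValueError("construct FASTA must contain exactly one sequence")
    (name, seq), = seqs.items()
    gff_id, feats = read_features_gff3(gff3_path)
    if gff_id and gff_id != name:
        raise ValueError(f"GFF3 seq id {gff_id!r} does not match FASTA id {name!r}")
    return ConstructMap(seq, is_circular=True, features=feats)
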