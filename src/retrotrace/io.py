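"""Small format helpers shared by the workflow stages."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

from .models import TEModel


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> ordered {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_te_library(te_models: dict[str, TEModel], path) -> None:
    """TE query library FASTA with separate LTR and internal records."""
    records = {}
    for name in sorted(te_models):
        te = te_models[name]
        records[te.ltr_query] = te.ltr_seq
        records[te.internal_query] = te.internal_seq
    write_fasta(records, path)


def read_te_library(path) -> dict[str, TEModel]:
    """Reassemble TEModels from a library FASTA of *_LTR / *_I records."""
    seqs = read_fasta(path)
    names = {rid.rsplit("_", 1)[0] for rid in seqs}
    out = {}
    for name in sorted(names):
        ltr, internal = seqs.get(f"{name}_LTR"), seqs.get(f"{name}_I")
        if ltr is None or internal is None:
            raise ValueError(f"library lacks paired LTR/internal records for {name!r}")
        out[name] = TEModel(name=name, ltr_seq=ltr, internal_seq=internal)
    return out
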