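"""File-format helpers: FASTA, membership maps and TSV matrices."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import ProteinRecord


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seq_records, str(path), "fasta-2line")


def read_membership(path: str | Path) -> pd.DataFrame:
    """Read a protein membership TSV: protein_id, group_id, phage_ids (';')."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id", "group_id", "phage_ids"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"membership table missing columns: {sorted(missing)}")
    return df


def load_proteins(fasta_path: str | Path, membership_path: str | Path | None = None
                  ) -> list[ProteinRecord]:
    """Combine a protein FASTA with an optional membership table.

    Without a membership table every protein is its own cluster with a
    single-phage membership named after itself.
    """
    seqs = read_fasta(fasta_path)
    if membership_path is None:
        return [ProteinRecord(pid, seq, group_id=pid, phage_ids=frozenset({pid}))
                for pid, seq in seqs]
    mem = read_membership(membership_path).set_index("protein_id")
    records = []
    for pid, seq in seqs:
        if pid not in mem.index:
            raise ValueError(f"protein {pid} missing from the membership table")
        row = mem.loc[pid]
        phages = frozenset(x for x in str(row["phage_ids"]).split(";") if x)
        records.append(ProteinRecord(pid, seq, group_id=str(row["group_id"]),
                                     phage_ids=phages))
    return records


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a peptide x sample TSV matrix (first column = peptide id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")
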