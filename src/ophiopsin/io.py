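"""File-format surface: FASTA in/out, tabular reports, tree serialisation.

FASTA records keep their ids verbatim up to the first whitespace; sequences
are written wrapped at 60 columns.  Tables are plain TSV with a header line.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqcore import NucleotideSequence, ProteinSequence

WRAP = 60


def read_nucleotide_fasta(path: str | os.PathLike) -> list[NucleotideSequence]:
    return [
        NucleotideSequence(id=rec.id, seq=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_protein_fasta(path: str | os.PathLike) -> list[ProteinSequence]:
    return [
        ProteinSequence(id=rec.id, seq=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[NucleotideSequence | ProteinSequence],
                path: str | os.PathLike) -> None:
    seqs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=WRAP)
        writer.write_file(seqs)


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gff3(rows: Sequence[dict], path: str | os.PathLike) -> None:
    """Write candidate loci as GFF3 (1-based inclusive coordinates).

    Each row needs: seqid, start, end, strand, id plus optional attrs.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in rows:
            attrs = f"ID={r['id']}"
            for k in ("name", "best_reference"):
                if r.get(k):
                    attrs += f";{k}={r[k]}"
            fh.write(
                "\t".join(
                    [
                        str(r["seqid"]), "ophiopsin", "opsin_candidate",
                        str(r["start"]), str(r["end"]),
                        f"{r.get('score', '.')}", r["strand"], ".", attrs,
                    ]
                )
                + "\n"
            )
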