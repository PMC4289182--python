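"""Transcript-to-gene expression matching.

A transcript supports a gene when its best translated local alignment against
the gene's predicted protein is near-perfect: identity strictly above 99.9%
over at least 30 aligned residues.  At the short alignment windows typical of
partial transcripts this effectively demands a perfect protein-level match
(one mismatch in a 33-residue window is ~97%).  The flag means "detected in
the transcript set", not "expressed in vivo": absence may reflect sequencing
depth rather than true silence.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .mining import OpsinCandidate
from .seqcore import (
    InputError,
    NucleotideSequence,
    ProteinSequence,
    ScoringScheme,
    local_align,
    percent_identity_and_similarity,
    translate_six_frames,
)


@dataclass(frozen=True)
class ExpressionConfig:
    min_identity: float = 99.9  # percent, strict inequality
    min_aligned_len: int = 30  # residues

    def __post_init__(self):
        if not 0 < self.min_identity <= 100:
            raise InputError("min_identity must be in (0, 100]")
        if self.min_aligned_len < 1:
            raise InputError("min_aligned_len must be >= 1")


@dataclass(frozen=True)
class ExpressionCall:
    gene_name: str
    transcript_id: str | None
    identity: float | None
    aligned_len: int
    expressed: bool


def match_transcripts(
    transcripts: list[NucleotideSequence],
    genes: list[OpsinCandidate],
    cfg: ExpressionConfig | None = None,
    sc: ScoringScheme | None = None,
) -> list[ExpressionCall]:
    """Best translated match per gene across all transcripts and frames.

    Every transcript is translated in six frames; the highest-scoring local
    alignment against each gene protein is retained, and the gene's expressed
    flag follows the identity/length rule of the config.
    """
    cfg = cfg or ExpressionConfig()
    sc = sc or ScoringScheme()
    frames: list[tuple[str, ProteinSequence]] = []
    for t in transcripts:
        if len(t) < 3:
            continue
        for fp in translate_six_frames(t):
            frames.append((t.id, fp))
    calls: list[ExpressionCall] = []
    for gene in genes:
        best = None  # (score, identity, aligned_len, transcript_id)
        for tid, fp in frames:
            aln = local_align(fp, gene.merged_protein, sc)
            if aln.n_columns == 0:
                continue
            identity, _ = percent_identity_and_similarity(aln, sc)
            key = (aln.score, identity, aln.n_columns)
            if best is None or key > best[0]:
                best = (key, identity, aln.n_columns, tid)
        if best is None:
            calls.append(
                ExpressionCall(gene.name, None, None, 0, expressed=False)
            )
        else:
            _, identity, length, tid = best
            expressed = identity > cfg.min_identity and length >= cfg.min_aligned_len
            calls.append(
                ExpressionCall(gene.name, tid, identity, length, expressed)
            )
    return calls


def expression_report(calls: list[ExpressionCall]) -> pd.DataFrame:
    """One row per gene: detection flag, best transcript, identity, length."""
    return pd.DataFrame(
        [
            {
                "gene": c.gene_name,
                "transcript": c.transcript_id,
                "identity_pct": c.identity,
                "aligned_len": c.aligned_len,
                "detected": c.expressed,
            }
            for c in calls
        ]
    )
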