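"""Ground-truth evaluation harness for the synthetic study design.

Runs the full mine -> diagnose -> classify chain on one seeded synthetic
assembly and scores it against the generator's ground truth.  This is the
package's own way of measuring pipeline operating characteristics (family
recovery, decoy admission, expression detection) under controlled conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

from .classify import assign_family, build_similarity_matrix, name_candidates
from .diagnostics import diagnose
from .expression import match_transcripts
from .mining import mine_assembly
from .references import (
    DiagnosticScheme,
    ReferenceOpsin,
    default_outgroup,
    default_panel,
    get_anchor,
)
from .synthetic import (
    SyntheticSpec,
    default_spec,
    generate_assembly,
    generate_transcripts,
)


@dataclass
class RecoveryResult:
    n_genes: int
    n_candidates: int
    n_family_correct: int
    n_decoys_admitted: int
    n_bona_fide: int
    expressed_truth: set[str]
    expressed_detected: set[str]
    names: dict[str, str]

    @property
    def family_recovery(self) -> float:
        return self.n_family_correct / self.n_genes if self.n_genes else 1.0

    @property
    def expression_exact(self) -> bool:
        return self.expressed_detected == self.expressed_truth


def recovery_trial(
    seed: int,
    divergence: float = 0.25,
    transcript_noise: float = 0.0,
    spec: SyntheticSpec | None = None,
    panel: list[ReferenceOpsin] | None = None,
    seed_prefilter: bool = True,
    with_mining: bool = True,
    with_expression: bool = True,
) -> RecoveryResult:
    """One seeded end-to-end run scored against ground truth.

    ``with_mining`` / ``with_expression`` switch the two expensive stages off
    when a caller only measures the other one.
    """
    panel = panel or default_panel()
    scheme = DiagnosticScheme()
    anchor = get_anchor(panel)
    spec = spec or default_spec(seed, divergence, transcript_noise)
    contigs, truth = generate_assembly(spec, panel, scheme)
    decoy_panel = [default_outgroup()] + truth.decoy_proteins

    candidates = []
    if with_mining:
        candidates = mine_assembly(contigs, panel, decoy_panel,
                                   seed_prefilter=seed_prefilter)
    contig_to_gene = {f.contig_id: g for g in truth.genes for f in g.fragments}
    decoy_contigs = set(truth.decoy_contigs)

    n_decoys = sum(
        1 for c in candidates
        if any(f.contig_id in decoy_contigs for f in c.fragments)
    )
    true_candidates = [
        c for c in candidates
        if all(f.contig_id in contig_to_gene for f in c.fragments)
    ]

    prots = [c.merged_protein for c in true_candidates]
    n_correct = n_bona = 0
    names: dict[str, str] = {}
    if prots:
        reports = {r.candidate_name: r
                   for r in diagnose(prots, anchor, scheme)}
        sim = build_similarity_matrix(prots, panel)
        calls = [assign_family(c.name, sim, reports[c.name], panel)
                 for c in true_candidates]
        names = name_candidates(calls)
        for cand, call in zip(true_candidates, calls):
            gene = contig_to_gene[cand.fragments[0].contig_id]
            n_correct += (call.family == gene.family)
        n_bona = sum(1 for r in reports.values() if r.bona_fide == "true")

    # expression detection against the true gene set (generator CDS copies)
    detected: set[str] = set()
    if with_expression:
        transcripts = generate_transcripts(truth, transcript_noise, seed)
        gene_candidates = []
        from .mining import OpsinCandidate
        from .seqcore import ProteinSequence

        for g in truth.genes:
            gene_candidates.append(OpsinCandidate(
                name=g.name, fragments=[],
                merged_protein=ProteinSequence(id=g.name, seq=g.protein),
                best_reference=g.exemplar,
            ))
        ex_calls = match_transcripts(transcripts, gene_candidates)
        detected = {c.gene_name for c in ex_calls if c.expressed}

    return RecoveryResult(
        n_genes=len(truth.genes),
        n_candidates=len(candidates),
        n_family_correct=n_correct,
        n_decoys_admitted=n_decoys,
        n_bona_fide=n_bona,
        expressed_truth=truth.expressed_genes,
        expressed_detected=detected,
        names=names,
    )
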