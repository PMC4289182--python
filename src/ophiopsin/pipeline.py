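"""End-to-end orchestration: mine -> diagnose -> classify/tree -> expression
-> behaviour, with a manifest recording inputs, thresholds and stage counts.

All coordinates are 0-based half-open internally and 1-based inclusive in
GFF3 and anchor-numbered reports.  Stage failures abort with the stage name;
partially written outputs are removed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .behaviour import DEFAULT_ALPHA, datasets_from_table, spectral_verdicts
from .classify import (
    PhyloConfig,
    assign_family,
    bootstrap_support,
    build_similarity_matrix,
    name_candidates,
    tree_neighbor_families,
    truncate_to_core,
)
from .diagnostics import diagnose, report_matrix
from .expression import ExpressionConfig, expression_report, match_transcripts
from .mining import DEFAULT_MIN_SCORE, TmConfig, mine_assembly
from .references import (
    DiagnosticScheme,
    default_outgroup,
    default_panel,
    get_anchor,
    load_reference_panel,
)
from .seqcore import ProteinSequence, ScoringScheme

logger = logging.getLogger("ophiopsin")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    assembly: str | None = None
    transcripts: str | None = None
    behaviour_table: str | None = None
    panel_fasta: str | None = None  # default: shipped fixture panel
    panel_sidecar: str | None = None
    out_dir: str = "ophiopsin_out"
    min_score: float = DEFAULT_MIN_SCORE
    seed_prefilter: bool = False
    name_prefix: str = "opsin"
    alpha: float = DEFAULT_ALPHA
    seed: int = 0
    tm: TmConfig = field(default_factory=TmConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    phylo: PhyloConfig = field(default_factory=PhyloConfig)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "tm" in kwargs:
            kwargs["tm"] = TmConfig(**kwargs["tm"])
        if "expression" in kwargs:
            kwargs["expression"] = ExpressionConfig(**kwargs["expression"])
        if "phylo" in kwargs:
            kwargs["phylo"] = PhyloConfig(**kwargs["phylo"])
        if "scoring" in kwargs:
            kwargs["scoring"] = ScoringScheme.from_config(kwargs["scoring"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, frozenset):
                return sorted(o)
            return str(o)

        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every applicable stage and write the output bundle.

    Returns the manifest dict.  Stages without inputs (no transcripts, no
    behaviour table) are skipped cleanly.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {
        "tool": "ophiopsin",
        "version": __version__,
        "config_hash": config.config_hash(),
        "inputs": {},
        "counts": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    stage = "setup"
    try:
        if config.panel_fasta:
            panel = load_reference_panel(config.panel_fasta,
                                         config.panel_sidecar)
        else:
            panel = default_panel()
        anchor = get_anchor(panel)
        scheme = DiagnosticScheme()
        outgroup = default_outgroup()
        sc = config.scoring
        for key in ("assembly", "transcripts", "behaviour_table",
                    "panel_fasta", "panel_sidecar"):
            path = getattr(config, key)
            if path:
                manifest["inputs"][key] = _checksum(path)

        candidates = []
        if config.assembly:
            stage = "mine"
            contigs = io.read_nucleotide_fasta(config.assembly)
            manifest["counts"]["contigs"] = len(contigs)
            candidates = mine_assembly(
                contigs, panel, [outgroup],
                min_score=config.min_score, sc=sc, tm_cfg=config.tm,
                seed_prefilter=config.seed_prefilter,
            )
            manifest["counts"]["candidates"] = len(candidates)
            logger.info("mine: %d candidates from %d contigs",
                        len(candidates), len(contigs))

        if config.assembly and not candidates:
            emit("classification.tsv", lambda p: io.write_tsv(
                pd.DataFrame(columns=[
                    "name", "family", "best_reference", "similarity_pct",
                    "triad", "tree_neighbor", "confidence", "bona_fide",
                    "tm_helices", "n_fragments",
                ]), p))

        reports = {}
        calls = []
        if candidates:
            stage = "diagnose"
            prots = [c.merged_protein for c in candidates]
            reports = {r.candidate_name: r
                       for r in diagnose(prots, anchor, scheme, sc)}
            manifest["counts"]["bona_fide"] = sum(
                1 for r in reports.values() if r.bona_fide == "true"
            )

            stage = "classify"
            sim = build_similarity_matrix(prots, panel, sc)

            stage = "tree"
            tree = None
            taxa = prots + [
                ProteinSequence(id=r.name, seq=r.protein.seq) for r in panel
            ] + [outgroup]
            cores = truncate_to_core(taxa, config.phylo, panel, sc)
            neighbors: dict[str, str | None] = {}
            if len(cores) >= 4:
                phylo = PhyloConfig(
                    anchor_for_truncation=config.phylo.anchor_for_truncation,
                    core_start=config.phylo.core_start,
                    core_end=config.phylo.core_end,
                    bootstrap_reps=config.phylo.bootstrap_reps,
                    outgroup_name=outgroup.id,
                )
                tree = bootstrap_support(cores, phylo, panel, config.seed, sc)
                neighbors = tree_neighbor_families(
                    tree, {p.id for p in prots}, panel
                )

            stage = "classify"
            calls = [
                assign_family(c.name, sim, reports[c.name], panel,
                              neighbors.get(c.name))
                for c in candidates
            ]
            names = name_candidates(calls, prefix=config.name_prefix)
            renamed = {}
            for cand in candidates:
                renamed[cand.name] = names[cand.name]
            manifest["counts"]["genes"] = len(candidates)

            stage = "write-candidates"
            emit("motif_matrix.tsv", lambda p: io.write_tsv(
                report_matrix(list(reports.values())).assign(
                    name=lambda df: df["candidate"].map(renamed)
                ), p))
            sim_out = sim.similarity.round(1).copy()
            sim_out.insert(0, "candidate", sim_out.index.map(renamed))
            emit("similarity_matrix.tsv",
                 lambda p: sim_out.to_csv(p, sep="\t", index=False))
            cls_rows = []
            for cand, call in zip(candidates, calls):
                cls_rows.append({
                    "name": renamed[cand.name],
                    "family": call.family,
                    "best_reference": call.best_similarity_reference,
                    "similarity_pct": round(call.best_similarity, 1),
                    "triad": call.triad_class,
                    "tree_neighbor": call.tree_neighbor_family,
                    "confidence": call.confidence,
                    "bona_fide": reports[cand.name].bona_fide,
                    "tm_helices": cand.tm_helix_count,
                    "n_fragments": len(cand.fragments),
                })
            emit("classification.tsv",
                 lambda p: io.write_tsv(pd.DataFrame(cls_rows), p))
            gff_rows = []
            for cand in candidates:
                multi = len(cand.fragments) > 1
                for k, frag in enumerate(cand.fragments):
                    fid = renamed[cand.name]
                    if multi:
                        fid += f".{chr(ord('A') + k)}"
                    gff_rows.append({
                        "seqid": frag.contig_id,
                        "start": frag.contig_span[0],
                        "end": frag.contig_span[1],
                        "strand": "+" if frag.frame > 0 else "-",
                        "score": frag.score,
                        "id": fid.replace(" ", "_"),
                        "best_reference": frag.reference_name.replace(" ", "_"),
                    })
            emit("candidates.gff3", lambda p: io.write_gff3(gff_rows, p))
            emit("candidates.fasta", lambda p: io.write_fasta(
                [ProteinSequence(id=renamed[c.name].replace(" ", "_"),
                                 seq=c.merged_protein.seq)
                 for c in candidates], p))
            if tree is not None:
                emit("tree.nwk", lambda p: tree.write(str(p)))

            if config.transcripts:
                stage = "expression"
                transcripts = io.read_nucleotide_fasta(config.transcripts)
                for cand in candidates:
                    cand.name = renamed[cand.name]
                ex_calls = match_transcripts(
                    transcripts, candidates, config.expression, sc
                )
                manifest["counts"]["transcripts"] = len(transcripts)
                manifest["counts"]["detected_genes"] = sum(
                    1 for c in ex_calls if c.expressed
                )
                emit("expression.tsv",
                     lambda p: io.write_tsv(expression_report(ex_calls), p))

        if config.behaviour_table:
            stage = "behaviour"
            table = io.read_tsv(config.behaviour_table)
            datasets = datasets_from_table(table)
            verdicts = spectral_verdicts(datasets, alpha=config.alpha)
            manifest["counts"]["treatments"] = len(datasets)
            emit("behaviour_stats.tsv", lambda p: io.write_tsv(verdicts, p))
            emit("behaviour_stats.json", lambda p: Path(p).write_text(
                verdicts.to_json(orient="records", indent=2)))

        stage = "manifest"
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        emit("manifest.json", lambda p: Path(p).write_text(
            json.dumps(manifest, indent=2, default=str)))
        return manifest
    except Exception as exc:
        for path in written:
            try:
                os.unlink(path)
            except OSError:
                pass
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
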