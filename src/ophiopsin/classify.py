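"""Family assignment, Sp-style naming, and neighbor-joining placement.

Family calls rest on three lines of evidence: best trimmed-local-alignment
similarity against the reference panel, the 310-312 triad class (NxQ supports
ciliary, HxK rhabdomeric), and the family of the nearest reference on a
neighbor-joining tree.  The tree is corroborating evidence only, never the
sole classifier.

Tree building is distance-based: sequences are truncated to the conserved
7-TM core (positions 68-357 of the truncation anchor), pairwise p-distances
(1 - fractional identity) feed a deterministic neighbor-joining
agglomeration, and branch support comes from column-bootstrap resampling of
an anchor-stacked pseudo-alignment.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .diagnostics import MotifReport, map_to_anchor
from .references import ReferenceOpsin
from .seqcore import (
    InputError,
    ProteinSequence,
    ScoringScheme,
    global_align,
    local_align,
    percent_identity_and_similarity,
    trim_alignment,
)


@dataclass(frozen=True)
class PhyloConfig:
    anchor_for_truncation: str = "Sp-opsin 1"
    core_start: int = 68
    core_end: int = 357
    bootstrap_reps: int = 500
    outgroup_name: str | None = None

    def __post_init__(self):
        if self.core_start >= self.core_end:
            raise InputError("core_start must be < core_end")
        if self.bootstrap_reps < 1:
            raise InputError("bootstrap_reps must be >= 1")


@dataclass
class SimilarityMatrix:
    """Percent similarity of candidates vs references on trimmed local alignments."""

    similarity: pd.DataFrame  # rows: candidates, cols: references; NaN = no alignment
    aligned_len: pd.DataFrame

    def best_reference(self, candidate: str,
                       exclude: set[str] = frozenset(),
                       min_aligned_len: int = 50) -> tuple[str, float]:
        """Highest-similarity reference over sufficiently long alignments.

        Similarity percentages are only comparable at comparable alignment
        lengths (a 2-column perfect alignment is meaningless), so cells
        shorter than ``min_aligned_len`` residues compete only when no cell
        reaches that length.
        """
        row = self.similarity.loc[candidate].drop(labels=list(exclude),
                                                  errors="ignore")
        row = row.dropna()
        if row.empty:
            raise InputError(f"no reference alignment for {candidate!r}")
        lens = self.aligned_len.loc[candidate]
        long_enough = row[[c for c in row.index if lens[c] >= min_aligned_len]]
        if not long_enough.empty:
            row = long_enough
        best = row.idxmax()
        return best, float(row[best])


@dataclass(frozen=True)
class FamilyCall:
    candidate_name: str
    family: str
    best_similarity_reference: str
    best_similarity: float
    triad_class: str
    tree_neighbor_family: str | None
    confidence: str  # consistent | ambiguous


def build_similarity_matrix(
    candidates: list[ProteinSequence],
    panel: list[ReferenceOpsin],
    sc: ScoringScheme | None = None,
) -> SimilarityMatrix:
    """Local-align every candidate against every reference; cell = similarity %.

    The similarity estimate is computed on the local (trimmed) alignment, so
    each cell has its own alignment length; cells with no positive-scoring
    alignment are NaN with length 0.
    """
    if not candidates or not panel:
        raise InputError("need at least one candidate and one reference")
    sc = sc or ScoringScheme()
    names = [c.id for c in candidates]
    refs = [r.name for r in panel]
    sim = pd.DataFrame(np.nan, index=names, columns=refs)
    ln = pd.DataFrame(0, index=names, columns=refs)
    for c in candidates:
        for r in panel:
            aln = trim_alignment(local_align(c, r.protein, sc), sc)
            if aln.n_columns == 0:
                continue
            _, similarity = percent_identity_and_similarity(aln, sc)
            sim.loc[c.id, r.name] = similarity
            ln.loc[c.id, r.name] = aln.n_columns
    return SimilarityMatrix(similarity=sim, aligned_len=ln)


def assign_family(
    candidate_name: str,
    sim: SimilarityMatrix,
    report: MotifReport,
    panel: list[ReferenceOpsin],
    tree_neighbor_family: str | None = None,
) -> FamilyCall:
    """Family of the most similar reference, checked against triad and tree.

    The anchor and any outgroup entries are excluded from the similarity
    argmax.  Confidence is ``consistent`` only when every non-missing line of
    evidence points at the same family.
    """
    if candidate_name not in sim.similarity.index:
        raise InputError(f"{candidate_name!r} absent from similarity matrix")
    fam_of = {r.name: r.family for r in panel}
    excluded = {r.name for r in panel if r.is_anchor or r.family == "outgroup"}
    best_ref, best_sim = sim.best_reference(candidate_name, exclude=excluded)
    family = fam_of[best_ref]
    triad_family = {"ciliary": "ciliary", "rhabdomeric": "rhabdomeric"}.get(
        report.triad_class
    )
    evidence = [family]
    if triad_family is not None:
        evidence.append(triad_family)
    if tree_neighbor_family is not None and tree_neighbor_family != "outgroup":
        evidence.append(tree_neighbor_family)
    confidence = "consistent" if len(set(evidence)) == 1 else "ambiguous"
    return FamilyCall(
        candidate_name=candidate_name,
        family=family,
        best_similarity_reference=best_ref,
        best_similarity=best_sim,
        triad_class=report.triad_class,
        tree_neighbor_family=tree_neighbor_family,
        confidence=confidence,
    )


_SP_NUMBER = re.compile(r"(\d+)")


def name_candidates(
    calls: list[FamilyCall], prefix: str = "opsin"
) -> dict[str, str]:
    """Sp-style names: base number of the best reference, .1/.2 for paralogs.

    Genes sharing a base number are suffixed .1, .2, ... by descending best
    similarity (ties broken by candidate name for determinism); a lone gene
    keeps the bare number.  The mapping is a bijection on candidate names.
    """
    by_base: dict[str, list[FamilyCall]] = {}
    for call in calls:
        m = _SP_NUMBER.search(call.best_similarity_reference)
        base = m.group(1) if m else call.best_similarity_reference
        by_base.setdefault(base, []).append(call)
    names: dict[str, str] = {}
    for base, group in by_base.items():
        group.sort(key=lambda c: (-c.best_similarity, c.candidate_name))
        if len(group) == 1:
            names[group[0].candidate_name] = f"{prefix} {base}"
        else:
            for i, call in enumerate(group, start=1):
                names[call.candidate_name] = f"{prefix} {base}.{i}"
    return names


def truncate_to_core(
    seqs: list[ProteinSequence],
    cfg: PhyloConfig,
    panel: list[ReferenceOpsin],
    sc: ScoringScheme | None = None,
) -> list[ProteinSequence]:
    """Trim every sequence to the residues mapping inside the anchor core.

    Each sequence is globally aligned to the truncation anchor; residues
    mapping before ``core_start`` or after ``core_end`` are dropped, while
    insertions inside the core are retained.  Sequences with no core overlap
    are excluded with a warning.
    """
    anchor = next(
        (r for r in panel if r.name == cfg.anchor_for_truncation), None
    )
    if anchor is None:
        raise InputError(
            f"truncation anchor {cfg.anchor_for_truncation!r} not in panel"
        )
    out: list[ProteinSequence] = []
    for s in seqs:
        rmap = map_to_anchor(s, anchor, sc)
        core_pos = [
            c for c, a in rmap.pairs if cfg.core_start <= a <= cfg.core_end
        ]
        if not core_pos:
            warnings.warn(f"{s.id!r} has no overlap with the core; excluded")
            continue
        out.append(
            ProteinSequence(id=s.id, seq=s.seq[min(core_pos) - 1 : max(core_pos)])
        )
    return out


def p_distance_matrix(
    seqs: list[ProteinSequence], sc: ScoringScheme | None = None
) -> tuple[list[str], np.ndarray]:
    """Pairwise 1 - fractional-identity distances from global alignments."""
    sc = sc or ScoringScheme()
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(seqs[i], seqs[j], sc)
            ident, _ = percent_identity_and_similarity(aln, sc)
            d[i, j] = d[j, i] = 1.0 - ident / 100.0
    return [s.id for s in seqs], d


def nj_from_distances(names: list[str], d: np.ndarray) -> TreeNode:
    """Deterministic neighbor joining; exact on additive matrices.

    Ties in the Q criterion are broken by joining the pair whose clusters
    have the lexicographically smallest representative leaf names.  The
    returned tree is unrooted in the usual sense: its root is the final
    degree-3 (or degree-2 for n = 3 inputs... always 3 here) junction.
    """
    n = len(names)
    if n < 3:
        raise InputError("neighbor joining needs at least 3 sequences")
    if len(set(names)) != n:
        raise InputError("duplicate sequence names")
    nodes: list[TreeNode] = [TreeNode(name=nm) for nm in names]
    reps = list(names)  # lexicographic representative per cluster
    D = d.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = (q, *sorted((reps[i], reps[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        ci, cj = nodes[i], nodes[j]
        ci.length, cj.length = float(li), float(lj)
        parent = TreeNode(children=[ci, cj])
        new_rep = min(reps[i], reps[j])
        dnew = np.array(
            [(D[i, k] + D[j, k] - D[i, j]) / 2.0 for k in range(m)]
        )
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep],
                       dnew[keep][None, :]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [new_rep]

    # resolve the last three clusters as a star (closed form)
    (a, b, c) = nodes
    la = (D[0, 1] + D[0, 2] - D[1, 2]) / 2.0
    lb = (D[0, 1] + D[1, 2] - D[0, 2]) / 2.0
    lc = (D[0, 2] + D[1, 2] - D[0, 1]) / 2.0
    a.length, b.length, c.length = float(la), float(lb), float(lc)
    return TreeNode(children=[a, b, c])


def nj_tree(
    seqs: list[ProteinSequence], sc: ScoringScheme | None = None
) -> TreeNode:
    """Neighbor-joining tree from global-alignment p-distances."""
    names, d = p_distance_matrix(seqs, sc)
    return nj_from_distances(names, d)


def _bipartitions(tree: TreeNode, taxa: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial splits, each canonicalised as the side excluding min(taxa)."""
    ref = min(taxa)
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = taxa - side
        if 1 < len(side) < len(taxa) - 1:
            splits.add(side)
    return splits


def stacked_pseudo_alignment(
    seqs: list[ProteinSequence],
    cfg: PhyloConfig,
    panel: list[ReferenceOpsin],
    sc: ScoringScheme | None = None,
) -> tuple[list[str], np.ndarray]:
    """Anchor-indexed character matrix for column bootstrap.

    Each sequence's residues are placed at their mapped anchor columns within
    the core interval; unmapped columns and insertions relative to the anchor
    are gaps ('-').  This deterministic stacking replaces a progressive
    multiple alignment.
    """
    anchor = next(
        (r for r in panel if r.name == cfg.anchor_for_truncation), None
    )
    if anchor is None:
        raise InputError(
            f"truncation anchor {cfg.anchor_for_truncation!r} not in panel"
        )
    cols = list(range(cfg.core_start, cfg.core_end + 1))
    col_idx = {a: k for k, a in enumerate(cols)}
    mat = np.full((len(seqs), len(cols)), "-", dtype="<U1")
    for i, s in enumerate(seqs):
        rmap = map_to_anchor(s, anchor, sc)
        for cpos, apos in rmap.pairs:
            k = col_idx.get(apos)
            if k is not None:
                mat[i, k] = s.seq[cpos - 1]
    return [s.id for s in seqs], mat


def _pseudo_msa_distances(mat: np.ndarray) -> np.ndarray:
    """p-distance per pair over columns where both rows carry residues."""
    n = mat.shape[0]
    d = np.zeros((n, n))
    gap = mat == "-"
    for i in range(n):
        for j in range(i + 1, n):
            both = ~gap[i] & ~gap[j]
            shared = int(both.sum())
            if shared == 0:
                dij = 1.0
            else:
                dij = float((mat[i, both] != mat[j, both]).sum()) / shared
            d[i, j] = d[j, i] = dij
    return d


def bootstrap_support(
    seqs: list[ProteinSequence],
    cfg: PhyloConfig,
    panel: list[ReferenceOpsin],
    seed: int,
    sc: ScoringScheme | None = None,
) -> TreeNode:
    """NJ tree with bootstrap-proportion labels on internal nodes.

    Columns of the stacked pseudo-alignment are resampled with replacement
    ``cfg.bootstrap_reps`` times; support for each original internal split is
    the fraction of replicate trees containing it.  The tree is rooted at the
    outgroup (when named in the config) for display.
    """
    names, mat = stacked_pseudo_alignment(seqs, cfg, panel, sc)
    taxa = frozenset(names)
    tree = nj_from_distances(names, _pseudo_msa_distances(mat))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {
        s: 0 for s in _bipartitions(tree, taxa)
    }
    ncol = mat.shape[1]
    for _ in range(cfg.bootstrap_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_tree = nj_from_distances(names, _pseudo_msa_distances(mat[:, cols]))
        rep_splits = _bipartitions(rep_tree, taxa)
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if min(taxa) in side:
            side = taxa - side
        if side in counts:
            node.name = f"{counts[side] / cfg.bootstrap_reps:.2f}"
    if cfg.outgroup_name and cfg.outgroup_name in taxa:
        tip = tree.find(cfg.outgroup_name)
        tree = tree.root_at(tip.parent)
    return tree


def tree_neighbor_families(
    tree: TreeNode,
    candidate_names: set[str],
    panel: list[ReferenceOpsin],
) -> dict[str, str | None]:
    """Family of the topologically nearest reference tip for each candidate."""
    fam_of = {r.name: r.family for r in panel}
    out: dict[str, str | None] = {}
    for name in candidate_names:
        try:
            tip = tree.find(name)
        except Exception:
            out[name] = None
            continue
        best: tuple[int, str] | None = None
        node, depth = tip, 0
        while node.parent is not None:
            node = node.parent
            depth += 1
            for t in node.tips():
                if t.name in fam_of:
                    key = (depth, t.name)
                    if best is None or key < best:
                        best = key
            if best is not None:
                break
        out[name] = fam_of[best[1]] if best else None
    return out
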