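"""Foundational sequence operations.

Validated nucleotide/protein containers, six-frame translation under the
standard genetic code, affine-gap pairwise alignment (Needleman-Wunsch and
Smith-Waterman via Biopython's PairwiseAligner), percent identity/similarity
on alignment columns, and average-mass molecular weight.

Conventions used throughout the package:

* substitution matrix BLOSUM62 with ``X`` rescored to 0 against everything
  (``X`` marks codons containing ``N`` and must be informationless);
* a gap of length *k* costs ``gap_open + gap_extend * (k - 1)``;
* global alignments penalise end gaps (true global), local alignments do not;
* all reported spans are 1-based inclusive on the ungapped sequences.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.SeqUtils import molecular_weight as _bio_mw

NUCLEOTIDE_ALPHABET = set("ACGTN")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = set(AMINO_ACIDS) | {"X", "*"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Default similarity groups (MEGA-style conservative classes).  Residues in
#: the same group count as "similar" columns in percent-similarity estimates.
DEFAULT_SIMILARITY_GROUPS: tuple[frozenset[str], ...] = (
    frozenset("GAST"),
    frozenset("ILVM"),
    frozenset("FYW"),
    frozenset("KRH"),
    frozenset("DENQ"),
    frozenset("C"),
    frozenset("P"),
)


class InputError(ValueError):
    """Raised on malformed user input (bad alphabet, empty sequence...)."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A linear DNA sequence over {A, C, G, T, N}."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise InputError(f"nucleotide sequence {self.id!r} is empty")
        for i, c in enumerate(self.seq):
            if c not in NUCLEOTIDE_ALPHABET:
                raise InputError(
                    f"invalid nucleotide {c!r} at position {i + 1} in {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence; ``*`` marks stops, ``X`` untranslatable codons."""

    id: str
    seq: str
    frame_of_origin: int | None = None

    def __post_init__(self):
        if not self.seq:
            raise InputError(f"protein sequence {self.id!r} is empty")
        for i, c in enumerate(self.seq):
            if c not in PROTEIN_ALPHABET:
                raise InputError(
                    f"invalid residue {c!r} at position {i + 1} in {self.id!r}"
                )
        if self.frame_of_origin is not None and self.frame_of_origin not in (
            1, 2, 3, -1, -2, -3,
        ):
            raise InputError(f"invalid frame {self.frame_of_origin}")

    def __len__(self) -> int:
        return len(self.seq)


@functools.lru_cache(maxsize=4)
def _load_matrix(name: str):
    """BLOSUM-style matrix with the X row/column neutralised to zero."""
    mat = substitution_matrices.load(name).copy()
    alphabet = mat.alphabet
    for c in alphabet:
        mat["X", c] = 0.0
        mat[c, "X"] = 0.0
    return mat


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties and similarity groups."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    similarity_groups: tuple[frozenset[str], ...] = DEFAULT_SIMILARITY_GROUPS

    def __post_init__(self):
        if self.gap_open < self.gap_extend:
            raise InputError("gap_open must be >= gap_extend")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise InputError("gap penalties must be positive")
        seen: set[str] = set()
        for group in self.similarity_groups:
            if seen & group:
                raise InputError("similarity groups must be disjoint")
            seen |= group
        if seen != set(AMINO_ACIDS):
            raise InputError("similarity groups must cover the 20 amino acids")

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)

    def score_pair(self, a: str, b: str) -> float:
        return float(self.matrix[a, b])

    def same_group(self, a: str, b: str) -> bool:
        if a == b and a in PROTEIN_ALPHABET:
            return True
        return any(a in g and b in g for g in self.similarity_groups)

    @classmethod
    def from_config(cls, cfg: dict) -> "ScoringScheme":
        """Build from a config block: matrix / gap_open / gap_extend / groups."""
        groups = cfg.get("similarity_groups")
        if groups is not None:
            groups = tuple(frozenset(g) for g in groups)
        else:
            groups = DEFAULT_SIMILARITY_GROUPS
        return cls(
            matrix_name=cfg.get("matrix", "BLOSUM62"),
            gap_open=float(cfg.get("gap_open", 10.0)),
            gap_extend=float(cfg.get("gap_extend", 0.5)),
            similarity_groups=groups,
        )


@dataclass(frozen=True)
class PairwiseAlignment:
    """A scored pairwise alignment; gapped rows have equal length."""

    query_id: str
    subject_id: str
    aligned_query: str
    aligned_subject: str
    score: float
    mode: str  # "global" | "local"
    query_span: tuple[int, int] | None  # 1-based inclusive; None if empty
    subject_span: tuple[int, int] | None

    def __post_init__(self):
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValueError("gapped rows differ in length")
        for a, b in zip(self.aligned_query, self.aligned_subject):
            if a == "-" and b == "-":
                raise ValueError("column gapped in both rows")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_query)

    def columns(self):
        return zip(self.aligned_query, self.aligned_subject)


def reverse_complement(s: NucleotideSequence) -> NucleotideSequence:
    """Watson-Crick complement, reversed; N maps to N."""
    return NucleotideSequence(id=s.id, seq=s.seq.translate(_COMPLEMENT)[::-1])


_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _translate_frame(nt: str) -> str:
    """Translate one reading frame; stops as '*', any codon with N as 'X'."""
    out = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in _STANDARD_TABLE.stop_codons:
            out.append("*")
        else:
            out.append(_STANDARD_TABLE.forward_table[codon])
    return "".join(out)


def translate_six_frames(s: NucleotideSequence) -> list[ProteinSequence]:
    """All six reading frames (+1..+3 forward, -1..-3 on the complement).

    Trailing incomplete codons are dropped.  Frames too short to hold a codon
    are still returned (as far as content allows) only when non-empty; a
    sequence shorter than 3 nt is an input error.
    """
    if len(s) < 3:
        raise InputError(f"sequence {s.id!r} shorter than one codon")
    rc = reverse_complement(s)
    frames = []
    for f in (1, 2, 3):
        pep = _translate_frame(s.seq[f - 1 :])
        if pep:
            frames.append(ProteinSequence(id=f"{s.id}|frame+{f}", seq=pep,
                                          frame_of_origin=f))
    for f in (1, 2, 3):
        pep = _translate_frame(rc.seq[f - 1 :])
        if pep:
            frames.append(ProteinSequence(id=f"{s.id}|frame-{f}", seq=pep,
                                          frame_of_origin=-f))
    return frames


def _aligner(sc: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = sc.matrix
    aligner.open_gap_score = -sc.gap_open
    aligner.extend_gap_score = -sc.gap_extend
    aligner.mode = mode
    return aligner


def _to_alignment(aln, a: ProteinSequence, b: ProteinSequence, score: float,
                  mode: str) -> PairwiseAlignment:
    qa, sa = str(aln[0]), str(aln[1])
    # Strip columns gapped in both rows (can occur at local-alignment edges).
    cols = [(x, y) for x, y in zip(qa, sa) if not (x == "-" and y == "-")]
    qa = "".join(x for x, _ in cols)
    sa = "".join(y for _, y in cols)
    q0, q1 = int(aln.coordinates[0][0]), int(aln.coordinates[0][-1])
    s0, s1 = int(aln.coordinates[1][0]), int(aln.coordinates[1][-1])
    return PairwiseAlignment(
        query_id=a.id, subject_id=b.id, aligned_query=qa, aligned_subject=sa,
        score=float(score), mode=mode,
        query_span=(q0 + 1, q1), subject_span=(s0 + 1, s1),
    )


def global_align(a: ProteinSequence, b: ProteinSequence,
                 sc: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal Needleman-Wunsch alignment under affine gaps (end gaps scored).

    Among co-optimal tracebacks the aligner's first enumeration is returned,
    which is deterministic for fixed inputs.
    """
    sc = sc or ScoringScheme()
    aligner = _aligner(sc, "global")
    alns = aligner.align(a.seq, b.seq)
    return _to_alignment(alns[0], a, b, alns.score, "global")


def local_align(a: ProteinSequence, b: ProteinSequence,
                sc: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal Smith-Waterman alignment; empty (score 0) when nothing positive."""
    sc = sc or ScoringScheme()
    aligner = _aligner(sc, "local")
    score = aligner.score(a.seq, b.seq)
    if score <= 0:
        return PairwiseAlignment(
            query_id=a.id, subject_id=b.id, aligned_query="",
            aligned_subject="", score=0.0, mode="local",
            query_span=None, subject_span=None,
        )
    alns = aligner.align(a.seq, b.seq)
    return _to_alignment(alns[0], a, b, alns.score, "local")


def local_score(a: ProteinSequence, b: ProteinSequence,
                sc: ScoringScheme | None = None) -> float:
    """Smith-Waterman score without traceback (cheap screen for search)."""
    sc = sc or ScoringScheme()
    return max(0.0, float(_aligner(sc, "local").score(a.seq, b.seq)))


def percent_identity_and_similarity(
    aln: PairwiseAlignment, sc: ScoringScheme | None = None
) -> tuple[float, float]:
    """(identity %, similarity %) over all alignment columns.

    Gap columns count in the denominator; a column is similar when its two
    residues are identical or share a similarity group, so similarity >=
    identity always.
    """
    sc = sc or ScoringScheme()
    if aln.n_columns == 0:
        raise InputError("identity/similarity undefined for an empty alignment")
    ident = sim = 0
    for x, y in aln.columns():
        if x == "-" or y == "-":
            continue
        if x == y:
            ident += 1
        if sc.same_group(x, y):
            sim += 1
    n = aln.n_columns
    return 100.0 * ident / n, 100.0 * sim / n


def _column_score(cols: list[tuple[str, str]], sc: ScoringScheme) -> float:
    """Score of an explicit alignment column list under the affine scheme."""
    score = 0.0
    prev_gap_q = prev_gap_s = False
    for x, y in cols:
        if x == "-":
            score -= sc.gap_extend if prev_gap_q else sc.gap_open
            prev_gap_q, prev_gap_s = True, False
        elif y == "-":
            score -= sc.gap_extend if prev_gap_s else sc.gap_open
            prev_gap_q, prev_gap_s = False, True
        else:
            score += sc.score_pair(x, y)
            prev_gap_q = prev_gap_s = False
    return score


def trim_alignment(
    aln: PairwiseAlignment,
    sc: ScoringScheme | None = None,
    min_identity: float = 0.5,
    window: int = 20,
) -> PairwiseAlignment:
    """Trim poorly supported alignment ends.

    Cheap long gaps let a local alignment glue spurious low-identity stretches
    onto its ends; this trims terminal columns while the outermost ``window``
    columns fall below ``min_identity`` fractional identity, then recomputes
    the score and spans on the surviving columns.  Alignments shorter than
    the window are returned unchanged.
    """
    sc = sc or ScoringScheme()
    cols = list(aln.columns())
    if len(cols) < window or aln.query_span is None:
        return aln

    def window_identity(segment) -> float:
        ident = sum(1 for x, y in segment if x == y and x != "-")
        return ident / len(segment)

    lo, hi = 0, len(cols)  # half-open on columns

    # Segment-level trim: long gap runs delimit alignment blocks; terminal
    # blocks below the identity floor are glued junk, not homology.
    def is_gap(i: int) -> bool:
        return "-" in cols[i]

    def segment_bounds() -> list[tuple[int, int]]:
        bounds, i = [], lo
        while i < hi:
            if is_gap(i):
                i += 1
                continue
            j = i
            run = 0
            while j < hi:
                if is_gap(j):
                    run += 1
                    if run >= gap_run:
                        break
                else:
                    run = 0
                j += 1
            bounds.append((i, j - run + 1 if run >= gap_run else j))
            i = j
        return bounds

    gap_run = 4
    changed = True
    while changed:
        changed = False
        segs = segment_bounds()
        if len(segs) >= 2:
            a, b = segs[0]
            if window_identity(cols[a:b]) < min_identity:
                lo = segs[1][0]
                changed = True
                continue
            a, b = segs[-1]
            if window_identity(cols[a:b]) < min_identity:
                hi = segs[-2][1]
                changed = True

    while hi - lo >= window and window_identity(cols[lo : lo + window]) < min_identity:
        lo += 1
    while hi - lo >= window and window_identity(cols[hi - window : hi]) < min_identity:
        hi -= 1
    if lo == 0 and hi == len(cols):
        return aln
    trimmed = cols[lo:hi]
    # strip gap columns left dangling at the new ends
    while trimmed and "-" in trimmed[0]:
        trimmed.pop(0)
        lo += 1
    while trimmed and "-" in trimmed[-1]:
        trimmed.pop()
        hi -= 1
    if not trimmed:
        return PairwiseAlignment(
            query_id=aln.query_id, subject_id=aln.subject_id,
            aligned_query="", aligned_subject="", score=0.0, mode=aln.mode,
            query_span=None, subject_span=None,
        )
    q_cut_left = sum(1 for x, _ in cols[:lo] if x != "-")
    s_cut_left = sum(1 for _, y in cols[:lo] if y != "-")
    q_cut_right = sum(1 for x, _ in cols[hi:] if x != "-")
    s_cut_right = sum(1 for _, y in cols[hi:] if y != "-")
    return PairwiseAlignment(
        query_id=aln.query_id,
        subject_id=aln.subject_id,
        aligned_query="".join(x for x, _ in trimmed),
        aligned_subject="".join(y for _, y in trimmed),
        score=_column_score(trimmed, sc),
        mode=aln.mode,
        query_span=(aln.query_span[0] + q_cut_left,
                    aln.query_span[1] - q_cut_right),
        subject_span=(aln.subject_span[0] + s_cut_left,
                      aln.subject_span[1] - s_cut_right),
    )


def molecular_weight(p: ProteinSequence) -> float:
    """Average (isotope-averaged) molecular mass in Da of an intact chain."""
    if "*" in p.seq or "X" in p.seq:
        raise InputError(
            f"molecular weight undefined for {p.id!r}: contains stop/unknown residues"
        )
    return float(_bio_mw(p.seq, seq_type="protein"))
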