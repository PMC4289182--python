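"""Anchor-frame residue mapping and diagnostic motif calls.

Position equivalence is defined by one global alignment of each candidate to
the rhodopsin anchor; every diagnostic is then read off the mapped candidate
residues in anchor numbering.  Sites whose anchor positions fall outside the
candidate's aligned coverage are ``not_covered`` (incomplete gene fragments
are normal), and a candidate is a bona fide opsin exactly when the mapped
Schiff-base position carries a lysine.

Site-call vocabulary: ``present`` (canonical state), ``variant:<residues>``
(covered, non-canonical), ``absent`` (a multi-position pattern whose anchor
positions are covered but whose pattern fails), ``not_covered``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .references import DiagnosticScheme, ReferenceOpsin
from .seqcore import ProteinSequence, ScoringScheme, global_align

SITES = (
    "schiff_base", "counterion_113", "counterion_181", "dry",
    "npxxy", "triad", "disulfide", "palmitoylation",
)


@dataclass(frozen=True)
class ResidueMap:
    """Candidate-to-anchor position equivalence from one global alignment."""

    candidate_name: str
    pairs: tuple[tuple[int, int], ...]  # (candidate_pos, anchor_pos), 1-based

    @property
    def coverage(self) -> frozenset[int]:
        return frozenset(a for _, a in self.pairs)

    def anchor_to_candidate(self) -> dict[int, int]:
        return {a: c for c, a in self.pairs}


@dataclass(frozen=True)
class MotifReport:
    candidate_name: str
    site_calls: dict[str, str]
    triad_class: str  # ciliary | rhabdomeric | derived | other | not_covered
    counterion_113_type: str  # vertebrate | invertebrate | other | not_covered
    bona_fide: str  # "true" | "false" | "indeterminate"


def map_to_anchor(
    candidate: ProteinSequence,
    anchor: ReferenceOpsin,
    sc: ScoringScheme | None = None,
) -> ResidueMap:
    """Global alignment of candidate vs anchor; aligned columns become pairs."""
    aln = global_align(candidate, anchor.protein, sc)
    pairs: list[tuple[int, int]] = []
    ci = ai = 0
    for x, y in aln.columns():
        if x != "-":
            ci += 1
        if y != "-":
            ai += 1
        if x != "-" and y != "-":
            pairs.append((ci, ai))
    return ResidueMap(candidate_name=candidate.id, pairs=tuple(pairs))


def _residue(candidate: ProteinSequence, mapping: dict[int, int],
             anchor_pos: int) -> str | None:
    cpos = mapping.get(anchor_pos)
    return candidate.seq[cpos - 1] if cpos is not None else None


def call_sites(
    residue_map: ResidueMap,
    candidate: ProteinSequence,
    scheme: DiagnosticScheme,
) -> MotifReport:
    """Resolve every diagnostic site of the scheme for one candidate."""
    m = residue_map.anchor_to_candidate()

    def res(pos: int) -> str | None:
        return _residue(candidate, m, pos)

    calls: dict[str, str] = {}

    def single(site: str, pos: int, expected: str):
        r = res(pos)
        if r is None:
            calls[site] = "not_covered"
        elif r == expected:
            calls[site] = "present"
        else:
            calls[site] = f"variant:{r}"

    single("schiff_base", scheme.schiff_base_pos, "K")

    r113 = res(scheme.counterion_vertebrate_pos)
    if r113 is None:
        calls["counterion_113"] = "not_covered"
        c113_type = "not_covered"
    elif r113 == "E":
        calls["counterion_113"] = "present"
        c113_type = "vertebrate"
    else:
        calls["counterion_113"] = f"variant:{r113}"
        c113_type = "invertebrate" if r113 == "Y" else "other"

    single("counterion_181", scheme.counterion_ancestral_pos, "E")

    d0, d1 = scheme.dry_span
    dry = [res(p) for p in range(d0, d1 + 1)]
    if None in dry:
        calls["dry"] = "not_covered"
    elif dry[0] in scheme.dry_first and dry[1] == "R" and dry[2] in scheme.dry_third:
        calls["dry"] = "present"
    else:
        calls["dry"] = "absent"

    # NPxxY(x)6F: fixed residues N302, P303, Y306, F313 (anchor numbering);
    # internal x positions unconstrained, insertions between mapped sites
    # tolerated because the mapping, not a window, decides.
    n0 = scheme.npxxy_span[0]
    fixed = {n0: "N", n0 + 1: "P", n0 + 4: "Y", scheme.npxxy_span[1]: "F"}
    got = {p: res(p) for p in fixed}
    if any(v is None for v in got.values()):
        calls["npxxy"] = "not_covered"
    elif all(got[p] == fixed[p] for p in fixed):
        calls["npxxy"] = "present"
    else:
        calls["npxxy"] = "absent"

    t0, t2 = scheme.triad_span
    r_first, r_last = res(t0), res(t2)
    if r_first is None or r_last is None:
        calls["triad"] = "not_covered"
        triad_class = "not_covered"
    else:
        triad_class = {
            ("N", "Q"): "ciliary",
            ("H", "K"): "rhabdomeric",
            ("H", "S"): "derived",
        }.get((r_first, r_last), "other")
        calls["triad"] = (
            "present" if triad_class != "other" else f"variant:{r_first}{r_last}"
        )

    def pair(site: str, positions: tuple[int, int]):
        a, b = (res(p) for p in positions)
        if a is None or b is None:
            calls[site] = "not_covered"
        elif a == "C" and b == "C":
            calls[site] = "present"
        else:
            calls[site] = f"variant:{a}{b}"

    pair("disulfide", scheme.disulfide_pair)
    pair("palmitoylation", scheme.palmitoylation_pair)

    report = MotifReport(
        candidate_name=residue_map.candidate_name,
        site_calls=calls,
        triad_class=triad_class,
        counterion_113_type=c113_type,
        bona_fide="",
    )
    return MotifReport(
        candidate_name=report.candidate_name,
        site_calls=report.site_calls,
        triad_class=report.triad_class,
        counterion_113_type=report.counterion_113_type,
        bona_fide=assign_bona_fide(report),
    )


def assign_bona_fide(report: MotifReport) -> str:
    """Bona fide status from the Schiff-base call alone.

    ``true`` when the mapped 296-equivalent is lysine, ``false`` when the site
    is covered by another residue, ``indeterminate`` when the fragment does
    not reach the site.
    """
    call = report.site_calls["schiff_base"]
    if call == "present":
        return "true"
    if call == "not_covered":
        return "indeterminate"
    return "false"


def diagnose(
    candidates: list[ProteinSequence],
    anchor: ReferenceOpsin,
    scheme: DiagnosticScheme,
    sc: ScoringScheme | None = None,
) -> list[MotifReport]:
    return [
        call_sites(map_to_anchor(c, anchor, sc), c, scheme) for c in candidates
    ]


def report_matrix(reports: list[MotifReport]) -> pd.DataFrame:
    """Candidates x sites matrix plus triad/counterion classes and status."""
    rows = []
    for r in reports:
        row = {"candidate": r.candidate_name}
        row.update({s: r.site_calls[s] for s in SITES})
        row["triad_class"] = r.triad_class
        row["counterion_113_type"] = r.counterion_113_type
        row["bona_fide"] = r.bona_fide
        rows.append(row)
    return pd.DataFrame(rows)
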