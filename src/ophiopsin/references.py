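"""Reference frame for all diagnostics: the rhodopsin anchor, the opsin
reference panel, and the diagnostic-site scheme.

Every diagnostic position in this package is expressed in the anchor
(rat-rhodopsin-style) numbering, 1-based: the Schiff-base lysine K296, the
counterion sites 113 (E = vertebrate-type, Y = invertebrate-type) and 181,
the D/E-R-Y tripeptide 134-136, the NPxxY(x)6F pattern 302-313 whose internal
triad 310-312 separates ciliary (NxQ) from rhabdomeric (HxK) opsins, the
disulfide cysteines C110/C187 and the palmitoylation cysteines C322/C323.
This module is the single home of those coordinates; downstream modules
consult the scheme instead of hard-coding positions.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass

import pandas as pd
import yaml

from .seqcore import ProteinSequence

FAMILIES = frozenset(
    {"ciliary", "rhabdomeric", "Go", "neuropsin", "peropsin", "RGR",
     "basal-branch", "outgroup"}
)


class ConfigError(ValueError):
    """Raised on malformed panel/scheme configuration."""


@dataclass(frozen=True)
class ReferenceOpsin:
    name: str
    family: str
    protein: ProteinSequence
    is_anchor: bool = False

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigError(
                f"unknown family {self.family!r} for {self.name!r}; "
                f"expected one of {sorted(FAMILIES)}"
            )


@dataclass(frozen=True)
class DiagnosticScheme:
    """Anchor-numbered diagnostic sites and their expected residues."""

    schiff_base_pos: int = 296          # expected K
    counterion_vertebrate_pos: int = 113  # E vertebrate-type, Y invertebrate-type
    counterion_ancestral_pos: int = 181   # expected E
    dry_span: tuple[int, int] = (134, 136)
    dry_first: frozenset[str] = frozenset("DE")
    dry_third: frozenset[str] = frozenset("YFWCSH")
    npxxy_span: tuple[int, int] = (302, 313)
    triad_span: tuple[int, int] = (310, 312)
    disulfide_pair: tuple[int, int] = (110, 187)
    palmitoylation_pair: tuple[int, int] = (322, 323)

    def __post_init__(self):
        t0, t1 = self.triad_span
        n0, n1 = self.npxxy_span
        if not (n0 <= t0 and t1 <= n1):
            raise ConfigError("triad span must lie inside the NPxxY(x)6F span")

    @property
    def all_positions(self) -> tuple[int, ...]:
        """Every anchor position consulted by any diagnostic call."""
        pos = {
            self.schiff_base_pos,
            self.counterion_vertebrate_pos,
            self.counterion_ancestral_pos,
            *range(self.dry_span[0], self.dry_span[1] + 1),
            *range(self.npxxy_span[0], self.npxxy_span[1] + 1),
            *self.disulfide_pair,
            *self.palmitoylation_pair,
        }
        return tuple(sorted(pos))

    def to_config(self) -> dict:
        return {
            "schiff_base_pos": self.schiff_base_pos,
            "counterion_vertebrate_pos": self.counterion_vertebrate_pos,
            "counterion_ancestral_pos": self.counterion_ancestral_pos,
            "dry_span": list(self.dry_span),
            "dry_first": sorted(self.dry_first),
            "dry_third": sorted(self.dry_third),
            "npxxy_span": list(self.npxxy_span),
            "triad_span": list(self.triad_span),
            "disulfide_pair": list(self.disulfide_pair),
            "palmitoylation_pair": list(self.palmitoylation_pair),
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "DiagnosticScheme":
        kwargs = dict(cfg)
        for key in ("dry_span", "npxxy_span", "triad_span", "disulfide_pair",
                    "palmitoylation_pair"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        for key in ("dry_first", "dry_third"):
            if key in kwargs:
                kwargs[key] = frozenset(kwargs[key])
        return cls(**kwargs)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh)

    @classmethod
    def load(cls, path) -> "DiagnosticScheme":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))


def load_reference_panel(fasta_path, sidecar_path) -> list[ReferenceOpsin]:
    """Load a panel from FASTA plus a TSV sidecar (id, name, family, is_anchor).

    Exactly one member must be flagged as the anchor; names must be unique and
    every FASTA record must have a sidecar row.
    """
    from .io import read_protein_fasta

    seqs = {p.id: p for p in read_protein_fasta(fasta_path)}
    meta = pd.read_csv(sidecar_path, sep="\t", dtype=str)
    required = {"id", "name", "family", "is_anchor"}
    if not required <= set(meta.columns):
        raise ConfigError(f"sidecar must have columns {sorted(required)}")
    panel: list[ReferenceOpsin] = []
    seen_names: set[str] = set()
    for row in meta.itertuples():
        if row.id not in seqs:
            raise ConfigError(f"sidecar id {row.id!r} missing from FASTA")
        if row.name in seen_names:
            raise ConfigError(f"duplicate panel name {row.name!r}")
        seen_names.add(row.name)
        panel.append(
            ReferenceOpsin(
                name=row.name,
                family=row.family,
                protein=seqs[row.id],
                is_anchor=str(row.is_anchor).lower() in ("1", "true", "yes"),
            )
        )
    missing = set(seqs) - set(meta["id"])
    if missing:
        raise ConfigError(f"FASTA ids without family label: {sorted(missing)}")
    anchors = [p for p in panel if p.is_anchor]
    if len(anchors) != 1:
        raise ConfigError(f"panel must have exactly one anchor, got {len(anchors)}")
    return panel


def _data_path(name: str):
    return resources.files("ophiopsin").joinpath("data", name)


def default_panel() -> list[ReferenceOpsin]:
    """The shipped fixture panel: rhodopsin anchor + nine Sp-style exemplars."""
    return load_reference_panel(
        _data_path("reference_panel.fasta"), _data_path("reference_panel.tsv")
    )


def default_outgroup() -> ProteinSequence:
    """Shipped synthetic melatonin-receptor-like non-opsin GPCR (outgroup/decoy)."""
    from .io import read_protein_fasta

    return read_protein_fasta(_data_path("outgroup_synthetic.fasta"))[0]


def get_anchor(panel: list[ReferenceOpsin]) -> ReferenceOpsin:
    return next(p for p in panel if p.is_anchor)


@dataclass(frozen=True)
class SiteCheck:
    site: str
    ok: bool
    expected: str
    observed: str


def validate_scheme(scheme: DiagnosticScheme,
                    anchor: ReferenceOpsin) -> list[SiteCheck]:
    """Report whether the anchor carries the canonical residue at every site.

    Report-only: structural problems (a position beyond the anchor length) are
    flagged as failed checks, never raised.
    """
    seq = anchor.protein.seq

    def res(pos: int) -> str | None:
        return seq[pos - 1] if 1 <= pos <= len(seq) else None

    checks: list[SiteCheck] = []

    def add(site, pos_residues, expected_desc, ok):
        observed = "".join(r if r is not None else "?" for r in pos_residues)
        checks.append(SiteCheck(site, ok, expected_desc, observed))

    k = res(scheme.schiff_base_pos)
    add("schiff_base", [k], "K", k == "K")
    e113 = res(scheme.counterion_vertebrate_pos)
    add("counterion_113", [e113], "E", e113 == "E")
    e181 = res(scheme.counterion_ancestral_pos)
    add("counterion_181", [e181], "E", e181 == "E")
    d0, d1 = scheme.dry_span
    dry = [res(p) for p in range(d0, d1 + 1)]
    ok_dry = (dry[0] in scheme.dry_first and dry[1] == "R"
              and dry[2] in scheme.dry_third) if None not in dry else False
    add("dry", dry, "[DE]R[YFWCSH]", ok_dry)
    n0, n1 = scheme.npxxy_span
    np_res = [res(p) for p in range(n0, n1 + 1)]
    ok_np = (None not in np_res and np_res[0] == "N" and np_res[1] == "P"
             and np_res[4] == "Y" and np_res[-1] == "F")
    add("npxxy", np_res, "NPxxY(x)6F", ok_np)
    c1, c2 = scheme.disulfide_pair
    ds = [res(c1), res(c2)]
    add("disulfide", ds, "CC", ds == ["C", "C"])
    p1, p2 = scheme.palmitoylation_pair
    pm = [res(p1), res(p2)]
    add("palmitoylation", pm, "CC", pm == ["C", "C"])
    return checks
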