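"""Synthetic study inputs with known ground truth.

Everything the pipeline consumes can be generated here under a single seed:
opsin genes of a chosen family derived from the reference-panel exemplars
with controlled divergence (diagnostic motif sites are protected, or knocked
out on request), back-translated with uniform codon choice and embedded in
random background contigs; melatonin-receptor-like decoy GPCRs; transcript
copies of the expressed subset with a per-base noise rate; and day/night
arm-count tables with stated per-treatment day-suppression effects.

The default 13-gene specification mirrors the gene-family structure the
pipeline is designed to resolve: one ciliary gene, six rhabdomeric paralogs,
one Go gene, two basal-branch genes, one split RGR gene (two disjoint
fragments of a single gene) and two neuropsins, of which three genes are
expressed.  Divergence defaults to 0.25 substitutions per site outside
protected motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .references import (
    ConfigError,
    DiagnosticScheme,
    ReferenceOpsin,
    default_outgroup,
)
from .seqcore import AMINO_ACIDS, NucleotideSequence, ProteinSequence

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODONS: dict[str, list[str]] = {}
for codon, aa in _TABLE.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()

#: Residue edits that break each diagnostic site (anchor numbering applied
#: through the scheme at generation time).
KNOCKOUTS = {
    "schiff_base": {"schiff": "R"},
    "counterion_113": {"c113": "F"},
    "counterion_181": {"c181": "Q"},
    "dry": {"dry_mid": "G"},
    "npxxy": {"np_n": "D"},
    "triad": {"triad_first": "A", "triad_last": "A"},
    "disulfide": {"ds_first": "S"},
    "palmitoylation": {"palm_first": "S"},
}


@dataclass(frozen=True)
class GeneSpec:
    family: str
    divergence: float = 0.25
    exemplar: str | None = None  # panel member name; default: family's first
    motif_overrides: dict = field(default_factory=dict)  # site -> keep|knockout
    split_into_fragments: bool = False
    expressed: bool = False
    name: str | None = None


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int
    genes: tuple[GeneSpec, ...]
    n_decoy_gpcrs: int = 2
    n_background_contigs: int = 3
    background_len: int = 400
    transcript_noise: float = 0.0


@dataclass
class FragmentTruth:
    fragment_id: str
    contig_id: str
    span: tuple[int, int]  # 1-based inclusive on the forward strand
    strand: str  # "+" | "-"
    cds: str
    protein_span: tuple[int, int]  # residue interval on the gene protein


@dataclass
class GeneTruth:
    name: str
    family: str
    exemplar: str
    divergence: float
    expressed: bool
    protein: str
    cds: str
    motif_overrides: dict
    fragments: list[FragmentTruth] = field(default_factory=list)


@dataclass
class GroundTruth:
    genes: list[GeneTruth]
    decoy_contigs: list[str] = field(default_factory=list)
    decoy_proteins: list[ProteinSequence] = field(default_factory=list)
    background_contigs: list[str] = field(default_factory=list)

    @property
    def expressed_genes(self) -> set[str]:
        return {g.name for g in self.genes if g.expressed}


def default_spec(seed: int, divergence: float = 0.25,
                 transcript_noise: float = 0.0) -> SyntheticSpec:
    """The default 13-gene study structure (see module docstring)."""
    g = []
    g.append(GeneSpec("ciliary", divergence, exemplar="Sp-opsin 1"))
    for i in range(6):
        g.append(GeneSpec("rhabdomeric", divergence, exemplar="Sp-opsin 4",
                          expressed=(i == 3)))
    g.append(GeneSpec("Go", divergence, exemplar="Sp-opsin 3.1"))
    g.append(GeneSpec("basal-branch", divergence, exemplar="Sp-opsin 2",
                      expressed=True))
    g.append(GeneSpec("basal-branch", divergence, exemplar="Sp-opsin 5"))
    g.append(GeneSpec("RGR", divergence, exemplar="Sp-opsin 7",
                      split_into_fragments=True))
    g.append(GeneSpec("neuropsin", divergence, exemplar="Sp-opsin 8"))
    g.append(GeneSpec("neuropsin", divergence, exemplar="Sp-opsin 8",
                      expressed=True))
    return SyntheticSpec(seed=seed, genes=tuple(g),
                         transcript_noise=transcript_noise)


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(
        _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein
    )


def _knockout_edits(scheme: DiagnosticScheme, site: str) -> dict[int, str]:
    pos = {
        "schiff": scheme.schiff_base_pos,
        "c113": scheme.counterion_vertebrate_pos,
        "c181": scheme.counterion_ancestral_pos,
        "dry_mid": scheme.dry_span[0] + 1,
        "np_n": scheme.npxxy_span[0],
        "triad_first": scheme.triad_span[0],
        "triad_last": scheme.triad_span[1],
        "ds_first": scheme.disulfide_pair[0],
        "palm_first": scheme.palmitoylation_pair[0],
    }
    return {pos[k]: res for k, res in KNOCKOUTS[site].items()}


def generate_opsin_gene(
    entry: GeneSpec,
    panel: list[ReferenceOpsin],
    scheme: DiagnosticScheme,
    rng: np.random.Generator,
    name: str = "gene",
) -> GeneTruth:
    """Derive one synthetic gene from a family exemplar.

    Divergence applies random substitutions outside the protected diagnostic
    positions; knockouts then break the requested sites.  The protein is
    back-translated with uniform synonymous codon choice, and optionally
    split into two fragments with disjoint anchor spans.
    """
    for site, action in entry.motif_overrides.items():
        if site not in KNOCKOUTS:
            raise ConfigError(f"unknown motif site {site!r}")
        if action not in ("keep", "knockout"):
            raise ConfigError(f"override for {site!r} must be keep|knockout")
    members = [
        r for r in panel
        if r.family == entry.family and not r.is_anchor
    ]
    if entry.exemplar is not None:
        members = [r for r in members if r.name == entry.exemplar]
    if not members:
        raise ConfigError(
            f"no panel exemplar for family {entry.family!r} "
            f"(exemplar={entry.exemplar!r})"
        )
    exemplar = members[0]
    protected = set(scheme.all_positions)
    prot = list(exemplar.protein.seq)
    for i in range(len(prot)):
        if (i + 1) in protected:
            continue
        if rng.random() < entry.divergence:
            choices = [a for a in AMINO_ACIDS if a != prot[i]]
            prot[i] = choices[rng.integers(len(choices))]
    for site, action in entry.motif_overrides.items():
        if action == "knockout":
            for pos, res in _knockout_edits(scheme, site).items():
                if pos <= len(prot):
                    prot[pos - 1] = res
    protein = "".join(prot)
    cds = _back_translate(protein, rng)
    truth = GeneTruth(
        name=name,
        family=entry.family,
        exemplar=exemplar.name,
        divergence=entry.divergence,
        expressed=entry.expressed,
        protein=protein,
        cds=cds,
        motif_overrides=dict(entry.motif_overrides),
    )
    if entry.split_into_fragments:
        half = len(protein) // 2
        spans = [(1, half), (half + 1, len(protein))]
    else:
        spans = [(1, len(protein))]
    for i, (a, b) in enumerate(spans):
        suffix = f".{chr(ord('A') + i)}" if len(spans) > 1 else ""
        truth.fragments.append(
            FragmentTruth(
                fragment_id=f"{name}{suffix}",
                contig_id="",  # assigned at assembly time
                span=(0, 0),
                strand="+",
                cds=cds[(a - 1) * 3 : b * 3],
                protein_span=(a, b),
            )
        )
    return truth


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def generate_assembly(
    spec: SyntheticSpec,
    panel: list[ReferenceOpsin],
    scheme: DiagnosticScheme,
) -> tuple[list[NucleotideSequence], GroundTruth]:
    """Emit assembly contigs plus consistent ground truth, fully seeded.

    Each gene fragment and each decoy CDS lands in its own contig at a random
    offset and strand inside ``background_len`` nt of uniform random flank;
    ``n_background_contigs`` contigs carry no insert at all.
    """
    if spec.background_len < 40:
        raise ConfigError("background_len too short to host a gene")
    rng = np.random.default_rng(spec.seed)
    truth = GroundTruth(genes=[])
    contigs: list[NucleotideSequence] = []
    counter = 0

    def new_contig_id():
        nonlocal counter
        counter += 1
        return f"contig_{counter:04d}"

    def embed(cds: str) -> tuple[str, tuple[int, int], str, str]:
        cid = new_contig_id()
        flank = spec.background_len
        left = int(rng.integers(10, flank - 10))
        bg = _random_dna(rng, flank)
        strand = "+" if rng.random() < 0.5 else "-"
        insert = cds
        if strand == "-":
            insert = str(
                NucleotideSequence(id="tmp", seq=cds).seq.translate(
                    str.maketrans("ACGTN", "TGCAN")
                )[::-1]
            )
        seq = bg[:left] + insert + bg[left:]
        span = (left + 1, left + len(insert))
        return cid, span, strand, seq

    for i, entry in enumerate(spec.genes, start=1):
        gname = entry.name or f"gene_{i:02d}"
        gene = generate_opsin_gene(entry, panel, scheme, rng, name=gname)
        for frag in gene.fragments:
            cid, span, strand, seq = embed(frag.cds)
            frag.contig_id = cid
            frag.span = span
            frag.strand = strand
            contigs.append(NucleotideSequence(id=cid, seq=seq))
        truth.genes.append(gene)

    template = default_outgroup()
    for d in range(spec.n_decoy_gpcrs):
        prot = _mutate_protein(template.seq, 0.15, rng)
        cds = _back_translate(prot, rng)
        cid, _, _, seq = embed(cds)
        truth.decoy_contigs.append(cid)
        truth.decoy_proteins.append(
            ProteinSequence(id=f"decoy_gpcr_{d + 1}", seq=prot)
        )
        contigs.append(NucleotideSequence(id=cid, seq=seq))

    for _ in range(spec.n_background_contigs):
        cid = new_contig_id()
        contigs.append(
            NucleotideSequence(id=cid, seq=_random_dna(rng, spec.background_len))
        )
        truth.background_contigs.append(cid)
    return contigs, truth


def generate_transcripts(
    truth: GroundTruth,
    noise: float = 0.0,
    seed: int = 0,
) -> list[NucleotideSequence]:
    """CDS copies of the expressed genes with per-base substitution noise."""
    rng = np.random.default_rng(seed)
    out = []
    for gene in truth.genes:
        if not gene.expressed:
            continue
        seq = list(gene.cds)
        for i in range(len(seq)):
            if noise > 0 and rng.random() < noise:
                choices = [c for c in "ACGT" if c != seq[i]]
                seq[i] = choices[rng.integers(3)]
        out.append(
            NucleotideSequence(id=f"transcript_{gene.name}", seq="".join(seq))
        )
    return out


DEFAULT_EFFECTS = {"white": 0.5, "green": 0.5, "blue": 0.5, "red": 0.0,
                   "none": 0.0}


def generate_behaviour_counts(
    effects: dict[str, float] | None = None,
    n_days: int = 8,
    obs_per_phase: int = 2,
    n_animals: int = 18,
    p_night: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy per-observation arm-count table across light treatments.

    Night counts are Binomial(2 * n_animals, p_night) per observation; day
    counts use a success probability reduced by the treatment's
    day-suppression effect.  Effects must be non-negative.
    """
    effects = DEFAULT_EFFECTS if effects is None else effects
    if any(e < 0 for e in effects.values()):
        raise ConfigError("day-suppression effects must be >= 0")
    rng = np.random.default_rng(seed)
    nmax = 2 * n_animals
    rows = []
    for treatment, effect in effects.items():
        p_day = p_night * (1.0 - effect)
        for day in range(1, n_days + 1):
            for s in range(obs_per_phase):
                rows.append(
                    {
                        "treatment": treatment,
                        "phase": "day",
                        "timestamp": f"{day}_d{s}",
                        "arm_count": int(rng.binomial(nmax, p_day)),
                    }
                )
            for s in range(obs_per_phase):
                rows.append(
                    {
                        "treatment": treatment,
                        "phase": "night",
                        "timestamp": f"{day}_n{s}",
                        "arm_count": int(rng.binomial(nmax, p_night)),
                    }
                )
    return pd.DataFrame(rows)
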