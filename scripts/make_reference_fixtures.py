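"""Regenerate the shipped synthetic reference fixtures (deterministic).

The anchor is the canonical 348-residue rhodopsin frame carrying every
diagnostic residue at its canonical position (K296, E113, E181, ERY 134-136,
NPxxY(x)6F 302-313 with the NxQ triad, C110/C187, C322/C323) and a realistic
7-TM hydropathy profile.  The nine Sp-style panel exemplars are synthetic:
each is derived from the anchor by seeded family-level divergence (sparing
the diagnostic sites) plus family-specific motif edits (triad class,
counterion type, Schiff-base knockout for the peropsin exemplar).  The
outgroup is a synthetic melatonin-receptor-like non-opsin GPCR: a seeded
random protein with seven hydrophobic stretches and no opsin motifs.

Run from the repository root:  python scripts/make_reference_fixtures.py
"""

import pathlib

import numpy as np

AAS = "ACDEFGHIKLMNPQRSTVWY"

ANCHOR = (
    "MNGTEGPNFYVPFSNKTGVVRSPFEAPQYYLAEPWQFSMLAAYMFLLIMLGFPINFLTLYVTVQHKKLR"
    "TPLNYILLNLAVADLFMVFGGFTTTLYTSLHGYFVFGPTGCNLEGFFATLGGEIALWSLVVLAIERYVV"
    "VCKPMSNFRFGENHAIMGVAFTWVMALACAAPPLVGWSRYIPEGMQCSCGIDYYTPHEETNNESFVIYM"
    "FVVHFIIPLIVIFFCYGQLVFTVKEAAAQQQESATTQKAEKEVTRMVIIMVIAFLICWLPYAGVAFYIF"
    "THQGSDFGPIFMTIPAFFAKTSAVYNPVIYIMMNKQFRNCMVTTLCCGKNPLGDDEASTTVSKTETSQV"
    "APA"
)

# Anchor positions never touched by random divergence (1-based).
PROTECTED = sorted(
    {110, 113, 181, 187, 296, 322, 323}
    | set(range(134, 137))
    | set(range(302, 314))
)


def mutate(seq: str, rate: float, rng: np.random.Generator,
           protected=PROTECTED) -> str:
    prot = set(protected)
    out = list(seq)
    for i in range(len(seq)):
        if (i + 1) in prot:
            continue
        if rng.random() < rate:
            choices = [a for a in AAS if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def edit(seq: str, edits: dict[int, str]) -> str:
    out = list(seq)
    for pos, res in edits.items():
        out[pos - 1] = res
    return "".join(out)


def main():
    rng = np.random.default_rng(20140101)
    panel: list[tuple[str, str, str, bool]] = []  # id, name, family, anchor
    seqs: dict[str, str] = {}

    seqs["Rn_rhodopsin"] = ANCHOR
    panel.append(("Rn_rhodopsin", "Rn-rhodopsin", "ciliary", True))

    # ciliary exemplar: modest divergence, NxQ triad kept, C-tail extended so
    # the tree-truncation interval 68-357 exists on it.
    sp1 = mutate(ANCHOR, 0.25, rng) + "".join(
        AAS[rng.integers(20)] for _ in range(13)
    )
    seqs["Sp_opsin_1"] = sp1
    panel.append(("Sp_opsin_1", "Sp-opsin 1", "ciliary", False))

    # basal-branch exemplars (types 2 and 5) share a basal ancestor.
    basal = mutate(ANCHOR, 0.40, rng)
    seqs["Sp_opsin_2"] = edit(mutate(basal, 0.15, rng), {113: "Y"})
    panel.append(("Sp_opsin_2", "Sp-opsin 2", "basal-branch", False))
    seqs["Sp_opsin_5"] = edit(mutate(basal, 0.15, rng), {113: "Y"})
    panel.append(("Sp_opsin_5", "Sp-opsin 5", "basal-branch", False))

    # Go exemplars 3.1 / 3.2 from a shared ancestor; E181 counterion, Y113,
    # non-canonical triad (S.Q).
    go = edit(mutate(ANCHOR, 0.40, rng), {113: "Y", 310: "S"})
    seqs["Sp_opsin_3_1"] = mutate(go, 0.08, rng)
    panel.append(("Sp_opsin_3_1", "Sp-opsin 3.1", "Go", False))
    seqs["Sp_opsin_3_2"] = mutate(go, 0.08, rng)
    panel.append(("Sp_opsin_3_2", "Sp-opsin 3.2", "Go", False))

    # rhabdomeric exemplar: invertebrate-type Y113, HxK triad.
    seqs["Sp_opsin_4"] = edit(mutate(ANCHOR, 0.40, rng),
                              {113: "Y", 310: "H", 312: "K"})
    panel.append(("Sp_opsin_4", "Sp-opsin 4", "rhabdomeric", False))

    # peropsin exemplar: lacks the Schiff-base lysine (pseudo-opsin).
    seqs["Sp_opsin_6"] = edit(mutate(ANCHOR, 0.40, rng), {113: "Y", 296: "Q"})
    panel.append(("Sp_opsin_6", "Sp-opsin 6", "peropsin", False))

    # RGR exemplar: photoisomerase-like, E181, non-canonical triad.
    seqs["Sp_opsin_7"] = edit(mutate(ANCHOR, 0.40, rng), {113: "Y", 310: "G"})
    panel.append(("Sp_opsin_7", "Sp-opsin 7", "RGR", False))

    # neuropsin exemplar: NxQ triad retained, Y113.
    seqs["Sp_opsin_8"] = edit(mutate(ANCHOR, 0.40, rng), {113: "Y"})
    panel.append(("Sp_opsin_8", "Sp-opsin 8", "neuropsin", False))

    # synthetic melatonin-receptor-like outgroup: 7 hydrophobic stretches in
    # a hydrophilic background, no opsin motifs.
    hydrophobic = "AILMFVW"
    hydrophilic = "DEGHKNPQRSTY"
    parts = []
    for h in range(7):
        parts.append("".join(hydrophilic[rng.integers(len(hydrophilic))]
                             for _ in range(rng.integers(15, 30))))
        parts.append("".join(hydrophobic[rng.integers(len(hydrophobic))]
                             for _ in range(rng.integers(20, 26))))
    parts.append("".join(hydrophilic[rng.integers(len(hydrophilic))]
                         for _ in range(20)))
    outgroup = "".join(parts)

    data = pathlib.Path(__file__).resolve().parents[1] / "src/ophiopsin/data"
    data.mkdir(parents=True, exist_ok=True)

    def write_fasta(path, items):
        with open(path, "w") as fh:
            for name, seq in items:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")

    write_fasta(data / "reference_panel.fasta",
                [(pid, seqs[pid]) for pid, *_ in panel])
    with open(data / "reference_panel.tsv", "w") as fh:
        fh.write("id\tname\tfamily\tis_anchor\n")
        for pid, name, family, is_anchor in panel:
            fh.write(f"{pid}\t{name}\t{family}\t{str(is_anchor).lower()}\n")
    write_fasta(data / "outgroup_synthetic.fasta",
                [("Mel_receptor_like_synthetic", outgroup)])
    print(f"wrote fixtures to {data}")


if __name__ == "__main__":
    main()
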