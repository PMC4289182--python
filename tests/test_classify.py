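import warnings

import numpy as np
import pytest

from ophiopsin.classify import (
    FamilyCall,
    PhyloConfig,
    assign_family,
    bootstrap_support,
    build_similarity_matrix,
    name_candidates,
    nj_from_distances,
    nj_tree,
    truncate_to_core,
)
from _oracles import random_additive_matrix
from ophiopsin.diagnostics import diagnose
from ophiopsin.seqcore import InputError, ProteinSequence


def tree_distance(tree, a, b):
    return tree.find(a).distance(tree.find(b))


class TestSimilarityMatrix:
    def test_verbatim_panel_member_scores_hundred(self, panel, sc):
        ref = next(p for p in panel if p.name == "Sp-opsin 4")
        cand = ProteinSequence(id="copy", seq=ref.protein.seq)
        sim = build_similarity_matrix([cand], panel, sc)
        assert sim.similarity.loc["copy", "Sp-opsin 4"] == 100.0
        assert sim.aligned_len.loc["copy", "Sp-opsin 4"] == len(ref.protein)

    def test_no_positive_alignment_is_flagged_nan(self, panel, sc):
        cand = ProteinSequence(id="poly", seq="K" * 40)
        ref = next(p for p in panel if p.name == "Sp-opsin 4")
        lll = ProteinSequence(id="anti", seq="L" * 40)
        sim = build_similarity_matrix([cand], [type(panel[0])(
            name="anti", family="ciliary", protein=lll)], sc)
        assert np.isnan(sim.similarity.loc["poly", "anti"])
        assert sim.aligned_len.loc["poly", "anti"] == 0

    def test_hand_built_gapless_pair(self, sc):
        """30 identical + 5 group-similar + 5 dissimilar over 40 -> 87.5%."""
        from ophiopsin.references import ReferenceOpsin
        from ophiopsin.seqcore import percent_identity_and_similarity, global_align

        base = ("MKWC" * 10)[:40]
        other = list(base)
        for i in range(5):            # group-similar: K -> R (basic group)
            other[4 * i + 1] = "R"
        for i in range(5, 10):        # dissimilar: K -> G
            other[4 * i + 1] = "G"
        a = ProteinSequence(id="a", seq=base)
        b = ProteinSequence(id="b", seq="".join(other))
        aln = global_align(a, b, sc)
        assert "-" not in aln.aligned_query
        ident, sim = percent_identity_and_similarity(aln, sc)
        assert ident == 75.0
        assert sim == 87.5


class TestAssignFamily:
    def _report(self, prot, anchor, scheme, sc):
        return diagnose([prot], anchor, scheme, sc)[0]

    def test_consistent_rhabdomeric_call(self, panel, anchor, scheme, sc):
        ref = next(p for p in panel if p.name == "Sp-opsin 4")
        cand = ProteinSequence(id="r", seq=ref.protein.seq)
        sim = build_similarity_matrix([cand], panel, sc)
        rep = self._report(cand, anchor, scheme, sc)
        call = assign_family("r", sim, rep, panel, tree_neighbor_family="rhabdomeric")
        assert call.family == "rhabdomeric"
        assert call.confidence == "consistent"

    def test_triad_conflict_marks_ambiguous(self, panel, anchor, scheme, sc):
        # neuropsin-like best hit but ciliary NxQ triad: evidence disagrees
        ref = next(p for p in panel if p.name == "Sp-opsin 8")
        seq = list(ref.protein.seq)
        seq[309], seq[311] = "N", "Q"
        cand = ProteinSequence(id="n", seq="".join(seq))
        sim = build_similarity_matrix([cand], panel, sc)
        rep = self._report(cand, anchor, scheme, sc)
        call = assign_family("n", sim, rep, panel)
        assert call.family == "neuropsin"
        assert call.triad_class == "ciliary"
        assert call.confidence == "ambiguous"

    def test_candidate_absent_from_matrix_rejected(self, panel, anchor, scheme, sc):
        ref = panel[1]
        cand = ProteinSequence(id="x", seq=ref.protein.seq)
        sim = build_similarity_matrix([cand], panel, sc)
        rep = self._report(cand, anchor, scheme, sc)
        with pytest.raises(InputError):
            assign_family("missing", sim, rep, panel)

    def test_leave_one_out_recovers_multi_member_families(
        self, panel, anchor, scheme, sc
    ):
        for name in ("Sp-opsin 3.1", "Sp-opsin 3.2", "Sp-opsin 2", "Sp-opsin 5"):
            member = next(p for p in panel if p.name == name)
            rest = [p for p in panel if p.name != name]
            cand = ProteinSequence(id=name, seq=member.protein.seq)
            sim = build_similarity_matrix([cand], rest, sc)
            rep = self._report(cand, anchor, scheme, sc)
            call = assign_family(name, sim, rep, rest)
            assert call.family == member.family, name


def _call(name, ref, similarity):
    return FamilyCall(
        candidate_name=name, family="x", best_similarity_reference=ref,
        best_similarity=similarity, triad_class="other",
        tree_neighbor_family=None, confidence="consistent",
    )


class TestNaming:
    def test_two_genes_sharing_a_base_get_numeric_suffixes(self):
        names = name_candidates(
            [_call("a", "Sp-opsin 8", 80), _call("b", "Sp-opsin 8", 70)],
            prefix="Af-opsin",
        )
        assert names == {"a": "Af-opsin 8.1", "b": "Af-opsin 8.2"}

    def test_six_paralogs_ordered_by_descending_similarity(self):
        calls = [_call(f"g{i}", "Sp-opsin 4", 60 + i) for i in range(6)]
        names = name_candidates(calls)
        assert names["g5"] == "opsin 4.1"
        assert names["g0"] == "opsin 4.6"

    def test_lone_gene_keeps_bare_number(self):
        assert name_candidates([_call("a", "Sp-opsin 3.1", 77)]) == {"a": "opsin 3"}

    def test_bijection_and_determinism(self):
        calls = [_call(f"g{i}", f"Sp-opsin {1 + i % 3}", 50 + (i * 7) % 13)
                 for i in range(9)]
        n1, n2 = name_candidates(calls), name_candidates(calls)
        assert n1 == n2
        assert len(set(n1.values())) == len(n1)


class TestCoreTruncation:
    def test_truncation_anchor_keeps_its_core_interval(self, panel, sc):
        cfg = PhyloConfig()
        sp1 = next(p for p in panel if p.name == "Sp-opsin 1")
        out = truncate_to_core(
            [ProteinSequence(id="Sp-opsin 1", seq=sp1.protein.seq)], cfg, panel, sc
        )
        assert len(out[0].seq) == cfg.core_end - cfg.core_start + 1 == 290
        assert out[0].seq == sp1.protein.seq[cfg.core_start - 1 : cfg.core_end]

    def test_sequence_outside_core_excluded_with_warning(self, panel, sc):
        sp1 = next(p for p in panel if p.name == "Sp-opsin 1")
        stub = ProteinSequence(id="stub", seq=sp1.protein.seq[:60])
        with pytest.warns(UserWarning, match="no overlap"):
            out = truncate_to_core([stub], PhyloConfig(), panel, sc)
        assert out == []

    def test_insertion_inside_core_is_retained(self, panel, sc):
        sp1 = next(p for p in panel if p.name == "Sp-opsin 1")
        seq = sp1.protein.seq
        with_ins = seq[:200] + "WWWWW" + seq[200:]
        out = truncate_to_core(
            [ProteinSequence(id="ins", seq=with_ins)], PhyloConfig(), panel, sc
        )
        assert len(out[0].seq) == 295

    def test_missing_truncation_anchor_rejected(self, panel, sc):
        cfg = PhyloConfig(anchor_for_truncation="no-such-reference")
        with pytest.raises(InputError):
            truncate_to_core([], cfg, panel, sc)


class TestNeighborJoining:
    def test_known_four_taxon_tree_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4)): additive distances below
        names = ["A", "B", "C", "D"]
        D = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
                     float)
        t = nj_from_distances(names, D)
        for a, b in [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")]:
            i, j = names.index(a), names.index(b)
            assert tree_distance(t, a, b) == pytest.approx(D[i, j])
        # A,B form a cherry
        assert {x.name for x in t.find("A").parent.children} >= {"A", "B"}

    def test_three_taxa_star(self):
        D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        t = nj_from_distances(["a", "b", "c"], D)
        assert len(t.children) == 3
        assert tree_distance(t, "a", "b") == pytest.approx(2)

    def test_duplicate_sequences_make_zero_length_cherry(self, sc):
        seqs = [
            ProteinSequence(id="a", seq="MKVIWREPDS" * 4),
            ProteinSequence(id="b", seq="MKVIWREPDS" * 4),
            ProteinSequence(id="c", seq="CCHHNNQQGG" * 4),
            ProteinSequence(id="d", seq="GGAATTSSYY" * 4),
        ]
        t = nj_tree(seqs, sc)
        assert tree_distance(t, "a", "b") == pytest.approx(0, abs=1e-12)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(InputError):
            nj_from_distances(["a", "b"], np.zeros((2, 2)))

    def test_additive_matrices_recovered_exactly(self, rng):
        """Topology and branch lengths from NJ match the generating tree."""
        for _ in range(60):
            n = int(rng.integers(4, 9))
            leaves, D = random_additive_matrix(n, rng)
            t = nj_from_distances(leaves, D)
            for i in range(n):
                for j in range(i + 1, n):
                    assert tree_distance(t, leaves[i], leaves[j]) == pytest.approx(
                        D[i, j], abs=1e-9
                    )

    def test_agrees_with_skbio_reference_nj(self, rng):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        leaves, D = random_additive_matrix(7, rng)
        mine = nj_from_distances(leaves, D)
        theirs = skbio_nj(DistanceMatrix(D, ids=leaves))
        assert mine.compare_rfd(theirs) == 0


class TestBootstrap:
    def test_default_replicates(self):
        assert PhyloConfig().bootstrap_reps == 500

    def test_congruent_signal_gets_full_support(self, panel, sc):
        sp1 = next(p for p in panel if p.name == "Sp-opsin 1")
        base = sp1.protein.seq
        rng = np.random.default_rng(5)

        def mutant(seq, rate, tag):
            out = [
                c if rng.random() > rate else "AILMFWV"[rng.integers(7)]
                for c in seq
            ]
            return ProteinSequence(id=tag, seq="".join(out))

        cladeA = mutant(base, 0.3, "a_anc").seq
        cladeB = mutant(base, 0.3, "b_anc").seq
        taxa = [mutant(cladeA, 0.02, "a1"), mutant(cladeA, 0.02, "a2"),
                mutant(cladeB, 0.02, "b1"), mutant(cladeB, 0.02, "b2")]
        cfg = PhyloConfig(bootstrap_reps=100)
        tree = bootstrap_support(taxa, cfg, panel, seed=0, sc=sc)
        supports = [float(n.name) for n in tree.non_tips(include_self=False)
                    if n.name]
        assert supports and min(supports) >= 0.95

    def test_iid_columns_fixed_split_frequency_near_one_third(self, panel, sc):
        """Unstructured signal: a fixed 4-taxon split appears in ~1/3 of
        bootstrap replicates (each of the 3 resolutions equally likely)."""
        from ophiopsin.classify import (
            _bipartitions,
            _pseudo_msa_distances,
            stacked_pseudo_alignment,
        )

        sp1 = next(p for p in panel if p.name == "Sp-opsin 1")
        base = sp1.protein.seq
        rng = np.random.default_rng(11)
        cfg = PhyloConfig()
        target = frozenset({"t2", "t3"})  # the side not containing min(taxa)
        hits = reps = 0
        for _ in range(60):
            taxa = []
            for k in range(4):
                out = [c if rng.random() > 0.3 else
                       "ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)] for c in base]
                taxa.append(ProteinSequence(id=f"t{k}", seq="".join(out)))
            names, mat = stacked_pseudo_alignment(taxa, cfg, panel, sc)
            ncol = mat.shape[1]
            for _ in range(10):
                cols = rng.integers(0, ncol, size=ncol)
                t = nj_from_distances(names, _pseudo_msa_distances(mat[:, cols]))
                reps += 1
                hits += target in _bipartitions(t, frozenset(names))
        assert 0.22 <= hits / reps <= 0.45
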