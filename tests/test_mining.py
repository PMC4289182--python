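import numpy as np
import pytest

from ophiopsin.mining import (
    OpsinCandidate,
    TmConfig,
    TranslatedHit,
    merge_nonoverlapping_fragments,
    predict_tm_helices,
    reciprocal_best_hit,
    translated_search,
)
from ophiopsin.references import DiagnosticScheme
from ophiopsin.seqcore import (
    InputError,
    NucleotideSequence,
    ProteinSequence,
    reverse_complement,
    translate_six_frames,
)
from ophiopsin.synthetic import (
    GeneSpec,
    SyntheticSpec,
    _back_translate,
    generate_assembly,
)


def _random_contig(rng, n=600, id="bg"):
    return NucleotideSequence(id=id, seq="".join("ACGT"[i] for i in rng.integers(0, 4, n)))


class TestTranslatedSearch:
    def test_exact_cds_copy_found_with_full_reference_coverage(self, panel, rng):
        ref = next(p for p in panel if p.name == "Sp-opsin 4")
        cds = _back_translate(ref.protein.seq, rng)
        contig = NucleotideSequence(id="c1", seq="A" * 30 + cds + "C" * 30)
        hits = translated_search([contig], [ref])
        best = max(hits, key=lambda h: h.score)
        assert best.frame == 1 + 30 % 3  # offset 30 -> frame +1
        assert best.reference_span == (1, len(ref.protein))
        assert best.contig_span == (31, 30 + len(cds))
        # span round-trip: the nucleotide interval re-translates to the segment
        sub = contig.seq[best.contig_span[0] - 1 : best.contig_span[1]]
        assert translate_six_frames(NucleotideSequence(id="s", seq=sub))[0].seq \
            == best.protein.seq

    def test_reverse_strand_hit_has_negative_frame(self, panel, rng):
        ref = next(p for p in panel if p.name == "Sp-opsin 4")
        cds = _back_translate(ref.protein.seq, rng)
        fwd = NucleotideSequence(id="c1", seq="A" * 31 + cds + "C" * 30)
        rev = reverse_complement(fwd)
        rev = NucleotideSequence(id="c2", seq=rev.seq)
        hits = translated_search([rev], [ref])
        best = max(hits, key=lambda h: h.score)
        assert best.frame < 0
        assert best.reference_span == (1, len(ref.protein))

    def test_random_contigs_yield_no_hits_at_default_threshold(self, panel, rng):
        contigs = [_random_contig(rng, 900, f"bg{i}") for i in range(8)]
        assert translated_search(contigs, panel) == []

    def test_prefilter_equivalent_to_exhaustive(self, panel, rng):
        ref = next(p for p in panel if p.name == "Sp-opsin 8")
        cds = _back_translate(ref.protein.seq, rng)
        contigs = [
            NucleotideSequence(id="c1", seq="G" * 20 + cds + "T" * 20),
            _random_contig(rng, 700, "bg"),
        ]
        exhaustive = translated_search(contigs, panel)
        prefiltered = translated_search(contigs, panel, seed_prefilter=True)
        assert exhaustive == prefiltered

    def test_empty_panel_rejected(self):
        with pytest.raises(InputError):
            translated_search([], [])


class TestReciprocalBestHit:
    def test_verbatim_panel_member_confirms_itself(self, panel, outgroup):
        ref = next(p for p in panel if p.name == "Sp-opsin 4")
        best, ok = reciprocal_best_hit(ref.protein, panel, [outgroup])
        assert best.name == "Sp-opsin 4" and ok

    def test_decoy_gpcr_fails_reverse_check(self, panel, outgroup, rng):
        # a melatonin-receptor-like candidate: reverse top hit is the decoy class
        best, ok = reciprocal_best_hit(outgroup, panel, [outgroup])
        assert not ok

    def test_empty_candidate_rejected(self, panel, outgroup):
        with pytest.raises(InputError):
            reciprocal_best_hit(None or ProteinSequence(id="x", seq="M"), [], [])


class TestTmHelices:
    def test_single_hydrophobic_stretch(self):
        p = ProteinSequence(id="p", seq="D" * 10 + "L" * 25 + "D" * 10)
        assert len(predict_tm_helices(p)) == 1

    def test_all_hydrophilic_has_none(self):
        assert predict_tm_helices(ProteinSequence(id="p", seq="D" * 60)) == []

    def test_anchor_has_seven_helices_under_default_config(self, anchor):
        assert len(predict_tm_helices(anchor.protein)) == 7

    def test_short_fragment_warns_instead_of_failing(self):
        with pytest.warns(UserWarning):
            out = predict_tm_helices(ProteinSequence(id="p", seq="MKVI"))
        assert out == []

    def test_intervals_sorted_and_disjoint(self, rng):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(20):
            seq = "".join(aas[i] for i in rng.integers(0, 20, 200))
            helices = predict_tm_helices(ProteinSequence(id="p", seq=seq))
            for (a0, a1), (b0, b1) in zip(helices, helices[1:]):
                assert a1 < b0

    def test_even_window_rejected(self):
        with pytest.raises(InputError):
            TmConfig(window=10)


def _hit(ref, span, contig="c", frame=1, cspan=None, score=500.0):
    n = span[1] - span[0] + 1
    return TranslatedHit(
        contig_id=contig, frame=frame,
        contig_span=cspan or (span[0] * 3, span[1] * 3 + 2),
        reference_name=ref, reference_span=span, score=score,
        protein=ProteinSequence(id="f", seq="M" * n),
    )


class TestFragmentMerging:
    def test_disjoint_fragments_of_one_reference_merge(self):
        hits = [_hit("Sp-opsin 7", (10, 120), contig="c1"),
                _hit("Sp-opsin 7", (200, 310), contig="c2")]
        cands = merge_nonoverlapping_fragments(hits)
        assert len(cands) == 1
        assert len(cands[0].fragments) == 2
        assert cands[0].reference_coverage == [(10, 120), (200, 310)]

    def test_substantially_overlapping_fragments_stay_separate(self):
        hits = [_hit("Sp-opsin 4", (10, 200), contig="c1"),
                _hit("Sp-opsin 4", (150, 310), contig="c2")]
        assert len(merge_nonoverlapping_fragments(hits)) == 2

    def test_different_references_never_merge(self):
        hits = [_hit("Sp-opsin 7", (10, 120), contig="c1"),
                _hit("Sp-opsin 8", (200, 310), contig="c2")]
        assert len(merge_nonoverlapping_fragments(hits)) == 2

    def test_merging_groups_without_losing_fragments(self, rng):
        refs = ["Sp-opsin 4", "Sp-opsin 7", "Sp-opsin 8"]
        hits = []
        for k in range(12):
            a = int(rng.integers(1, 300))
            b = a + int(rng.integers(10, 60))
            hits.append(_hit(refs[k % 3], (a, b), contig=f"c{k}"))
        cands = merge_nonoverlapping_fragments(hits)
        assert sum(len(c.fragments) for c in cands) == len(hits)
        assert len(cands) <= len(hits)

    def test_merged_protein_concatenates_in_reference_order(self):
        ha = _hit("Sp-opsin 7", (200, 204), contig="c2")
        hb = _hit("Sp-opsin 7", (10, 14), contig="c1")
        ha = TranslatedHit(**{**ha.__dict__, "protein": ProteinSequence(id="a", seq="WWWWW")})
        hb = TranslatedHit(**{**hb.__dict__, "protein": ProteinSequence(id="b", seq="CCCCC")})
        cand = merge_nonoverlapping_fragments([ha, hb])[0]
        assert cand.merged_protein.seq == "CCCCC" + "WWWWW"
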