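"""Family assignment, true-gene filtering, LINE 3'-UTR similarity."""

import pytest

import sinescout as ss
from sinescout.classify import (
    ConfigurationError,
    Thresholds,
    classify_element,
    line_3prime_similarity,
    true_gene_filter,
)


def trna_refs(catalogue):
    """Heads of the tRNA-derived elements, used as tRNA references."""
    return ss.Catalogue(
        [
            ss.ElementRecord(id=r.id + "-head", seq=r.seq[:80], origin_label=r.origin_label)
            for r in catalogue
            if r.id.startswith("AfuSINE2")
        ]
    )


class TestClassifyElement:
    def test_fixture_5s_elements_called_sine3(self, catalogue, sine3_head_refs):
        for rec in catalogue:
            if rec.id.startswith("AfuSINE3"):
                res = classify_element(rec, refs_5s=sine3_head_refs)
                assert res.family == "SINE3"
                assert res.origin_call == "5S"

    def test_fixture_trna_elements_not_called_sine3(self, catalogue, sine3_head_refs):
        """No tRNA-derived element satisfies the 5S head rule; with the
        promoter fallback disabled they all stay unclassified."""
        for rec in catalogue:
            if rec.id.startswith("AfuSINE2"):
                res = classify_element(rec, refs_5s=sine3_head_refs, motif_models={})
                assert res.family == "unclassified"

    def test_trna_head_gives_sine2_with_isotype(self, catalogue, sine3_head_refs):
        refs = trna_refs(catalogue)
        rec = catalogue["AfuSINE2-1a"]
        res = classify_element(rec, refs_trna=refs, refs_5s=sine3_head_refs)
        assert res.family == "SINE2"
        assert res.origin_call == "Arg"  # isotype from the winning reference
        assert res.head_alignment.identity_pct == 100.0

    def test_synthetic_head_copy_classified(self, rng):
        ref_head = ss.random_sequence(80, 0.5, rng)
        refs = ss.Catalogue(
            [ss.ElementRecord(id="t1", seq=ref_head, origin_label="tRNA/Leu")]
        )
        cand = ss.ElementRecord(
            id="c", seq=ss.mutate(ref_head, 0.10, 7) + ss.random_sequence(150, 0.5, rng)
        )
        res = classify_element(cand, refs_trna=refs, motif_models={})
        assert res.family == "SINE2" and res.origin_call == "Leu"

    def test_random_sequence_unclassified(self, rng, catalogue, sine3_head_refs):
        cand = ss.ElementRecord(id="r", seq=ss.random_sequence(300, 0.5, rng))
        res = classify_element(
            cand, refs_trna=trna_refs(catalogue), refs_5s=sine3_head_refs, motif_models={}
        )
        assert res.family == "unclassified"

    def test_promoter_fallback_calls_sine2(self, rng):
        lead = ss.random_sequence(20, 0.5, rng)
        seq = (
            lead
            + "TAGCGTAGTGG"
            + ss.random_sequence(30, 0.5, rng)
            + "GATTGGTGACC"
            + ss.random_sequence(100, 0.5, rng)
        )
        res = classify_element(ss.ElementRecord(id="p", seq=seq))
        assert res.family == "SINE2"
        assert res.promoter_type == "type2"
        assert res.origin_call is None  # no reference evidence for an isotype

    def test_no_refs_and_no_models_rejected(self):
        with pytest.raises(ConfigurationError):
            classify_element(ss.ElementRecord(id="x", seq="ACGT" * 30), motif_models={})

    def test_threshold_monotonicity(self, catalogue, sine3_head_refs):
        """Loosening the head thresholds never turns a SINE3 call into
        unclassified."""
        loose = Thresholds(id_threshold=50.0, overlap_threshold=30)
        for rec in catalogue:
            strict = classify_element(rec, refs_5s=sine3_head_refs, motif_models={})
            relaxed = classify_element(
                rec, refs_5s=sine3_head_refs, thresholds=loose, motif_models={}
            )
            if strict.family == "SINE3":
                assert relaxed.family == "SINE3"

    def test_reference_order_invariance(self, catalogue, sine3_head_refs):
        refs_rev = ss.Catalogue(list(sine3_head_refs)[::-1])
        for rec in catalogue:
            a = classify_element(rec, refs_5s=sine3_head_refs, motif_models={})
            b = classify_element(rec, refs_5s=refs_rev, motif_models={})
            assert a.family == b.family
            if a.head_alignment and b.head_alignment:
                assert a.head_alignment.identity_pct == b.head_alignment.identity_pct


class TestTrueGeneFilter:
    def test_identical_to_reference_gene_discarded(self, rng):
        gene = ss.random_sequence(120, 0.5, rng)
        refs = [ss.ElementRecord(id="gene", seq=gene)]
        assert not true_gene_filter(ss.ElementRecord(id="c", seq=gene), refs)

    def test_derived_element_kept(self, catalogue, rng):
        """A fixture element is NOT a full 5S gene: pad a 5S-like gene with
        sequence the element does not carry and the filter keeps it."""
        gene = catalogue["AfuSINE3-1a"].seq[:100] + ss.random_sequence(60, 0.5, rng)
        refs = [ss.ElementRecord(id="r5s_gene", seq=gene)]
        assert true_gene_filter(catalogue["AfuSINE3-1a"], refs)

    def test_exclusion_interval_discards(self, rng):
        cand = ss.ElementRecord(id="c", seq=ss.random_sequence(100, 0.5, rng))
        keep = true_gene_filter(
            cand,
            [],
            candidate_interval=("chr1", 1000, 1100),
            exclusion_intervals=[("chr1", 1040, 1200)],
        )
        assert not keep  # 60% of the candidate overlaps the annotation
        keep = true_gene_filter(
            cand,
            [],
            candidate_interval=("chr1", 1000, 1100),
            exclusion_intervals=[("chr2", 1040, 1200), ("chr1", 1090, 1200)],
        )
        assert keep  # wrong contig / only 10% overlap

    def test_no_refs_no_exclusions_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            true_gene_filter(ss.ElementRecord(id="c", seq="ACGT" * 10), [])


class TestLine3PrimeSimilarity:
    def test_planted_utr_match(self, rng):
        utr = ss.random_sequence(120, 0.5, rng)
        cand = ss.ElementRecord(id="c", seq=ss.random_sequence(200, 0.5, rng) + utr)
        refs = ss.Catalogue([ss.ElementRecord(id="line1", seq=utr)])
        aln = line_3prime_similarity(cand, refs)
        assert aln.identity_pct == 100.0 and aln.overlap_nt == 120
        assert aln.subject_id == "line1"

    def test_best_reference_wins(self, rng):
        utr = ss.random_sequence(100, 0.5, rng)
        cand = ss.ElementRecord(id="c", seq=ss.random_sequence(100, 0.5, rng) + utr)
        refs = ss.Catalogue(
            [
                ss.ElementRecord(id="far", seq=ss.random_sequence(100, 0.5, rng)),
                ss.ElementRecord(id="near", seq=ss.mutate(utr, 0.05, 3)),
            ]
        )
        aln = line_3prime_similarity(cand, refs)
        assert aln.subject_id == "near"

    def test_empty_reference_set_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            line_3prime_similarity(
                ss.ElementRecord(id="c", seq="ACGT" * 50), ss.Catalogue([])
            )
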