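"""Genome-scale scanning: copy mapping, boundary extension, de-novo
discovery and distribution reports."""

import pytest

import sinescout as ss
from sinescout.motifs import MotifModel, reverse_complement
from sinescout.scan import (
    ExtendedWindow,
    Locus,
    ScanParams,
    discover_candidates,
    distribution_report,
    extend_boundaries,
    map_copies,
)

from .oracles import binomial_tail


def naive_exact_loci(query, genome):
    """Exact substring occurrences of query on both strands (oracle)."""
    out = []
    for rec in genome:
        for strand, target in (("+", rec.seq), ("-", reverse_complement(rec.seq))):
            i = target.find(query)
            while i != -1:
                s, e = i, i + len(query)
                if strand == "-":
                    s, e = len(target) - e, len(target) - s
                out.append((rec.id, s, e, strand))
                i = target.find(query, i + 1)
    return sorted(out)


class TestMapCopies:
    def test_empty_genome_region(self, rng):
        genome = ss.Catalogue([ss.ElementRecord(id="c1", seq=ss.random_sequence(5000, 0.5, rng))])
        elem = ss.ElementRecord(id="e", seq=ss.random_sequence(200, 0.5, rng))
        assert map_copies(elem, genome) == []

    def test_planted_copies_found_exactly(self):
        cfg = ss.SimConfig(seed=1, contig_lengths=(50_000,), copies_per_element=5)
        genome, truth, families = ss.simulate_genome(cfg)
        loci = map_copies(families[0], genome)
        assert len(loci) == 5
        got = sorted((l.start, l.end) for l in loci)
        want = sorted((t.start, t.end) for t in truth)
        assert got == want
        assert all(l.identity_pct == 100.0 for l in loci)

    def test_exact_mode_matches_substring_oracle(self, rng):
        elem_seq = ss.random_sequence(150, 0.5, rng)
        bg = ss.random_sequence(8000, 0.5, rng)
        genome = ss.Catalogue(
            [
                ss.ElementRecord(
                    id="c1",
                    seq=bg[:2000] + elem_seq + bg[2000:5000]
                    + reverse_complement(elem_seq) + bg[5000:],
                )
            ]
        )
        params = ScanParams(min_identity=100.0, min_coverage=1.0)
        loci = map_copies(ss.ElementRecord(id="e", seq=elem_seq), genome, params)
        got = sorted((l.contig, l.start, l.end, l.strand) for l in loci)
        assert got == naive_exact_loci(elem_seq, genome)

    def test_fixture_element_unique_in_concatenated_catalogue(self, catalogue):
        """Each published element occurs once in a genome built by
        concatenating all 13 with random-free spacers of N-less sequence."""
        joined = "GGGGCCCC".join(r.seq for r in catalogue)
        genome = ss.Catalogue([ss.ElementRecord(id="cat", seq=joined)])
        loci = map_copies(catalogue["AfuSINE2-7e"], genome)
        exact = [l for l in loci if l.identity_pct == 100.0 and l.query_coverage == 1.0]
        assert len(exact) == 1

    def test_recall_at_ten_percent_divergence(self):
        cfg = ss.SimConfig(
            seed=11, contig_lengths=(60_000,), n_elements=2,
            copies_per_element=5, divergence=0.10,
        )
        genome, truth, families = ss.simulate_genome(cfg)
        found = 0
        for fam in families:
            loci = map_copies(fam, genome)
            for t in (t for t in truth if t.family_id == fam.id):
                if any(
                    l.contig == t.contig and l.start < t.end and t.start < l.end
                    for l in loci
                ):
                    found += 1
        assert found >= 0.95 * len(truth)

    def test_minus_strand_copies_reported_with_strand(self):
        cfg = ss.SimConfig(seed=5, copies_per_element=6, minus_strand_fraction=1.0)
        genome, truth, families = ss.simulate_genome(cfg)
        loci = map_copies(families[0], genome)
        assert len(loci) == 6 and all(l.strand == "-" for l in loci)

    def test_short_element_rejected(self, rng):
        genome = ss.Catalogue([ss.ElementRecord(id="c", seq=ss.random_sequence(1000, 0.5, rng))])
        with pytest.raises(ValueError):
            map_copies(ss.ElementRecord(id="e", seq="ACGTACGT"), genome)


class TestExtendBoundaries:
    def make_genome(self, rng, n=10_000):
        return ss.Catalogue([ss.ElementRecord(id="c1", seq=ss.random_sequence(n, 0.5, rng))])

    def test_plus_strand_margins(self, rng):
        genome = self.make_genome(rng)
        loc = Locus("c1", 5000, 5300, "+", 100.0, 1.0, "e")
        win = extend_boundaries(loc, genome, extend_up=1000, extend_down=2000)
        assert (win.start, win.end) == (4000, 7300)
        assert win.seq == genome["c1"].seq[4000:7300]
        assert win.seq[win.locus_offset : win.locus_offset + 300] == genome["c1"].seq[5000:5300]

    def test_clipping_at_contig_start(self, rng):
        genome = self.make_genome(rng)
        loc = Locus("c1", 200, 500, "+", 100.0, 1.0, "e")
        win = extend_boundaries(loc, genome)
        assert win.start == 0 and win.locus_offset == 200

    def test_minus_strand_orientation(self, rng):
        genome = self.make_genome(rng)
        loc = Locus("c1", 5000, 5300, "-", 100.0, 1.0, "e")
        win = extend_boundaries(loc, genome, extend_up=1000, extend_down=2000)
        # upstream of a minus-strand element is genomic rightward
        assert (win.start, win.end) == (3000, 6300)
        elem = win.seq[win.locus_offset : win.locus_offset + 300]
        assert elem == reverse_complement(genome["c1"].seq[5000:5300])


# Strict zero-mismatch box models matching the simulator's default element
# template: the right setting for false-positive budgeting under the i.i.d.
# null, where degenerate consensi with mismatch budgets would fire by chance.
STRICT_MODELS = {
    "A_box": MotifModel("A_box", "TAGCGTAGTGG", 0),
    "B_box": MotifModel("B_box", "GATTGGTGACC", 0),
}


class TestDiscoverCandidates:
    def test_null_genome_nearly_clean(self, rng):
        genome = ss.Catalogue(
            [ss.ElementRecord(id="c1", seq=ss.random_sequence(100_000, 0.5, rng))]
        )
        cands = discover_candidates(genome, STRICT_MODELS)
        assert len(cands) <= 1  # chance promoter-like pairs are rare

    def test_planted_elements_recovered_with_boundaries(self):
        cfg = ss.SimConfig(seed=3, contig_lengths=(100_000,), copies_per_element=10)
        genome, truth, _ = ss.simulate_genome(cfg)
        cands = discover_candidates(genome, STRICT_MODELS)
        hit = 0
        for t in truth:
            for c in cands:
                loc = c.source_interval
                if (
                    loc.contig == t.contig
                    and abs(loc.start - t.start) <= 10
                    and abs(loc.end - t.end) <= 10
                ):
                    hit += 1
                    break
        assert hit >= 9

    def test_recovered_tsds_sit_at_insertion_junctions(self):
        """Every recovered candidate reports a flanking TSD, and the
        reported repeat lies in the true upstream junction. Candidates
        start at the A box (inside the element), so the reported repeat
        may be a shifted form of the planted TSD rather than equal to it."""
        cfg = ss.SimConfig(seed=3, contig_lengths=(100_000,), copies_per_element=10)
        genome, truth, _ = ss.simulate_genome(cfg)
        cands = discover_candidates(genome, STRICT_MODELS)
        good = 0
        for t in truth:
            for c in cands:
                loc = c.source_interval
                if loc.contig == t.contig and abs(loc.start - t.start) <= 10:
                    tag = c.chromosome_tag
                    if ";tsd=" in tag:
                        tsd = tag.split(";tsd=")[1]
                        junction = genome[t.contig].seq[t.start - 30 : t.start + 30]
                        if tsd in junction:
                            good += 1
                    break
        assert good >= 9

    def test_all_n_contig_yields_nothing(self):
        genome = ss.Catalogue([ss.ElementRecord(id="n", seq="N" * 5000)])
        assert len(discover_candidates(genome, STRICT_MODELS)) == 0


class TestDistributionReport:
    def test_per_contig_counts(self):
        loci = [Locus("c1", 0, 100, "+", 90.0, 1.0)] * 3 + [
            Locus("c2", 0, 100, "+", 90.0, 1.0)
        ]
        df = distribution_report(loci)
        assert dict(zip(df["contig"], df["n_loci"])) == {"c1": 3, "c2": 1}

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            distribution_report(
                [], region_bed=[("c1", 0, 100, "a"), ("c1", 50, 200, "b")]
            )

    def test_enrichment_matches_binomial_oracle(self):
        regions = [("c1", 0, 10_000, "subtelomeric"), ("c1", 10_000, 100_000, "core")]
        loci = [Locus("c1", i * 500, i * 500 + 100, "+", 90.0, 1.0) for i in range(12)]
        df = distribution_report(loci, regions).set_index("label")
        k = int(df.loc["subtelomeric", "n_loci"])
        assert df.loc["subtelomeric", "enrichment_p"] == pytest.approx(
            binomial_tail(k, 12, 0.1)
        )

    def test_strong_clustering_is_significant(self):
        regions = [("c1", 0, 10_000, "subtelomeric"), ("c1", 10_000, 100_000, "core")]
        loci = [Locus("c1", i * 400, i * 400 + 100, "+", 90.0, 1.0) for i in range(20)]
        df = distribution_report(loci, regions).set_index("label")
        assert df.loc["subtelomeric", "n_loci"] == 20
        assert df.loc["subtelomeric", "enrichment_p"] < 0.01
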