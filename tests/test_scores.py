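"""The four component scores: worked values, bounds, monotonicity, oracles."""

import logging

import pytest
from hypothesis import given
from hypothesis import strategies as st

from genoscore import (
    AssemblyMetrics,
    ComponentScores,
    Contig,
    DomainHit,
    FeatureSet,
    GenomeAssembly,
    RRNAGene,
    ScoringConfig,
    STANDARD_AMINO_ACIDS,
    TRNAGene,
    compute_assembly_metrics,
    essential_gene_score,
    raw_combined,
    rrna_score,
    score_genome,
    sequence_quality_score,
    trna_score,
)


def metrics(good=0, bad=0, n=0, contigs=1, gaps=0, gap_bases=0):
    return AssemblyMetrics(good, bad, n, contigs, gaps, gap_bases,
                           good + bad + n + gap_bases)


class TestSequenceQuality:
    @pytest.mark.parametrize(
        "m, status, expected",
        [
            # clean single-contig draft: no penalty terms
            (metrics(good=1_000_000), "draft", 1.0),
            # two clean contigs: one 10 kb contig penalty
            (metrics(good=2_000_000, contigs=2), "draft", 2_000_000 / 2_010_000),
            # complete status exempts the contig penalty entirely
            (metrics(good=5_000_000, contigs=3), "complete", 1.0),
            # one gap: 10 kb gap penalty
            (metrics(good=1_000_000, gaps=1, gap_bases=15), "draft",
             1_000_000 / 1_010_000),
            # complete genomes still pay for gaps
            (metrics(good=1_000_000, contigs=3, gaps=1, gap_bases=15), "complete",
             1_000_000 / 1_010_000),
            # bad bases land in the denominator only
            (metrics(good=999_000, bad=1_000), "draft", 999_000 / 1_000_000),
        ],
    )
    def test_worked_values(self, m, status, expected, config):
        assert sequence_quality_score(m, status, config) == pytest.approx(expected)

    def test_degenerate_assembly_scores_zero_with_warning(self, config, caplog):
        with caplog.at_level(logging.WARNING, logger="genoscore.scores"):
            assert sequence_quality_score(metrics(good=0, bad=50), "draft", config) == 0.0
        assert "degenerate" in caplog.text

    def test_penalties_are_monotone(self, config):
        base = sequence_quality_score(metrics(good=10**6), "draft", config)
        more_contigs = sequence_quality_score(metrics(good=10**6, contigs=2), "draft", config)
        more_gaps = sequence_quality_score(metrics(good=10**6, gaps=1), "draft", config)
        more_bad = sequence_quality_score(metrics(good=10**6, bad=100), "draft", config)
        assert more_contigs < base and more_gaps < base and more_bad < base

    @given(
        st.lists(st.text(alphabet="ACGTNR", min_size=1, max_size=120), min_size=1, max_size=5),
        st.sampled_from(["draft", "complete"]),
    )
    def test_matches_character_level_oracle(self, seqs, status):
        """Score equals a brute-force recomputation from the raw characters."""
        asm = GenomeAssembly("h", [Contig(f"c{i}", s) for i, s in enumerate(seqs)],
                             status=status)
        config = ScoringConfig()
        m = compute_assembly_metrics(asm, config)
        # brute force: rebuild the denominator character by character
        good = sum(ch in "ACGT" for s in seqs for ch in s)
        bad = sum(ch not in "ACGTN" for s in seqs for ch in s)
        gaps = 0
        for s in seqs:
            run = 0
            for ch in s + "$":
                if ch == "N":
                    run += 1
                else:
                    if run >= 10:
                        gaps += 1
                    run = 0
        if good == 0:
            expected = 0.0
        else:
            den = good + bad + 10_000 * gaps
            if status == "draft":
                den += 10_000 * (len(seqs) - 1)
            expected = good / den
        assert sequence_quality_score(m, status, config) == pytest.approx(expected)

    def test_scale_invariance_of_clean_draft(self, config):
        """Doubling every contig (same contig count) barely moves the score."""
        small = metrics(good=2_000_000, contigs=2)
        large = metrics(good=4_000_000, contigs=2)
        s1 = sequence_quality_score(small, "draft", config)
        s2 = sequence_quality_score(large, "draft", config)
        assert abs(s1 - s2) < 0.005
        assert s2 > s1  # penalties dilute with size


class TestRRNAScore:
    def test_no_predictions_floor(self, config):
        assert rrna_score([], config) == pytest.approx(0.1)

    def test_all_ideal_is_perfect(self, config):
        rrnas = [RRNAGene("16S", 1550), RRNAGene("23S", 3000), RRNAGene("5S", 110)]
        assert rrna_score(rrnas, config) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "length, expected",
        [
            (1550, 0.4),   # ideal window
            (800, 0.3),    # > half of 1450
            (726, 0.3),    # just above 725
            (725, 0.2),    # exactly half: not strictly greater
            (100, 0.2),    # any prediction at all
            (2400, 0.3),   # over-long: still the half tier
        ],
    )
    def test_single_16s_tiers(self, length, expected, config):
        assert rrna_score([RRNAGene("16S", length)], config) == pytest.approx(expected)

    def test_best_prediction_per_type_wins(self, config):
        rrnas = [RRNAGene("16S", 90), RRNAGene("16S", 1500), RRNAGene("16S", 800)]
        assert rrna_score(rrnas, config) == pytest.approx(0.4)

    def test_overlong_prediction_is_logged(self, config, caplog):
        with caplog.at_level(logging.WARNING, logger="genoscore.scores"):
            rrna_score([RRNAGene("16S", 2400)], config)
        assert "over-long" in caplog.text

    def test_adding_a_prediction_never_decreases(self, config):
        base = [RRNAGene("16S", 800)]
        for extra in (RRNAGene("16S", 1500), RRNAGene("5S", 3), RRNAGene("23S", 3000)):
            assert rrna_score(base + [extra], config) >= rrna_score(base, config)

    def test_lattice_of_attainable_values(self, config):
        # every score is 0.1 + a sum of three tiers from {0, .1, .2, .3}
        attainable = {
            round(0.1 + a + b + c, 10)
            for a in (0, 0.1, 0.2, 0.3)
            for b in (0, 0.1, 0.2, 0.3)
            for c in (0, 0.1, 0.2, 0.3)
        }
        cases = [
            [],
            [RRNAGene("16S", 1550)],
            [RRNAGene("16S", 10), RRNAGene("5S", 110)],
            [RRNAGene("16S", 800), RRNAGene("23S", 3000), RRNAGene("5S", 50)],
        ]
        for rrnas in cases:
            assert round(rrna_score(rrnas, config), 10) in attainable


def cover(amino_acids, pseudo=False):
    return [TRNAGene(aa, None, pseudo) for aa in amino_acids]


class TestTRNAScore:
    def test_full_coverage(self):
        assert trna_score(cover(STANDARD_AMINO_ACIDS)) == pytest.approx(1.0)

    @pytest.mark.parametrize("n_missing, expected", [(1, 0.9), (3, 0.7), (8, 0.2)])
    def test_decrement_per_missing(self, n_missing, expected):
        covered = STANDARD_AMINO_ACIDS[: 20 - n_missing]
        assert trna_score(cover(covered)) == pytest.approx(expected)

    @pytest.mark.parametrize("n_missing", [9, 10, 15, 20])
    def test_floor_at_nine_or_more_missing(self, n_missing):
        covered = STANDARD_AMINO_ACIDS[: 20 - n_missing]
        assert trna_score(cover(covered)) == pytest.approx(0.1)

    def test_pseudo_never_counts(self):
        trnas = cover(STANDARD_AMINO_ACIDS[:19]) + cover(["Val"], pseudo=True)
        assert "Val" not in STANDARD_AMINO_ACIDS[:19]
        assert trna_score(trnas) == pytest.approx(0.9)

    def test_optional_types_are_outside_the_twenty(self):
        trnas = cover(STANDARD_AMINO_ACIDS) + [TRNAGene("SeC", "TCA"), TRNAGene("other")]
        assert trna_score(trnas) == pytest.approx(1.0)
        assert trna_score([TRNAGene("SeC", "TCA")]) == pytest.approx(0.1)

    def test_values_form_the_expected_lattice(self):
        values = {
            round(trna_score(cover(STANDARD_AMINO_ACIDS[:k])), 10) for k in range(21)
        }
        assert values == {round(0.1 * k, 10) for k in range(1, 11)}


class TestEssentialGeneScore:
    def test_all_present(self, config):
        hits = [DomainHit(a) for a in config.essential_domains]
        assert essential_gene_score(hits, config) == pytest.approx(1.0)

    def test_ten_missing_of_102(self, config):
        hits = [DomainHit(a) for a in config.essential_domains[:-10]]
        assert essential_gene_score(hits, config) == pytest.approx(0.90)

    def test_floor_when_nearly_all_missing(self, config):
        hits = [DomainHit(a) for a in config.essential_domains[:7]]  # 95 missing
        assert essential_gene_score(hits, config) == pytest.approx(0.1)

    def test_copies_do_not_add(self, config):
        one = config.essential_domains[0]
        hits = [DomainHit(one, f"g{i}") for i in range(50)]
        missing = len(config.essential_domains) - 1
        assert essential_gene_score(hits, config) == pytest.approx(
            max(0.1, 1.0 - 0.01 * missing)
        )

    def test_versioned_accessions_match(self, config):
        hits = [DomainHit(a + ".14") for a in config.essential_domains]
        assert essential_gene_score(hits, config) == pytest.approx(1.0)

    def test_off_panel_hits_are_ignored(self, config):
        assert essential_gene_score([DomainHit("PF99999")], config) == pytest.approx(
            essential_gene_score([], config)
        )


class TestRawCombined:
    def test_mean_of_four(self):
        assert raw_combined(0.0, 0.1, 0.1, 0.1) == pytest.approx(0.075)
        assert raw_combined(1.0, 1.0, 1.0, 1.0) == 1.0

    @given(st.permutations([0.3, 0.55, 0.7, 1.0]))
    def test_permutation_invariant(self, values):
        assert raw_combined(*values) == pytest.approx(raw_combined(0.3, 0.55, 0.7, 1.0))


class TestScoreGenome:
    def test_component_scores_are_consistent(self, config):
        asm = GenomeAssembly("g", [Contig("c1", "ACGT" * 50_000)], status="draft")
        fs = FeatureSet(
            "g",
            trnas=cover(STANDARD_AMINO_ACIDS),
            rrnas=[RRNAGene("5S", 110), RRNAGene("16S", 1550), RRNAGene("23S", 3000)],
            domains=[DomainHit(a) for a in config.essential_domains],
        )
        scores = score_genome(asm, fs, config)
        assert isinstance(scores, ComponentScores)
        assert scores.raw_combined == pytest.approx(
            (scores.sequence_quality + scores.rrna + scores.trna + scores.essential) / 4
        )
        assert scores.raw_combined == pytest.approx(1.0)
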