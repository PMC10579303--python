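"""Synthetic community generator: presets, expectations, sampling, FASTA."""

import math

import pytest

from nitriquant import (CommunityTruth, ConfigurationError,
                        FeatureLookupError, InputDataError, LineageSpec,
                        SimulationConfig, emit_marker_fasta, expected_count,
                        generate_community, pairwise_identity,
                        simulate_counts, estimate_guild_proportions)
from conftest import make_lineage


class TestLineageSpec:
    def test_rpob_must_be_single_copy(self):
        with pytest.raises(InputDataError, match="rpoB"):
            LineageSpec(name="X", family="F", order="O", cell_abundance=1.0,
                        gene_copies={"rpoB": 2.0},
                        expression_rate={"rpoB": 1.0})

    def test_carried_gene_needs_expression_rate(self):
        with pytest.raises(InputDataError, match="expression rate"):
            make_lineage("X", 1.0, {"amoA": 1.0}, {})

    def test_all_zero_abundance_rejected(self):
        lin = make_lineage("X", 0.0, {}, {})
        with pytest.raises(InputDataError, match="zero"):
            CommunityTruth(lineages=(lin,), background_rpob=0.0,
                           marker_lengths={"rpoB": 100})


class TestGenerateCommunity:
    def test_single_uniform_lineage_is_degenerate(self):
        truth = generate_community(1, seed=1, profile="uniform")
        assert len(truth.lineages) == 1
        assert truth.lineages[0].cell_abundance == 1.0
        assert truth.lineages[0].gene_copies["rpoB"] == 1

    def test_soil_like_guild_ordering(self):
        truth = generate_community(4, seed=7, profile="soil-like")
        p = truth.true_guild_proportions()
        assert p["AOA"] > p["comammox"] > p["AOB"]
        assert truth.background_rpob > sum(
            l.cell_abundance for l in truth.lineages)

    def test_seed_determinism(self):
        a = generate_community(3, seed=5, profile="soil-like")
        b = generate_community(3, seed=5, profile="soil-like")
        assert a == b

    def test_unknown_profile_rejected(self):
        with pytest.raises(ConfigurationError, match="profile"):
            generate_community(2, seed=0, profile="marine")

    def test_scale_invariance_of_true_proportions(self):
        truth = generate_community(5, seed=2, profile="soil-like")
        doubled = truth.scaled(2.0)
        for guild, p in truth.true_guild_proportions().items():
            assert doubled.true_guild_proportion(guild) == pytest.approx(
                p, rel=1e-14)


class TestExpectedCount:
    def test_zero_copies_gives_zero(self, two_marker_truth):
        assert expected_count(two_marker_truth, "L1", "rpoB", "DNA",
                              1000) > 0
        lin = make_lineage("L2", 1.0, {"g1": 0.0}, {"g1": 1.0})
        truth = CommunityTruth(lineages=(lin,), background_rpob=0.0,
                               marker_lengths={"rpoB": 2000, "g1": 1000})
        assert expected_count(truth, "L2", "g1", "DNA", 1000) == 0.0

    def test_abundance_proportionality(self):
        lins = (make_lineage("A", 1.0, {"amoA": 1.0}, {"amoA": 1.0}),
                make_lineage("B", 2.0, {"amoA": 1.0}, {"amoA": 1.0}))
        truth = CommunityTruth(lineages=lins, background_rpob=0.0,
                               marker_lengths={"rpoB": 2000, "amoA": 600})
        a = expected_count(truth, "A", "amoA", "DNA", 10 ** 6)
        b = expected_count(truth, "B", "amoA", "DNA", 10 ** 6)
        assert b == pytest.approx(2 * a, rel=1e-14)

    def test_length_weighting_is_exact(self, two_marker_truth):
        """Equal copy numbers: a 1000 bp gene draws exactly twice the
        expected DNA reads of a 500 bp gene."""
        c1 = expected_count(two_marker_truth, "L1", "g1", "DNA", 7000)
        c2 = expected_count(two_marker_truth, "L1", "g2", "DNA", 7000)
        assert c1 == pytest.approx(2 * c2, rel=1e-14)
        # and expectations over all features sum to depth
        total = c1 + c2 + expected_count(two_marker_truth, "L1", "rpoB",
                                         "DNA", 7000)
        assert total == pytest.approx(7000, rel=1e-14)

    def test_unknown_lineage_or_marker(self, two_marker_truth):
        with pytest.raises(FeatureLookupError):
            expected_count(two_marker_truth, "nope", "g1", "DNA", 100)
        with pytest.raises(FeatureLookupError):
            expected_count(two_marker_truth, "L1", "nope", "DNA", 100)


class TestSimulateCounts:
    def test_zero_depth_rejected(self):
        with pytest.raises(ConfigurationError, match="depth"):
            SimulationConfig(depth_dna=0, depth_rna=10, seed=1)

    def test_expected_mode_recovers_truth_exactly(self):
        truth = generate_community(6, seed=11, profile="soil-like")
        cfg = SimulationConfig(depth_dna=10 ** 6, depth_rna=10 ** 6,
                               seed=11, mode="expected")
        dna, _ = simulate_counts(truth, cfg)
        est = estimate_guild_proportions(dna, truth.guild_map())
        for guild in ("AOA", "comammox", "AOB"):
            assert est[guild] == pytest.approx(
                truth.true_guild_proportion(guild), rel=1e-10)

    def test_sampled_mode_seed_determinism(self):
        truth = generate_community(4, seed=3, profile="soil-like")
        cfg = SimulationConfig(depth_dna=10 ** 4, depth_rna=10 ** 4, seed=9)
        d1, r1 = simulate_counts(truth, cfg)
        d2, r2 = simulate_counts(truth, cfg)
        assert d1.data.equals(d2.data) and r1.data.equals(r2.data)

    def test_sampled_counts_sum_to_depth(self):
        truth = generate_community(4, seed=3, profile="soil-like")
        cfg = SimulationConfig(depth_dna=5000, depth_rna=7000, seed=1)
        dna, rna = simulate_counts(truth, cfg)
        assert dna.data["count"].sum() == 5000
        assert rna.data["count"].sum() == 7000
        dna.validate()
        rna.validate()

    def test_rna_expectation_carries_expression_rate(self):
        lins = (make_lineage("A", 1.0, {"amoA": 1.0}, {"amoA": 4.0}),
                make_lineage("B", 1.0, {"amoA": 1.0}, {"amoA": 1.0}))
        truth = CommunityTruth(lineages=lins, background_rpob=0.0,
                               marker_lengths={"rpoB": 2000, "amoA": 600})
        a = expected_count(truth, "A", "amoA", "RNA", 10 ** 6)
        b = expected_count(truth, "B", "amoA", "RNA", 10 ** 6)
        assert a == pytest.approx(4 * b, rel=1e-14)


class TestEmitMarkerFasta:
    def test_zero_divergence_gives_identical_sequences(self):
        truth = generate_community(3, seed=2, profile="uniform")
        recs = emit_marker_fasta(truth, 3, divergence=0.0, seed=4)
        by_group = {}
        for r in recs:
            by_group.setdefault(r.id.rsplit("|", 1)[0], []).append(
                str(r.seq))
        for seqs in by_group.values():
            assert len(set(seqs)) == 1

    def test_within_lineage_identity_bound(self):
        truth = generate_community(3, seed=2, profile="uniform")
        recs = [r for r in emit_marker_fasta(truth, 3, divergence=0.05,
                                             seed=4)
                if r.id.split("|")[1] == "amoA"]
        by_lin = {}
        for r in recs:
            by_lin.setdefault(r.id.split("|")[0], []).append(str(r.seq))
        for seqs in by_lin.values():
            for i in range(len(seqs)):
                for j in range(i + 1, len(seqs)):
                    assert pairwise_identity(seqs[i], seqs[j]) >= 0.95
        # between-lineage identity strictly lower than within-lineage floor
        lins = sorted(by_lin)
        for i in range(len(lins)):
            for j in range(i + 1, len(lins)):
                for s1 in by_lin[lins[i]]:
                    for s2 in by_lin[lins[j]]:
                        assert pairwise_identity(s1, s2) < 0.95

    def test_divergence_one_rejected(self):
        truth = generate_community(2, seed=2, profile="uniform")
        with pytest.raises(ConfigurationError, match="divergence"):
            emit_marker_fasta(truth, 2, divergence=1.0, seed=1)

    def test_seed_changes_sequences_not_structure(self):
        truth = generate_community(2, seed=2, profile="uniform")
        a = emit_marker_fasta(truth, 2, divergence=0.1, seed=1)
        b = emit_marker_fasta(truth, 2, divergence=0.1, seed=2)
        assert [r.id for r in a] == [r.id for r in b]
        assert any(str(x.seq) != str(y.seq) for x, y in zip(a, b))


def test_expected_counts_nonnegative_and_sum_to_depth():
    truth = generate_community(6, seed=8, profile="soil-like")
    cfg = SimulationConfig(depth_dna=12345, depth_rna=54321, seed=8,
                           mode="expected")
    dna, rna = simulate_counts(truth, cfg)
    for t, depth in ((dna, 12345), (rna, 54321)):
        assert (t.data["count"] >= 0).all()
        assert t.data["count"].sum() == pytest.approx(depth, rel=1e-12)


def test_proportion_standard_error_scales_with_depth():
    truth = generate_community(5, seed=1, profile="soil-like")
    se4 = truth.proportion_standard_error("AOA", "amoA", 10 ** 4)
    se6 = truth.proportion_standard_error("AOA", "amoA", 10 ** 6)
    assert se4 == pytest.approx(10 * se6, rel=1e-12)
    assert math.isfinite(se4) and se4 > 0
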