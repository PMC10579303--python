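"""Lineage expression profiles, state logic, and culture comparison."""

import math

import pandas as pd
import pytest

from nitriquant import (CountTable, ExpressionProfile, InputDataError,
                        SimulationConfig, fold_difference, flag_divergent,
                        lineage_aggregate, rpob_profile, simulate_counts,
                        average_profiles, generate_community)
from nitriquant.exprofile import ABSENT, ND, heatmap_frame, \
    profiles_from_aggregate, read_reference_profiles, write_heatmap_tsv


def table(rows, totals):
    cols = ["feature_id", "lineage", "marker", "length_bp", "sample_id",
            "molecule", "count"]
    return CountTable(data=pd.DataFrame(rows, columns=cols), totals=totals)


class TestLineageAggregate:
    def test_singleton_equals_phylotype_rpkm(self):
        t = table([("p1", "Lin1", "amoA", 600, "S1", "RNA", 30.0),
                   ("p2", "Lin1", "rpoB", 3000, "S1", "RNA", 60.0)],
                  {("S1", "RNA"): 1000.0})
        agg = lineage_aggregate(t, {"p1": "Lin1", "p2": "Lin1"})
        assert agg[("Lin1", "amoA")] == pytest.approx(
            (30 / 1000) * (1e9 / 600))

    def test_counts_are_additive(self):
        t = table([("p1", "L", "amoA", 600, "S1", "RNA", 3.0),
                   ("p2", "L", "amoA", 600, "S1", "RNA", 7.0),
                   ("p3", "L", "rpoB", 3000, "S1", "RNA", 10.0)],
                  {("S1", "RNA"): 100.0})
        agg = lineage_aggregate(t, {p: "L" for p in ("p1", "p2", "p3")})
        assert agg[("L", "amoA")] == pytest.approx((10 / 100) * (1e9 / 600))

    def test_member_weighted_representative_length(self):
        t = table([("p1", "L", "amoA", 900, "S1", "RNA", 1.0),
                   ("p2", "L", "amoA", 1100, "S1", "RNA", 1.0),
                   ("p3", "L", "rpoB", 3000, "S1", "RNA", 1.0)],
                  {("S1", "RNA"): 100.0})
        agg = lineage_aggregate(t, {p: "L" for p in ("p1", "p2", "p3")},
                                members={"p1": 2, "p2": 2})
        assert agg[("L", "amoA")] == pytest.approx((2 / 100) * (1e9 / 1000))

    def test_unmapped_phylotype_listed(self):
        t = table([("p1", "L", "amoA", 600, "S1", "RNA", 1.0)],
                  {("S1", "RNA"): 10.0})
        with pytest.raises(InputDataError, match="p1"):
            lineage_aggregate(t, {})


class TestRpobProfile:
    def test_log2_values(self):
        prof = rpob_profile("L", {"rpoB": 2.0, "a": 2.0, "b": 16.0}, 2.0,
                            {"rpoB": True, "a": True, "b": True})
        assert prof.values["rpoB"] == 0.0
        assert prof.values["a"] == 0.0
        assert prof.values["b"] == pytest.approx(3.0)

    def test_absent_state_wins_over_counts(self, caplog):
        with caplog.at_level("WARNING", logger="nitriquant.exprofile"):
            prof = rpob_profile("L", {"rpoB": 1.0, "a": 5.0}, 1.0,
                                {"rpoB": True, "a": False})
        assert prof.values["a"] is ABSENT
        assert any("absent" in r.message for r in caplog.records)

    def test_nd_state_for_present_gene_without_transcripts(self):
        prof = rpob_profile("L", {"rpoB": 1.0}, 1.0,
                            {"rpoB": True, "a": True})
        assert prof.values["a"] is ND

    def test_zero_rpob_profile_unavailable(self):
        with pytest.raises(InputDataError):
            rpob_profile("L", {"a": 1.0}, 0.0, {"a": True})
        out = profiles_from_aggregate({("L", "a"): 1.0}, {"L": {"a": True}})
        assert out["L"].available is False


class TestFoldDifference:
    def prof(self, name, values):
        inv = {m: not isinstance(v, type(ABSENT)) or v is ND
               for m, v in values.items()}
        return ExpressionProfile(lineage=name, values=dict(values),
                                 inventory=inv)

    def test_identity(self):
        a = self.prof("soil", {"x": 0.0})
        b = self.prof("ref", {"x": 0.0})
        out = fold_difference(a, b, "x")
        assert out.fold == pytest.approx(1.0)
        assert out.log2_delta == 0.0

    def test_sixteen_fold(self):
        out = fold_difference(self.prof("s", {"x": 2.0}),
                              self.prof("r", {"x": -2.0}), "x")
        assert out.fold == pytest.approx(16.0)
        assert out.log2_delta == pytest.approx(4.0)

    def test_reference_nd_incomparable(self):
        out = fold_difference(self.prof("s", {"x": 1.0}),
                              self.prof("r", {"x": ND}), "x")
        assert out.incomparable == "reference_nd"
        assert out.fold is None

    def test_self_comparison_is_identity(self):
        p = self.prof("s", {"x": 1.3, "y": -0.4})
        for m in ("x", "y"):
            assert fold_difference(p, p, m).fold == pytest.approx(1.0)


class TestFlagDivergent:
    def prof(self, name, values):
        return ExpressionProfile(lineage=name, values=dict(values),
                                 inventory={m: True for m in values})

    def test_within_cutoff_empty(self):
        soil = self.prof("s", {"a": 0.5, "b": -0.5})
        ref = self.prof("r", {"a": 0.0, "b": 0.0})
        divergent, incomparable = flag_divergent(soil, ref, 10)
        assert divergent == [] and incomparable == []

    def test_higher_and_lower_directions(self):
        soil = self.prof("s", {"a": 4.0, "b": -4.0, "c": 0.0})
        ref = self.prof("r", {"a": 0.0, "b": 0.5, "c": ND})
        divergent, incomparable = flag_divergent(soil, ref, 10)
        assert ("a", pytest.approx(16.0), "higher_in_soil") in divergent
        dirs = {m: d for m, _, d in divergent}
        assert dirs["b"] == "lower_in_soil"
        assert incomparable == [("c", "reference_nd")]


class TestAverageProfiles:
    def test_mean_of_numeric_and_nd_propagation(self):
        p1 = ExpressionProfile("L", {"a": 1.0, "b": ND},
                               {"a": True, "b": True})
        p2 = ExpressionProfile("L", {"a": 3.0, "b": ND},
                               {"a": True, "b": True})
        p3 = ExpressionProfile("L", {"a": ND, "b": ND},
                               {"a": True, "b": True})
        avg = average_profiles([p1, p2, p3])
        assert avg.values["a"] == pytest.approx(2.0)  # mean over numeric
        assert avg.values["b"] is ND                  # all samples ND


class TestSyntheticRecovery:
    def test_rpob_entry_exactly_zero_and_rates_recovered(self):
        truth = generate_community(4, seed=6, profile="soil-like")
        cfg = SimulationConfig(depth_dna=10 ** 6, depth_rna=10 ** 6,
                               seed=6, mode="expected")
        _, rna = simulate_counts(truth, cfg)
        fmap = {fid: fid.split("|")[0] for fid in rna.data["feature_id"]}
        agg = lineage_aggregate(rna, fmap)
        agg = {k: v for k, v in agg.items() if k[0] != "background"}
        invs = {l.name: {m: True for m in l.markers()}
                for l in truth.lineages}
        profiles = profiles_from_aggregate(agg, invs)
        for lin in truth.lineages:
            prof = profiles[lin.name]
            assert prof.values["rpoB"] == 0.0
            for m in lin.markers():
                expected = math.log2(lin.gene_copies[m]
                                     * lin.expression_rate[m])
                assert prof.values[m] == pytest.approx(expected, abs=1e-9)

    def test_profiles_depth_invariant_in_expected_mode(self):
        truth = generate_community(4, seed=6, profile="soil-like")
        profs = []
        for depth in (10 ** 5, 10 ** 6):
            cfg = SimulationConfig(depth_dna=depth, depth_rna=depth,
                                   seed=6, mode="expected")
            _, rna = simulate_counts(truth, cfg)
            fmap = {fid: fid.split("|")[0]
                    for fid in rna.data["feature_id"]}
            agg = {k: v for k, v in lineage_aggregate(rna, fmap).items()
                   if k[0] != "background"}
            profs.append(profiles_from_aggregate(agg, {}))
        for lin in profs[0]:
            for m, v in profs[0][lin].values.items():
                w = profs[1][lin].values[m]
                if isinstance(v, float):
                    assert w == pytest.approx(v, abs=1e-12)
                else:
                    assert w is v


class TestHeatmapIO:
    def test_roundtrip_with_states(self, tmp_path):
        p1 = ExpressionProfile("LinA", {"rpoB": 0.0, "amoA": 1.5,
                                        "ut": ABSENT, "ureC": ND},
                               {"rpoB": True, "amoA": True, "ut": False,
                                "ureC": True})
        path = tmp_path / "heat.tsv"
        write_heatmap_tsv([p1], path)
        back = read_reference_profiles(path)
        assert back["LinA"].values["amoA"] == pytest.approx(1.5)
        assert back["LinA"].values["ut"] is ABSENT
        assert back["LinA"].values["ureC"] is ND

    def test_marker_row_order(self):
        p1 = ExpressionProfile("L", {"amoA": 1.0, "rpoB": 0.0, "nirK": 0.5},
                               {"amoA": True, "rpoB": True, "nirK": True})
        frame = heatmap_frame([p1])
        assert list(frame.index) == ["rpoB", "amoA", "nirK"]
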