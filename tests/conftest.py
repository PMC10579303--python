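"""Shared fixtures and deterministic hypothesis settings."""

import hypothesis
import pytest

from nitriquant import CommunityTruth, LineageSpec

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None)
hypothesis.settings.load_profile("ci")


def make_lineage(name, abundance, copies, rates, *, family=None,
                 order="OrderA", guild="AOA"):
    """Lineage with rpoB pinned to one copy and rate 1."""
    gene_copies = {"rpoB": 1.0, **copies}
    expression_rate = {"rpoB": 1.0, **rates}
    return LineageSpec(name=name, family=family or name, order=order,
                       cell_abundance=abundance, gene_copies=gene_copies,
                       expression_rate=expression_rate, guild=guild)


@pytest.fixture
def two_marker_truth():
    """One lineage carrying two genes of 1000 and 500 bp at equal copy
    number; the length-weighting of expected read counts is exact."""
    lin = make_lineage("L1", 1.0, {"g1": 1.0, "g2": 1.0},
                       {"g1": 1.0, "g2": 1.0})
    return CommunityTruth(
        lineages=(lin,), background_rpob=0.0,
        marker_lengths={"rpoB": 2000, "g1": 1000, "g2": 500})


@pytest.fixture
def activity_truth():
    """Five equal lineages whose amoA expression rates are 4x and 0.25x the
    community mean (mean exactly 1)."""
    rates = [4.0, 0.25, 0.25, 0.25, 0.25]
    lineages = tuple(
        make_lineage(f"L{i + 1}", 1.0, {"amoA": 1.0}, {"amoA": r},
                     family=f"F{i + 1}")
        for i, r in enumerate(rates))
    return CommunityTruth(lineages=lineages, background_rpob=0.0,
                          marker_lengths={"rpoB": 3200, "amoA": 650})
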