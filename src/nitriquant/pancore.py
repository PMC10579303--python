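"""Core vs. lineage-specific classification of protein clusters from a
presence/absence matrix with genome taxonomy.

A cluster belongs to the *core proteome* when every order represented in
the genome panel contains at least one genome carrying it.  A cluster is
*lineage-specific* to a family when every genome carrying it belongs to
that family and the carriers number at least the family's minimum (default
two genomes; singleton families may be given a minimum of one).  Presence
is binary; within-genome copy numbers are ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from ._exceptions import ConfigurationError, InputDataError

logger = logging.getLogger(__name__)


@dataclass
class ClusterMatrix:
    """Protein-cluster x genome presence matrix plus genome taxonomy.

    ``presence``: clusters (index) x genomes (columns), values 0/1.
    ``taxonomy``: genomes (index) with ``order`` and ``family`` columns.
    ``annotated``: optional boolean per cluster (functional annotation).
    """

    presence: pd.DataFrame
    taxonomy: pd.DataFrame
    annotated: pd.Series | None = None

    def __post_init__(self) -> None:
        if not set(self.presence.columns) <= set(self.taxonomy.index):
            missing = sorted(set(self.presence.columns)
                             - set(self.taxonomy.index))
            raise InputDataError(f"genomes without taxonomy: {missing}")
        for col in ("order", "family"):
            if col not in self.taxonomy.columns:
                raise InputDataError(f"taxonomy lacks a {col!r} column")
            if (self.taxonomy[col].astype(str).str.len() == 0).any():
                raise InputDataError(f"empty {col} labels in taxonomy")
        vals = set(pd.unique(self.presence.values.ravel()))
        if not vals <= {0, 1}:
            raise InputDataError(f"presence matrix not binary: {vals}")
        empty = self.presence.index[self.presence.sum(axis=1) == 0]
        if len(empty):
            raise InputDataError(
                f"clusters present in no genome: {list(empty[:5])}")
        if self.annotated is not None:
            self.annotated = self.annotated.reindex(
                self.presence.index, fill_value=False).astype(bool)

    def orders(self) -> list[str]:
        tax = self.taxonomy.loc[list(self.presence.columns)]
        return sorted(tax["order"].unique())

    def families(self) -> list[str]:
        tax = self.taxonomy.loc[list(self.presence.columns)]
        return sorted(tax["family"].unique())

    def genomes_of_family(self, family: str) -> list[str]:
        tax = self.taxonomy.loc[list(self.presence.columns)]
        return sorted(tax.index[tax["family"] == family])


def classify_core(matrix: ClusterMatrix) -> set[str]:
    """Clusters present in at least one genome of every order."""
    tax = matrix.taxonomy.loc[list(matrix.presence.columns)]
    core = pd.Series(True, index=matrix.presence.index)
    for order in matrix.orders():
        genomes = tax.index[tax["order"] == order]
        core &= matrix.presence[list(genomes)].any(axis=1)
    return set(matrix.presence.index[core])


def classify_lineage_specific(matrix: ClusterMatrix,
                              min_genomes: Mapping[str, int] | int = 2
                              ) -> dict[str, set[str]]:
    """Family-specific clusters: carried only by one family's genomes, by at
    least that family's minimum number of them.

    ``min_genomes`` is the default minimum or a per-family override map
    (use 1 for singleton families).
    """
    if isinstance(min_genomes, int):
        overrides: dict[str, int] = {}
        default = min_genomes
    else:
        overrides = dict(min_genomes)
        default = 2
        unknown = sorted(set(overrides) - set(matrix.families()))
        if unknown:
            raise ConfigurationError(
                f"min_genomes families absent from matrix: {unknown}")
    tax = matrix.taxonomy.loc[list(matrix.presence.columns)]
    fam_counts = matrix.presence.T.groupby(tax["family"]).sum().T
    total = matrix.presence.sum(axis=1)
    out: dict[str, set[str]] = {}
    for fam in matrix.families():
        need = overrides.get(fam, default)
        if need < 1:
            raise ConfigurationError(f"minimum for {fam} must be >= 1")
        in_fam = fam_counts[fam]
        mask = (in_fam == total) & (in_fam >= need)
        out[fam] = set(matrix.presence.index[mask])
    return out


@dataclass
class PancoreSummary:
    per_family: pd.DataFrame  # family, n_specific, n_annotated
    total_clusters: int
    n_core: int
    degenerate_taxonomy: bool  # single order: core/specific overlap possible


def summarize(matrix: ClusterMatrix, core: set[str],
              specific: Mapping[str, set[str]]) -> PancoreSummary:
    """Per-family specific-cluster counts and global core/total counts."""
    ann = matrix.annotated
    rows = []
    for fam in sorted(specific):
        clusters = specific[fam]
        n_ann = int(ann.loc[sorted(clusters)].sum()) if ann is not None \
            and clusters else 0
        rows.append({"family": fam, "n_specific": len(clusters),
                     "n_annotated": n_ann})
    degenerate = len(matrix.orders()) < 2
    if degenerate:
        logger.warning("single order in matrix: core and lineage-specific "
                       "sets may overlap")
    return PancoreSummary(
        per_family=pd.DataFrame(rows,
                                columns=["family", "n_specific",
                                         "n_annotated"]),
        total_clusters=len(matrix.presence.index),
        n_core=len(core),
        degenerate_taxonomy=degenerate)


# ---------------------------------------------------------------------------
def read_cluster_matrix(matrix_tsv: str | Path, taxonomy_tsv: str | Path,
                        annotation_tsv: str | Path | None = None
                        ) -> ClusterMatrix:
    """Read a cluster x genome 0/1 TSV, a (genome, order, family) TSV, and
    an optional (cluster, annotated) TSV."""
    presence = pd.read_csv(matrix_tsv, sep="\t", comment="#", index_col=0)
    taxonomy = pd.read_csv(taxonomy_tsv, sep="\t", comment="#", index_col=0)
    annotated = None
    if annotation_tsv is not None:
        ann = pd.read_csv(annotation_tsv, sep="\t", comment="#",
                          index_col=0)
        annotated = ann.iloc[:, 0].astype(bool)
    return ClusterMatrix(presence=presence, taxonomy=taxonomy,
                         annotated=annotated)
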