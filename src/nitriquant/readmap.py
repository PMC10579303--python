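"""Naive best-hit classification of peptide reads against a phylotype
database.

Reads are placed ungapped at every offset along each representative;
identity is identical residues over aligned read residues and coverage is
aligned read residues over read length.  A hit must reach both thresholds
(defaults mirror common short-read protein mapping practice: 90% identity,
60% coverage); among qualifying hits the highest identity wins, ties going
to the lexicographically smallest phylotype id.  This stands in for a real
aligner on synthetic data, where reads are exact or near-exact substrings;
externally produced count tables can be used instead at any point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._exceptions import InputDataError
from .counts import CountTable
from .phylodb import Phylotype

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeptideRead:
    id: str
    sequence: str
    sample: str
    molecule: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputDataError(f"{self.id}: empty read")


def _best_placement(read: np.ndarray, rep: np.ndarray,
                    min_identity: float, min_coverage: float
                    ) -> tuple[float, float] | None:
    """Best qualifying ungapped placement of ``read`` along ``rep``.

    Returns (identity, coverage) of the qualifying placement with maximal
    identity (ties: maximal coverage), or None.
    """
    lr, lp = len(read), len(rep)
    min_overlap = max(1, int(np.ceil(min_coverage * lr)))
    best: tuple[float, float] | None = None
    for offset in range(-(lr - 1), lp):
        lo = max(0, offset)
        hi = min(lp, offset + lr)
        overlap = hi - lo
        if overlap < min_overlap:
            continue
        matches = int(np.count_nonzero(
            rep[lo:hi] == read[lo - offset:hi - offset]))
        identity = matches / overlap
        coverage = overlap / lr
        if identity < min_identity:
            continue
        if best is None or (identity, coverage) > best:
            best = (identity, coverage)
    return best


def best_hit(read: PeptideRead, db: Sequence[Phylotype],
             min_identity: float = 0.90,
             min_coverage: float = 0.60) -> str | None:
    """Classify one read; returns the winning phylotype id or None."""
    if not db:
        raise InputDataError("empty phylotype database")
    if not (0 < min_identity <= 1 and 0 < min_coverage <= 1):
        raise InputDataError("thresholds must be in (0, 1]")
    r = np.frombuffer(read.sequence.encode("ascii"), dtype=np.uint8)
    best_id: str | None = None
    best_ident = -1.0
    tied = False
    for pt in sorted(db, key=lambda p: p.id):
        rep = np.frombuffer(pt.representative.sequence.encode("ascii"),
                            dtype=np.uint8)
        placed = _best_placement(r, rep, min_identity, min_coverage)
        if placed is None:
            continue
        ident = placed[0]
        if ident > best_ident:
            best_id, best_ident, tied = pt.id, ident, False
        elif ident == best_ident:
            tied = True  # earlier (smaller) id kept
    if tied:
        logger.info("best-hit tie for read %s at identity %.4f; kept %s",
                    read.id, best_ident, best_id)
    return best_id


def count_reads(reads: Iterable[PeptideRead], db: Sequence[Phylotype],
                min_identity: float = 0.90, min_coverage: float = 0.60
                ) -> tuple[CountTable, dict[tuple[str, str], int]]:
    """Tally best hits into a count table.

    Every phylotype appears in every observed (sample, molecule) group,
    zero-filled; unmapped reads are returned per (sample, molecule) and the
    recorded totals count *mapped* reads only (the RPKM denominator).
    """
    if not db:
        raise InputDataError("empty phylotype database")
    counts: dict[tuple[str, str, str], int] = {}
    unmapped: dict[tuple[str, str], int] = {}
    groups: set[tuple[str, str]] = set()
    for read in reads:
        key = (read.sample, read.molecule)
        groups.add(key)
        hit = best_hit(read, db, min_identity, min_coverage)
        if hit is None:
            unmapped[key] = unmapped.get(key, 0) + 1
        else:
            counts[(read.sample, read.molecule, hit)] = \
                counts.get((read.sample, read.molecule, hit), 0) + 1
    rows = []
    totals: dict[tuple[str, str], float] = {}
    for sample, mol in sorted(groups):
        mapped = 0
        for pt in sorted(db, key=lambda p: p.id):
            c = counts.get((sample, mol, pt.id), 0)
            mapped += c
            rows.append({
                "feature_id": pt.id,
                "lineage": pt.assigned_family or "unassigned",
                "marker": pt.marker,
                "length_bp": 3 * len(pt.representative.sequence),
                "sample_id": sample, "molecule": mol, "count": float(c),
            })
        totals[(sample, mol)] = float(mapped)
    data = pd.DataFrame(rows, columns=list(
        ("feature_id", "lineage", "marker", "length_bp",
         "sample_id", "molecule", "count")))
    return CountTable(data=data, totals=totals), unmapped
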