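"""Phylotype construction: greedy protein dereplication and family
assignment against a labelled reference panel.

A *phylotype* is a dereplicated marker protein sequence treated as a taxon
proxy.  Dereplication follows the greedy incremental scheme of CD-HIT:
records are processed longest-first and join the first existing cluster
whose representative they match at or above the identity threshold, else
found a new cluster.  Identity is computed from a global alignment (match
+1, mismatch 0, linear gap -1) as identical residues divided by the shorter
sequence length, so substrings collapse at 100%.  Among score-optimal
alignments the one with the most identical residues is used, which makes
the identity value well defined and order independent.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from ._exceptions import InputDataError

logger = logging.getLogger(__name__)

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

ASSEMBLY = "assembly"
REFERENCE = "reference"


@dataclass(frozen=True)
class ProteinRecord:
    """A marker protein sequence from an assembly or a reference genome."""

    id: str
    marker: str
    sequence: str
    source: str = ASSEMBLY
    family: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputDataError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise InputDataError(
                f"{self.id}: invalid residues {sorted(bad)}")
        if self.source not in (ASSEMBLY, REFERENCE):
            raise InputDataError(f"{self.id}: unknown source {self.source!r}")
        if self.source == REFERENCE and not self.family:
            raise InputDataError(f"{self.id}: reference without family label")


@dataclass
class Phylotype:
    """A dereplicated representative sequence and its member records."""

    id: str
    representative: ProteinRecord
    members: list[str]
    marker: str
    assigned_family: str | None = None
    best_ref_identity: float | None = None


# ---------------------------------------------------------------------------
# pairwise identity
# ---------------------------------------------------------------------------
def _align_score_matches(a: str, b: str) -> tuple[int, int]:
    """Global alignment maximizing (score, matches) lexicographically.

    Score: match +1, mismatch 0, gap -1 (linear).  Returns the optimal
    score and, among all score-optimal alignments, the maximal number of
    identical aligned residues.
    """
    A = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    B = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    la, lb = len(A), len(B)
    # encode (score, matches) as score * K + matches with K > max matches;
    # Python ints below stay within int64 for realistic lengths
    K = min(la, lb) + 1
    gap = K  # penalty of one gap column in the combined encoding
    jidx = np.arange(lb + 1, dtype=np.int64)
    row = -gap * jidx  # top row: all-gap prefixes of b
    for i in range(1, la + 1):
        eq = (B == A[i - 1]).astype(np.int64)
        diag = row[:-1] + eq * (K + 1)  # match: +1 score, +1 matches
        up = row[1:] - gap
        new = np.empty(lb + 1, dtype=np.int64)
        new[0] = -gap * i
        new[1:] = np.maximum(diag, up)
        # left-gap chain via running max of (value + gap * j)
        shifted = np.maximum.accumulate(new + gap * jidx) - gap * jidx
        row = shifted
    combined = int(row[-1])
    matches = combined % K
    score = (combined - matches) // K
    return score, matches


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: identical residues / shorter length.

    Symmetric; 1.0 for identical sequences and for exact substrings.
    """
    if not a or not b:
        raise InputDataError("cannot align an empty sequence")
    _, matches = _align_score_matches(a, b)
    return matches / min(len(a), len(b))


# ---------------------------------------------------------------------------
# dereplication
# ---------------------------------------------------------------------------
def dereplicate(records: Sequence[ProteinRecord],
                threshold: float = 1.0) -> list[Phylotype]:
    """Greedy incremental clustering at an identity threshold.

    Records are sorted by length descending (ties: id ascending) and each
    joins the first phylotype, in foundation order, whose representative it
    matches at >= ``threshold``; otherwise it founds a new phylotype.  The
    founder is always the longest member and remains representative.
    """
    if not 0 < threshold <= 1:
        raise InputDataError("threshold must be in (0, 1]")
    if not records:
        return []
    markers = {r.marker for r in records}
    if len(markers) > 1:
        raise InputDataError(f"mixed markers in one run: {sorted(markers)}")
    marker = markers.pop()
    order = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    phylotypes: list[Phylotype] = []
    for rec in order:
        for pt in phylotypes:
            if pairwise_identity(rec.sequence,
                                 pt.representative.sequence) >= threshold:
                pt.members.append(rec.id)
                break
        else:
            phylotypes.append(Phylotype(
                id=f"{marker}_pt{len(phylotypes) + 1:04d}",
                representative=rec, members=[rec.id], marker=marker))
    return phylotypes


def assign_family(p: Phylotype, refs: Sequence[ProteinRecord],
                  min_identity: float = 0.85) -> Phylotype:
    """Assign a family by best identity to a labelled reference panel.

    The family of the best-identity reference is adopted when that identity
    reaches ``min_identity``; ties on identity go to the lexicographically
    smallest reference id (and are logged).  ``best_ref_identity`` is
    recorded either way.
    """
    if not refs:
        raise InputDataError(f"{p.id}: no references for marker {p.marker}")
    for r in refs:
        if r.source != REFERENCE or not r.family:
            raise InputDataError(f"{r.id}: not a labelled reference record")
        if r.marker != p.marker:
            raise InputDataError(
                f"{r.id}: marker {r.marker} does not match {p.marker}")
    best: ProteinRecord | None = None
    best_ident = -1.0
    tied = False
    for r in sorted(refs, key=lambda r: r.id):
        ident = pairwise_identity(p.representative.sequence, r.sequence)
        if ident > best_ident:
            best, best_ident, tied = r, ident, False
        elif ident == best_ident:
            tied = True
    assert best is not None
    if tied:
        logger.info("family tie for %s at identity %.4f; kept %s",
                    p.id, best_ident, best.id)
    family = best.family if best_ident >= min_identity else None
    return replace(p, assigned_family=family, best_ref_identity=best_ident)


def build_phylodb(records: Sequence[ProteinRecord],
                  refs: Sequence[ProteinRecord],
                  threshold: float = 1.0,
                  min_identity: float = 0.85) -> list[Phylotype]:
    """Dereplicate one marker's records and family-assign every phylotype."""
    return [assign_family(p, list(refs), min_identity)
            for p in dereplicate(records, threshold)]


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------
def records_from_fasta(path: str | Path, *, source: str = ASSEMBLY,
                       default_marker: str | None = None,
                       family_map: Mapping[str, str] | None = None
                       ) -> list[ProteinRecord]:
    """Read protein records from FASTA.

    ``marker=`` / ``family=`` / ``lineage=`` tokens in the description (as
    written by the synthetic generator) are honoured; ``family_map``
    overrides per-id family labels for reference panels.
    """
    out: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = dict(t.split("=", 1) for t in rec.description.split()
                      if "=" in t)
        marker = tokens.get("marker", default_marker)
        if marker is None:
            raise InputDataError(
                f"{rec.id}: no marker token and no default marker")
        family = tokens.get("family")
        if family_map is not None:
            family = family_map.get(rec.id, family)
        out.append(ProteinRecord(
            id=rec.id, marker=marker, sequence=str(rec.seq),
            source=source, family=family))
    return out


def write_phylotype_table(phylotypes: Iterable[Phylotype],
                          path: str | Path,
                          extra_header: Iterable[str] = ()) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("# nitriquant phylotype table\n")
        for line in extra_header:
            fh.write(f"# {line}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["phylotype_id", "marker", "representative_id",
                    "n_members", "assigned_family", "best_ref_identity"])
        for p in phylotypes:
            w.writerow([
                p.id, p.marker, p.representative.id, len(p.members),
                p.assigned_family or "",
                "" if p.best_ref_identity is None
                else f"{p.best_ref_identity:.6f}"])
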