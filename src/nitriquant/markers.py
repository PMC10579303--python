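"""Marker-gene registry: canonical names, display order, and typical lengths.

The 26 archaeal marker proteins cover RNA synthesis (rpoB), ammonia oxidation
(amoA/B/C and the accessory amoX/Y/Z subunits), nitrite reduction (nirK),
carbon fixation (accB, msr, 4hbd), respiration and ATP synthesis (coxA, petB,
atpA), nitrogen uptake and regulation (amt1/2, sss1/2, ut, ureC, glnB),
phosphate uptake (pstA/B/C, piT), and motility (flaB).  Two additional
bacterial nitrifier markers (hao, nxrB) are carried for guild quantification
of ammonia- and nitrite-oxidizing bacteria.

Lengths are nucleotide gene lengths (bp) typical of nitrifier genomes; they
are defaults for the synthetic-community generator and can be overridden per
community.
"""

from __future__ import annotations

#: Row order used for expression-profile matrices (housekeeping anchor first).
MARKER_ORDER: tuple[str, ...] = (
    "rpoB",
    "amoA", "amoB", "amoC", "amoX", "amoY", "amoZ",
    "nirK",
    "accB", "msr", "4hbd",
    "coxA", "petB",
    "amt1", "amt2", "sss1", "sss2", "ut", "ureC", "glnB",
    "pstA", "pstB", "pstC", "piT",
    "atpA", "flaB",
)

#: Bacterial nitrifier markers used for AOB / comammox / Nitrospira guilds.
BACTERIAL_MARKERS: tuple[str, ...] = ("hao", "nxrB")

#: Typical gene length in bp (defaults for synthetic communities).
DEFAULT_MARKER_LENGTHS: dict[str, int] = {
    "rpoB": 3201,
    "amoA": 651, "amoB": 591, "amoC": 621,
    "amoX": 252, "amoY": 351, "amoZ": 402,
    "nirK": 1152,
    "accB": 471, "msr": 552, "4hbd": 1452,
    "coxA": 1602, "petB": 522,
    "amt1": 1350, "amt2": 1350, "sss1": 1500, "sss2": 1500,
    "ut": 1002, "ureC": 1710, "glnB": 339,
    "pstA": 900, "pstB": 771, "pstC": 960, "piT": 1002,
    "atpA": 1752, "flaB": 603,
    "hao": 1710, "nxrB": 1290,
}


def marker_sort_key(marker: str) -> tuple[int, str]:
    """Sort key placing known markers in canonical order, others after."""
    known = MARKER_ORDER + BACTERIAL_MARKERS
    try:
        return (known.index(marker), marker)
    except ValueError:
        return (len(known), marker)
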