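"""Gene vocabularies and TCR gene-symbol normalization.

The V/J segment lists below are the IMGT-style symbols observed in human
MAIT-cell repertoires: the canonical semi-invariant combination
(TRAV1-2 joined to TRAJ33/20/12, typically paired with TRBV6-1/6-4/20-1)
plus the noncanonical segments recurrently reported in TRAV1-2-negative
MAIT cells.
"""

from __future__ import annotations

import re

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

CANONICAL_TRAV = "TRAV1-2"
CANONICAL_TRAJ = ("TRAJ33", "TRAJ20", "TRAJ12")
CANONICAL_TRBV = ("TRBV6-1", "TRBV6-4", "TRBV20-1")

# Germline-encoded CDR3alpha tails of the canonical joining segments.  Each is
# 7 residues long and carries the conserved tyrosine (Y95alpha, required for
# riboflavin-intermediate recognition) at the 5th position from the C-terminus.
CANONICAL_TRAJ_TAILS = {
    "TRAJ33": "SNYQLIW",
    "TRAJ20": "NDYKLSF",
    "TRAJ12": "SSYKLIF",
}

# Noncanonical alpha V segments reported in TRAV1-2- MAIT cells.
NONCANONICAL_TRAV = (
    "TRAV21", "TRAV8-1", "TRAV8-2", "TRAV8-3", "TRAV12-2", "TRAV12-3",
    "TRAV35", "TRAV19", "TRAV16", "TRAV25", "TRAV26-1", "TRAV34",
    "TRAV36/DV7", "TRAV40", "TRAV41", "TRAV13-1", "TRAV14/DV4", "TRAV20",
    "TRAV17", "TRAV5", "TRAV1-1", "TRAV39", "TRAV29/DV5",
)

NONCANONICAL_TRAJ = (
    "TRAJ3", "TRAJ4", "TRAJ5", "TRAJ6", "TRAJ7", "TRAJ8", "TRAJ9", "TRAJ10",
    "TRAJ11", "TRAJ13", "TRAJ21", "TRAJ22", "TRAJ23", "TRAJ24", "TRAJ26",
    "TRAJ27", "TRAJ28", "TRAJ29", "TRAJ30", "TRAJ32", "TRAJ34", "TRAJ35",
    "TRAJ36", "TRAJ37", "TRAJ38", "TRAJ39", "TRAJ40", "TRAJ42", "TRAJ43",
    "TRAJ44", "TRAJ45", "TRAJ46", "TRAJ48", "TRAJ49", "TRAJ52", "TRAJ53",
    "TRAJ54", "TRAJ56", "TRAJ57", "TRAJ58",
)

NONCANONICAL_TRBV = (
    "TRBV25-1", "TRBV24-1", "TRBV28", "TRBV11-1", "TRBV19", "TRBV5-1",
    "TRBV7-2", "TRBV4-1", "TRBV9", "TRBV2",
)

TRBJ_SEGMENTS = (
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ1-4", "TRBJ1-5", "TRBJ1-6",
    "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-4", "TRBJ2-5", "TRBJ2-6",
    "TRBJ2-7",
)

TRBD_SEGMENTS = ("TRBD1", "TRBD2")

_ALLELE_RE = re.compile(r"\*\d+$")
# "TRAJ-33" and friends: a stray hyphen between the locus prefix and the
# segment number (TRAJ has no gene families, so any hyphen there is a
# spelling variant).
_TRAJ_HYPHEN_RE = re.compile(r"^(TRAJ)-(\d+)$")


def normalize_gene_symbol(symbol: str) -> str:
    """Normalize a TCR gene symbol to its IMGT-style gene-level name.

    Strips allele suffixes (``TRAV1-2*01`` -> ``TRAV1-2``), canonicalizes
    case, collapses spelling variants such as ``TRAJ-33`` -> ``TRAJ33``,
    and preserves dual ``/DV`` names verbatim (``TRAV14/DV4``).
    """
    s = symbol.strip().upper()
    if not s or s in {"NONE", "NA", "N/A", "."}:
        return ""
    s = _ALLELE_RE.sub("", s)
    m = _TRAJ_HYPHEN_RE.match(s)
    if m:
        s = m.group(1) + m.group(2)
    return s


def is_trav12(v_gene: str) -> bool:
    """True if the (normalized) alpha V segment is TRAV1-2."""
    return normalize_gene_symbol(v_gene) == CANONICAL_TRAV
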