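"""CDR3 sequence analysis: length distributions, positional residue
frequencies (sequence-logo data), central-region motif detection, and
conserved-anchor summaries.

Positions are 1-based in all reported tables, matching the convention in
which the conserved cysteine/alanine pair occupies "the first and second
positions".  The conserved TRAJ33-encoded tyrosine (Y95alpha) is
operationalized as the 5th residue from the CDR3alpha C-terminus, the
slot the germline ...NYQLIW tail places it in across canonical lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genes import AA_ALPHABET


@dataclass(frozen=True)
class MotifSpec:
    """Contiguous residue-run motifs with an optional central-window gate."""

    patterns: Tuple[str, ...] = ("GGG", "GGGG", "NNNN")
    central_window: Tuple[int, int] = (6, 9)  # 1-based inclusive
    require_in_window: bool = False

    def __post_init__(self):
        if not self.patterns:
            raise ValueError("patterns must be nonempty")
        if any(p != p.upper() or not p for p in self.patterns):
            raise ValueError("patterns must be nonempty uppercase strings")
        if self.central_window[0] < 1:
            raise ValueError("central window start must be >= 1")


def detect_motif(cdr3: str, spec: MotifSpec = MotifSpec()) -> List[Tuple[str, int]]:
    """All (pattern, 1-based start) motif occurrences in ``cdr3``.

    Overlapping occurrences are enumerated (a GGGG run therefore also
    yields its two contained GGG hits).  With ``require_in_window``, an
    occurrence counts only if its span intersects the central window.
    """
    hits = []
    lo, hi = spec.central_window
    for pattern in spec.patterns:
        k = len(pattern)
        for start0 in range(len(cdr3) - k + 1):
            if cdr3[start0:start0 + k] != pattern:
                continue
            start = start0 + 1
            if spec.require_in_window and (start + k - 1 < lo or start > hi):
                continue
            hits.append((pattern, start))
    return hits


def has_motif(cdr3: str, spec: MotifSpec = MotifSpec()) -> bool:
    return bool(detect_motif(cdr3, spec))


def tyr95_test(cdr3: str) -> bool:
    """True iff the conserved-tyrosine slot (5th residue from the
    C-terminus) is tyrosine.  Sequences shorter than 6 residues cannot
    carry the slot and return False with a warning."""
    if len(cdr3) < 6:
        warnings.warn(
            f"CDR3 {cdr3!r} is too short (<6) to carry the conserved-Tyr "
            "slot; returning False", stacklevel=2)
        return False
    return cdr3[len(cdr3) - 5] == "Y"


def length_distribution(
    sequences: Sequence[str],
    groups: Optional[Sequence] = None,
    query_range: Optional[Tuple[int, int]] = None,
) -> pd.DataFrame:
    """Per-group integer length histogram with range summaries.

    Returns a tidy frame (group, length, count) with per-group min/max and
    — when ``query_range`` is given — the fraction of sequences whose
    length falls inside the inclusive range, stored as a plain dict in
    ``.attrs['summary']`` (keyed by group).
    """
    if len(sequences) == 0:
        raise ValueError("no sequences supplied")
    df = pd.DataFrame({
        "group": list(groups) if groups is not None else ["all"] * len(sequences),
        "length": [len(s) for s in sequences],
    })
    hist = (df.groupby(["group", "length"], observed=True).size()
            .rename("count").reset_index())
    summary = df.groupby("group", observed=True)["length"].agg(["min", "max", "count"])
    if query_range is not None:
        lo, hi = query_range
        summary["fraction_in_range"] = df.groupby("group", observed=True)["length"] \
            .apply(lambda s: ((s >= lo) & (s <= hi)).mean())
    hist.attrs["summary"] = summary.to_dict(orient="index")
    return hist


@dataclass
class PositionalMatrix:
    """Residue frequencies by position (the data behind a sequence logo)."""

    anchoring: str
    matrix: pd.DataFrame  # index: position (1..L or -1..-L), columns: residues
    n_sequences: int

    def frequency(self, position: int, residue: str) -> float:
        if position in self.matrix.index and residue in self.matrix.columns:
            return float(self.matrix.loc[position, residue])
        return 0.0


def positional_matrix(sequences: Sequence[str],
                      anchoring: str = "left") -> PositionalMatrix:
    """Positional residue-frequency matrix over a set of CDR3 sequences.

    Left anchoring indexes positions 1..L from the N-terminal cysteine;
    right anchoring indexes -1..-L from the C-terminus.  At every covered
    position the frequencies over observed residues sum to 1 (positions
    with no coverage are omitted).
    """
    if len(sequences) == 0:
        raise ValueError("no sequences supplied")
    if anchoring not in ("left", "right"):
        raise ValueError("anchoring must be 'left' or 'right'")
    tallies: Dict[int, Dict[str, int]] = {}
    for seq in sequences:
        L = len(seq)
        for i, res in enumerate(seq):
            pos = i + 1 if anchoring == "left" else i - L
            tallies.setdefault(pos, {}).setdefault(res, 0)
            tallies[pos][res] += 1
    mat = pd.DataFrame(tallies).T.fillna(0).sort_index()
    mat = mat.div(mat.sum(axis=1), axis=0)
    mat = mat[sorted(mat.columns)]
    return PositionalMatrix(anchoring=anchoring, matrix=mat,
                            n_sequences=len(sequences))


def positional_matrix_long(pm: PositionalMatrix, **labels) -> pd.DataFrame:
    """Long-format (position, residue, frequency) table for export."""
    long = (pm.matrix.rename_axis("position").reset_index()
            .melt(id_vars="position", var_name="residue",
                  value_name="frequency"))
    long = long.loc[long["frequency"] > 0].reset_index(drop=True)
    long.insert(0, "anchoring", pm.anchoring)
    for k, v in labels.items():
        long.insert(0, k, v)
    return long


def terminal_conservation(sequences: Sequence[str], k: int = 3,
                          terminal_set: str = "LITFW") -> Dict[str, float]:
    """Conserved-anchor summary of a CDR3 set.

    Reports the fractions with C at position 1, A at position 2, and V at
    position 3, plus the fraction of sequences whose last ``k`` residues
    are all drawn from ``terminal_set`` (the J-segment-encoded end
    residues L/I/T/F plus the TRAJ33 tryptophan).
    """
    if len(sequences) == 0:
        raise ValueError("no sequences supplied")
    seqs = list(sequences)
    n = len(seqs)
    return {
        "frac_C_at_1": sum(s[0:1] == "C" for s in seqs) / n,
        "frac_A_at_2": sum(s[1:2] == "A" for s in seqs) / n,
        "frac_V_at_3": sum(s[2:3] == "V" for s in seqs) / n,
        f"frac_last{k}_in_{terminal_set}": sum(
            len(s) >= k and all(c in terminal_set for c in s[-k:])
            for s in seqs) / n,
        "n_sequences": n,
    }
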