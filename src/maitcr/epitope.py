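"""Fuzzy CDR3-epitope matching against a McPAS-style reference table.

Percent similarity between two CDR3 strings is defined as 100 x (matched
positions in an optimal global alignment scoring match=1, mismatch=0,
gap=0) / max(length); with those scores the optimum equals the longest
common subsequence, and the measure reduces to percent identity for
equal-length strings.  Queries may additionally be perturbed in silico by
one or two amino-acid insertions (+1, +2) or deletions (-1, -2) —
never both in the same variant, and never touching the reference — and
the best-scoring (variant, reference) pair is reported together with the
edits used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import Align

from .genes import AA_ALPHABET

_AA_SET = frozenset(AA_ALPHABET)

_aligner = Align.PairwiseAligner(
    mode="global", match_score=1, mismatch_score=0,
    open_gap_score=0, extend_gap_score=0,
)


@dataclass(frozen=True)
class ReferenceEntry:
    """One reference CDR3 with its epitope and disease annotations."""

    cdr3_aa: str
    chain: str  # "alpha" | "beta"
    epitope: str
    pathology: str
    source_id: str = ""

    def __post_init__(self):
        if not self.cdr3_aa or set(self.cdr3_aa) - _AA_SET:
            raise ValueError(
                f"reference CDR3 {self.cdr3_aa!r} is not an uppercase "
                "amino-acid string")


@dataclass
class EpitopeHit:
    """Best reference match for one query CDR3."""

    query_cdr3: str
    best_reference: ReferenceEntry
    similarity_pct: float
    indel_budget_used: int
    edit_operations: List[Tuple[str, int, str]]  # (type, 1-based pos, residue)
    variant: str = ""


def _check_sequence(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label} sequence is empty")
    bad = set(seq) - _AA_SET
    if bad:
        raise ValueError(f"{label} sequence {seq!r} contains non-amino-acid "
                         f"characters {sorted(bad)}")


def similarity(query: str, reference: str) -> float:
    """Percent similarity between two CDR3 amino-acid strings.

    Symmetric, in [0, 100], and equal to 100 iff the strings are
    identical.
    """
    _check_sequence(query, "query")
    _check_sequence(reference, "reference")
    matches = _aligner.score(query, reference)
    return 100.0 * matches / max(len(query), len(reference))


def _deletion_variants(query: str, n_del: int):
    for idx in combinations(range(len(query)), n_del):
        variant = "".join(c for i, c in enumerate(query) if i not in idx)
        ops = [("del", i + 1, query[i]) for i in idx]
        yield variant, ops


def _insertion_variants(query: str, n_ins: int):
    """Variants with exactly ``n_ins`` inserted residues at internal
    positions (the C anchor and the terminal residue stay in place)."""
    states = [(query, [])]
    for _ in range(n_ins):
        nxt = []
        for seq, ops in states:
            for pos in range(1, len(seq)):  # between first and last residue
                for res in AA_ALPHABET:
                    nxt.append((seq[:pos] + res + seq[pos:],
                                ops + [("ins", pos + 1, res)]))
        states = nxt
    return states


def perturbed_match(
    query: str,
    references: Sequence[ReferenceEntry],
    max_insertions: int = 0,
    max_deletions: int = 0,
) -> EpitopeHit:
    """Best reference match over all indel-perturbed variants of the query.

    Enumerates the unmodified query, every variant with up to
    ``max_deletions`` deletions, and every variant with up to
    ``max_insertions`` insertions of any of the 20 residues at internal
    positions (insertions and deletions are not mixed within a variant).
    Ties are broken toward the smaller edit budget, then the
    lexicographically smaller epitope, then reference CDR3.
    """
    _check_sequence(query, "query")
    if not 0 <= max_insertions <= 2 or not 0 <= max_deletions <= 2:
        raise ValueError("indel budgets must be between 0 and 2")
    refs = list(references)
    if not refs:
        raise ValueError("reference set is empty")

    variants: List[Tuple[str, List, int]] = [(query, [], 0)]
    for d in range(1, max_deletions + 1):
        if d < len(query):
            variants.extend((v, ops, d) for v, ops in _deletion_variants(query, d))
    for i in range(1, max_insertions + 1):
        variants.extend((v, ops, i) for v, ops in _insertion_variants(query, i))

    best: Optional[Tuple] = None
    seen: Dict[Tuple[str, str], float] = {}
    for variant, ops, budget in variants:
        for ref in refs:
            key = (variant, ref.cdr3_aa)
            sim = seen.get(key)
            if sim is None:
                sim = similarity(variant, ref.cdr3_aa)
                seen[key] = sim
            rank = (-sim, budget, ref.epitope, ref.cdr3_aa)
            if best is None or rank < best[0]:
                best = (rank, variant, ops, budget, ref, sim)
    _, variant, ops, budget, ref, sim = best
    return EpitopeHit(
        query_cdr3=query, best_reference=ref, similarity_pct=sim,
        indel_budget_used=budget, edit_operations=ops, variant=variant,
    )


def match_table(
    queries: Sequence[str],
    references: Sequence[ReferenceEntry],
    max_insertions: int = 2,
    max_deletions: int = 2,
) -> pd.DataFrame:
    """Best-hit table for a list of query CDR3s."""
    rows = []
    for q in queries:
        hit = perturbed_match(q, references, max_insertions, max_deletions)
        rows.append({
            "query_cdr3": q,
            "best_cdr3": hit.best_reference.cdr3_aa,
            "chain": hit.best_reference.chain,
            "epitope": hit.best_reference.epitope,
            "pathology": hit.best_reference.pathology,
            "similarity_pct": hit.similarity_pct,
            "indel_budget_used": hit.indel_budget_used,
            "edits": ";".join(f"{t}@{p}:{r}" for t, p, r in
                              hit.edit_operations),
        })
    return pd.DataFrame(rows)


def central_similarity(query: str, reference: str, margin: int = 3) -> float:
    """Similarity restricted to the central region (positions 4..L-3),
    an optional windowed variant of the headline measure."""
    _check_sequence(query, "query")
    _check_sequence(reference, "reference")
    q, r = query[margin:-margin], reference[margin:-margin]
    if not q or not r:
        raise ValueError("sequences too short for a central window")
    return similarity(q, r)


def read_reference(path) -> List[ReferenceEntry]:
    """Parse a McPAS-style CSV of CDR3-epitope associations.

    Expects columns CDR3_alpha, CDR3_beta (either may be empty per row),
    Epitope, and Pathology; each nonempty chain field becomes one entry.
    Duplicates are retained.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ("CDR3_alpha", "CDR3_beta", "Epitope", "Pathology")
               if c not in df.columns]
    if missing:
        raise ValueError(f"reference CSV {path} is missing columns: {missing}")
    entries = []
    for i, row in df.iterrows():
        for col, chain in (("CDR3_alpha", "alpha"), ("CDR3_beta", "beta")):
            cdr3 = (row[col] or "").strip().upper() if pd.notna(row[col]) else ""
            if cdr3:
                entries.append(ReferenceEntry(
                    cdr3_aa=cdr3, chain=chain,
                    epitope=(row["Epitope"] or "").strip(),
                    pathology=(row["Pathology"] or "").strip(),
                    source_id=str(row.get("Source", i)),
                ))
    return entries


def packaged_reference() -> List[ReferenceEntry]:
    """The small synthetic reference table shipped with the package."""
    from importlib.resources import files

    path = files("maitcr").joinpath("data/synthetic_mcpas_reference.csv")
    return read_reference(str(path))
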