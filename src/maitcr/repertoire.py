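"""Chain pairing, dual-alpha categorization, canonical TCR classification,
and per-group usage/diversity summaries.

A cell contributes to repertoire statistics only through its productive,
high-confidence contigs.  One TRA plus one TRB is a single paired TCR;
two distinct TRAs plus one TRB is a dual-alpha cell, categorized by how
many of its alpha chains are TRAV1-2; more than two TRAs or more than one
TRB marks a multiplet, which is excluded from repertoire statistics.

The canonical MAIT TCR is TRAV1-2 joined to TRAJ33/20/12; canonical beta
pairing uses TRBV6-1, TRBV6-4, or TRBV20-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genes import CANONICAL_TRAJ, CANONICAL_TRAV, CANONICAL_TRBV

PAIRING_STATUSES = ("paired_single", "dual_alpha", "alpha_only", "beta_only",
                    "none", "multiplet")


@dataclass(frozen=True)
class CanonicalDefinition:
    """Membership sets defining the canonical (semi-invariant) MAIT TCR."""

    canonical_trav: FrozenSet[str] = frozenset({CANONICAL_TRAV})
    canonical_traj: FrozenSet[str] = frozenset(CANONICAL_TRAJ)
    canonical_trbv: FrozenSet[str] = frozenset(CANONICAL_TRBV)
    trbv_family_mode: bool = False  # treat every TRBV6-* as canonical

    def is_canonical_trbv(self, v_gene: str) -> bool:
        if self.trbv_family_mode and v_gene.startswith("TRBV6"):
            return True
        return v_gene in self.canonical_trbv


CALL_COLUMNS = [
    "barcode", "pairing_status", "dual_category",
    "alpha_v", "alpha_j", "alpha_cdr3",
    "alpha2_v", "alpha2_j", "alpha2_cdr3",
    "beta_v", "beta_d", "beta_j", "beta_cdr3",
]


def _dedupe(chains: pd.DataFrame) -> pd.DataFrame:
    """Collapse redundant identical contigs (same v/j/cdr3), keeping the
    highest-UMI copy; order deterministically by UMIs desc then cdr3."""
    chains = chains.sort_values(["umis", "cdr3"], ascending=[False, True],
                                kind="mergesort")
    return chains.drop_duplicates(subset=["v_gene", "j_gene", "cdr3"])


def pair_chains(contigs: pd.DataFrame) -> pd.DataFrame:
    """Resolve one ClonotypeCall per barcode from its contigs.

    Only productive, high-confidence contigs are considered.  For
    dual-alpha cells the two alphas are ordered TRAV1-2 first (then by UMI
    support, then lexicographic CDR3), so ``alpha_*`` is the chain a
    TRAV1-2-stratified analysis counts.
    """
    usable = contigs.loc[
        contigs["productive"] & contigs["high_confidence"]
        & contigs["chain"].isin(["TRA", "TRB"])
    ]
    rows = []
    for barcode, grp in usable.groupby("barcode", sort=True):
        tra = _dedupe(grp[grp["chain"] == "TRA"])
        trb = _dedupe(grp[grp["chain"] == "TRB"])
        n_a, n_b = len(tra), len(trb)
        row = dict.fromkeys(CALL_COLUMNS, "")
        row["barcode"] = barcode
        if n_a > 2 or n_b > 1:
            row["pairing_status"] = "multiplet"
        elif n_a == 0 and n_b == 0:
            row["pairing_status"] = "none"
        elif n_b == 0:
            row["pairing_status"] = "alpha_only"
        elif n_a == 0:
            row["pairing_status"] = "beta_only"
        else:
            row["pairing_status"] = ("paired_single" if n_a == 1
                                     else "dual_alpha")
        if row["pairing_status"] in ("paired_single", "dual_alpha"):
            alphas = tra.copy()
            alphas["_trav12"] = alphas["v_gene"] == CANONICAL_TRAV
            alphas = alphas.sort_values(
                ["_trav12", "umis", "cdr3"], ascending=[False, False, True],
                kind="mergesort")
            a1 = alphas.iloc[0]
            row["alpha_v"], row["alpha_j"] = a1["v_gene"], a1["j_gene"]
            row["alpha_cdr3"] = a1["cdr3"]
            if row["pairing_status"] == "dual_alpha":
                a2 = alphas.iloc[1]
                row["alpha2_v"], row["alpha2_j"] = a2["v_gene"], a2["j_gene"]
                row["alpha2_cdr3"] = a2["cdr3"]
                n12 = int(a1["v_gene"] == CANONICAL_TRAV) + int(
                    a2["v_gene"] == CANONICAL_TRAV)
                row["dual_category"] = ("both_trav12", "one_trav12",
                                        "neither")[2 - n12]
            b = trb.iloc[0]
            row["beta_v"], row["beta_d"] = b["v_gene"], b["d_gene"]
            row["beta_j"], row["beta_cdr3"] = b["j_gene"], b["cdr3"]
        rows.append(row)
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return calls


def classify_tcr(calls: pd.DataFrame,
                 defn: CanonicalDefinition = CanonicalDefinition()
                 ) -> pd.DataFrame:
    """Annotate clonotype calls with canonicality labels.

    Adds ``trav12_status`` (positive iff any alpha chain is TRAV1-2),
    ``canonical_traj`` / ``canonical_trbv`` membership flags (evaluated on
    the representative alpha — the TRAV1-2 chain of a dual cell), and the
    ``fully_canonical`` MAIT TCR flag (TRAV1-2 AND canonical TRAJ).
    Only paired cells (single or dual-alpha) are classified.
    """
    out = calls.copy()
    paired = out["pairing_status"].isin(["paired_single", "dual_alpha"])
    trav12 = (
        out["alpha_v"].isin(defn.canonical_trav)
        | out["alpha2_v"].isin(defn.canonical_trav)
    )
    out["trav12_status"] = np.where(
        ~paired, "", np.where(trav12, "positive", "negative"))
    out["canonical_traj"] = paired & out["alpha_j"].isin(defn.canonical_traj)
    out["canonical_trbv"] = paired & out["beta_v"].map(defn.is_canonical_trbv)
    out["fully_canonical"] = (
        paired & (out["trav12_status"] == "positive") & out["canonical_traj"]
    )
    return out


def usage_table(
    calls: pd.DataFrame,
    group_by: Sequence[str] = ("subset",),
    gene_classes: Sequence[str] = ("TRAV", "TRAJ", "TRBV"),
) -> pd.DataFrame:
    """Per-group V/J usage counts and proportions.

    Each paired cell is counted once per gene class through its
    representative chain.  Proportions sum to 1 within each
    (group, gene_class) stratum; empty groups yield count 0 with
    proportion flagged as NaN.
    """
    gene_col = {"TRAV": "alpha_v", "TRAJ": "alpha_j", "TRBV": "beta_v"}
    paired = calls.loc[
        calls["pairing_status"].isin(["paired_single", "dual_alpha"])
    ]
    group_by = list(group_by)
    frames = []
    for cls in gene_classes:
        col = gene_col[cls]
        grouped = (
            paired.groupby(group_by + [col], observed=True, dropna=False)
            .size().rename("count").reset_index()
            .rename(columns={col: "gene"})
        )
        totals = grouped.groupby(group_by, observed=True)["count"].transform("sum")
        grouped["proportion"] = np.where(
            totals > 0, grouped["count"] / totals, np.nan)
        grouped.insert(len(group_by), "gene_class", cls)
        frames.append(grouped)
    return pd.concat(frames, ignore_index=True)


def gene_sharing(usage: pd.DataFrame, gene_class: str,
                 group_col: str = "subset") -> Dict:
    """Shared and group-unique gene sets for one gene class."""
    sub = usage.loc[(usage["gene_class"] == gene_class) & (usage["count"] > 0)]
    by_group = {g: set(d["gene"]) for g, d in sub.groupby(group_col,
                                                          observed=True)}
    if not by_group:
        return {"shared": set(), "unique": {}}
    shared = set.intersection(*by_group.values())
    unique = {
        g: genes - set.union(*(v for k, v in by_group.items() if k != g))
        if len(by_group) > 1 else genes
        for g, genes in by_group.items()
    }
    return {"shared": shared, "unique": unique}


def diversity(counts: Iterable[float], metric: str = "shannon") -> float:
    """Diversity of a category-count vector.

    shannon = -sum p_i ln p_i (natural log); simpson = 1 - sum p_i^2;
    richness = number of categories with count > 0; pielou =
    shannon / ln(richness), defined only for richness >= 2.
    """
    x = np.asarray(list(counts), dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero count vector has no diversity")
    p = x[x > 0] / total
    if metric == "shannon":
        return float(-(p * np.log(p)).sum())
    if metric == "simpson":
        return float(1.0 - (p ** 2).sum())
    if metric == "richness":
        return float(len(p))
    if metric == "pielou":
        rich = len(p)
        if rich < 2:
            raise ValueError("pielou evenness requires richness >= 2")
        return float(-(p * np.log(p)).sum() / np.log(rich))
    raise ValueError(f"unknown diversity metric {metric!r}")


def diversity_table(
    calls: pd.DataFrame,
    group_by: Sequence[str] = ("subset",),
    category_col: str = "alpha_v",
    metrics: Sequence[str] = ("shannon", "simpson", "richness", "pielou"),
) -> pd.DataFrame:
    """All diversity indices of ``category_col`` usage per group."""
    paired = calls.loc[
        calls["pairing_status"].isin(["paired_single", "dual_alpha"])
    ]
    rows = []
    for keys, grp in paired.groupby(list(group_by), observed=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        counts = grp[category_col].value_counts().to_numpy()
        row = dict(zip(group_by, keys))
        for m in metrics:
            try:
                row[m] = diversity(counts, m)
            except ValueError:
                row[m] = np.nan
        row["n_cells"] = len(grp)
        rows.append(row)
    return pd.DataFrame(rows)
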