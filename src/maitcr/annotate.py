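"""Cell-level QC, MAIT lineage gating, and dual-modality subset assignment.

QC removes cells exceeding a detected-gene ceiling or a mitochondrial
fraction ceiling (strict inequalities).  Two presets ship: "kaur"
(6,000 genes / 5% mitochondrial) and "garner" (3,000 genes / 8%), the
thresholds used for the primary and validation CITE-Seq datasets.

Lineage gating scores each cell by the mean normalized expression of MAIT
marker genes (KLRB1, ZBTB16, IL18R1, SLC4A10) and calls MAIT cells above
an Otsu split of the bimodal score, gated on detectable CD3E.  Subsets are
assigned by the dual-modality rule: a cell is CD8+ only when both the
CD8B transcript (not CD8A, which is detectable in essentially all MAIT
cells) and the anti-CD8 antibody tag are positive, and likewise for CD4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse, stats
from skimage.filters import threshold_otsu
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

DEFAULT_MAIT_MARKERS = ("KLRB1", "ZBTB16", "IL18R1", "SLC4A10")


@dataclass(frozen=True)
class QCThresholds:
    """Per-cell quality-control ceilings (strict inequalities)."""

    max_genes_detected: int
    max_mito_fraction: float
    preset_name: str = "custom"

    def __post_init__(self):
        if self.max_genes_detected <= 0:
            raise ValueError("max_genes_detected must be positive")
        if not 0 < self.max_mito_fraction < 1:
            raise ValueError("max_mito_fraction must lie in (0, 1)")


QC_PRESETS: Dict[str, QCThresholds] = {
    "kaur": QCThresholds(6000, 0.05, "kaur"),
    "garner": QCThresholds(3000, 0.08, "garner"),
}


def qc_preset(name: str) -> QCThresholds:
    try:
        return QC_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown QC preset {name!r}; available: {sorted(QC_PRESETS)}"
        ) from None


def apply_qc(qc: pd.DataFrame, thresholds: QCThresholds
             ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Partition cells into (kept, removed) by the QC ceilings.

    A cell is removed iff n_genes_detected > max_genes_detected OR
    mito_fraction > max_mito_fraction; cells exactly at a ceiling are kept.
    """
    removed_mask = (
        (qc["n_genes_detected"] > thresholds.max_genes_detected)
        | (qc["mito_fraction"] > thresholds.max_mito_fraction)
    )
    return qc.loc[~removed_mask], qc.loc[removed_mask]


def qc_metrics_from_counts(counts: ad.AnnData,
                           mito_prefix: str = "MT-") -> pd.DataFrame:
    """Derive n_genes_detected and mito_fraction from a count matrix."""
    X = counts.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    mito_cols = counts.var_names.str.startswith(mito_prefix)
    total = np.asarray(X.sum(axis=1)).ravel()
    mito = np.asarray(X[:, mito_cols].sum(axis=1)).ravel()
    return pd.DataFrame(
        {"n_genes_detected": n_genes.astype(int),
         "mito_fraction": np.divide(mito, total, out=np.zeros_like(mito,
                                                                   dtype=float),
                                    where=total > 0)},
        index=counts.obs_names,
    )


def normalize_counts(counts: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Library-size normalization (CP10K) followed by log1p, on a copy."""
    norm = counts.copy()
    sc.pp.normalize_total(norm, target_sum=target_sum)
    sc.pp.log1p(norm)
    return norm


def score_mait_lineage(
    norm: ad.AnnData,
    counts: ad.AnnData,
    marker_set: Sequence[str] = DEFAULT_MAIT_MARKERS,
    cd3_gene: str = "CD3E",
    threshold: Optional[float] = None,
) -> pd.DataFrame:
    """Score cells for MAIT identity and call the lineage.

    The score is the mean normalized (CP10K, log1p) expression over
    ``marker_set``.  A cell is called MAIT iff its score exceeds the
    threshold (Otsu split of the bimodal score distribution unless a fixed
    value is supplied) AND ``cd3_gene`` is detected in the raw counts.

    Returns a DataFrame with columns ``score``, ``cd3_detected``,
    ``lineage`` and the threshold in ``.attrs``.
    """
    missing = [g for g in list(marker_set) + [cd3_gene]
               if g not in norm.var_names]
    if missing:
        raise KeyError(f"marker genes absent from panel: {missing}")
    M = norm[:, list(marker_set)].X
    M = M.toarray() if sparse.issparse(M) else np.asarray(M)
    score = M.mean(axis=1)
    cd3 = counts[:, cd3_gene].X
    cd3 = cd3.toarray() if sparse.issparse(cd3) else np.asarray(cd3)
    cd3_detected = cd3.ravel() >= 1
    if threshold is None:
        threshold = float(threshold_otsu(score))
    lineage = np.where((score > threshold) & cd3_detected, "MAIT", "other")
    out = pd.DataFrame(
        {"score": score, "cd3_detected": cd3_detected, "lineage": lineage},
        index=norm.obs_names,
    )
    out.attrs["threshold"] = threshold
    return out


@dataclass(frozen=True)
class SubsetRule:
    """Dual-modality CD4/CD8 positivity rule.

    CD8 positivity requires the CD8B transcript (CD8A is deliberately not
    used: it is detectable in essentially all MAIT cells and does not
    track surface CD8) at ``transcript_min_count`` or above AND a positive
    anti-CD8 antibody tag; symmetrically for CD4.
    """

    cd8_transcript_gene: str = "CD8B"
    cd4_transcript_gene: str = "CD4"
    cd8_adt_tag: str = "CD8"
    cd4_adt_tag: str = "CD4"
    transcript_min_count: int = 1
    adt_positive_method: str = "gmm"  # "gmm" (CLR + 2-Gaussian split) | "quantile"
    adt_threshold_param: float = 0.65  # quantile when method == "quantile"

    def __post_init__(self):
        if self.cd8_transcript_gene == "CD8A":
            raise ValueError(
                "CD8A does not discriminate surface-CD8+ MAIT cells; "
                "use CD8B for the transcript arm of the rule"
            )
        if self.transcript_min_count < 1:
            raise ValueError("transcript_min_count must be >= 1")


def clr_transform(adt: pd.DataFrame) -> pd.DataFrame:
    """Centered log-ratio of ADT counts, per cell across tags.

    clr(x)_t = log(x_t + 1) - mean_t log(x_t + 1); invariant to scaling
    all of a cell's tags by a common factor (up to the +1 pseudocount).
    """
    logx = np.log(adt.astype(float) + 1.0)
    return logx.sub(logx.mean(axis=1), axis=0)


def adt_positive(adt: pd.DataFrame, tag: str, rule: SubsetRule) -> pd.Series:
    """Per-cell positivity call for one antibody tag.

    Default method fits a 2-component Gaussian mixture to the tag's CLR
    values and thresholds at the midpoint of the component means; the
    quantile method thresholds at a fixed quantile instead.
    """
    if tag not in adt.columns:
        raise KeyError(f"ADT tag {tag!r} missing from table "
                       f"(available: {list(adt.columns)})")
    clr = clr_transform(adt)[tag].to_numpy()
    if rule.adt_positive_method == "gmm":
        gm = GaussianMixture(n_components=2, random_state=0, n_init=3)
        gm.fit(clr.reshape(-1, 1))
        means = np.sort(gm.means_.ravel())
        thr = float(means.mean())
    elif rule.adt_positive_method == "quantile":
        thr = float(np.quantile(clr, rule.adt_threshold_param))
    else:
        raise ValueError(f"unknown ADT method {rule.adt_positive_method!r}")
    return pd.Series(clr > thr, index=adt.index, name=tag)


def assign_subset(
    counts: ad.AnnData,
    adt: pd.DataFrame,
    rule: SubsetRule = SubsetRule(),
) -> pd.Series:
    """Assign CD4/CD8/DN/DP subsets to (MAIT) cells by the dual-modality rule.

    ``counts`` and ``adt`` should be restricted to the MAIT cells being
    gated; the ADT thresholds are derived from that population.
    """
    missing = [g for g in (rule.cd8_transcript_gene, rule.cd4_transcript_gene)
               if g not in counts.var_names]
    if missing:
        raise KeyError(f"subset-rule transcripts absent from panel: {missing}")
    adt = adt.loc[counts.obs_names]

    def transcript_pos(gene):
        x = counts[:, gene].X
        x = x.toarray() if sparse.issparse(x) else np.asarray(x)
        return x.ravel() >= rule.transcript_min_count

    cd8 = transcript_pos(rule.cd8_transcript_gene) & adt_positive(
        adt, rule.cd8_adt_tag, rule).to_numpy()
    cd4 = transcript_pos(rule.cd4_transcript_gene) & adt_positive(
        adt, rule.cd4_adt_tag, rule).to_numpy()
    subset = np.select(
        [cd8 & cd4, cd8, cd4], ["DP", "CD8", "CD4"], default="DN"
    )
    return pd.Series(subset, index=counts.obs_names, name="subset")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg FDR adjustment (monotone nondecreasing in p)."""
    return multipletests(np.asarray(pvalues, dtype=float),
                         method="fdr_bh")[1]


def marker_de(
    norm: ad.AnnData,
    group_a: Sequence[str],
    group_b: Sequence[str],
    genes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Two-group differential expression by unpaired Wilcoxon rank-sum test.

    Per gene: the Mann-Whitney U statistic, two-sided p-value (midrank tie
    handling), Benjamini-Hochberg adjusted p-value, and the log2 fold
    change of group means on the normalized scale (0.1 pseudocount).
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 cells")
    genes = list(genes) if genes is not None else list(norm.var_names)
    A = norm[group_a, genes].X
    B = norm[group_b, genes].X
    A = A.toarray() if sparse.issparse(A) else np.asarray(A)
    B = B.toarray() if sparse.issparse(B) else np.asarray(B)
    stat, pval = stats.mannwhitneyu(A, B, axis=0, alternative="two-sided",
                                    method="asymptotic")
    eps = 0.1
    logfc = np.log2((A.mean(axis=0) + eps) / (B.mean(axis=0) + eps))
    padj = bh_adjust(pval)
    return (
        pd.DataFrame(
            {"gene": genes, "statistic": stat, "pvalue": pval,
             "padj": padj, "log2fc": logfc}
        )
        .sort_values("pvalue", kind="mergesort")
        .reset_index(drop=True)
    )
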