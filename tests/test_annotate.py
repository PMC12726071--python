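"""QC boundaries, lineage gating, subset rule, and rank-sum DE."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from maitcr import (
    QCThresholds,
    SubsetRule,
    apply_qc,
    assign_subset,
    bh_adjust,
    clr_transform,
    marker_de,
    normalize_counts,
    qc_preset,
    score_mait_lineage,
)


def _qc_frame(rows):
    return pd.DataFrame(
        rows, columns=["n_genes_detected", "mito_fraction"],
        index=[f"c{i}" for i in range(len(rows))])


class TestApplyQC:
    @pytest.mark.parametrize(
        "preset,n_genes,mito,removed",
        [
            # exceeding the detected-gene ceiling is removed
            ("kaur", 6500, 0.02, True),
            # exceeding the mitochondrial ceiling is removed
            ("kaur", 2000, 0.055, True),
            # exactly at both ceilings is kept (strict inequalities)
            ("kaur", 6000, 0.05, False),
            ("garner", 3001, 0.01, True),
            ("garner", 1000, 0.081, True),
            ("garner", 3000, 0.08, False),
        ],
    )
    def test_boundaries(self, preset, n_genes, mito, removed):
        kept, rem = apply_qc(_qc_frame([(n_genes, mito)]), qc_preset(preset))
        assert (len(rem) == 1) is removed

    def test_partition_is_exact_and_order_independent(self):
        rng = np.random.default_rng(0)
        qc = _qc_frame(list(zip(rng.integers(100, 9000, 50),
                                rng.uniform(0, 0.2, 50))))
        kept, rem = apply_qc(qc, qc_preset("kaur"))
        assert set(kept.index) | set(rem.index) == set(qc.index)
        assert not set(kept.index) & set(rem.index)
        shuffled = qc.sample(frac=1, random_state=1)
        kept2, rem2 = apply_qc(shuffled, qc_preset("kaur"))
        assert set(kept2.index) == set(kept.index)

    def test_empty_input(self):
        kept, rem = apply_qc(_qc_frame([]), qc_preset("kaur"))
        assert len(kept) == 0 and len(rem) == 0

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            QCThresholds(0, 0.05)
        with pytest.raises(ValueError):
            QCThresholds(6000, 1.5)


def _adata(matrix, genes, barcodes=None):
    barcodes = barcodes or [f"c{i}" for i in range(len(matrix))]
    return ad.AnnData(
        X=sparse.csr_matrix(np.asarray(matrix, dtype=np.int32)),
        obs=pd.DataFrame(index=barcodes),
        var=pd.DataFrame(index=genes),
    )


class TestLineageGate:
    genes = ["KLRB1", "ZBTB16", "IL18R1", "SLC4A10", "CD3E", "ACTB"]

    def test_all_zero_markers_not_mait(self):
        counts = _adata([[0, 0, 0, 0, 5, 50], [9, 9, 9, 9, 5, 50]], self.genes)
        res = score_mait_lineage(normalize_counts(counts), counts,
                                 threshold=0.5)
        assert res.loc["c0", "score"] == 0.0
        assert res.loc["c0", "lineage"] == "other"
        assert res.loc["c1", "lineage"] == "MAIT"

    def test_cd3_negative_cell_never_mait(self):
        counts = _adata([[9, 9, 9, 9, 0, 50], [9, 9, 9, 9, 5, 50]], self.genes)
        res = score_mait_lineage(normalize_counts(counts), counts,
                                 threshold=0.0)
        assert res.loc["c0", "lineage"] == "other"
        assert res.loc["c1", "lineage"] == "MAIT"

    def test_missing_marker_error_names_genes(self):
        counts = _adata([[1, 1]], ["KLRB1", "CD3E"])
        with pytest.raises(KeyError, match="ZBTB16"):
            score_mait_lineage(normalize_counts(counts), counts)

    def test_recall_on_synthetic_truth(self, paper_bundle):
        """The Otsu-gated marker score recovers >=95% of true MAIT cells."""
        counts = paper_bundle.counts
        res = score_mait_lineage(normalize_counts(counts), counts)
        truth = paper_bundle.truth
        mait = truth.index[truth["lineage"] == "MAIT"]
        recall = (res.loc[mait, "lineage"] == "MAIT").mean()
        assert recall >= 0.95
        contaminants = truth.index[truth["lineage"] != "MAIT"]
        fpr = (res.loc[contaminants, "lineage"] == "MAIT").mean()
        assert fpr <= 0.05


def _subset_fixture():
    """20 cells with clearly separated transcript/ADT structure.

    A constant CD161 tag emulates the rest of the antibody panel, keeping
    per-cell CLR values interpretable for the double-positive cell.
    """
    rows, adt_rows, expected = [], [], []
    for i in range(20):
        if i < 8:  # CD8-like
            rows.append([0, 3, 0, 40]); adt_rows.append([100, 2, 150]); expected.append("CD8")
        elif i < 12:  # CD4-like
            rows.append([0, 0, 4, 40]); adt_rows.append([3, 90, 150]); expected.append("CD4")
        elif i < 19:  # DN
            rows.append([5, 0, 0, 40]); adt_rows.append([2, 3, 150]); expected.append("DN")
        else:  # DP
            rows.append([0, 2, 2, 40]); adt_rows.append([180, 160, 150]); expected.append("DP")
    counts = _adata(rows, ["CD8A", "CD8B", "CD4", "ACTB"])
    adt = pd.DataFrame(adt_rows, columns=["CD8", "CD4", "CD161"],
                       index=counts.obs_names)
    return counts, adt, expected


class TestAssignSubset:
    def test_dual_modality_rule(self):
        counts, adt, expected = _subset_fixture()
        res = assign_subset(counts, adt)
        assert list(res) == expected

    def test_cd8a_alone_does_not_make_cd8(self):
        # CD8A transcript is detectable in all MAIT cells; without CD8B and
        # the anti-CD8 tag the cell stays DN.
        counts, adt, expected = _subset_fixture()
        assert counts["c12", "CD8A"].X[0, 0] == 5
        assert assign_subset(counts, adt)["c12"] == "DN"

    def test_cd8a_as_transcript_gene_rejected(self):
        with pytest.raises(ValueError, match="CD8A"):
            SubsetRule(cd8_transcript_gene="CD8A")

    def test_missing_adt_tag_named(self):
        counts, adt, _ = _subset_fixture()
        with pytest.raises(KeyError, match="CD4"):
            assign_subset(counts, adt.drop(columns=["CD4"]))

    def test_accuracy_on_synthetic_truth(self, paper_bundle):
        truth = paper_bundle.truth
        mait = truth.index[truth["lineage"] == "MAIT"].to_list()
        res = assign_subset(paper_bundle.counts[mait],
                            paper_bundle.adt.loc[mait])
        acc = (res == truth.loc[mait, "subset"]).mean()
        assert acc >= 0.95

    def test_clr_approximately_invariant_to_cell_scaling(self):
        rng = np.random.default_rng(0)
        adt = pd.DataFrame(rng.integers(100, 2000, size=(30, 3)),
                           columns=["CD8", "CD4", "CD161"])
        scaled = (adt * 7).astype(int)
        diff = (clr_transform(adt) - clr_transform(scaled)).abs().to_numpy()
        assert diff.max() < 0.01  # exact up to the +1 pseudocount


class TestMarkerDE:
    def _groups(self, shift_gene=None, fold=4.0, n=200, seed=0):
        rng = np.random.default_rng(seed)
        genes = ["G1", "G2", "G3", "G4", "G5"]
        mean = np.full(len(genes), 4.0)
        A = rng.poisson(mean, size=(n, len(genes)))
        meanB = mean.copy()
        if shift_gene is not None:
            meanB[genes.index(shift_gene)] *= fold
        B = rng.poisson(meanB, size=(n, len(genes)))
        X = np.vstack([A, B])
        counts = _adata(X, genes)
        norm = normalize_counts(counts)
        cells = list(counts.obs_names)
        return norm, cells[:n], cells[n:]

    def test_identical_groups_null(self):
        norm, a, _ = self._groups()
        res = marker_de(norm, a, a)
        assert (res["padj"] > 0.95).all()
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-12)

    def test_planted_shift_is_top_hit(self):
        norm, a, b = self._groups(shift_gene="G3")
        res = marker_de(norm, a, b)
        assert res.iloc[0]["gene"] == "G3"
        assert res.iloc[0]["padj"] == res["padj"].min()
        assert res.iloc[0]["log2fc"] < 0  # planted in group B

    def test_padj_monotone_in_p(self):
        norm, a, b = self._groups(shift_gene="G1", fold=1.5)
        res = marker_de(norm, a, b).sort_values("pvalue")
        assert res["padj"].is_monotonic_increasing

    def test_empty_group_raises(self):
        norm, a, b = self._groups()
        with pytest.raises(ValueError):
            marker_de(norm, a, [])


def test_bh_hand_example():
    np.testing.assert_allclose(
        bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])
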