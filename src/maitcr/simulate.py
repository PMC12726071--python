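"""Seeded synthetic CITE-Seq repertoire generator.

Emits a dataset bundle — gene counts, antibody-derived-tag (ADT) counts,
per-cell QC metrics, paired VDJ contigs, and a ground-truth table — whose
statistical structure matches blood MR1-5-OP-RU-tetramer+ MAIT cells:
subset composition, subset-conditional TRAV1-2 usage, canonical TRAJ/TRBV
pairing, dual-TCRalpha rates, and the CDR3alpha length/motif/anchor
grammar.  Every draw flows from a single numpy Generator, so a fixed
(config, seed) pair yields byte-identical output files.

Count model: negative binomial for genes (size = ``nb_dispersion``),
log-normal rounded to integers for ADTs.  The mitochondrial fraction is
planted directly per cell (Beta-distributed, with QC violators sampled
above the filtering thresholds) and carried by five mitochondrial genes
whose counts realize the planted fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .config import (
    CONDITIONS,
    DUAL_CATEGORIES,
    GROUPS,
    MITO_GENES,
    SUBSETS,
    GeneratorConfig,
    MotifParams,
)
from .genes import (
    AA_ALPHABET,
    CANONICAL_TRAJ,
    CANONICAL_TRAJ_TAILS,
    CANONICAL_TRAV,
    CANONICAL_TRBV,
    NONCANONICAL_TRAJ,
    NONCANONICAL_TRAV,
    NONCANONICAL_TRBV,
    TRBD_SEGMENTS,
    TRBJ_SEGMENTS,
)

# Sampling weights within the canonical sets: TRAJ33 and TRAJ12 predominate
# among canonical joins; TRBV6-4 is the most frequent canonical beta V.
_CANON_TRAJ_W = {"TRAJ33": 0.55, "TRAJ20": 0.15, "TRAJ12": 0.30}
_CANON_TRBV_W = {"TRBV6-4": 0.50, "TRBV6-1": 0.30, "TRBV20-1": 0.20}

_CDR3B_TAILS = ("EQYF", "EQFF", "YGYTF", "TEAFF")

_NON_G = [c for c in AA_ALPHABET if c != "G"]
_NON_V = [c for c in AA_ALPHABET if c != "V"]

_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def _reverse_translate(aa: str) -> str:
    return "".join(_CODON[c] for c in aa)


def _scrub_g_runs(chars: list, rng: np.random.Generator,
                  protect: Tuple[int, int] | None = None) -> None:
    """Break every unplanted glycine run of length >= 3 in place.

    ``protect`` is a half-open 0-based span whose residues are never
    touched (the planted motif).
    """
    i = 0
    n = len(chars)
    while i <= n - 3:
        if chars[i] == chars[i + 1] == chars[i + 2] == "G":
            j = i + 1  # middle of the run
            if protect is not None and protect[0] <= j < protect[1]:
                i += 1
                continue
            chars[j] = str(rng.choice(_NON_G))
        else:
            i += 1


def sample_cdr3_alpha(
    canonical: bool,
    length_range: Tuple[int, int],
    motif_params: MotifParams,
    rng: np.random.Generator,
    traj: str = "TRAJ33",
    subset: str = "DN",
    exclude_lengths: frozenset = frozenset(),
) -> Tuple[str, Dict]:
    """Draw one CDR3alpha amino-acid string.

    All strings start with the conserved C/A anchor pair.  Canonical
    strings (TRAV1-2 joined to TRAJ33/20/12) end in the 7-residue
    germline J tail carrying the conserved tyrosine at the 5th position
    from the C-terminus.  Noncanonical strings plant valine at position 3
    and central glycine-run (or, in CD4+ cells, tetra-asparagine) motifs
    at the configured probabilities, and keep a J-like C-terminal
    composition drawn from {L, I, T, F, W}.

    Returns the string plus a dict of the planted features.
    """
    lo, hi = length_range
    if hi < lo:
        raise ValueError("empty length range")
    if lo < 5:
        raise ValueError("CDR3alpha length < 5 cannot satisfy anchors")
    info: Dict = {"gly_pattern": "", "gly_start": 0, "nnnn": False, "v3": False}

    if canonical:
        if lo < 9:
            raise ValueError("canonical CDR3alpha needs length >= 9")
        lengths = np.arange(lo, hi + 1)
        if tuple(length_range) == (12, 14):
            weights = np.array([0.5, 0.3, 0.2])
        else:
            weights = np.full(len(lengths), 1 / len(lengths))
        length = int(rng.choice(lengths, p=weights))
        tail = CANONICAL_TRAJ_TAILS[traj]
        mid = [str(c) for c in rng.choice(list(AA_ALPHABET), size=length - 9)]
        chars = list("CA") + mid + list(tail)
        _scrub_g_runs(chars, rng)
        return "".join(chars), info

    plant_gly = rng.random() < motif_params.gly_motif_prob
    if plant_gly:
        if subset == "CD4":
            pattern = "GGGG" if rng.random() < 0.7 else "GGG"
        else:
            pattern = "GGG" if rng.random() < 0.7 else "GGGG"
    else:
        pattern = ""
    plant_nnnn = (
        not plant_gly
        and subset == "CD4"
        and rng.random() < motif_params.nnnn_motif_prob_cd4
    )

    min_len = 10 if (plant_gly or plant_nnnn) else lo
    allowed = [l for l in range(min_len, hi + 1) if l not in exclude_lengths]
    if not allowed:
        raise ValueError("no admissible CDR3 length under the constraints")
    length = int(rng.integers(lo, hi + 1))
    if length not in allowed:
        length = int(rng.choice(allowed))

    chars = [""] * length
    chars[0], chars[1] = "C", "A"
    info["v3"] = bool(rng.random() < motif_params.v_at_pos3_prob)
    chars[2] = "V" if info["v3"] else str(rng.choice(_NON_V))
    # J-segment-like conserved C-terminal residues
    chars[-1] = str(rng.choice(["F", "W"], p=[0.8, 0.2]))
    chars[-2] = str(rng.choice(list("LITF")))
    chars[-3] = str(rng.choice(list("LITF")))
    for i in range(3, length - 3):
        chars[i] = str(rng.choice(list(AA_ALPHABET)))

    protect = None
    run = pattern if plant_gly else ("NNNN" if plant_nnnn else "")
    if run:
        k = len(run)
        w_lo, w_hi = motif_params.central_window
        # 1-based starts keeping the run inside the free region (after the
        # position-3 anchor, before the 3-residue tail) and intersecting the
        # central window.
        s_min = max(4, w_lo - k + 1)
        s_max = min(length - 3 - k + 1, w_hi)
        if s_min <= s_max:
            start = int(rng.integers(s_min, s_max + 1))
            chars[start - 1:start - 1 + k] = list(run)
            protect = (start - 1, start - 1 + k)
            if plant_gly:
                info["gly_pattern"] = run
                info["gly_start"] = start
            else:
                info["nnnn"] = True
    _scrub_g_runs(chars, rng, protect=protect)
    return "".join(chars), info


def _sample_cdr3_beta(rng: np.random.Generator) -> str:
    length = int(rng.integers(14, 17))
    tail = str(rng.choice(_CDR3B_TAILS))
    mid = "".join(str(c) for c in rng.choice(list(AA_ALPHABET),
                                             size=length - 4 - len(tail)))
    return "CASS" + mid + tail


@dataclass
class RepertoireBundle:
    """In-memory synthetic dataset: counts, ADTs, QC metrics, contigs, truth."""

    counts: ad.AnnData
    adt: pd.DataFrame
    qc: pd.DataFrame
    contigs: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig

    @property
    def barcodes(self) -> pd.Index:
        return self.counts.obs_names


def _sample_alpha_chain(cfg: GeneratorConfig, rng, trav12: bool, subset: str):
    """Draw (v, j, cdr3, canonical_traj) for one alpha chain."""
    if trav12:
        v = CANONICAL_TRAV
        canon_j = rng.random() < cfg.canonical_traj_prob_given_trav12
    else:
        v = str(rng.choice(NONCANONICAL_TRAV))
        canon_j = rng.random() < cfg.canonical_traj_prob_given_noncanonical
    if canon_j:
        j = str(rng.choice(list(_CANON_TRAJ_W), p=list(_CANON_TRAJ_W.values())))
    else:
        j = str(rng.choice(NONCANONICAL_TRAJ))
    if trav12 and canon_j:
        cdr3, info = sample_cdr3_alpha(
            True, cfg.canonical_len_range, cfg.motif_params, rng,
            traj=j, subset=subset,
        )
    else:
        # A TRAV1-2+ chain with a noncanonical join falls outside the
        # canonical 12-14 length band, so that band's prevalence among
        # TRAV1-2+ cells equals the planted canonical-join rate.
        lo, hi = cfg.canonical_len_range
        exclude = frozenset(range(lo, hi + 1)) if trav12 else frozenset()
        cdr3, info = sample_cdr3_alpha(
            False, cfg.noncanonical_len_range, cfg.motif_params, rng,
            subset=subset, exclude_lengths=exclude,
        )
    return v, j, cdr3, canon_j, info


def generate_repertoire(config: GeneratorConfig) -> RepertoireBundle:
    """Generate a full synthetic dataset bundle under ``config``.

    Every MAIT cell receives one productive beta contig and one productive
    alpha contig (two with probability ``dual_alpha_prob``); contaminant
    NK/gamma-delta-like cells receive no TCR contigs.  CD8A transcript
    counts are strictly positive in every MAIT cell, while CD8B and CD4
    transcript and ADT levels are subset-dependent, feeding the
    dual-modality subset rule downstream.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    n_cont = int(round(cfg.n_cells * cfg.contaminant_fraction))
    n_mait = cfg.n_cells - n_cont
    if n_mait <= 0:
        raise ValueError("contaminant_fraction leaves no MAIT cells")
    barcodes = [f"CELL{i:06d}-1" for i in range(cfg.n_cells)]

    subsets = rng.choice(SUBSETS, size=n_mait, p=[cfg.subset_probs[s] for s in SUBSETS])
    cont_lineage = rng.choice(["NK", "gdT"], size=n_cont)
    lineage = np.concatenate([np.full(n_mait, "MAIT"), cont_lineage])
    group = np.array(
        [f"MAIT_{s}" for s in subsets] + list(cont_lineage), dtype=object
    )
    condition = rng.choice(
        CONDITIONS, size=cfg.n_cells, p=[cfg.condition_probs[c] for c in CONDITIONS]
    )

    # ---- VDJ contigs and per-cell truth -------------------------------
    contig_rows = []
    truth_rows = []
    for i in range(n_mait):
        bc = barcodes[i]
        subset = str(subsets[i])
        p_canon = float(
            np.clip(
                cfg.canonical_alpha_prob_by_subset[subset]
                + cfg.canonical_shift_by_condition[str(condition[i])],
                0.0, 1.0,
            )
        )
        dual = bool(rng.random() < cfg.dual_alpha_prob)
        if dual:
            cat = str(rng.choice(
                DUAL_CATEGORIES, p=[cfg.dual_alpha_category_probs[c]
                                    for c in DUAL_CATEGORIES]))
            flags = {"both_trav12": [True, True],
                     "one_trav12": [True, False],
                     "neither": [False, False]}[cat]
        else:
            cat = ""
            flags = [bool(rng.random() < p_canon)]

        alphas = [_sample_alpha_chain(cfg, rng, f, subset) for f in flags]
        trav12_cell = any(flags)
        # representative alpha: the TRAV1-2 chain when present, else the first
        rep = alphas[flags.index(True)] if trav12_cell else alphas[0]

        if trav12_cell:
            if rng.random() < cfg.canonical_trbv_prob_given_trav12:
                trbv = str(rng.choice(list(_CANON_TRBV_W),
                                      p=list(_CANON_TRBV_W.values())))
            else:
                trbv = str(rng.choice(NONCANONICAL_TRBV))
        else:
            trbv = str(rng.choice(NONCANONICAL_TRBV + CANONICAL_TRBV))
        trbj = str(rng.choice(TRBJ_SEGMENTS))
        trbd = str(rng.choice(TRBD_SEGMENTS))
        cdr3b = _sample_cdr3_beta(rng)

        for k, (v, j, cdr3, _cj, _info) in enumerate(alphas):
            umis = int(rng.integers(2, 60))
            contig_rows.append(
                (bc, "TRA", v, "", j, cdr3, True, True, umis,
                 umis * int(rng.integers(20, 40)), f"{bc}_contig_{k + 1}")
            )
        umis = int(rng.integers(2, 60))
        contig_rows.append(
            (bc, "TRB", trbv, trbd, trbj, cdr3b, True, True, umis,
             umis * int(rng.integers(20, 40)), f"{bc}_contig_b")
        )
        if rng.random() < cfg.nonproductive_extra_prob:
            v = str(rng.choice(NONCANONICAL_TRAV))
            j = str(rng.choice(NONCANONICAL_TRAJ))
            cdr3, _ = sample_cdr3_alpha(False, cfg.noncanonical_len_range,
                                        cfg.motif_params, rng, subset=subset)
            umis = int(rng.integers(1, 5))
            contig_rows.append(
                (bc, "TRA", v, "", j, cdr3, False, True, umis,
                 umis * int(rng.integers(20, 40)), f"{bc}_contig_np")
            )

        rep_v, rep_j, rep_cdr3, rep_canon_j, rep_info = rep
        truth_rows.append({
            "barcode": bc,
            "lineage": "MAIT",
            "subset": subset,
            "condition": str(condition[i]),
            "trav12": trav12_cell,
            "dual_alpha": dual,
            "dual_category": cat,
            "canonical_traj": rep_canon_j,
            "canonical_trbv": trbv in CANONICAL_TRBV,
            "cdr3a": rep_cdr3,
            "cdr3a2": alphas[1][2] if dual else "",
            "cdr3b": cdr3b,
            "gly_motif": bool(rep_info["gly_pattern"]),
            "gly_pattern": rep_info["gly_pattern"],
            "nnnn_motif": rep_info["nnnn"],
            "v_at_pos3": rep_info["v3"],
        })
    for i in range(n_mait, cfg.n_cells):
        truth_rows.append({
            "barcode": barcodes[i], "lineage": str(lineage[i]), "subset": "",
            "condition": str(condition[i]), "trav12": False,
            "dual_alpha": False, "dual_category": "", "canonical_traj": False,
            "canonical_trbv": False, "cdr3a": "", "cdr3a2": "", "cdr3b": "",
            "gly_motif": False, "gly_pattern": "", "nnnn_motif": False,
            "v_at_pos3": False,
        })

    contigs = pd.DataFrame(
        contig_rows,
        columns=["barcode", "chain", "v_gene", "d_gene", "j_gene", "cdr3",
                 "productive", "high_confidence", "umis", "reads", "contig_id"],
    )

    # ---- gene counts ---------------------------------------------------
    panel_genes = list(cfg.marker_means)
    size = cfg.nb_dispersion
    mean_mat = np.zeros((cfg.n_cells, len(panel_genes)))
    for gi, gene in enumerate(panel_genes):
        per_group = cfg.marker_means[gene]
        mean_mat[:, gi] = [per_group[g] for g in group]
    with np.errstate(divide="ignore"):
        p = size / (size + mean_mat)
    X = rng.negative_binomial(size, np.clip(p, 1e-12, 1.0))
    # every MAIT cell has detectable CD8A transcript (shifted draw)
    if "CD8A" in panel_genes:
        gi = panel_genes.index("CD8A")
        mait_mask = lineage == "MAIT"
        mu = np.maximum(mean_mat[mait_mask, gi] - 1.0, 1e-6)
        X[mait_mask, gi] = 1 + rng.negative_binomial(size, size / (size + mu))

    # ---- planted QC metrics and mitochondrial counts -------------------
    n_out = int(round(cfg.n_cells * cfg.qc_outlier_fraction))
    out_idx = rng.choice(cfg.n_cells, size=n_out, replace=False)
    out_type = rng.choice(["genes", "mito", "both"], size=n_out, p=[0.45, 0.45, 0.10])
    mito_f = rng.beta(4, 156, size=cfg.n_cells)
    n_genes = np.clip(rng.normal(2500, 500, size=cfg.n_cells), 300, 5800)
    for idx, typ in zip(out_idx, out_type):
        if typ in ("mito", "both"):
            mito_f[idx] = rng.uniform(0.055, 0.25)
        if typ in ("genes", "both"):
            n_genes[idx] = rng.uniform(6100, 9500)
    n_genes = n_genes.astype(int)
    qc_outlier = np.zeros(cfg.n_cells, dtype=bool)
    qc_outlier[out_idx] = True

    nonmito_total = X.sum(axis=1)
    mito_total = np.round(mito_f / (1 - mito_f) * nonmito_total).astype(int)
    mito_counts = rng.multinomial(
        mito_total, np.full(len(MITO_GENES), 1 / len(MITO_GENES))
    )
    X = np.hstack([X, mito_counts])
    genes = panel_genes + list(MITO_GENES)
    denom = np.maximum(mito_total + nonmito_total, 1)
    mito_fraction = mito_total / denom

    counts = ad.AnnData(
        X=sparse.csr_matrix(X.astype(np.int32)),
        obs=pd.DataFrame(
            {"condition": pd.Categorical(condition)},
            index=pd.Index(barcodes, name="barcode"),
        ),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )

    qc = pd.DataFrame(
        {
            "n_genes_detected": n_genes,
            "mito_fraction": mito_fraction,
            "qc_outlier": qc_outlier,
            "condition": condition,
        },
        index=pd.Index(barcodes, name="barcode"),
    )

    # ---- ADT counts ----------------------------------------------------
    adt_cols = {}
    for tag, per_group in cfg.adt_means.items():
        mu = np.array([per_group[g] for g in group], dtype=float)
        adt_cols[tag] = np.round(
            np.exp(rng.normal(np.log(mu), 0.4))
        ).astype(int)
    adt = pd.DataFrame(adt_cols, index=pd.Index(barcodes, name="barcode"))

    truth = pd.DataFrame(truth_rows).set_index("barcode")
    tra_per_bc = (
        contigs.loc[(contigs["chain"] == "TRA") & contigs["productive"]]
        .groupby("barcode").size()
    )
    dual_bcs = truth.index[truth["dual_alpha"]]
    assert (tra_per_bc.reindex(dual_bcs).fillna(0) == 2).all(), (
        "dual-alpha truth labels inconsistent with emitted contigs"
    )

    return RepertoireBundle(counts=counts, adt=adt, qc=qc, contigs=contigs,
                            truth=truth, config=cfg)
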