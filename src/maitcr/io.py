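"""Readers and writers for the standard file formats of the pipeline.

Formats: Matrix Market gene counts with features/barcodes lists (the 10x
Cell Ranger layout), ADT count CSV, 10x ``filtered_contig_annotations.csv``
dialect, AIRR Rearrangement TSV, per-cell QC CSV, ground-truth CSV, and a
McPAS-style CDR3-epitope reference CSV.
"""

from __future__ import annotations

import os
from typing import Dict, List

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .genes import normalize_gene_symbol

TENX_COLUMNS = [
    "barcode", "is_cell", "high_confidence", "chain", "v_gene", "d_gene",
    "j_gene", "cdr3", "cdr3_nt", "productive", "reads", "umis",
    "raw_clonotype_id",
]
_TENX_MANDATORY = ["barcode", "chain", "v_gene", "j_gene", "cdr3", "productive"]

AIRR_COLUMNS = [
    "sequence_id", "cell_id", "locus", "v_call", "d_call", "j_call",
    "junction", "junction_aa", "productive", "duplicate_count",
    "consensus_count",
]
_AIRR_MANDATORY = ["cell_id", "locus", "v_call", "j_call", "junction_aa",
                   "productive"]

CONTIG_FIELDS = ["barcode", "chain", "v_gene", "d_gene", "j_gene", "cdr3",
                 "productive", "high_confidence", "umis", "reads", "contig_id"]

_TRUTHY = {"true", "t", "yes", "1"}


def _to_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    return series.astype(str).str.strip().str.lower().isin(_TRUTHY)


def _normalize_contigs(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("v_gene", "d_gene", "j_gene"):
        df[col] = df[col].fillna("").map(normalize_gene_symbol)
    df["cdr3"] = df["cdr3"].fillna("").astype(str).str.upper()
    df["chain"] = df["chain"].where(df["chain"].isin(["TRA", "TRB"]), "other")
    df["umis"] = pd.to_numeric(df["umis"], errors="coerce").fillna(0).astype(int)
    return df[CONTIG_FIELDS].reset_index(drop=True)


def read_contigs(path, dialect: str = "10x-csv") -> pd.DataFrame:
    """Parse VDJ contigs from a 10x contig CSV or an AIRR rearrangement TSV.

    Gene symbols are normalized at read time (allele suffixes stripped,
    ``/DV`` dual names preserved); nonproductive and low-confidence contigs
    are retained with their flags set.
    """
    if dialect == "10x-csv":
        df = pd.read_csv(path, dtype=str)
        missing = [c for c in _TENX_MANDATORY if c not in df.columns]
        if missing:
            raise ValueError(
                f"10x contig CSV {path} is missing mandatory columns: {missing}"
            )
        out = pd.DataFrame({
            "barcode": df["barcode"],
            "chain": df["chain"].str.upper(),
            "v_gene": df["v_gene"],
            "d_gene": df.get("d_gene", ""),
            "j_gene": df["j_gene"],
            "cdr3": df["cdr3"],
            "productive": _to_bool(df["productive"]),
            "high_confidence": _to_bool(df["high_confidence"])
            if "high_confidence" in df.columns else True,
            "umis": df.get("umis", 1),
            "reads": pd.to_numeric(df.get("reads", 0), errors="coerce"),
            "contig_id": df.get("contig_id",
                                pd.Series(np.arange(len(df)).astype(str))),
        })
    elif dialect == "airr-tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in _AIRR_MANDATORY if c not in df.columns]
        if missing:
            raise ValueError(
                f"AIRR TSV {path} is missing mandatory columns: {missing}"
            )
        out = pd.DataFrame({
            "barcode": df["cell_id"],
            "chain": df["locus"].str.upper(),
            "v_gene": df["v_call"],
            "d_gene": df.get("d_call", ""),
            "j_gene": df["j_call"],
            "cdr3": df["junction_aa"],
            "productive": _to_bool(df["productive"]),
            "high_confidence": True,
            "umis": df.get("duplicate_count", 1),
            "reads": pd.to_numeric(df.get("consensus_count", 0),
                                   errors="coerce"),
            "contig_id": df.get("sequence_id",
                                pd.Series(np.arange(len(df)).astype(str))),
        })
    else:
        raise ValueError(f"unknown contig dialect: {dialect!r}")
    out["reads"] = out["reads"].fillna(0).astype(int)
    return _normalize_contigs(out)


def write_contigs_10x(contigs: pd.DataFrame, path) -> None:
    df = pd.DataFrame({
        "barcode": contigs["barcode"],
        "is_cell": "true",
        "high_confidence": np.where(contigs["high_confidence"], "true", "false"),
        "chain": contigs["chain"],
        "v_gene": contigs["v_gene"],
        "d_gene": contigs["d_gene"].replace("", "None"),
        "j_gene": contigs["j_gene"],
        "cdr3": contigs["cdr3"],
        "cdr3_nt": contigs["cdr3_nt"]
        if "cdr3_nt" in contigs.columns else "",
        "productive": np.where(contigs["productive"], "true", "false"),
        "reads": contigs["reads"],
        "umis": contigs["umis"],
        "raw_clonotype_id": "",
    })
    df.to_csv(path, index=False)


def write_contigs_airr(contigs: pd.DataFrame, path,
                       allele_suffix: str = "*01") -> None:
    """Write contigs as an AIRR rearrangement TSV (allele-level gene calls)."""

    def call(series):
        return series.map(lambda g: f"{g}{allele_suffix}" if g else "")

    df = pd.DataFrame({
        "sequence_id": contigs["contig_id"],
        "cell_id": contigs["barcode"],
        "locus": contigs["chain"],
        "v_call": call(contigs["v_gene"]),
        "d_call": call(contigs["d_gene"]),
        "j_call": call(contigs["j_gene"]),
        "junction": contigs["cdr3_nt"] if "cdr3_nt" in contigs.columns else "",
        "junction_aa": contigs["cdr3"],
        "productive": np.where(contigs["productive"], "T", "F"),
        "duplicate_count": contigs["umis"],
        "consensus_count": contigs["reads"],
    })
    df.to_csv(path, sep="\t", index=False)


def write_counts_mtx(counts: ad.AnnData, out_dir) -> None:
    """Write counts in the Cell Ranger layout (genes x cells matrix.mtx)."""
    os.makedirs(out_dir, exist_ok=True)
    mat = sparse.csc_matrix(counts.X.T.astype(np.int64))
    spio.mmwrite(os.path.join(out_dir, "matrix.mtx"), mat, field="integer")
    pd.DataFrame({
        "gene_id": counts.var_names,
        "gene_name": counts.var_names,
        "feature_type": "Gene Expression",
    }).to_csv(os.path.join(out_dir, "features.tsv"), sep="\t", index=False,
              header=False)
    pd.Series(counts.obs_names).to_csv(
        os.path.join(out_dir, "barcodes.tsv"), sep="\t", index=False,
        header=False)


def read_counts_mtx(in_dir) -> ad.AnnData:
    mat = spio.mmread(os.path.join(in_dir, "matrix.mtx"))
    genes = pd.read_csv(os.path.join(in_dir, "features.tsv"), sep="\t",
                        header=None)[0]
    barcodes = pd.read_csv(os.path.join(in_dir, "barcodes.tsv"), sep="\t",
                           header=None)[0]
    return ad.AnnData(
        X=sparse.csr_matrix(mat.T.astype(np.int32)),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )


def write_bundle(bundle, out_dir) -> Dict[str, str]:
    """Write a generated dataset bundle to ``out_dir``; returns file paths.

    Re-reading the files reproduces the in-memory records (round trip);
    fixed (config, seed) pairs give byte-identical output.
    """
    if len(bundle.barcodes) == 0:
        raise ValueError("cannot write an empty dataset bundle")
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "counts_dir": str(out_dir),
        "adt": os.path.join(out_dir, "adt.csv"),
        "qc": os.path.join(out_dir, "cell_qc.csv"),
        "contigs_10x": os.path.join(out_dir, "filtered_contig_annotations.csv"),
        "contigs_airr": os.path.join(out_dir, "airr_rearrangement.tsv"),
        "truth": os.path.join(out_dir, "truth.csv"),
        "config": os.path.join(out_dir, "config.yaml"),
    }
    write_counts_mtx(bundle.counts, out_dir)
    bundle.adt.to_csv(paths["adt"])
    bundle.qc.to_csv(paths["qc"])
    contigs = bundle.contigs.copy()
    from .simulate import _reverse_translate  # naive back-translation
    contigs["cdr3_nt"] = contigs["cdr3"].map(_reverse_translate)
    write_contigs_10x(contigs, paths["contigs_10x"])
    write_contigs_airr(contigs, paths["contigs_airr"])
    bundle.truth.to_csv(paths["truth"])
    bundle.config.to_yaml(paths["config"])
    return paths


def read_adt(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def read_cell_qc(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, keep_default_na=False)
    for col in ("trav12", "dual_alpha", "canonical_traj", "canonical_trbv",
                "gly_motif", "nnnn_motif", "v_at_pos3"):
        df[col] = _to_bool(df[col])
    return df
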