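"""Generator configuration and the packaged study preset.

The preset encodes the repertoire proportions reported for blood
MR1-5-OP-RU-tetramer+ MAIT cells: subset composition (DN 50%, CD8+ 35%,
CD4+ 15%), subset-conditional TRAV1-2 usage (CD4+ cells are 90%
TRAV1-2-negative; CD8+ 15%; DN 35%), canonical joining-segment usage
(TRAJ33/20/12 in 90% of TRAV1-2+ cells but only 8% of TRAV1-2- cells),
canonical beta pairing (TRBV6-1/6-4/20-1 in 90% of TRAV1-2+ cells), a 9%
dual-TCRalpha rate splitting 35/40/25 into both/one/neither TRAV1-2
chains, and the CDR3alpha grammar of TRAV1-2- cells (glycine-run motifs
in ~25%, valine at position 3 in ~65%, lengths 7-23).
"""

from __future__ import annotations

import math
from typing import Dict, Tuple

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

SUBSETS = ("DN", "CD8", "CD4")
DUAL_CATEGORIES = ("both_trav12", "one_trav12", "neither")
CONDITIONS = ("ex_vivo", "IL2", "IL2_Mtb")

#: Cell populations the count model distinguishes.  MAIT cells are split by
#: coreceptor subset; contaminants emulate NK and gamma-delta T cells sorted
#: in the same batch.
GROUPS = ("MAIT_DN", "MAIT_CD8", "MAIT_CD4", "NK", "gdT")

MITO_GENES = ("MT-CO1", "MT-ND1", "MT-CYB", "MT-ATP6", "MT-ND4")


def _panel(dn, cd8, cd4, nk, gdt):
    return {"MAIT_DN": dn, "MAIT_CD8": cd8, "MAIT_CD4": cd4, "NK": nk, "gdT": gdt}


def default_marker_means() -> Dict[str, Dict[str, float]]:
    """Negative-binomial mean counts per gene and population.

    A compact ~40-gene panel: MAIT identity markers, CD3 complex,
    coreceptors, cytotoxic/costimulatory effector programs, and
    housekeeping filler.  Mitochondrial genes are handled separately (the
    per-cell mitochondrial fraction is planted directly).
    """
    return {
        # MAIT identity markers (high in MAIT, low in contaminants)
        "KLRB1": _panel(18, 18, 18, 2.0, 0.5),
        "ZBTB16": _panel(12, 12, 12, 0.1, 0.3),
        "IL18R1": _panel(15, 15, 15, 0.3, 0.5),
        "CXCR6": _panel(8, 8, 8, 0.1, 0.3),
        "SLC4A10": _panel(10, 10, 10, 0.05, 0.2),
        # CD3 complex: absent in NK
        "CD3D": _panel(8, 8, 8, 0.0, 8),
        "CD3E": _panel(15, 15, 15, 0.0, 15),
        "CD3G": _panel(6, 6, 6, 0.0, 6),
        # Coreceptors.  CD8A is universal in MAIT cells; CD8B tracks surface
        # CD8 and CD4 transcript tracks surface CD4 (the dual-modality rule).
        "CD8A": _panel(3, 6, 3, 1.0, 2),
        "CD8B": _panel(0.02, 15, 0.02, 0.02, 1.0),
        "CD4": _panel(0.02, 0.02, 15, 0.02, 0.1),
        # Cytotoxic program (CD8-biased)
        "NKG7": _panel(3, 8, 1, 10, 4),
        "GZMA": _panel(2, 6, 1, 6, 3),
        "GZMK": _panel(2, 6, 1, 2, 2),
        "GZMB": _panel(1, 4, 0.5, 8, 2),
        "PRF1": _panel(1, 4, 0.5, 6, 2),
        "GNLY": _panel(1, 3, 0.5, 8, 2),
        "KLRG1": _panel(1, 3, 0.5, 3, 1),
        "EOMES": _panel(0.5, 2, 0.3, 2, 0.5),
        "TNF": _panel(1, 2, 1, 0.5, 1),
        # Costimulatory / regulatory program (CD4-biased)
        "CTLA4": _panel(0.3, 0.3, 3, 0.1, 0.3),
        "TNFRSF4": _panel(0.3, 0.3, 3, 0.1, 0.3),
        "IL2RA": _panel(0.3, 0.3, 4, 0.1, 0.3),
        "FOXP3": _panel(0.1, 0.1, 2, 0.05, 0.1),
        "ICOS": _panel(0.5, 0.5, 3, 0.1, 0.5),
        "SELL": _panel(1, 1, 4, 1, 1),
        "MAL": _panel(0.3, 0.3, 3, 0.1, 0.3),
        "IL32": _panel(2, 2, 5, 0.5, 2),
        # Activation-associated (DN-biased)
        "JUN": _panel(5, 2, 2, 2, 2),
        "FOS": _panel(5, 2, 2, 2, 2),
        "DUSP1": _panel(4, 2, 2, 2, 2),
        "XCL1": _panel(2, 0.5, 0.5, 1, 0.5),
        "IFITM3": _panel(3, 1.5, 1.5, 2, 1.5),
        "IFNG": _panel(1, 2, 1, 1, 1),
        # Housekeeping
        "ACTB": _panel(20, 20, 20, 20, 20),
        "B2M": _panel(15, 15, 15, 15, 15),
        "GAPDH": _panel(12, 12, 12, 12, 12),
        "RPL13A": _panel(10, 10, 10, 10, 10),
        "RPS18": _panel(8, 8, 8, 8, 8),
    }


def default_adt_means() -> Dict[str, Dict[str, float]]:
    """Log-normal mean levels per antibody-derived tag and population."""
    return {
        "CD8": _panel(2, 100, 2, 2, 2),
        "CD4": _panel(2, 2, 80, 2, 2),
        "CD161": _panel(150, 150, 150, 30, 20),
    }


class MotifParams(BaseModel):
    """CDR3alpha motif-planting parameters for noncanonical chains."""

    gly_motif_prob: float = Field(0.25, ge=0, le=1)
    v_at_pos3_prob: float = Field(0.65, ge=0, le=1)
    nnnn_motif_prob_cd4: float = Field(0.10, ge=0, le=1)
    central_window: Tuple[int, int] = (6, 9)


class GeneratorConfig(BaseModel):
    """Full configuration of the synthetic CITE-Seq repertoire generator."""

    n_cells: int = Field(..., gt=0, description="total cells to simulate")
    seed: int = 0
    subset_probs: Dict[str, float] = {"DN": 0.50, "CD8": 0.35, "CD4": 0.15}
    canonical_alpha_prob_by_subset: Dict[str, float] = {
        "DN": 0.65, "CD8": 0.85, "CD4": 0.10,
    }
    canonical_traj_prob_given_trav12: float = Field(0.90, ge=0, le=1)
    canonical_traj_prob_given_noncanonical: float = Field(0.08, ge=0, le=1)
    canonical_trbv_prob_given_trav12: float = Field(0.90, ge=0, le=1)
    dual_alpha_prob: float = Field(0.09, ge=0, le=1)
    dual_alpha_category_probs: Dict[str, float] = {
        "both_trav12": 0.35, "one_trav12": 0.40, "neither": 0.25,
    }
    gly_motif_prob: float = Field(0.25, ge=0, le=1)
    v_at_pos3_prob: float = Field(0.65, ge=0, le=1)
    nnnn_motif_prob_cd4: float = Field(0.10, ge=0, le=1)
    canonical_len_range: Tuple[int, int] = (12, 14)
    noncanonical_len_range: Tuple[int, int] = (7, 23)
    marker_means: Dict[str, Dict[str, float]] = Field(
        default_factory=default_marker_means
    )
    adt_means: Dict[str, Dict[str, float]] = Field(default_factory=default_adt_means)
    nb_dispersion: float = Field(2.0, gt=0, description="NB size parameter")
    contaminant_fraction: float = Field(0.05, ge=0, lt=1)
    qc_outlier_fraction: float = Field(0.02, ge=0, lt=1)
    nonproductive_extra_prob: float = Field(0.02, ge=0, le=1)
    condition_probs: Dict[str, float] = {
        "ex_vivo": 1 / 3, "IL2": 1 / 3, "IL2_Mtb": 1 / 3,
    }
    # Additive shift applied to the subset-conditional canonical-alpha
    # probability per condition.  The study pools conditions when reporting
    # proportions, so the preset leaves all shifts at 0.
    canonical_shift_by_condition: Dict[str, float] = {
        "ex_vivo": 0.0, "IL2": 0.0, "IL2_Mtb": 0.0,
    }

    @field_validator("subset_probs")
    @classmethod
    def _subset_keys(cls, v):
        if set(v) != set(SUBSETS):
            raise ValueError(f"subset_probs must have keys {SUBSETS}")
        return v

    @field_validator("dual_alpha_category_probs")
    @classmethod
    def _dual_keys(cls, v):
        if set(v) != set(DUAL_CATEGORIES):
            raise ValueError(
                f"dual_alpha_category_probs must have keys {DUAL_CATEGORIES}"
            )
        return v

    @model_validator(mode="after")
    def _validate(self):
        for name in ("subset_probs", "dual_alpha_category_probs", "condition_probs"):
            probs = getattr(self, name)
            if any(p < 0 or p > 1 for p in probs.values()):
                raise ValueError(f"{name}: probabilities must lie in [0, 1]")
            if not math.isclose(sum(probs.values()), 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} must sum to 1 (got {sum(probs.values())})")
        for p in self.canonical_alpha_prob_by_subset.values():
            if not 0 <= p <= 1:
                raise ValueError("canonical_alpha_prob_by_subset values in [0, 1]")
        lo, hi = self.canonical_len_range
        nlo, nhi = self.noncanonical_len_range
        if lo > hi or nlo > nhi:
            raise ValueError("length ranges must be nonempty")
        if lo < 9:
            raise ValueError(
                "canonical CDR3alpha needs length >= 9 (CA anchor + 7-mer J tail)"
            )
        if nlo < 5:
            raise ValueError("noncanonical CDR3alpha needs length >= 5")
        if not (nlo <= lo and hi <= nhi):
            raise ValueError(
                "canonical_len_range must lie within noncanonical plausible lengths"
            )
        return self

    @property
    def motif_params(self) -> MotifParams:
        return MotifParams(
            gly_motif_prob=self.gly_motif_prob,
            v_at_pos3_prob=self.v_at_pos3_prob,
            nnnn_motif_prob_cd4=self.nnnn_motif_prob_cd4,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def paper_preset(n_cells: int = 10_000, seed: int = 42, **overrides) -> GeneratorConfig:
    """The packaged study preset (all defaults encode the printed proportions)."""
    return GeneratorConfig(n_cells=n_cells, seed=seed, **overrides)
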