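import pandas as pd
import pytest

from maitcr import paper_preset, generate_repertoire
from maitcr.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def paper_bundle():
    """Full-scale synthetic dataset under the packaged study preset."""
    return generate_repertoire(paper_preset(n_cells=10_000, seed=42))


@pytest.fixture(scope="session")
def paper_run(paper_bundle):
    """Full pipeline run on the study preset (QC -> gate -> subset ->
    pairing -> classification -> CDR3 report)."""
    cfg = PipelineConfig(
        generator=paper_preset(n_cells=10_000, seed=42), run_match=False,
    )
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def small_bundle():
    """Small bundle for I/O and structural tests."""
    return generate_repertoire(paper_preset(n_cells=500, seed=7))


@pytest.fixture()
def truth_single_neg(paper_bundle, paper_run):
    """Ground-truth rows for single-paired TRAV1-2-negative MAIT cells."""
    truth = paper_bundle.truth
    return truth.loc[
        (truth["lineage"] == "MAIT") & ~truth["dual_alpha"] & ~truth["trav12"]
    ]
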