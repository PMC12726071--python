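"""Chain pairing, canonical classification, usage, and diversity."""

import math
from itertools import count

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maitcr import (
    CanonicalDefinition,
    classify_tcr,
    diversity,
    gene_sharing,
    pair_chains,
    usage_table,
)

_ids = count()


def contig(barcode, chain, v, j, cdr3, productive=True, hc=True, umis=10,
           d=""):
    return {"barcode": barcode, "chain": chain, "v_gene": v, "d_gene": d,
            "j_gene": j, "cdr3": cdr3, "productive": productive,
            "high_confidence": hc, "umis": umis, "reads": umis * 30,
            "contig_id": f"ctg{next(_ids)}"}


def frame(rows):
    return pd.DataFrame(rows)


BETA = contig("b1", "TRB", "TRBV6-4", "TRBJ2-1", "CASSEGQYF", d="TRBD1")


def test_single_pair():
    calls = pair_chains(frame([
        contig("b1", "TRA", "TRAV1-2", "TRAJ33", "CAVMDSNYQLIW"), BETA]))
    row = calls.iloc[0]
    assert row["pairing_status"] == "paired_single"
    assert row["alpha_v"] == "TRAV1-2" and row["beta_v"] == "TRBV6-4"


def test_dual_alpha_both_trav12():
    calls = pair_chains(frame([
        contig("b1", "TRA", "TRAV1-2", "TRAJ33", "CAVMDSNYQLIW"),
        contig("b1", "TRA", "TRAV1-2", "TRAJ12", "CAVRSSYKLIF"), BETA]))
    row = calls.iloc[0]
    assert row["pairing_status"] == "dual_alpha"
    assert row["dual_category"] == "both_trav12"


def test_dual_alpha_one_trav12_orders_trav12_first():
    calls = pair_chains(frame([
        contig("b1", "TRA", "TRAV21", "TRAJ28", "CAVLDGGGSNKLTF", umis=50),
        contig("b1", "TRA", "TRAV1-2", "TRAJ33", "CAVMDSNYQLIW", umis=5),
        BETA]))
    row = calls.iloc[0]
    assert row["dual_category"] == "one_trav12"
    assert row["alpha_v"] == "TRAV1-2"  # representative despite fewer UMIs


def test_multiplets_flagged_and_unclassified():
    three_alphas = [contig("b1", "TRA", "TRAV1-2", f"TRAJ{j}",
                           f"CAVMD{j}SNYQLIW") for j in (33, 20, 12)]
    calls = pair_chains(frame(three_alphas + [BETA]))
    assert calls.iloc[0]["pairing_status"] == "multiplet"
    two_betas = [contig("b1", "TRA", "TRAV1-2", "TRAJ33", "CAVMDSNYQLIW"),
                 BETA, contig("b1", "TRB", "TRBV28", "TRBJ1-1", "CASSLQYF")]
    assert pair_chains(frame(two_betas)).iloc[0]["pairing_status"] == "multiplet"


def test_nonproductive_and_low_confidence_ignored():
    calls = pair_chains(frame([
        contig("b1", "TRA", "TRAV1-2", "TRAJ33", "CAVMDSNYQLIW"),
        contig("b1", "TRA", "TRAV21", "TRAJ28", "CAVLDSGNKLTF",
               productive=False),
        contig("b1", "TRA", "TRAV35", "TRAJ42", "CAVNYGGSQGNLIF", hc=False),
        BETA]))
    assert calls.iloc[0]["pairing_status"] == "paired_single"


def test_redundant_identical_contigs_collapse_to_highest_umi():
    calls = pair_chains(frame([
        contig("b1", "TRA", "TRAV1-2", "TRAJ33", "CAVMDSNYQLIW", umis=3),
        contig("b1", "TRA", "TRAV1-2", "TRAJ33", "CAVMDSNYQLIW", umis=30),
        BETA]))
    assert calls.iloc[0]["pairing_status"] == "paired_single"


def test_statuses_partition_barcodes():
    rows = [contig("a", "TRA", "TRAV1-2", "TRAJ33", "CAVMDSNYQLIW"),
            contig("b", "TRB", "TRBV6-1", "TRBJ1-2", "CASSDRGYTF"),
            contig("c", "TRA", "TRAV21", "TRAJ8", "CAVNTGFQKLVF")]
    calls = pair_chains(frame(rows))
    assert sorted(calls["barcode"]) == ["a", "b", "c"]
    assert calls.set_index("barcode")["pairing_status"].to_dict() == {
        "a": "alpha_only", "b": "beta_only", "c": "alpha_only"}


def _naive_pairing(contigs: pd.DataFrame) -> dict:
    """Independent re-derivation of the pairing rules by direct counting."""
    out = {}
    usable = contigs[contigs["productive"] & contigs["high_confidence"]]
    for bc in sorted(usable["barcode"].unique()):
        grp = usable[usable["barcode"] == bc]
        tra = {(r.v_gene, r.j_gene, r.cdr3) for r in grp.itertuples()
               if r.chain == "TRA"}
        trb = {(r.v_gene, r.j_gene, r.cdr3) for r in grp.itertuples()
               if r.chain == "TRB"}
        if len(tra) > 2 or len(trb) > 1:
            out[bc] = "multiplet"
        elif tra and trb:
            out[bc] = "paired_single" if len(tra) == 1 else "dual_alpha"
        elif tra:
            out[bc] = "alpha_only"
        elif trb:
            out[bc] = "beta_only"
        else:
            out[bc] = "none"
    return out


def test_pairing_matches_bruteforce_on_random_fixtures():
    rng = np.random.default_rng(11)
    vs = ["TRAV1-2", "TRAV21", "TRAV35"]
    for trial in range(30):
        rows = []
        for b in range(rng.integers(2, 10)):
            for _ in range(rng.integers(0, 5)):
                chain = "TRA" if rng.random() < 0.6 else "TRB"
                v = vs[rng.integers(3)] if chain == "TRA" else "TRBV6-4"
                j = f"TRAJ{rng.integers(3, 40)}" if chain == "TRA" else "TRBJ1-1"
                cdr3 = "CA" + "".join(rng.choice(list("VGSDN"), 6)) + "LF"
                rows.append(contig(f"bc{b}", chain, v, j, cdr3,
                                   productive=rng.random() < 0.85,
                                   hc=rng.random() < 0.9,
                                   umis=int(rng.integers(1, 40))))
        if not rows:
            continue
        contigs = frame(rows)
        calls = pair_chains(contigs)
        got = calls.set_index("barcode")["pairing_status"].to_dict()
        assert got == _naive_pairing(contigs), f"trial {trial}"


def test_pairing_invariant_to_contig_order():
    rows = [contig("b1", "TRA", "TRAV1-2", "TRAJ33", "CAVMDSNYQLIW", umis=4),
            contig("b1", "TRA", "TRAV21", "TRAJ8", "CAVNTGFQKLVF", umis=9),
            BETA,
            contig("b2", "TRA", "TRAV35", "TRAJ42", "CAVRGGSQGNLIF"),
            contig("b2", "TRB", "TRBV28", "TRBJ2-3", "CASSTDTQYF")]
    base = classify_tcr(pair_chains(frame(rows)))
    for seed in (0, 1, 2):
        shuffled = frame(rows).sample(frac=1, random_state=seed)
        pd.testing.assert_frame_equal(
            classify_tcr(pair_chains(shuffled)).reset_index(drop=True), base)


class TestClassify:
    def _classify(self, v, j, bv):
        calls = pair_chains(frame([
            contig("b1", "TRA", v, j, "CAVMDSNYQLIW"),
            contig("b1", "TRB", bv, "TRBJ2-1", "CASSEGQYF")]))
        return classify_tcr(calls).iloc[0]

    def test_fully_canonical(self):
        row = self._classify("TRAV1-2", "TRAJ33", "TRBV6-4")
        assert row["trav12_status"] == "positive"
        assert row["canonical_traj"] and row["canonical_trbv"]
        assert row["fully_canonical"]

    def test_fully_noncanonical(self):
        row = self._classify("TRAV21", "TRAJ28", "TRBV28")
        assert row["trav12_status"] == "negative"
        assert not row["canonical_traj"] and not row["canonical_trbv"]
        assert not row["fully_canonical"]

    def test_trav12_with_noncanonical_j(self):
        row = self._classify("TRAV1-2", "TRAJ42", "TRBV6-1")
        assert row["trav12_status"] == "positive"
        assert not row["canonical_traj"] and not row["fully_canonical"]

    def test_trbv_family_mode(self):
        defn = CanonicalDefinition(trbv_family_mode=True)
        calls = pair_chains(frame([
            contig("b1", "TRA", "TRAV1-2", "TRAJ33", "CAVMDSNYQLIW"),
            contig("b1", "TRB", "TRBV6-2", "TRBJ2-1", "CASSEGQYF")]))
        assert classify_tcr(calls, defn).iloc[0]["canonical_trbv"]
        assert not classify_tcr(calls).iloc[0]["canonical_trbv"]


class TestUsage:
    def _calls(self):
        rows = []
        for i, v in enumerate(["TRAV1-2", "TRAV1-2", "TRAV21", "TRAV21"]):
            rows += [contig(f"b{i}", "TRA", v, "TRAJ33", "CAVMDSNYQLIW"),
                     contig(f"b{i}", "TRB", "TRBV6-4", "TRBJ2-1", "CASSEGQYF")]
        calls = classify_tcr(pair_chains(frame(rows)))
        calls["subset"] = "DN"
        return calls

    def test_proportions(self):
        usage = usage_table(self._calls(), group_by=("subset",))
        trav = usage[usage["gene_class"] == "TRAV"].set_index("gene")
        assert trav.loc["TRAV1-2", "proportion"] == 0.5
        assert trav.loc["TRAV21", "proportion"] == 0.5

    def test_proportions_sum_to_one_per_group_and_class(self, paper_run):
        usage = paper_run.usage
        sums = usage.groupby(["subset", "gene_class"])["proportion"].sum()
        np.testing.assert_allclose(sums, 1.0)

    def test_disjoint_usage_has_empty_shared_set(self):
        calls = self._calls()
        calls.loc[calls["alpha_v"] == "TRAV21", "subset"] = "CD4"
        usage = usage_table(calls, group_by=("subset",))
        sharing = gene_sharing(usage, "TRAV")
        assert sharing["shared"] == set()
        assert sharing["unique"]["CD4"] == {"TRAV21"}


class TestDiversity:
    def test_closed_forms(self):
        assert math.isclose(diversity([5, 5, 5, 5], "shannon"), math.log(4))
        assert diversity([7], "shannon") == 0.0
        assert diversity([7], "simpson") == 0.0
        assert diversity([7], "richness") == 1.0
        assert math.isclose(diversity([2, 1, 1], "shannon"), 1.0397, abs_tol=1e-4)
        assert math.isclose(diversity([1, 1], "pielou"), 1.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            diversity([0, 0], "shannon")
        with pytest.raises(ValueError):
            diversity([-1, 2], "shannon")
        with pytest.raises(ValueError):
            diversity([5], "pielou")
        with pytest.raises(ValueError):
            diversity([1, 2], "chao1")

    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=1,
                    max_size=20).filter(lambda x: sum(x) > 0))
    @settings(deadline=None, derandomize=True)
    def test_entropy_bounds(self, counts):
        h = diversity(counts, "shannon")
        rich = diversity(counts, "richness")
        assert -1e-12 <= h <= math.log(rich) + 1e-12
        s = diversity(counts, "simpson")
        assert -1e-12 <= s <= 1 - 1 / rich + 1e-12

    def test_uniform_reaches_entropy_maximum(self):
        assert math.isclose(diversity([3, 3, 3], "shannon"), math.log(3))
        assert diversity([3, 3, 2], "shannon") < math.log(3)

    def test_matches_scikit_bio(self):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        counts = [8, 3, 1, 0, 5]
        assert math.isclose(diversity(counts, "shannon"),
                            float(skbio_alpha.shannon(counts, base=math.e)))
        assert math.isclose(diversity(counts, "simpson"),
                            float(skbio_alpha.simpson(counts)))


def test_dual_category_frequencies_recover_preset(paper_run):
    dual = paper_run.calls[paper_run.calls["pairing_status"] == "dual_alpha"]
    n = len(dual)
    for cat, p in {"both_trav12": 0.35, "one_trav12": 0.40,
                   "neither": 0.25}.items():
        obs = (dual["dual_category"] == cat).mean()
        assert abs(obs - p) <= 3 * np.sqrt(p * (1 - p) / n), (cat, obs)
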