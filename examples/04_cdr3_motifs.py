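"""CDR3alpha grammar: lengths, positional frequencies, motifs, anchors.

Canonical TRAV1-2+ CDR3alpha loops are 12-14 residues with a conserved
tyrosine 5 positions from the C-terminus (the germline TRAJ33 tail);
TRAV1-2- loops vary from 7 to 23 residues, often carry central
glycine runs, and keep the C/A anchor with valine at position 3.
"""

from maitcr import (
    MotifSpec, detect_motif, generate_repertoire, has_motif, paper_preset,
    positional_matrix, terminal_conservation, tyr95_test,
)

bundle = generate_repertoire(paper_preset(n_cells=4000, seed=1))
truth = bundle.truth
mait = truth[(truth["lineage"] == "MAIT") & ~truth["dual_alpha"]]
pos = mait.loc[mait["trav12"], "cdr3a"]
neg = mait.loc[~mait["trav12"], "cdr3a"]

print(f"TRAV1-2+ CDR3a 12-14 long: {pos.str.len().between(12, 14).mean():.1%}")
print(f"TRAV1-2+ with conserved Tyr slot: {pos.map(tyr95_test).mean():.1%}")
print(f"TRAV1-2- length range: {neg.str.len().min()}-{neg.str.len().max()}")

spec = MotifSpec(patterns=("GGG", "GGGG"), require_in_window=False)
print(f"TRAV1-2- with GGG/GGGG run: {neg.map(lambda s: has_motif(s, spec)).mean():.1%}")
example = next(s for s in neg if has_motif(s, spec))
print(f"  e.g. {example}: hits {detect_motif(example, spec)} (pattern, 1-based start)")

pm = positional_matrix(neg.to_list(), anchoring="left")
print(f"TRAV1-2- valine at position 3: {pm.frequency(3, 'V'):.1%}")

cons = terminal_conservation(neg.to_list())
print(f"C@1 = {cons['frac_C_at_1']:.0%}, A@2 = {cons['frac_A_at_2']:.0%}, "
      f"last 3 residues all in LITFW: {cons['frac_last3_in_LITFW']:.0%}")
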