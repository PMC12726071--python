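"""One-call reproduction of the headline repertoire report.

Runs simulate -> QC -> lineage gate -> subset assignment -> pairing ->
classification -> CDR3 analysis on the packaged study preset and prints
the consolidated report: every value is a percentage with its auditable
numerator/denominator pair.
"""

from maitcr import reproduce

result = reproduce(seed=42, n_cells=4000)
print(result.report.to_string(index=False))
print("\nkey numbers: trav12_neg_pct_CD4 ~ 90 (CD4+ MAIT cells carry "
      "noncanonical TCRs), subset_pct_DN ~ 50, dual_alpha_pct ~ 9, "
      "canonical TRAJ/TRBV ~ 90 among TRAV1-2+ cells.")
print(f"\nprovenance: {result.provenance}")
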