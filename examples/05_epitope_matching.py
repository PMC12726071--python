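"""Indel-perturbed CDR3 similarity search against a reference table.

Percent similarity counts matched positions in an optimal gap-tolerant
alignment over the longer sequence; in-silico insertions (+1, +2) or
deletions (-1, -2) in the query show how close a noncanonical CDR3 is
to a published epitope-associated sequence.
"""

from maitcr import packaged_reference, perturbed_match, similarity

refs = packaged_reference()  # small synthetic stand-in for a McPAS download
print(f"reference entries: {len(refs)} "
      f"({sum(r.chain == 'alpha' for r in refs)} alpha, "
      f"{sum(r.chain == 'beta' for r in refs)} beta)")

query = "CAVRDGSNYQLIW"  # noncanonical-looking alpha loop
print(f"\nquery {query}")
base = perturbed_match(query, refs)
print(f"  budget 0: {base.similarity_pct:.1f}% to {base.best_reference.cdr3_aa} "
      f"({base.best_reference.epitope}, {base.best_reference.pathology})")
for ins, dele in ((0, 1), (0, 2), (1, 0)):
    hit = perturbed_match(query, refs, max_insertions=ins, max_deletions=dele)
    ops = ", ".join(f"{t}@{p}:{r}" for t, p, r in hit.edit_operations) or "none"
    print(f"  ins<={ins} del<={dele}: {hit.similarity_pct:.1f}% "
          f"to {hit.best_reference.cdr3_aa} (edits: {ops})")

print("\npairwise similarity is symmetric percent identity with gaps:")
print(f"  similarity('CASSF', 'CASTF') = {similarity('CASSF', 'CASTF')}")
print(f"  similarity('CAS', 'CASAAA') = {similarity('CAS', 'CASAAA')}")
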