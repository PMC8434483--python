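"""Curate a toy ligand library and build the reproducible split plan.

Runs the inclusion criteria (MW < 500, Ki < 5000 nM, basic ring nitrogen,
specified stereochemistry, scaffold exclusion) over ~20 hand-written
structures, converts Ki to pKi = 9 - log10(Ki), and derives the 4:1
modeling/testing split with repeated train/validation partitions.
"""

from s2rqsar import curate, make_split_plan, toy_molecule_set

records = toy_molecule_set()
kept, rejected = curate(records)

print(f"curated {len(kept)} of {len(records)} toy ligands")
print("\nkept (id, Ki nM, pKi):")
for r in kept:
    print(f"  {r.id:32s} {r.ki_nM:8.1f}  {r.pki:.3f}")
print("\nrejected (id -> reasons):")
for r, reasons in rejected:
    print(f"  {r.id:32s} {', '.join(reasons)}")

plan = make_split_plan([r.id for r in kept], seed=42, n_repeats=5, min_compounds=len(kept))
print(f"\nsplit plan: {len(plan.modeling_ids)} modeling / {len(plan.testing_ids)} testing,")
print(f"each of {plan.n_repeats} repeats: {len(plan.repeats[0][0])} train / {len(plan.repeats[0][1])} validation")
print("(a pKi of 6 means Ki = 1 uM; every kept compound sits in the modeled affinity window)")
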