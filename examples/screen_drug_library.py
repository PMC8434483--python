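"""Screen a small drug library with the published five-descriptor model.

Pushes a handful of approved drugs through the applicability-domain
filter chain, computes open-toolkit analog descriptors for the
survivors, scores them with the frozen published model at the pKi >= 5.5
cutoff, and finishes with a decoy-selection + enrichment-factor demo.

Note: the published coefficients were fit on proprietary descriptor
values; scoring RDKit analogs through them illustrates the pipeline, not
a validated affinity prediction.
"""

from s2rqsar import (
    DescriptorMatrix,
    compute_descriptors,
    evaluate_enrichment,
    filter_library,
    max_tanimoto_to_actives,
    predict_library,
    published_model,
    select_decoys,
)

library = [
    ("CCC1=NN(CCCN2CCN(CC2)C2=CC(Cl)=CC=C2)C(=O)N1CCOC1=CC=CC=C1", "nefazodone"),
    ("C[C@H](NCCCC1=CC=CC(=C1)C(F)(F)F)C1=CC=CC2=CC=CC=C12", "cinacalcet"),
    ("O=C1NC2=CC=CC=C2N1C1CCN(CCCC(C2=CC=C(F)C=C2)C2=CC=C(F)C=C2)CC1", "pimozide"),
    ("COC1=CC=CC=C1OCC(O)CN1CCN(CC(=O)NC2=C(C)C=CC=C2C)CC1", "ranolazine"),
    ("OC(=O)CC(O)(CC(O)=O)C(O)=O", "citric_acid"),
]

kept, rejected = filter_library(library)
print("applicability-domain filtering:")
for mid, reasons in rejected:
    print(f"  excluded {mid}: {', '.join(reasons)}")
print(f"  {len(kept)} compounds remain: {[mid for _, mid in kept]}")

model = published_model()
matrix = compute_descriptors([smi for smi, _ in kept], names=model.descriptor_names)
matrix = DescriptorMatrix([mid for _, mid in kept], matrix.descriptor_names, matrix.values, "rdkit")
hits = predict_library(model, matrix, cutoff=5.5)
print("\npredicted pKi (RDKit analog descriptors through the frozen model):")
for h in hits:
    print(f"  {h.id:12s} {h.predicted_pki:6.2f}  {'PASS' if h.passed_all else 'below cutoff'}")

# decoy selection + enrichment on the same tiny set
actives_smiles = [smi for smi, mid in library if mid in ("nefazodone", "pimozide")]
candidates = [(smi, mid) for smi, mid in library if mid not in ("nefazodone", "pimozide")]
scored = max_tanimoto_to_actives(candidates, actives_smiles)
decoys = select_decoys(scored, fraction=0.34)
print(f"\nmost dissimilar third kept as decoys: {[d.id for d in decoys]} "
      f"(max Tc {decoys[0].max_tc:.2f})")

db = [mid for _, mid in library]
report = evaluate_enrichment([h.id for h in hits if h.passed_all], ["nefazodone", "pimozide"], db)
print(f"enrichment on this toy database: sensitivity {report.sensitivity_pct:.0f}%, "
      f"specificity {report.specificity_pct:.0f}%, EF {report.ef:.2f}")
print("(EF > 1 means the screen concentrates actives better than random picking)")
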