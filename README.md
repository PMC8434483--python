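# s2rqsar

A ligand-based 2D-QSAR toolkit for Sigma-2 receptor (S2R) ligands. S2R is
a drug target implicated in several cancers and in neurodegenerative
disease, and — with no crystal structure available — affinity prediction
for it has to be ligand-based. This package implements the complete
discovery workflow around a five-descriptor multivariate linear model of
S2R binding affinity:

- **Curation** of literature Ki data: inclusion criteria (MW < 500 g/mol,
  Ki < 5000 nM, a basic ring nitrogen, fully specified stereocenters,
  scaffold exclusions) and conversion pKi = 9 − log₁₀(Ki/nM).
- **2D descriptors** computed with RDKit, including documented open-toolkit
  analogs of the five modeled descriptors (Balaban J, longest single-bond
  chain, negative-polar VSA, pure H-bond-acceptor VSA, an atomic-logP VSA
  bin), plus screening heuristics (zero-dominant and near-binary columns)
  and greedy |r| > 0.9 correlation pruning.
- **Four descriptor selectors** returning exactly k descriptors (default
  k = 5): forward stepwise, Lasso/LARS path entry, a genetic algorithm
  over exactly-k bitstrings, and **GreedGene** — repeated GA runs vote on
  a consensus core, the core is completed by exhaustive enumeration
  (C(p−|core|, k−|core|) model fits instead of C(p, k)), and a
  correlated-swap refinement re-examines descriptors removed during
  pruning.
- **Model validation**: ordinary least-squares MLR, leave-one-out Q²
  (1 − PRESS/SS_tot), and the repeated-split protocol — a 4:1
  modeling/testing split, 50 random 4:1 train/validation re-splits of the
  modeling set, and stability = ≥ 95% of splits reaching validation
  R² ≥ 0.5.
- **Virtual screening**: applicability-domain filters (Lipinski RO5,
  basic nitrogen, ≤ 2 positive groups, specified stereo, organic
  elements, peptidomimetic heuristic), pKi prediction at a 5.5 cutoff,
  Tanimoto-based decoy selection (most dissimilar 25% by maximum Tc),
  and enrichment metrics: sensitivity TP/(TP+FN), specificity
  TN/(TN+FP), EF = (TP/Ht)/(A/D).

The published model itself ships frozen:

    pKi = 11.29 − 3.77·balabanJ + 0.23·b_max1len − 0.029·Q_VSA_PNEG
          + 0.043·vsa_acc − 0.026·SlogP_VSA1

Its coefficients were fit on proprietary (MOE) descriptor values;
numeric parity of the RDKit analogs is deliberately not promised, and the
scorer also accepts externally computed descriptor CSVs.

## Worked example

`examples/compare_selectors.py` plants 5 informative columns in a
synthetic 160 × 60 descriptor matrix (population R² = 0.7) and races the
four selectors:

```
planted support: ['D02', 'D13', 'D52', 'D54', 'D55'] (population R^2 = 0.70)

algorithm   Q2(LOO)  recovered  selected
stepwise      0.581  4/5        ['D04', 'D13', 'D52', 'D54', 'D55']
lasso         0.575  4/5        ['D13', 'D34', 'D52', 'D54', 'D55']
ga            0.578  4/5        ['D13', 'D14', 'D52', 'D54', 'D55']
greedgene     0.581  4/5        ['D04', 'D13', 'D52', 'D54', 'D55']

GreedGene consensus core: ['D04', 'D13', 'D52', 'D54', 'D55']; exhaustive completion cost: 1 model fits
```

Each line is one algorithm's best 5-descriptor subset, its leave-one-out
Q² (higher = better out-of-sample prediction), and how many of the 5
planted columns it recovered. At this noise level one planted column
(`D02`) is genuinely not worth its degree of freedom — every algorithm
prefers a noise column that happens to fit better, and GreedGene's Q²
is, by construction, never below its own GA repeats.

The other examples cover curation + splitting
(`curate_and_split.py`), descriptor screening
(`descriptor_screening.py`), the 50-split validation protocol
(`validation_protocol.py`), and an end-to-end drug-library screen with
decoys and enrichment (`screen_drug_library.py`). A thin CLI mirrors the
library: `s2rqsar curate|split|describe|screen-desc|select|fit|validate|predict|screen|decoys|enrich|synth`.

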