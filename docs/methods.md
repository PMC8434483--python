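# Methods

## The modeling problem

S2R binding affinities (Ki, nM) pooled from heterogeneous literature
sources are regressed on conformation-independent 2D molecular
descriptors. Affinities are expressed as pKi = 9 − log₁₀(Ki/nM), so
1 nM ↦ 9 and 1 µM ↦ 6. The model class is deliberately minimal —
ordinary least-squares multivariate linear regression on exactly five
descriptors — because with ~127 modeling compounds a 1:25
descriptor-to-compound ratio is the accepted ceiling before chance
correlation dominates. All of the method's complexity lives in (a) which
five descriptors to pick and (b) how to prove the pick generalizes.

## Curation

Inclusion criteria and their defaults:

| criterion | default | rationale |
|---|---|---|
| molecular weight | < 500 g/mol | drug-like window of the training chemistry |
| Ki | < 5000 nM | keeps the affinity range informative |
| basic ring nitrogen | required | conserved pharmacophore of S2R ligands |
| stereocenters | all specified | racemates have ambiguous descriptors |
| scaffold exclusion | 9-azabicyclo[3.3.1]nonane (substructure) | chemotype outside the modeled series |

"Basic ring nitrogen" is operationalized as a non-aromatic nitrogen with
only single bonds, not adjacent to a carbonyl/sulfonyl (no amides or
sulfonamides), that is a ring member or bonded to a ring atom. This is
looser than a literal "rigid cyclohexyl ring" reading because the
modeled chemotypes themselves are piperidines, piperazines and
tetrahydroisoquinolines; the matcher is overridable by SMARTS. The
scaffold exclusion is a substructure match by default (configurable), as
a full-scaffold-only match would silently admit decorated granatanines.

Unparsable structures are rejected with reason `parse_error`, never
raised, so one bad record cannot abort a batch.

## Splits

The curated set is partitioned modeling : testing = 4 : 1 with the
modeling size equal to round-half-up(N·4/5) — the only rounding
convention consistent with both published set sizes (159 → 127/32 and
127 → 102/25). The modeling set is then re-partitioned 4:1 into
train/validation `n_repeats` = 50 times. Ids are canonically sorted
before shuffling so the plan depends only on the id set and the seed;
repeat r draws from a fresh generator seeded `seed + r` (r starting at
1), making every split independently reproducible.

## Descriptors

Five analogs of the modeled descriptors are computed with RDKit and
documented here precisely because numeric parity with the proprietary
originals is not claimed:

- `balabanJ` — Balaban's distance-connectivity index J (RDKit
  implementation); 0 with a warning for single-heavy-atom graphs, where
  J is undefined.
- `b_max1len` — bonds in the longest path of the molecular graph
  restricted to acyclic single bonds between heavy atoms (ethane → 1,
  benzene → 0).
- `Q_VSA_PNEG` — Labute approximate-ASA contributions summed over atoms
  with Gasteiger partial charge < −0.2, computed on the neutral form.
  The −0.2 polar threshold (configurable) keeps mildly negative alkane
  carbons from counting the whole hydrocarbon surface as "negative".
- `vsa_acc` — ASA contributions of pure hydrogen-bond acceptors:
  acceptor-pattern atoms carrying no hydrogen (so they cannot donate).
- `SlogP_VSA1` — ASA contributions of atoms whose Crippen atomic logP
  falls in [−0.4, −0.2).

A provider label travels with every matrix (`rdkit`, `csv:...`,
`synthetic`), and the full RDKit 2D catalog (~210 further descriptors)
can be appended for realistic screening exercises. Externally computed
matrices load from CSV, which is the intended path when scoring the
frozen published model on its native descriptor source.

Screening removes, in order: blacklisted names (synthesizability-type
scores with no physical link to affinity; the list is configurable
because only its flavor, not its full content, is documented for the
original workflow), columns with > 95% exact zeros, and columns with ≤ 2
distinct values. Each excluded column gets exactly one reason.
Correlation pruning then groups columns greedily at |Pearson r| > 0.9:
the next group seed is the remaining column most correlated with the
response (or the lexicographically smallest name without a response;
random seeding is available), and the seed becomes the representative.
Because every kept representative was, at selection time, below
threshold against all earlier representatives, the operation is
idempotent. Zero-variance columns are set aside as degenerate. Group
membership is retained for GreedGene's swap stage.

## Selection

All four algorithms return exactly k distinct descriptor names
(default k = 5) and share one fitness: leave-one-out Q² of the OLS refit
on the candidate subset. The original workflow never states its GA
objective; LOO Q² was chosen because it matches the validation criterion
the workflow does state and penalizes overfitted subsets, and
`r2_train` remains available. Ties are always broken by lexicographic
name order, making every algorithm deterministic given its seed.

- **Forward stepwise** adds the fitness-maximizing descriptor per step.
  A `classic` flag switches to traditional correlation-driven entry
  (first by |r| with y, then by |r| with the running residual).
- **Lasso/LARS** standardizes columns and takes the first k variables to
  enter the lasso-mode LARS path (scikit-learn `lars_path`), then refits
  unpenalized OLS; it errors if fewer than k ever activate.
- **GA** evolves exactly-k subsets (repair after uniform crossover and
  swap mutation, tournament size 3, elitism, population 100 ×
  50 generations, crossover 0.8, mutation 1/p per included gene).
  Fixed-size representation was preferred over penalized variable-length
  bitstrings because the downstream protocol always builds
  k-descriptor models.
- **GreedGene** runs the GA `ga_repeats` = 5 times (seeds `seed + r`),
  takes as core every descriptor present in ≥ 80% of the repeats' best
  subsets (both knobs configurable; a core of ≥ k is truncated to the k
  most frequent), exhaustively evaluates all C(p−|core|, k−|core|)
  completions (refusing above a configurable budget, default 2·10⁶
  fits), and finally sweeps correlated swaps: each selected descriptor
  is tentatively replaced by each member of its correlation group,
  strict improvements are kept, and the sweep repeats to a fixed point.
  Pruned-away group members are reachable when the pre-pruning matrix is
  supplied as `swap_candidates`. The GA repeats' own winners stay in the
  final candidate pool, which guarantees the hybrid never scores below
  its best repeat even when that repeat's subset lacks the core.

The fitness evaluator computes LOO Q² from one QR factorization per
subset via the linear-smoother identity e_LOO,i = e_i/(1−h_ii); the
identity is exact, and a literal refit-per-row mode exists and is tested
to agree within 1e−10. Subsets with numerically rank-deficient designs
score −∞ rather than raising, so degenerate candidates lose rather than
crash a search. All subset fitnesses are memoized per (X, y).

## Model statistics and the repeated-split protocol

R² is the coefficient of determination 1 − SS_res/SS_tot about the
observed mean of whichever subset is being scored. Out-of-sample,
squared Pearson correlation differs from this definition; both are
implemented (`use_pearson_r2`), coefficient-of-determination is the
default, and the choice is surfaced because the original report does not
say which it used. Q² is 1 − PRESS/SS_tot with SS_tot about the full-set
mean.

`run_protocol` runs, per repeat: descriptor selection (either a fixed
name list — final-model usage — or a callable re-run per split, the
honest protocol), OLS fit on train, train R² and LOO Q², validation R²
on the held-out fifth. Split-level criteria mirror the stated protocol:
train R² strictly > 0.6, Q² ≥ 0.5, validation R² ≥ 0.5, and a model is
stable when ≥ 95% of splits meet the validation criterion (the headline
percentage counts the validation criterion; an all-three percentage is
reported alongside). Afterwards the model is refit on the full modeling
set and scored once on the external testing set.

## Published model scorer

The frozen five-coefficient model (intercept 11.29; −3.77, +0.23,
−0.029, +0.043, −0.026) is exposed as `published_model()`. On an
all-zero descriptor vector it returns exactly its intercept, 11.29; on
an all-ones vector the hand sum is 7.738. Its coefficients are
constants, not recomputation targets: the descriptor values they were
fit on came from a proprietary engine, so refitting them from open
descriptors would produce a different (incomparable) model.

## Virtual screening

The applicability-domain chain rejects, with full reason lists:
Lipinski violations (strict by default, `ro5_max_violations = 0`),
absence of a basic nitrogen, more than 2 basic (protonatable) amine
groups, unspecified stereocenters, atoms outside the organic whitelist
{H, C, N, O, S, P, F, Cl, Br, I}, and > 4 amide bonds (a documented
peptidomimetic heuristic standing in for a judgment call that cannot be
encoded exactly). Predicted pKi ≥ 5.5 (inclusive) marks a hit.

Decoy selection sorts candidates by maximum Tanimoto coefficient to any
active — fingerprints default to 2048-bit Morgan, radius 2, but
precomputed `max_tc` values are accepted so the choice of fingerprint is
decoupled — and keeps the lowest ⌊fraction·n⌋ (default 25%), ties broken
by id. The 1:50 actives-to-decoys guideline is available as an assembly
option but never enforced, since realistic benchmark sets (191 actives,
12,148 decoys) deviate from it. Enrichment reports assert their count
identities (TP+FN = A, TP+FP = Ht, TP+TN+FP+FN = D) at construction;
EF with an empty hit list is reported as an explicit error, not NaN.

## Synthetic data

`generate_matrix` draws unit-variance Gaussian descriptor columns with
pairwise equicorrelation ρ (single-factor construction, default 0.2 — a
mild, realistic background correlation), plants a support of known
coefficients, and adds Gaussian noise. When a target population R² is
requested the noise SD is solved analytically from
var_signal = βᵀΣβ = (1−ρ)·Σβᵢ² + ρ·(Σβᵢ)², so the declared R² is exact
in the population. Options append near-duplicate columns (|r| > 0.9, to
exercise pruning and swap refinement) and screening-trap columns (96%
zeros; two-valued). The generator emulates only the statistical shape
of a curated QSAR table — it contains no chemistry, no descriptor
semantics, and no inter-column structure beyond equicorrelation and the
planted duplicates — so passing tests demonstrate the selection and
validation machinery, not predictive validity on real S2R data.

The toy molecule set is 20 hand-written structures covering every
curation outcome at least once, each with a designed single reason.

## Verification problem sizes

The statistical acceptance checks run at these sizes, chosen to give
stable pass/fail behavior at interactive runtimes:

- LOO shortcut vs literal refits: 20 seeded fixtures, n ∈ [12, 30),
  p ∈ [1, 5), agreement to 1e−10.
- GreedGene vs global exhaustive optimum: 10 seeds at n = 70, p = 20,
  k = 3 (C(20,3) = 1140 subsets enumerated per seed).
- Planted-support recovery: 20 trials at n = 160, p = 60, k = 5,
  population R² = 0.7; ≥ 4/5 descriptors recovered in ≥ 90% of trials
  and hybrid fitness ≥ every GA repeat.
- y-scrambling: 20 seeds, n = 100, p = 20, selection re-run on the
  scrambled response, 10 validation splits each; mean validation
  R² < 0.2.

## Known limitations

- The five descriptor analogs follow their published definitions but not
  the proprietary implementations; absolute predictions of the frozen
  model on analog descriptors are illustrative, not validated.
- Gasteiger charges are a coarse charge model; the −0.2 polar threshold
  compensates for its systematic mild negativity on carbon.
- The basic-nitrogen and peptidomimetic rules are heuristics; both are
  configurable and both err on the side of excluding edge cases.
- Equicorrelated synthetic descriptors are far better conditioned than
  real descriptor tables, whose correlation structure is blocky and
  heavy-tailed; selector rankings observed on synthetic data need not
  transfer quantitatively.
- 3D structure handling (conformers, protonation enumeration, force-field
  minimization) is out of scope; inputs are scored as drawn.
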