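"""Virtual-screening filters, pKi prediction, decoys, and enrichment.

Applies the applicability-domain filter chain (Lipinski's Rule of Five,
basic-nitrogen requirement, positive-group cap, stereo specification,
organic-element whitelist, peptidomimetic heuristic) to a compound
library, predicts pKi with a linear QSAR model at a cutoff (default
5.5), selects decoys as the most Tanimoto-dissimilar fraction of a
candidate pool, and computes sensitivity, specificity, and enrichment
factor from confusion counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from rdkit import Chem, DataStructs
from rdkit.Chem import Descriptors as _RD
from rdkit.Chem import rdFingerprintGenerator

from .curation import has_basic_ring_nitrogen, has_unspecified_stereocenter
from .descriptors import DescriptorMatrix
from .modeling import LinearModel

__all__ = [
    "EnrichmentReport",
    "DecoyCandidate",
    "ScreeningHit",
    "FilterRules",
    "filter_library",
    "predict_library",
    "select_decoys",
    "evaluate_enrichment",
    "max_tanimoto_to_actives",
]


class ScreeningError(ValueError):
    pass


ORGANIC_ELEMENTS = frozenset([1, 6, 7, 8, 16, 15, 9, 17, 35, 53])  # H C N O S P F Cl Br I

_BASIC_AMINE_SMARTS = Chem.MolFromSmarts("[N;!a;!$(N=*);!$(N-C=[O,N,S]);!$(N-S(=O))]")
_AMIDE_SMARTS = Chem.MolFromSmarts("[NX3][CX3](=O)")


@dataclass
class FilterRules:
    """Applicability-domain filter chain configuration.

    ``ro5_max_violations = 0`` is the strict default: every Lipinski rule
    (MW <= 500, cLogP <= 5, H-bond donors <= 5, acceptors <= 10) must
    hold. ``max_positive_groups`` caps basic (protonatable) amine groups;
    ``max_amide_bonds`` is a peptidomimetic heuristic.
    """

    ro5_max_violations: int = 0
    require_basic_nitrogen: bool = True
    max_positive_groups: int = 2
    exclude_unspecified_stereo: bool = True
    element_whitelist: frozenset[int] = ORGANIC_ELEMENTS
    max_amide_bonds: int = 4


@dataclass
class ScreeningHit:
    id: str
    predicted_pki: float
    filter_flags: dict[str, bool] = field(default_factory=dict)
    passed_all: bool = False


@dataclass
class DecoyCandidate:
    """A presumed-inactive compound with its similarity to the actives.

    ``max_tc`` is the maximum Tanimoto coefficient of the candidate's
    fingerprint to any active; low values mean structurally dissimilar.
    """

    id: str
    smiles: str = ""
    max_tc: float = float("nan")


def _ro5_violations(mol: Chem.Mol) -> dict[str, bool]:
    return {
        "ro5_mw": _RD.MolWt(mol) > 500.0,
        "ro5_logp": _RD.MolLogP(mol) > 5.0,
        "ro5_hbd": _RD.NumHDonors(mol) > 5,
        "ro5_hba": _RD.NumHAcceptors(mol) > 10,
    }


def filter_library(
    library: Sequence[tuple[str, str]],
    rules: FilterRules | None = None,
) -> tuple[list[tuple[str, str]], list[tuple[str, list[str]]]]:
    """Filter (smiles, id) pairs through the applicability-domain chain.

    Returns (kept, rejected) with input order preserved; each rejection
    carries every violated-rule label (``ro5_*``, ``no_basic_N``,
    ``positive_groups``, ``unspecified_stereo``, ``element``,
    ``peptidomimetic``, ``parse_error``).
    """
    rules = rules or FilterRules()
    kept: list[tuple[str, str]] = []
    rejected: list[tuple[str, list[str]]] = []
    for smiles, mid in library:
        mol = Chem.MolFromSmiles(smiles) if smiles else None
        if mol is None:
            rejected.append((mid, ["parse_error"]))
            continue
        reasons: list[str] = []
        ro5 = _ro5_violations(mol)
        if sum(ro5.values()) > rules.ro5_max_violations:
            reasons.extend([k for k, v in ro5.items() if v])
        if rules.require_basic_nitrogen and not has_basic_ring_nitrogen(mol):
            reasons.append("no_basic_N")
        n_basic = len(mol.GetSubstructMatches(_BASIC_AMINE_SMARTS))
        if n_basic > rules.max_positive_groups:
            reasons.append("positive_groups")
        if rules.exclude_unspecified_stereo and has_unspecified_stereocenter(mol):
            reasons.append("unspecified_stereo")
        if any(a.GetAtomicNum() not in rules.element_whitelist for a in mol.GetAtoms()):
            reasons.append("element")
        if len(mol.GetSubstructMatches(_AMIDE_SMARTS)) > rules.max_amide_bonds:
            reasons.append("peptidomimetic")
        if reasons:
            rejected.append((mid, reasons))
        else:
            kept.append((smiles, mid))
    return kept, rejected


def predict_library(
    model: LinearModel,
    matrix: DescriptorMatrix,
    cutoff: float = 5.5,
    filter_flags: Mapping[str, Mapping[str, bool]] | None = None,
) -> list[ScreeningHit]:
    """Predict pKi for every library compound and apply the cutoff.

    Hits are returned sorted by predicted pKi descending (ties by id).
    ``passed_all`` requires predicted pKi >= cutoff (inclusive boundary)
    and, when per-compound ``filter_flags`` are supplied, that every flag
    is True.
    """
    preds = model.predict(matrix)  # raises naming any missing column
    hits = []
    for mid, pki in zip(matrix.molecule_ids, preds):
        flags = dict(filter_flags.get(mid, {})) if filter_flags else {}
        passed = bool(pki >= cutoff) and all(flags.values())
        hits.append(ScreeningHit(id=mid, predicted_pki=float(pki), filter_flags=flags, passed_all=passed))
    hits.sort(key=lambda h: (-h.predicted_pki, h.id))
    return hits


def max_tanimoto_to_actives(
    candidates: Sequence[tuple[str, str]],
    actives_smiles: Sequence[str],
    radius: int = 2,
    n_bits: int = 2048,
) -> list[DecoyCandidate]:
    """Compute each candidate's maximum Tanimoto coefficient to the actives.

    Fingerprints default to 2048-bit Morgan (circular, radius 2).
    Precomputed ``max_tc`` values can be fed straight to
    :func:`select_decoys` instead to decouple from fingerprint choice.
    """
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    active_fps = []
    for s in actives_smiles:
        m = Chem.MolFromSmiles(s)
        if m is None:
            raise ScreeningError(f"unparsable active SMILES: {s!r}")
        active_fps.append(gen.GetFingerprint(m))
    out = []
    for smiles, mid in candidates:
        m = Chem.MolFromSmiles(smiles)
        if m is None:
            raise ScreeningError(f"unparsable candidate SMILES for id {mid!r}")
        fp = gen.GetFingerprint(m)
        tcs = DataStructs.BulkTanimotoSimilarity(fp, active_fps)
        out.append(DecoyCandidate(id=mid, smiles=smiles, max_tc=float(max(tcs))))
    return out


def select_decoys(candidates: Sequence[DecoyCandidate], fraction: float = 0.25) -> list[DecoyCandidate]:
    """Keep the most dissimilar fraction of decoy candidates.

    Candidates are sorted ascending by ``max_tc`` (ties broken by id) and
    the lowest ``floor(fraction * n)`` are returned — the compounds least
    similar to any active, i.e. the safest presumed inactives.
    """
    if not candidates:
        raise ScreeningError("empty decoy candidate list")
    if not (0.0 < fraction <= 1.0):
        raise ScreeningError("fraction must be in (0, 1]")
    if any(math.isnan(c.max_tc) for c in candidates):
        raise ScreeningError("max_tc not populated for all candidates")
    n_keep = int(math.floor(fraction * len(candidates)))
    ranked = sorted(candidates, key=lambda c: (c.max_tc, c.id))
    return ranked[:n_keep]


@dataclass
class EnrichmentReport:
    """Confusion counts and screening quality metrics.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    EF = (TP/Ht) / (A/D) where Ht is the number of selected hits, A the
    number of actives, and D the database size. Identity checks
    (TP+FN=A, TP+FP=Ht, TP+TN+FP+FN=D) are asserted at construction.
    """

    TP: int
    TN: int
    FP: int
    FN: int
    Ht: int
    A: int
    D: int
    top_fraction: float = 1.0

    def __post_init__(self) -> None:
        assert self.TP + self.FN == self.A, "TP + FN must equal A"
        assert self.TP + self.FP == self.Ht, "TP + FP must equal Ht"
        assert self.TP + self.TN + self.FP + self.FN == self.D, "confusion counts must total D"

    @property
    def sensitivity(self) -> float:
        return self.TP / self.A if self.A else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.TN + self.FP
        return self.TN / denom if denom else float("nan")

    @property
    def ef(self) -> float:
        if self.Ht == 0:
            raise ScreeningError("EF undefined: no hits selected (Ht = 0)")
        return (self.TP / self.Ht) / (self.A / self.D)

    @property
    def sensitivity_pct(self) -> float:
        return 100.0 * self.sensitivity

    @property
    def specificity_pct(self) -> float:
        return 100.0 * self.specificity

    def to_json_dict(self) -> dict:
        return {
            "TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN,
            "Ht": self.Ht, "A": self.A, "D": self.D,
            "top_fraction": self.top_fraction,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "enrichment_factor": self.ef if self.Ht else None,
        }


def evaluate_enrichment(
    predicted_active_ids: Sequence[str],
    actives_ids: Sequence[str],
    database_ids: Sequence[str],
    top_fraction: float = 1.0,
) -> EnrichmentReport:
    """Score a ranked hit list against known actives.

    ``predicted_active_ids`` is the ranked hit list (best first). With
    ``top_fraction`` < 1 only the top fraction of that list counts as
    selected hits (e.g. 0.01 for EF at 1%). Actives and predictions must
    be subsets of the database.
    """
    db = list(dict.fromkeys(database_ids))
    actives = set(actives_ids)
    preds = list(dict.fromkeys(predicted_active_ids))
    if not actives <= set(db):
        raise ScreeningError("actives must be a subset of the database")
    if not set(preds) <= set(db):
        raise ScreeningError("predictions must be a subset of the database")
    if not (0.0 < top_fraction <= 1.0):
        raise ScreeningError("top_fraction must be in (0, 1]")
    if top_fraction < 1.0:
        preds = preds[: int(math.ceil(top_fraction * len(preds)))]
    hit_set = set(preds)
    D = len(db)
    A = len(actives)
    TP = len(hit_set & actives)
    FP = len(hit_set) - TP
    FN = A - TP
    TN = D - A - FP
    return EnrichmentReport(TP=TP, TN=TN, FP=FP, FN=FN, Ht=len(hit_set), A=A, D=D, top_fraction=top_fraction)
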