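"""Dataset curation for Sigma-2 receptor (S2R) ligand QSAR modeling.

Reads molecule/activity inputs, applies the inclusion criteria used to
assemble the S2R ligand set (molecular weight, Ki ceiling, presence of a
basic ring nitrogen, fully specified stereochemistry, scaffold exclusions),
converts Ki (nM) to pKi = 9 - log10(Ki), and produces the reproducible
modeling/testing and train/validation splits of the 50-repeat protocol.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors as _RDDescriptors
from rdkit.Chem import FindMolChiralCenters

__all__ = [
    "MoleculeRecord",
    "CurationCriteria",
    "SplitPlan",
    "convert_ki_to_pki",
    "curate",
    "make_split_plan",
    "read_smiles_file",
    "read_sdf_file",
    "read_activity_csv",
    "join_structures_activities",
    "write_curated_csv",
    "read_curated_csv",
    "write_rejection_log",
]

#: Bridged tropane-like scaffold excluded from the S2R training chemistry.
AZABICYCLO_331_NONANE_SMARTS = "C1CC2CCCC(C1)N2"


class CurationError(ValueError):
    """Raised for invalid activity values or criteria."""


def convert_ki_to_pki(ki_nM: float, mol_id: str | None = None) -> float:
    """Convert an inhibition constant in nM to pKi = 9 - log10(Ki).

    The offset of 9 accounts for the nM unit: Ki = 1 nM = 1e-9 M gives
    pKi = 9, and Ki = 1000 nM (1 uM) gives pKi = 6.

    Raises
    ------
    CurationError
        If ``ki_nM`` is non-positive or non-finite; the message names the
        offending molecule id when one is given.
    """
    if not math.isfinite(ki_nM) or ki_nM <= 0:
        who = f" for molecule {mol_id!r}" if mol_id else ""
        raise CurationError(f"Ki must be a positive finite value in nM{who}; got {ki_nM!r}")
    return 9.0 - math.log10(ki_nM)


@dataclass
class MoleculeRecord:
    """One curated ligand: structure, affinity, provenance.

    ``pki`` is derived from ``ki_nM`` at construction when not supplied.
    """

    id: str
    smiles: str
    ki_nM: float
    pki: float | None = None
    source_ref: str = ""
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.pki is None:
            self.pki = convert_ki_to_pki(self.ki_nM, self.id)

    def mol(self) -> Chem.Mol | None:
        """Parsed RDKit molecule, or None for unparsable SMILES."""
        return Chem.MolFromSmiles(self.smiles)


@dataclass
class CurationCriteria:
    """Inclusion criteria for the S2R ligand set.

    Defaults mirror the assembly rules of the modeled dataset: MW below
    500 g/mol, Ki below 5000 nM, a basic (non-aromatic, non-amide)
    nitrogen in or on a ring, fully specified stereocenters, and exclusion
    of the 9-azabicyclo[3.3.1]nonane scaffold (substructure match).
    """

    max_mw: float = 500.0
    max_ki_nM: float = 5000.0
    require_basic_ring_nitrogen: bool = True
    exclude_unspecified_stereo: bool = True
    excluded_scaffold_patterns: tuple[str, ...] = (AZABICYCLO_331_NONANE_SMARTS,)
    basic_nitrogen_smarts: str | None = None  # override the built-in atom logic

    def __post_init__(self) -> None:
        if self.max_mw <= 0 or self.max_ki_nM <= 0:
            raise CurationError("curation thresholds must be strictly positive")


def _is_basic_ring_nitrogen(atom: Chem.Atom) -> bool:
    """Basic nitrogen embedded in or attached to a ring.

    Operationalized as a non-aromatic nitrogen that is not an amide /
    sulfonamide N, carries no double bond, and is either a ring member or
    bonded to a ring atom. Piperidines and piperazines qualify; pyridine
    (aromatic N) and anilide N do not.
    """
    if atom.GetAtomicNum() != 7 or atom.GetIsAromatic():
        return False
    if atom.GetFormalCharge() < 0:
        return False
    for bond in atom.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE:
            return False
        nbr = bond.GetOtherAtom(atom)
        if nbr.GetAtomicNum() in (6, 16):  # amide / sulfonamide carbonyl
            for b2 in nbr.GetBonds():
                if b2.GetBondType() == Chem.BondType.DOUBLE and b2.GetOtherAtom(nbr).GetAtomicNum() in (7, 8, 16):
                    return False
    if atom.IsInRing():
        return True
    return any(nbr.IsInRing() for nbr in atom.GetNeighbors())


def has_basic_ring_nitrogen(mol: Chem.Mol, smarts: str | None = None) -> bool:
    """True if the molecule has a basic ring (or ring-attached) nitrogen."""
    if smarts is not None:
        patt = Chem.MolFromSmarts(smarts)
        return mol.HasSubstructMatch(patt)
    return any(_is_basic_ring_nitrogen(a) for a in mol.GetAtoms())


def has_unspecified_stereocenter(mol: Chem.Mol) -> bool:
    """True if any tetrahedral stereocenter lacks an assigned configuration."""
    centers = FindMolChiralCenters(mol, includeUnassigned=True)
    return any(code == "?" for _, code in centers)


def curate(
    records: Sequence[MoleculeRecord],
    criteria: CurationCriteria | None = None,
) -> tuple[list[MoleculeRecord], list[tuple[MoleculeRecord, list[str]]]]:
    """Apply inclusion criteria; split records into kept and rejected.

    Returns ``(kept, rejected)`` where each rejected entry carries the full
    list of violated-criterion labels drawn from ``{parse_error, mw, ki,
    no_basic_ring_N, unspecified_stereo, excluded_scaffold}``. Input order
    is preserved in both lists and every input appears in exactly one.
    """
    criteria = criteria or CurationCriteria()
    scaffold_patts = [Chem.MolFromSmarts(s) for s in criteria.excluded_scaffold_patterns]
    kept: list[MoleculeRecord] = []
    rejected: list[tuple[MoleculeRecord, list[str]]] = []
    for rec in records:
        mol = rec.mol()
        if mol is None or mol.GetNumHeavyAtoms() < 1:
            rejected.append((rec, ["parse_error"]))
            continue
        reasons: list[str] = []
        if _RDDescriptors.MolWt(mol) >= criteria.max_mw:
            reasons.append("mw")
        if rec.ki_nM >= criteria.max_ki_nM:
            reasons.append("ki")
        if criteria.require_basic_ring_nitrogen and not has_basic_ring_nitrogen(
            mol, criteria.basic_nitrogen_smarts
        ):
            reasons.append("no_basic_ring_N")
        if criteria.exclude_unspecified_stereo and has_unspecified_stereocenter(mol):
            reasons.append("unspecified_stereo")
        if any(mol.HasSubstructMatch(p) for p in scaffold_patts if p is not None):
            reasons.append("excluded_scaffold")
        if reasons:
            rejected.append((rec, reasons))
        else:
            kept.append(rec)
    return kept, rejected


def round_half_up(x: float) -> int:
    """Round to nearest integer with exact halves rounded up."""
    return int(math.floor(x + 0.5))


@dataclass
class SplitPlan:
    """Modeling/testing split plus the repeated train/validation splits.

    The full id set is first partitioned into a modeling set and an
    external testing set at ``ratio`` (default 4:1, modeling size =
    round-half-up of the 4/5 fraction). The modeling set is then randomly
    re-partitioned ``n_repeats`` times into train/validation at the same
    ratio; repeat ``r`` (1-based) draws from a generator seeded with
    ``seed + r`` so each split is independently reproducible.
    """

    modeling_ids: list[str]
    testing_ids: list[str]
    repeats: list[tuple[list[str], list[str]]]
    seed: int
    ratio: tuple[int, int] = (4, 1)
    n_repeats: int = 50

    def to_json(self, path: str | Path) -> None:
        payload = {
            "modeling_ids": self.modeling_ids,
            "testing_ids": self.testing_ids,
            "repeats": [{"train": t, "validation": v} for t, v in self.repeats],
            "seed": self.seed,
            "ratio": list(self.ratio),
            "n_repeats": self.n_repeats,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        return cls(
            modeling_ids=d["modeling_ids"],
            testing_ids=d["testing_ids"],
            repeats=[(r["train"], r["validation"]) for r in d["repeats"]],
            seed=d["seed"],
            ratio=tuple(d["ratio"]),
            n_repeats=d["n_repeats"],
        )


def _partition(ids: list[str], rng: np.random.Generator, ratio: tuple[int, int]) -> tuple[list[str], list[str]]:
    n = len(ids)
    n_major = round_half_up(n * ratio[0] / (ratio[0] + ratio[1]))
    perm = rng.permutation(n)
    major = sorted(ids[i] for i in perm[:n_major])
    minor = sorted(ids[i] for i in perm[n_major:])
    return major, minor


def make_split_plan(
    ids: Iterable[str],
    seed: int,
    ratio: tuple[int, int] = (4, 1),
    n_repeats: int = 50,
    min_compounds: int = 10,
) -> SplitPlan:
    """Build the deterministic modeling/testing + 50x train/validation plan.

    Ids are canonically sorted before shuffling, so the plan depends only
    on the id *set* and the seed, not on input ordering. Sets smaller
    than ``min_compounds`` are refused (lower it deliberately for toy
    demonstrations of the 4:1 sizing).
    """
    ids = sorted(set(ids))
    if len(ids) < min_compounds:
        raise CurationError(
            f"too few compounds to split: need >= {min_compounds}, got {len(ids)}"
        )
    master = np.random.default_rng(seed)
    modeling, testing = _partition(ids, master, ratio)
    repeats = []
    for r in range(1, n_repeats + 1):
        rng = np.random.default_rng(seed + r)
        repeats.append(_partition(modeling, rng, ratio))
    return SplitPlan(modeling, testing, repeats, seed=seed, ratio=ratio, n_repeats=n_repeats)


# ---------------------------------------------------------------------------
# I/O

def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """Read a SMILES file with one `smiles<TAB>id` record per line."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise CurationError(f"line {i + 1} of {path}: expected 'smiles<TAB>id'")
        out.append((parts[0], parts[1]))
    return out


def read_sdf_file(path: str | Path, id_prop: str = "_Name") -> list[tuple[str, str]]:
    """Read an SDF file into (smiles, id) pairs. Unparsable blocks get id-less placeholders."""
    out = []
    suppl = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(suppl):
        if mol is None:
            out.append(("", f"sdf_record_{i}"))
            continue
        mid = mol.GetProp(id_prop) if mol.HasProp(id_prop) and mol.GetProp(id_prop) else f"sdf_record_{i}"
        out.append((Chem.MolToSmiles(mol), mid))
    return out


def read_activity_csv(path: str | Path) -> pd.DataFrame:
    """Read an activity table with header ``id,ki_nM[,source_ref]``."""
    df = pd.read_csv(path, dtype={"id": str})
    missing = {"id", "ki_nM"} - set(df.columns)
    if missing:
        raise CurationError(f"activity CSV missing columns: {sorted(missing)}")
    if "source_ref" not in df.columns:
        df["source_ref"] = ""
    return df


def join_structures_activities(
    structures: Sequence[tuple[str, str]], activities: pd.DataFrame
) -> list[MoleculeRecord]:
    """Join (smiles, id) pairs to the activity table on id, canonicalizing SMILES."""
    act = activities.set_index("id")
    records = []
    for smiles, mid in structures:
        if mid not in act.index:
            continue
        row = act.loc[mid]
        mol = Chem.MolFromSmiles(smiles) if smiles else None
        canonical = Chem.MolToSmiles(mol) if mol is not None else smiles
        records.append(
            MoleculeRecord(
                id=mid,
                smiles=canonical,
                ki_nM=float(row["ki_nM"]),
                source_ref=str(row.get("source_ref", "")),
            )
        )
    return records


def write_curated_csv(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"id": r.id, "smiles": r.smiles, "ki_nM": r.ki_nM, "pki": r.pki, "source_ref": r.source_ref}
            for r in records
        ]
    ).to_csv(path, index=False)


def read_curated_csv(path: str | Path) -> list[MoleculeRecord]:
    df = pd.read_csv(path, dtype={"id": str, "source_ref": str})
    df["source_ref"] = df["source_ref"].fillna("")
    return [
        MoleculeRecord(
            id=row.id, smiles=row.smiles, ki_nM=float(row.ki_nM), pki=float(row.pki), source_ref=row.source_ref
        )
        for row in df.itertuples()
    ]


def write_rejection_log(
    rejected: Sequence[tuple[MoleculeRecord, list[str]]], path: str | Path
) -> None:
    pd.DataFrame(
        [{"id": r.id, "smiles": r.smiles, "ki_nM": r.ki_nM, "reasons": ";".join(reasons)} for r, reasons in rejected]
    ).to_csv(path, index=False)
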