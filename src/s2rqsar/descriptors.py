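"""2D molecular descriptors and descriptor-matrix screening.

Computes named 2D descriptors with RDKit, including open-toolkit analogs
of the five descriptors in the published S2R affinity model (Balaban J,
longest acyclic single-bond chain, VSA of negatively charged atoms, VSA
of pure H-bond acceptors, and the SlogP VSA bin for atomic logP in
[-0.4, -0.2)). Exact numeric parity with proprietary (MOE) descriptor
values is NOT promised: each analog documents its own definition and the
matrix carries a provider label. Externally computed descriptor CSVs can
be loaded as an alternative provider.

Also implements descriptor screening (blacklist, zero-dominant columns,
near-binary columns) and greedy absolute-Pearson correlation pruning at
|r| > 0.9 with group bookkeeping for later swap refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors, GraphDescriptors, rdMolDescriptors

from .curation import MoleculeRecord

__all__ = [
    "DescriptorMatrix",
    "ScreenReport",
    "MODEL_DESCRIPTOR_NAMES",
    "DEFAULT_BLACKLIST",
    "compute_descriptors",
    "screen_descriptors",
    "prune_correlated",
    "balaban_j",
    "longest_single_bond_chain",
    "vsa_negative_charge",
    "vsa_hbond_acceptors",
    "slogp_vsa_bin1",
]


class DescriptorError(ValueError):
    pass


#: Names of the five descriptors used by the published affinity model.
MODEL_DESCRIPTOR_NAMES = ("balabanJ", "b_max1len", "Q_VSA_PNEG", "vsa_acc", "SlogP_VSA1")

#: Default irrelevance blacklist: synthesizability/feasibility-type scores
#: that carry no physical relationship to binding affinity.
DEFAULT_BLACKLIST = ("rsynth", "SAscore", "sa_score", "synth_feasibility", "qed_like")


@dataclass
class DescriptorMatrix:
    """Molecules x named numeric 2D descriptors.

    Thin wrapper over a pandas DataFrame keeping explicit ordered id and
    descriptor-name lists plus a provider label ("rdkit" or "csv:...").
    """

    molecule_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    provider: str = "rdkit"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.molecule_ids), len(self.descriptor_names)):
            raise DescriptorError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.molecule_ids)} molecules x {len(self.descriptor_names)} descriptors"
            )
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise DescriptorError("descriptor names must be unique")

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.molecule_ids, columns=self.descriptor_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provider: str = "frame") -> "DescriptorMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy(float), provider)

    def select(self, names: Sequence[str]) -> "DescriptorMatrix":
        """Sub-matrix restricted to ``names`` (order as given)."""
        idx = [self.descriptor_names.index(n) for n in names]
        return DescriptorMatrix(self.molecule_ids, list(names), self.values[:, idx], self.provider)

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DescriptorMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls.from_frame(df, provider=f"csv:{path}")


# ---------------------------------------------------------------------------
# The five analog descriptors of the published model

def balaban_j(mol: Chem.Mol) -> float:
    """Balaban's J distance-connectivity index (RDKit implementation).

    Undefined for single-atom graphs; returns 0 with a warning there.
    """
    if mol.GetNumHeavyAtoms() < 2:
        warnings.warn("Balaban J undefined for single-atom molecule; returning 0")
        return 0.0
    return float(GraphDescriptors.BalabanJ(mol))


def longest_single_bond_chain(mol: Chem.Mol) -> float:
    """Number of bonds in the longest chain of acyclic single bonds.

    The molecular graph is restricted to non-ring single bonds between
    heavy atoms; the result is the longest path (in bonds) in that forest.
    Ethane -> 1; benzene -> 0 (all bonds are in the ring).
    """
    adj: dict[int, list[int]] = {}
    for bond in mol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    if not adj:
        return 0.0

    def farthest(start: int) -> tuple[int, int]:
        # BFS over the acyclic-single-bond forest
        seen = {start: 0}
        frontier = [start]
        far, dist = start, 0
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj.get(u, ()):
                    if v not in seen:
                        seen[v] = seen[u] + 1
                        if seen[v] > dist:
                            far, dist = v, seen[v]
                        nxt.append(v)
            frontier = nxt
        return far, dist

    best = 0
    visited: set[int] = set()
    for node in adj:
        if node in visited:
            continue
        # double-BFS diameter of this tree component
        a, _ = farthest(node)
        _, d = farthest(a)
        best = max(best, d)
        comp = {node}
        stack = [node]
        while stack:
            u = stack.pop()
            for v in adj.get(u, ()):
                if v not in comp:
                    comp.add(v)
                    stack.append(v)
        visited |= comp
    return float(best)


def _labute_contribs(mol: Chem.Mol) -> np.ndarray:
    heavy, h_contrib = rdMolDescriptors._CalcLabuteASAContribs(mol)
    return np.asarray(list(heavy), dtype=float)


def vsa_negative_charge(mol: Chem.Mol, charge_threshold: float = -0.2) -> float:
    """Approximate-VdW surface area of negatively *polar* charged atoms.

    Gasteiger charges are computed on the molecule as given (the neutral
    form when curated structures are neutral); Labute approximate-ASA
    per-atom contributions are summed over atoms whose charge falls below
    ``charge_threshold``. The default of -0.2 counts only genuinely polar
    atoms — mildly negative alkane carbons do not contribute.
    """
    m = Chem.Mol(mol)
    AllChem.ComputeGasteigerCharges(m)
    charges = np.array([a.GetDoubleProp("_GasteigerCharge") for a in m.GetAtoms()])
    charges = np.nan_to_num(charges, nan=0.0)
    contribs = _labute_contribs(m)
    return float(contribs[charges < charge_threshold].sum())


_ACCEPTOR_SMARTS = Chem.MolFromSmarts(
    "[$([O;H0;v2;!$(O=*)]),$([O;-]),$([o;+0]),$([N;v3;H0;!$(N-*=[O,N,P,S]);!$(N=*)]),$([n;+0;H0])]"
)
_DONOR_SMARTS = Chem.MolFromSmarts("[$([N,O,S;!H0])]")


def vsa_hbond_acceptors(mol: Chem.Mol) -> float:
    """VdW surface area of pure hydrogen-bond acceptor atoms.

    "Pure" acceptors accept but do not donate: acceptor-pattern atoms that
    carry no attached hydrogen are summed by their Labute ASA contribution.
    """
    acceptors = {i[0] for i in mol.GetSubstructMatches(_ACCEPTOR_SMARTS)}
    donors = {i[0] for i in mol.GetSubstructMatches(_DONOR_SMARTS)}
    pure = sorted(acceptors - donors)
    if not pure:
        return 0.0
    contribs = _labute_contribs(mol)
    return float(contribs[pure].sum())


def slogp_vsa_bin1(mol: Chem.Mol) -> float:
    """VdW surface area of atoms with atomic logP contribution in [-0.4, -0.2).

    Uses Crippen per-atom logP contributions and Labute ASA contributions.
    """
    crippen = np.array([c[0] for c in rdMolDescriptors._CalcCrippenContribs(mol)])
    contribs = _labute_contribs(mol)
    mask = (crippen >= -0.4) & (crippen < -0.2)
    return float(contribs[mask].sum())


_ANALOGS: dict[str, Callable[[Chem.Mol], float]] = {
    "balabanJ": balaban_j,
    "b_max1len": longest_single_bond_chain,
    "Q_VSA_PNEG": vsa_negative_charge,
    "vsa_acc": vsa_hbond_acceptors,
    "SlogP_VSA1": slogp_vsa_bin1,
}


def _rdkit_catalog() -> dict[str, Callable[[Chem.Mol], float]]:
    # full RDKit 2D descriptor list, excluding names that would shadow the analogs
    cat = {}
    for name, fn in Descriptors._descList:
        if name in _ANALOGS:
            continue
        cat[name] = fn
    return cat


def compute_descriptors(
    molecules: Sequence[MoleculeRecord | Chem.Mol | str],
    names: Sequence[str] | None = None,
    include_rdkit_catalog: bool = False,
) -> DescriptorMatrix:
    """Compute named 2D descriptors for a molecule set.

    Always includes the five published-model analogs; with
    ``include_rdkit_catalog=True`` (or names drawn from it) the full RDKit
    2D descriptor list is available as well. Values that come back
    non-finite (a descriptor undefined for some molecule) are set to 0
    with a warning rather than raising.
    """
    catalog = dict(_ANALOGS)
    if include_rdkit_catalog or (names and any(n not in _ANALOGS for n in names)):
        catalog.update(_rdkit_catalog())
    if names is None:
        names = list(_ANALOGS) + (list(_rdkit_catalog()) if include_rdkit_catalog else [])
    unknown = [n for n in names if n not in catalog]
    if unknown:
        raise DescriptorError(f"unknown descriptor names: {unknown}")

    ids, mols = [], []
    for i, m in enumerate(molecules):
        if isinstance(m, MoleculeRecord):
            ids.append(m.id)
            mols.append(m.mol())
        elif isinstance(m, str):
            ids.append(f"mol_{i}")
            mols.append(Chem.MolFromSmiles(m))
        else:
            ids.append(m.GetProp("_Name") if m.HasProp("_Name") and m.GetProp("_Name") else f"mol_{i}")
            mols.append(m)
    bad = [ids[i] for i, m in enumerate(mols) if m is None]
    if bad:
        raise DescriptorError(f"unparsable molecules: {bad}")

    values = np.zeros((len(mols), len(names)))
    for j, name in enumerate(names):
        fn = catalog[name]
        for i, mol in enumerate(mols):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    v = float(fn(mol))
                except Exception:
                    v = float("nan")
            if not np.isfinite(v):
                warnings.warn(f"descriptor {name} undefined for molecule {ids[i]}; using 0")
                v = 0.0
            values[i, j] = v
    return DescriptorMatrix(ids, list(names), values, provider="rdkit")


# ---------------------------------------------------------------------------
# Screening

@dataclass
class ScreenReport:
    """Outcome of descriptor screening: exclusions with one reason each."""

    excluded: dict[str, str] = field(default_factory=dict)
    retained_names: list[str] = field(default_factory=list)
    zero_fraction_threshold: float = 0.95
    distinct_value_threshold: int = 2
    correlation_threshold: float = 0.9

    def to_json_dict(self) -> dict:
        return {
            "excluded": self.excluded,
            "retained_names": self.retained_names,
            "thresholds": {
                "zero_fraction": self.zero_fraction_threshold,
                "distinct_values": self.distinct_value_threshold,
                "correlation": self.correlation_threshold,
            },
        }


def screen_descriptors(
    matrix: DescriptorMatrix,
    blacklist: Sequence[str] = DEFAULT_BLACKLIST,
    zero_fraction_threshold: float = 0.95,
    distinct_value_threshold: int = 2,
) -> tuple[DescriptorMatrix, ScreenReport]:
    """Remove uninformative descriptor columns.

    Exclusion rules, applied in order (each excluded name gets exactly one
    reason): (1) ``blacklist`` membership; (2) zero-dominant columns whose
    fraction of exact zeros exceeds ``zero_fraction_threshold``; (3)
    near-binary columns with at most ``distinct_value_threshold`` distinct
    values. Retained column order is preserved.
    """
    if matrix.n_descriptors == 0 or matrix.n_molecules == 0:
        raise DescriptorError("cannot screen an empty descriptor matrix")
    bl = set(blacklist)
    excluded: dict[str, str] = {}
    retained: list[str] = []
    for j, name in enumerate(matrix.descriptor_names):
        col = matrix.values[:, j]
        if name in bl:
            excluded[name] = "blacklist"
        elif np.mean(col == 0.0) > zero_fraction_threshold:
            excluded[name] = "zero_dominant"
        elif len(np.unique(col)) <= distinct_value_threshold:
            excluded[name] = "near_binary"
        else:
            retained.append(name)
    if not retained:
        raise DescriptorError("no descriptors survive screening")
    report = ScreenReport(
        excluded=excluded,
        retained_names=retained,
        zero_fraction_threshold=zero_fraction_threshold,
        distinct_value_threshold=distinct_value_threshold,
    )
    return matrix.select(retained), report


def prune_correlated(
    matrix: DescriptorMatrix,
    threshold: float = 0.9,
    response: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[DescriptorMatrix, dict[str, list[str]]]:
    """Greedy pruning of descriptor pairs with absolute Pearson |r| > threshold.

    Representatives are chosen greedily: with a ``response`` given, the
    ungrouped column most correlated (in absolute value) with the response
    seeds the next group; otherwise the lexicographically smallest name
    does (``seed`` switches to random seeding for parity with protocols
    that "randomly chose one"). Each group absorbs every still-ungrouped
    column with |r| > threshold to its seed, so kept representatives are
    pairwise below threshold and the operation is idempotent.

    Zero-variance columns are excluded up front with reason recorded under
    the pseudo-group ``"__degenerate__"``.

    Returns the pruned matrix and a map representative -> full member list
    (representative first) used later for correlated-swap refinement.
    """
    names = matrix.descriptor_names
    X = matrix.values
    variances = X.var(axis=0)
    degenerate = [names[j] for j in range(len(names)) if variances[j] == 0.0]
    live = [n for n in names if n not in degenerate]
    if not live:
        raise DescriptorError("all columns are constant; nothing to prune")
    live_idx = {n: names.index(n) for n in live}

    with np.errstate(invalid="ignore"):
        sub = X[:, [live_idx[n] for n in live]]
        corr = np.corrcoef(sub, rowvar=False)
    corr = np.atleast_2d(corr)
    pos = {n: i for i, n in enumerate(live)}

    if response is not None:
        y = np.asarray(response, dtype=float)
        yc = y - y.mean()
        resp_corr = {}
        for n in live:
            col = sub[:, pos[n]]
            cc = col - col.mean()
            denom = np.sqrt((cc**2).sum() * (yc**2).sum())
            resp_corr[n] = abs(float(cc @ yc) / denom) if denom > 0 else 0.0

    rng = np.random.default_rng(seed) if seed is not None else None
    ungrouped = sorted(live)
    groups: dict[str, list[str]] = {}
    while ungrouped:
        if response is not None:
            rep = min(ungrouped, key=lambda n: (-resp_corr[n], n))
        elif rng is not None:
            rep = ungrouped[int(rng.integers(len(ungrouped)))]
        else:
            rep = ungrouped[0]
        members = [rep] + [
            n for n in ungrouped if n != rep and abs(corr[pos[rep], pos[n]]) > threshold
        ]
        groups[rep] = members
        ungrouped = [n for n in ungrouped if n not in members]

    kept = [n for n in names if n in groups]  # preserve original column order
    if degenerate:
        groups["__degenerate__"] = degenerate
    return matrix.select(kept), groups
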