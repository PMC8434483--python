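"""Synthetic fixtures: planted-support descriptor matrices and toy molecules.

The matrix generator draws equicorrelated Gaussian descriptor columns,
plants a linear support of known coefficients, and adds Gaussian noise
calibrated (optionally) to a target population R-squared — mimicking the
statistical shape of a curated QSAR table (n in the low hundreds, p in
the tens-to-hundreds, a handful of truly informative descriptors) without
simulating any real chemistry. The toy molecule set spans every curation
case (weight, affinity, basic nitrogen, stereochemistry, excluded
scaffold) so the structure-handling code paths are testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .curation import MoleculeRecord
from .descriptors import DescriptorMatrix

__all__ = ["SyntheticSpec", "generate_matrix", "toy_molecule_set", "add_screening_trap_columns"]


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Parameters of a planted-linear-support descriptor matrix.

    ``inter_descriptor_correlation`` is the pairwise equicorrelation of
    the Gaussian descriptor block; ``n_near_duplicates`` appends copies
    of support columns perturbed to correlate above 0.9 with their
    original (exercising correlation pruning and swap refinement).
    Exactly one of ``noise_sd`` / ``target_r2`` controls the noise level:
    when ``target_r2`` is set, noise_sd is solved analytically from the
    planted signal variance.
    """

    n_molecules: int = 160
    n_descriptors: int = 60
    support_size: int = 5
    coefficients: tuple[float, ...] | None = None
    noise_sd: float | None = 1.0
    target_r2: float | None = None
    inter_descriptor_correlation: float = 0.2
    n_near_duplicates: int = 0
    intercept: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.support_size > self.n_descriptors:
            raise SyntheticError("support_size cannot exceed n_descriptors")
        if not (0.0 <= self.inter_descriptor_correlation < 1.0):
            raise SyntheticError("inter_descriptor_correlation must be in [0, 1)")
        if self.coefficients is None:
            self.coefficients = tuple(1.0 + 0.25 * i for i in range(self.support_size))
        if len(self.coefficients) != self.support_size:
            raise SyntheticError("need one coefficient per support descriptor")
        if self.target_r2 is not None:
            if not (0.0 < self.target_r2 < 1.0):
                raise SyntheticError("target_r2 must be in (0, 1)")
        elif self.noise_sd is None or self.noise_sd < 0:
            raise SyntheticError("noise_sd must be >= 0")


def _signal_variance(spec: SyntheticSpec) -> float:
    # beta' Sigma beta for the equicorrelation matrix Sigma = (1-rho) I + rho J
    beta = np.asarray(spec.coefficients)
    rho = spec.inter_descriptor_correlation
    return float((1 - rho) * (beta**2).sum() + rho * beta.sum() ** 2)


def generate_matrix(spec: SyntheticSpec) -> tuple[DescriptorMatrix, np.ndarray, list[str], dict]:
    """Generate (matrix, y, true_support_names, info).

    Descriptor columns are unit-variance Gaussians with the specified
    pairwise equicorrelation (single-factor construction). The response
    is ``intercept + X[:, support] @ coefficients + noise``. ``info``
    reports the realized population R-squared, the noise sd used, and the
    near-duplicate column map.
    """
    rng = np.random.default_rng(spec.seed)
    n, p, rho = spec.n_molecules, spec.n_descriptors, spec.inter_descriptor_correlation
    common = rng.standard_normal((n, 1))
    idio = rng.standard_normal((n, p))
    X = np.sqrt(rho) * common + np.sqrt(1 - rho) * idio

    support_idx = sorted(rng.choice(p, size=spec.support_size, replace=False).tolist())
    width = len(str(p + spec.n_near_duplicates))
    names = [f"D{j + 1:0{width}d}" for j in range(p)]
    support_names = [names[j] for j in support_idx]

    var_signal = _signal_variance(spec)
    if spec.target_r2 is not None:
        noise_sd = float(np.sqrt(var_signal * (1.0 / spec.target_r2 - 1.0)))
    else:
        noise_sd = float(spec.noise_sd)
    beta = np.asarray(spec.coefficients)
    y = spec.intercept + X[:, support_idx] @ beta + noise_sd * rng.standard_normal(n)

    duplicates: dict[str, str] = {}
    if spec.n_near_duplicates > 0:
        # near-copies of the first support columns, |r| > 0.9 with the original
        extra = []
        for d in range(spec.n_near_duplicates):
            src = support_idx[d % len(support_idx)]
            col = X[:, src] + 0.25 * rng.standard_normal(n)
            extra.append(col)
            dup_name = f"D{p + d + 1:0{width}d}"
            names.append(dup_name)
            duplicates[dup_name] = names[src]
        X = np.column_stack([X] + extra)

    pop_r2 = var_signal / (var_signal + noise_sd**2) if (var_signal + noise_sd**2) > 0 else 1.0
    ids = [f"M{i + 1:04d}" for i in range(n)]
    matrix = DescriptorMatrix(ids, names, X, provider="synthetic")
    info = {"population_r2": pop_r2, "noise_sd": noise_sd, "near_duplicates": duplicates}
    return matrix, y, support_names, info


def add_screening_trap_columns(matrix: DescriptorMatrix, seed: int = 0) -> DescriptorMatrix:
    """Append a 96%-zeros column and a two-valued column.

    These exercise the zero-dominant and near-binary descriptor screening
    rules on otherwise clean synthetic matrices.
    """
    rng = np.random.default_rng(seed)
    n = matrix.n_molecules
    zeros = np.zeros(n)
    n_nonzero = max(1, int(round(0.04 * n)))
    zeros[rng.choice(n, size=n_nonzero, replace=False)] = rng.standard_normal(n_nonzero)
    binary = np.where(rng.random(n) < 0.5, 0.0, 5.6826)
    values = np.column_stack([matrix.values, zeros, binary])
    names = matrix.descriptor_names + ["trap_zero_dominant", "trap_near_binary"]
    return DescriptorMatrix(matrix.molecule_ids, names, values, matrix.provider)


# ---------------------------------------------------------------------------
# Toy molecules

#: (id, smiles, Ki in nM, designed curation outcome)
_TOY_SET: list[tuple[str, str, float, str]] = [
    # kept: drug-like piperidines / piperazines / tetrahydroisoquinolines, Ki < 5000, MW < 500
    ("ok_piperidine_butyrophenone", "O=C(CCCN1CCCCC1)c1ccc(F)cc1", 35.0, "kept"),
    ("ok_phenylpiperazine", "c1ccc(N2CCN(CCCC(=O)c3ccccc3)CC2)cc1", 12.0, "kept"),
    ("ok_thiq", "C1Cc2ccccc2CN1CCCOc1ccccc1", 80.0, "kept"),
    ("ok_methoxy_piperidine", "COc1ccc(CCN2CCCCC2)cc1", 450.0, "kept"),
    ("ok_benzyl_pyrrolidine", "C(N1CCCC1)c1ccc2ccccc2c1", 950.0, "kept"),
    ("ok_fluoro_piperazine", "Fc1ccc(N2CCN(Cc3ccccc3)CC2)cc1", 28.0, "kept"),
    ("ok_benzyl_piperidine", "C(c1ccccc1)C1CCNCC1", 4.5, "kept"),
    ("ok_specified_stereo", "C[C@H](N1CCCCC1)c1ccccc1", 600.0, "kept"),
    ("ok_morpholine_aryl", "O1CCN(CCCc2ccccc2)CC1", 2400.0, "kept"),
    ("ok_granatane_free", "CN1CCC(CCOc2ccccc2)CC1", 150.0, "kept"),
    # rejected: molecular weight >= 500
    ("bad_mw_heavy", "O=C(CCCN1CCN(c2ccc(OCCCCCCCCCC(=O)NCCc3ccccc3)cc2)CC1)c1ccc(F)cc1", 90.0, "mw"),
    ("bad_mw_dibenzhydryl", "C(OCCN1CCN(CCOC(c2ccccc2)c2ccccc2)CC1)(c1ccccc1)c1ccccc1", 55.0, "mw"),
    # rejected: Ki >= 5000 nM
    ("bad_ki_weak", "CCCN1CCN(c2ccccc2)CC1", 7800.0, "ki"),
    ("bad_ki_borderline", "OCCN1CCN(CCc2ccccc2)CC1", 5000.0, "ki"),
    # rejected: no basic ring nitrogen
    ("bad_nobasic_pyridine", "c1ccncc1", 900.0, "no_basic_ring_N"),
    ("bad_nobasic_amide", "O=C(N1CCCCC1)c1ccccc1", 1200.0, "no_basic_ring_N"),
    ("bad_nobasic_ether", "COc1ccc2ccccc2c1", 3300.0, "no_basic_ring_N"),
    # rejected: unspecified stereocenter
    ("bad_stereo_racemic", "CC(N1CCCCC1)c1ccccc1", 300.0, "unspecified_stereo"),
    # rejected: 9-azabicyclo[3.3.1]nonane scaffold
    ("bad_scaffold_granatanine", "CN1C2CCCC1CCC2", 40.0, "excluded_scaffold"),
    # rejected: unparsable structure
    ("bad_parse", "C1CC", 100.0, "parse_error"),
]


def toy_molecule_set(with_expected: bool = False):
    """~20 hand-written structures spanning every curation case.

    Returns MoleculeRecords; with ``with_expected=True`` returns
    (records, expected) where expected maps id -> "kept" or the designed
    primary rejection reason.
    """
    records = []
    for mid, smi, ki, _ in _TOY_SET:
        if mid == "bad_parse":
            rec = MoleculeRecord(id=mid, smiles=smi, ki_nM=ki, source_ref="toy")
        else:
            rec = MoleculeRecord(id=mid, smiles=smi, ki_nM=ki, source_ref="toy")
        records.append(rec)
    if with_expected:
        return records, {mid: outcome for mid, _, _, outcome in _TOY_SET}
    return records


def write_fixture_dir(spec: SyntheticSpec, out_dir: str | Path) -> None:
    """Write desc.csv, y.csv and truth.json for a synthetic spec."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, y, support, info = generate_matrix(spec)
    matrix.to_csv(out / "desc.csv")
    import pandas as pd

    pd.DataFrame({"id": matrix.molecule_ids, "pki": y}).to_csv(out / "y.csv", index=False)
    (out / "truth.json").write_text(
        json.dumps({"support": support, "coefficients": list(spec.coefficients), **info}, indent=1)
    )
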