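"""Multivariate linear regression QSAR models and the 50-split protocol.

Fits ordinary least-squares models on selected descriptor subsets,
computes training R-squared and leave-one-out Q-squared, runs the
repeated train/validation protocol with external testing, and exposes
the frozen published five-descriptor S2R affinity model as a scorer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .curation import SplitPlan
from .descriptors import DescriptorMatrix

__all__ = [
    "LinearModel",
    "ModelStats",
    "ProtocolCriteria",
    "fit_mlr",
    "r_squared",
    "q2_loo",
    "run_protocol",
    "published_model",
]


class ModelingError(ValueError):
    pass


@dataclass
class LinearModel:
    """Intercept plus named coefficients; predicts pKi from descriptors."""

    intercept: float
    coefficients: dict[str, float]
    provider_label: str = ""

    def __post_init__(self) -> None:
        if len(set(self.coefficients)) != len(self.coefficients):
            raise ModelingError("coefficient names must be unique")

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.coefficients)

    def predict(self, data: DescriptorMatrix | pd.DataFrame | Mapping[str, float]) -> np.ndarray:
        """Predict responses; every coefficient name must be present."""
        if isinstance(data, DescriptorMatrix):
            df = data.to_frame()
        elif isinstance(data, pd.DataFrame):
            df = data
        else:
            df = pd.DataFrame([dict(data)])
        missing = [n for n in self.coefficients if n not in df.columns]
        if missing:
            raise ModelingError(f"input is missing model descriptor columns: {missing}")
        X = df[self.descriptor_names].to_numpy(float)
        beta = np.array([self.coefficients[n] for n in self.descriptor_names])
        return self.intercept + X @ beta

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"intercept": self.intercept, "coefficients": self.coefficients, "provider_label": self.provider_label},
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearModel":
        d = json.loads(Path(path).read_text())
        return cls(d["intercept"], d["coefficients"], d.get("provider_label", ""))


def published_model() -> LinearModel:
    """The frozen published five-descriptor S2R binding-affinity model.

    pKi = 11.29 - 3.77*balabanJ + 0.23*b_max1len - 0.029*Q_VSA_PNEG
          + 0.043*vsa_acc - 0.026*SlogP_VSA1

    The coefficients were fit on proprietary (MOE 2018) descriptor values;
    scoring open-toolkit analog descriptors through it is an approximation
    and the provider label records which descriptor source was intended.
    """
    return LinearModel(
        intercept=11.29,
        coefficients={
            "balabanJ": -3.77,
            "b_max1len": 0.23,
            "Q_VSA_PNEG": -0.029,
            "vsa_acc": 0.043,
            "SlogP_VSA1": -0.026,
        },
        provider_label="MOE 2018 descriptors (frozen published fit)",
    )


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def fit_mlr(
    X: DescriptorMatrix | np.ndarray,
    y: np.ndarray,
    names: Sequence[str] | None = None,
    provider_label: str = "",
) -> LinearModel:
    """Ordinary least-squares multivariate linear regression.

    ``X`` may be a DescriptorMatrix (optionally restricted to ``names``)
    or a plain array (then ``names`` labels its columns). Raises on a
    rank-deficient design, naming the collinear columns.
    """
    if isinstance(X, DescriptorMatrix):
        if names is not None:
            X = X.select(names)
        names = X.descriptor_names
        A = X.values
    else:
        A = np.asarray(X, dtype=float)
        if names is None:
            names = [f"x{j}" for j in range(A.shape[1])]
    y = np.asarray(y, dtype=float)
    n, k = A.shape
    if n <= k + 1:
        raise ModelingError(f"need n > k + 1 rows to fit {k} descriptors; got n = {n}")
    D = _design(A)
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        collinear = _collinear_columns(D, list(names))
        raise ModelingError(f"rank-deficient design; collinear columns: {collinear}")
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    return LinearModel(float(beta[0]), {n_: float(b) for n_, b in zip(names, beta[1:])}, provider_label)


def _collinear_columns(D: np.ndarray, names: list[str]) -> list[str]:
    # identify columns whose removal restores full rank
    out = []
    full = np.linalg.matrix_rank(D)
    for j in range(1, D.shape[1]):
        reduced = np.delete(D, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full:
            out.append(names[j - 1])
    return out or names


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot about mean(y)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise ModelingError("r_squared needs two same-length vectors with >= 2 entries")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ModelingError("r_squared undefined for zero-variance observations")
    ss_res = float(((y - y_hat) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def pearson_r2(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    r = np.corrcoef(y, y_hat)[0, 1]
    return float(r * r)


def q2_loo(
    X: DescriptorMatrix | np.ndarray,
    y: np.ndarray,
    names: Sequence[str] | None = None,
    literal_refit: bool = False,
) -> float:
    """Leave-one-out cross-validated Q-squared, 1 - PRESS/SS_tot.

    Each compound is left out in turn and predicted by the model refit on
    the rest. The default path uses the hat-matrix identity for the LOO
    residual of a linear smoother, e_i / (1 - h_ii), which is numerically
    identical to the literal n-refit computation (``literal_refit=True``
    performs the n refits explicitly).
    """
    if isinstance(X, DescriptorMatrix):
        if names is not None:
            X = X.select(names)
        A = X.values
    else:
        A = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = A.shape
    if n <= k + 2:
        raise ModelingError(f"need n > k + 2 for leave-one-out; got n = {n}, k = {k}")
    D = _design(A)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ModelingError("rank-deficient design in leave-one-out fit")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ModelingError("Q2 undefined for zero-variance response")
    if literal_refit:
        press = 0.0
        for i in range(n):
            mask = np.arange(n) != i
            Di = D[mask]
            if np.linalg.matrix_rank(Di) < Di.shape[1]:
                raise ModelingError(f"rank-deficient design when leaving out row {i}")
            beta, *_ = np.linalg.lstsq(Di, y[mask], rcond=None)
            press += (y[i] - D[i] @ beta) ** 2
    else:
        Q, R = np.linalg.qr(D)
        h = (Q**2).sum(axis=1)
        if np.any(h >= 1.0 - 1e-12):
            raise ModelingError("leverage ~1: a leave-one-out refit would be rank-deficient")
        beta = np.linalg.solve(R, Q.T @ y)
        resid = y - D @ beta
        press = float(((resid / (1.0 - h)) ** 2).sum())
    return 1.0 - press / ss_tot


# ---------------------------------------------------------------------------
# 50-split protocol

@dataclass
class ProtocolCriteria:
    """Acceptance thresholds for the repeated-split validation protocol.

    Training R-squared must exceed ``train_r2`` (strict), leave-one-out
    Q-squared and validation R-squared must reach ``q2`` / ``val_r2``
    (non-strict), and a model is called stable when at least
    ``stability_pct`` percent of splits meet the validation criterion.
    """

    train_r2: float = 0.6
    q2: float = 0.5
    val_r2: float = 0.5
    stability_pct: float = 95.0


@dataclass
class ModelStats:
    """Per-split and aggregate statistics of the repeated-split protocol."""

    per_split: list[tuple[float, float, float]]  # (train R2, train Q2, validation R2)
    pct_meeting_criteria: float  # % of splits with validation R2 >= criteria.val_r2
    pct_meeting_all_criteria: float  # % of splits meeting train/Q2/validation together
    training_r2: float = float("nan")  # full modeling-set fit
    training_q2_loo: float = float("nan")
    validation_r2: float = float("nan")  # mean over splits
    testing_r2: float | None = None
    per_split_names: list[list[str]] = field(default_factory=list)
    final_model: LinearModel | None = None
    criteria: ProtocolCriteria = field(default_factory=ProtocolCriteria)

    @property
    def ranges(self) -> dict[str, tuple[float, float]]:
        arr = np.array(self.per_split)
        return {
            "train_r2": (float(arr[:, 0].min()), float(arr[:, 0].max())),
            "train_q2": (float(arr[:, 1].min()), float(arr[:, 1].max())),
            "validation_r2": (float(arr[:, 2].min()), float(arr[:, 2].max())),
        }

    def is_stable(self) -> bool:
        return self.pct_meeting_criteria >= self.criteria.stability_pct

    def summary(self) -> str:
        r = self.ranges
        lines = [
            f"train R2      {r['train_r2'][0]:.3f} - {r['train_r2'][1]:.3f}",
            f"train Q2(LOO) {r['train_q2'][0]:.3f} - {r['train_q2'][1]:.3f}",
            f"validation R2 {r['validation_r2'][0]:.3f} - {r['validation_r2'][1]:.3f}",
            f"% splits meeting validation criterion: {self.pct_meeting_criteria:.0f}%",
            f"modeling-set R2 {self.training_r2:.3f}, Q2 {self.training_q2_loo:.3f}",
        ]
        if self.testing_r2 is not None:
            lines.append(f"external testing R2 {self.testing_r2:.3f}")
        return "\n".join(lines)


def run_protocol(
    matrix: DescriptorMatrix,
    y: Mapping[str, float] | pd.Series,
    selector: Callable[[DescriptorMatrix, np.ndarray], Sequence[str]] | Sequence[str],
    split_plan: SplitPlan,
    criteria: ProtocolCriteria | None = None,
    use_pearson_r2: bool = False,
) -> ModelStats:
    """Run the repeated train/validation protocol with external testing.

    For each repeat of ``split_plan``: select descriptors (``selector`` is
    either a fixed name list — the published-model usage — or a callable
    ``(train_matrix, train_y) -> names`` for the honest per-split
    protocol), fit MLR on the train split, record train R2 and LOO Q2,
    and score the held-out validation split. Afterwards the model is refit
    on the full modeling set (selection re-run there when per-split) and
    scored on the external testing set.

    ``pct_meeting_criteria`` is the percentage of splits whose validation
    R2 reaches the validation threshold; the percentage of splits meeting
    all three split-level criteria is reported alongside.
    """
    criteria = criteria or ProtocolCriteria()
    y_map = dict(y.items()) if hasattr(y, "items") else dict(y)
    df = matrix.to_frame()
    missing = [i for i in split_plan.modeling_ids + split_plan.testing_ids if i not in df.index]
    if missing:
        raise ModelingError(f"split plan ids missing from descriptor matrix: {missing[:5]}")
    score = pearson_r2 if use_pearson_r2 else r_squared

    def sub(ids: Sequence[str]) -> tuple[DescriptorMatrix, np.ndarray]:
        m = DescriptorMatrix(list(ids), matrix.descriptor_names, df.loc[list(ids)].to_numpy(float), matrix.provider)
        return m, np.array([y_map[i] for i in ids])

    fixed_names = None if callable(selector) else list(selector)
    per_split, per_split_names = [], []
    for idx, (train_ids, val_ids) in enumerate(split_plan.repeats):
        Xtr, ytr = sub(train_ids)
        Xval, yval = sub(val_ids)
        try:
            names = fixed_names if fixed_names is not None else list(selector(Xtr, ytr))
        except Exception as exc:
            raise ModelingError(f"descriptor selection failed on split {idx}: {exc}") from exc
        model = fit_mlr(Xtr, ytr, names)
        tr_r2 = r_squared(ytr, model.predict(Xtr))
        tr_q2 = q2_loo(Xtr, ytr, names)
        val_r2 = score(yval, model.predict(Xval))
        per_split.append((tr_r2, tr_q2, val_r2))
        per_split_names.append(list(names))

    arr = np.array(per_split)
    pct_val = 100.0 * float(np.mean(arr[:, 2] >= criteria.val_r2))
    pct_all = 100.0 * float(
        np.mean((arr[:, 0] > criteria.train_r2) & (arr[:, 1] >= criteria.q2) & (arr[:, 2] >= criteria.val_r2))
    )

    Xmod, ymod = sub(split_plan.modeling_ids)
    final_names = fixed_names if fixed_names is not None else list(selector(Xmod, ymod))
    final = fit_mlr(Xmod, ymod, final_names)
    train_r2_full = r_squared(ymod, final.predict(Xmod))
    train_q2_full = q2_loo(Xmod, ymod, final_names)
    testing_r2 = None
    if split_plan.testing_ids:
        Xte, yte = sub(split_plan.testing_ids)
        testing_r2 = score(yte, final.predict(Xte))

    return ModelStats(
        per_split=per_split,
        pct_meeting_criteria=pct_val,
        pct_meeting_all_criteria=pct_all,
        training_r2=train_r2_full,
        training_q2_loo=train_q2_full,
        validation_r2=float(arr[:, 2].mean()),
        testing_r2=testing_r2,
        per_split_names=per_split_names,
        final_model=final,
        criteria=criteria,
    )
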