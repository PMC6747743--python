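"""Reference-based blood cell-composition estimation.

Whole-blood methylation is a mixture of cell-type-specific profiles, so each
sample's beta vector is modelled as a non-negative combination of flow-sorted
reference mean profiles: minimise ||x - R w||^2 subject to w >= 0 and
sum(w) <= 1 (the inequality tolerates references that do not span every cell
type present), then renormalise to proportions summing to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from ..errors import NoDataError, ValidationError
from .model import BetaMatrix

__all__ = ["CellReference", "CellProportions", "estimate_cell_proportions"]


@dataclass
class CellReference:
    """Reference mean-beta profiles: probes x cell types."""

    probe_ids: list[str]
    cell_types: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.cell_types)):
            raise ValidationError("reference shape does not match probe/cell-type lists")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValidationError("reference betas must lie in [0, 1]")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CellReference":
        return cls(list(df.index), list(df.columns), df.to_numpy(float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.cell_types)


@dataclass
class CellProportions:
    """Per-sample cell-type proportion vectors (rows sum to 1)."""

    table: pd.DataFrame  # samples x cell types

    def __post_init__(self) -> None:
        v = self.table.to_numpy(float)
        if (v < -1e-9).any():
            raise ValidationError("proportions must be non-negative")
        if not np.allclose(v.sum(axis=1), 1.0, atol=1e-6):
            raise ValidationError("proportion rows must sum to 1")

    def for_sample(self, sample_id: str) -> pd.Series:
        return self.table.loc[sample_id]


def _collinear_types(R: np.ndarray, cell_types: list[str]) -> list[tuple[str, str]]:
    c = np.corrcoef(R.T)
    pairs = []
    for i in range(len(cell_types)):
        for j in range(i + 1, len(cell_types)):
            if abs(c[i, j]) > 1 - 1e-8:
                pairs.append((cell_types[i], cell_types[j]))
    return pairs


def _solve_one(R: np.ndarray, x: np.ndarray) -> np.ndarray:
    w, _ = optimize.nnls(R, x)
    if w.sum() <= 1.0 + 1e-9:
        return w
    # simplex bound binds: quadratic programme via SLSQP
    K = R.shape[1]
    res = optimize.minimize(
        lambda v: (0.5 * np.sum((R @ v - x) ** 2), R.T @ (R @ v - x)),
        x0=w / w.sum(),
        jac=True,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * K,
        constraints=[{"type": "ineq", "fun": lambda v: 1.0 - v.sum(), "jac": lambda v: -np.ones(K)}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    return np.maximum(res.x, 0.0)


def estimate_cell_proportions(betas: BetaMatrix, ref: CellReference) -> CellProportions:
    """Constrained projection of each sample onto the reference profiles.

    Uses the probes shared between the beta matrix and the reference; requires
    at least as many shared probes as cell types and a full-rank reference.
    """
    shared = [p for p in ref.probe_ids if p in set(betas.probe_ids)]
    K = len(ref.cell_types)
    if len(shared) < K:
        raise NoDataError(
            f"only {len(shared)} probes shared with the reference; need >= {K}"
        )
    ref_idx = {p: i for i, p in enumerate(ref.probe_ids)}
    beta_idx = {p: i for i, p in enumerate(betas.probe_ids)}
    R = ref.values[[ref_idx[p] for p in shared]]
    X = betas.values[[beta_idx[p] for p in shared]]
    if np.linalg.matrix_rank(R) < K:
        pairs = _collinear_types(R, ref.cell_types)
        raise ValidationError(
            f"reference matrix is rank-deficient; collinear cell types: {pairs}"
        )
    W = np.empty((len(betas.sample_ids), K))
    for j in range(X.shape[1]):
        w = _solve_one(R, X[:, j])
        s = w.sum()
        if s <= 0:
            raise NoDataError(
                f"sample {betas.sample_ids[j]!r} projects to the zero mixture"
            )
        W[j] = w / s
    return CellProportions(
        pd.DataFrame(W, index=betas.sample_ids, columns=ref.cell_types)
    )
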