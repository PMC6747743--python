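"""Methylation containers, the clock coefficient model, and age transforms.

An epigenetic clock here is a sparse linear predictor on beta values passed
through a piecewise log/linear age transformation: for adult_age ``A``,

    f(age) = log(age + 1) - log(A + 1)   if age <= A
           = (age - A) / (A + 1)         otherwise,

continuous and strictly increasing with branch point at ``A`` (default 20 y,
where developmental methylation change flattens). Predicted age is the exact
inverse applied to ``intercept + sum_i w_i * beta_i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import ValidationError

__all__ = [
    "BetaMatrix",
    "ProbeAnnotation",
    "ClockModel",
    "age_forward",
    "age_inverse",
    "clock_age",
    "read_beta_tsv",
    "write_beta_tsv",
    "read_probe_annotation",
    "read_clock_csv",
    "write_clock_csv",
]


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation fractions in [0, 1]."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("duplicate probe ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if not np.isfinite(self.values).all():
            raise ValidationError("beta values must be finite (impute upstream)")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValidationError("beta values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BetaMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(float))

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(list(self.probe_ids), list(self.sample_ids), self.values.copy())


@dataclass
class ProbeAnnotation:
    """Probe design type (Infinium I vs II chemistry)."""

    design_type: dict[str, str]

    def __post_init__(self) -> None:
        bad = {t for t in self.design_type.values() if t not in ("I", "II")}
        if bad:
            raise ValidationError(f"design types must be 'I' or 'II', got {bad}")

    def types_for(self, probe_ids: list[str]) -> np.ndarray:
        missing = [p for p in probe_ids if p not in self.design_type]
        if missing:
            raise ValidationError(
                f"{len(missing)} probes lack a design-type annotation "
                f"(first few: {missing[:5]})"
            )
        return np.array([self.design_type[p] for p in probe_ids])


@dataclass
class ClockModel:
    """Intercept + sparse probe weights + adult-age branch point."""

    intercept: float
    weights: dict[str, float]
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValidationError("a clock needs at least one weighted probe")
        if self.adult_age <= -1:
            raise ValidationError("adult_age must exceed -1")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.weights)


def age_forward(age, adult_age: float = 20.0):
    """Piecewise log/linear transform of chronological age (vectorised)."""
    age = np.asarray(age, dtype=float)
    if np.any(age <= -1.0):
        raise ValidationError("age must exceed -1 year")
    out = np.where(
        age <= adult_age,
        np.log1p(age) - np.log1p(adult_age),
        (age - adult_age) / (adult_age + 1.0),
    )
    return float(out) if out.ndim == 0 else out


def age_inverse(m, adult_age: float = 20.0):
    """Exact inverse of :func:`age_forward` (vectorised)."""
    m = np.asarray(m, dtype=float)
    out = np.where(
        m <= 0.0,
        np.expm1(m + np.log1p(adult_age)),
        m * (adult_age + 1.0) + adult_age,
    )
    return float(out) if out.ndim == 0 else out


def clock_age(betas: BetaMatrix, clock: ClockModel) -> pd.Series:
    """Per-sample epigenetic age from corrected betas via the clock model."""
    idx = {p: i for i, p in enumerate(betas.probe_ids)}
    missing = [p for p in clock.weights if p not in idx]
    if missing:
        raise ValidationError(
            f"beta matrix lacks {len(missing)} weighted clock probes "
            f"(first few: {missing[:5]})"
        )
    rows = np.array([idx[p] for p in clock.weights])
    w = np.array(list(clock.weights.values()))
    m = clock.intercept + w @ betas.values[rows]
    ages = age_inverse(m, clock.adult_age)
    return pd.Series(np.atleast_1d(ages), index=betas.sample_ids, name="epigenetic_age")


def read_beta_tsv(path) -> BetaMatrix:
    """Read a probes x samples TSV (first column probe ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return BetaMatrix.from_frame(df)


def write_beta_tsv(betas: BetaMatrix, path) -> None:
    betas.to_frame().to_csv(path, sep="\t", index_label="probe_id")


def read_probe_annotation(path) -> ProbeAnnotation:
    """Read ``probe_id,design_type`` CSV."""
    df = pd.read_csv(path, dtype=str)
    return ProbeAnnotation(dict(zip(df["probe_id"], df["design_type"])))


def write_probe_annotation(ann: ProbeAnnotation, path) -> None:
    pd.DataFrame(
        {"probe_id": list(ann.design_type), "design_type": list(ann.design_type.values())}
    ).to_csv(path, index=False)


_INTERCEPT_ROW = "(Intercept)"
_ADULT_AGE_ROW = "(AdultAge)"


def read_clock_csv(path) -> ClockModel:
    """Read ``probe_id,weight`` CSV with reserved rows (Intercept) and (AdultAge)."""
    df = pd.read_csv(path, dtype={"probe_id": str})
    table = dict(zip(df["probe_id"], df["weight"].astype(float)))
    if _INTERCEPT_ROW not in table:
        raise ValidationError(f"clock file lacks the {_INTERCEPT_ROW} row")
    intercept = table.pop(_INTERCEPT_ROW)
    adult_age = table.pop(_ADULT_AGE_ROW, 20.0)
    return ClockModel(intercept=intercept, weights=table, adult_age=adult_age)


def write_clock_csv(clock: ClockModel, path) -> None:
    rows = [(_INTERCEPT_ROW, clock.intercept), (_ADULT_AGE_ROW, clock.adult_age)]
    rows += list(clock.weights.items())
    pd.DataFrame(rows, columns=["probe_id", "weight"]).to_csv(path, index=False)
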