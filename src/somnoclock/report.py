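"""Structured analysis report: schema (pydantic) and validation.

The report is the machine-readable product of a full run: participant
summaries, group assignments, descriptive statistics, the baseline one-way
ANOVA, and the three ANCOVA blocks (crossed groups, duration-only,
regularity-only) with adjusted means, CIs and contrasts. JSON carries full
precision; human-readable tables round to 2 dp.
"""

from __future__ import annotations

from importlib import resources

from pydantic import BaseModel, ConfigDict

REPORT_VERSION = "1"


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParticipantBlock(_Strict):
    participant_id: str
    tst: float
    sri: float
    duration_class: str
    regularity_class: str
    group: str
    age_diff_t1: float
    age_diff_t2: float
    age_diff_change: float


class DescriptivesBlock(_Strict):
    n: int
    mean: float
    sd: float | None = None
    min: float
    max: float
    median: float


class AnovaBlock(_Strict):
    fvalue: float
    df1: int
    df2: int
    pvalue: float
    group_means: dict[str, float]


class ContrastBlock(_Strict):
    groups: list[str]
    estimate: float
    se: float
    lower: float
    upper: float
    df: int


class AdjustedMeanBlock(_Strict):
    estimate: float
    se: float
    lower: float
    upper: float
    n: int


class AncovaBlock(_Strict):
    outcome: str
    covariate: str
    eval_at: float
    slope: float
    slope_se: float
    fvalue: float
    df1: int
    df2: int
    pvalue: float
    mse: float
    adjusted_means: dict[str, AdjustedMeanBlock]
    contrasts: list[ContrastBlock]


class Report(_Strict):
    report_version: str
    package_version: str
    seed: int | None = None
    input_hashes: dict[str, str]
    sri_median: float
    participants: list[ParticipantBlock]
    descriptives: dict[str, DescriptivesBlock]
    anova_t1: dict[str, AnovaBlock]
    ancova: dict[str, AncovaBlock]


def validate_report(payload: dict) -> Report:
    """Validate a report dict against the shipped schema; raises on mismatch."""
    return Report.model_validate(payload)


def json_schema() -> dict:
    return Report.model_json_schema()


def shipped_schema_text() -> str:
    """The JSON-schema document distributed with the package."""
    return resources.files("somnoclock.data").joinpath("report_schema.json").read_text()
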