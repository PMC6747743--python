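"""End-to-end orchestration: diaries -> TST/SRI -> groups, betas -> ages,
cohort -> ANOVA/ANCOVA report.

`run_full` accepts any of three entry points, in decreasing order of work:
diaries + an age table, a beta matrix + clock coefficient files + an age
table, or a ready-made cohort table. Stage outputs are cached in the output
directory keyed by input content hashes; identical inputs and configuration
reproduce byte-identical report bodies.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .clock import (
    BmiqParams,
    bmiq_normalize,
    celltype_correct,
    clock_age,
    estimate_cell_proportions,
    read_beta_tsv,
    read_clock_csv,
    read_probe_annotation,
)
from .clock.deconvolution import CellReference
from .diary import participant_summary, read_diary_csv
from .errors import SomnoclockError, ValidationError
from .report import REPORT_VERSION, validate_report
from .sri import diary_to_grid, sri_binary, sri_probabilistic
from .stats import (
    OneWayANOVA,
    SleepAgingANCOVA,
    age_difference,
    classify_duration,
    classify_regularity,
    cross_groups,
    descriptives,
    load_cohort_csv,
)

log = logging.getLogger("somnoclock")

__all__ = ["RunConfig", "run_full", "compute_sleep_summaries", "compute_ages", "build_report"]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    out_dir: str
    cohort: str | None = None  # ready-made cohort table (skips earlier stages)
    diaries: str | None = None
    betas_t1: str | None = None
    betas_t2: str | None = None
    probes: str | None = None
    clock: str | None = None
    cellref: str | None = None
    ages: str | None = None  # chronological-age table for diary/beta entry points
    epoch_min: int = 1
    sri_mode: str = "probabilistic"
    bmiq: bool = True
    cell_correct: bool = True
    adult_age: float = 20.0
    eval_at: float = 0.0
    seed: int | None = None
    log_level: str = "INFO"
    force: bool = False

    def validate(self) -> None:
        if self.cohort is None and (self.diaries is None or self.ages is None):
            raise ValidationError(
                "need either a cohort table, or diaries plus an age table"
            )
        if self.sri_mode not in ("probabilistic", "binary"):
            raise ValidationError(f"unknown SRI mode {self.sri_mode!r}")
        for name in ("cohort", "diaries", "betas_t1", "betas_t2", "probes", "clock", "cellref", "ages"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{name} path does not exist: {p}")


def _hash_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def compute_sleep_summaries(
    diaries_path, epoch_min: int = 1, sri_mode: str = "probabilistic"
) -> pd.DataFrame:
    """Diaries -> per-participant mean TST and SRI table."""
    diaries = read_diary_csv(diaries_path)
    summary = participant_summary(diaries, ndigits=None)
    score = sri_binary if sri_mode == "binary" else sri_probabilistic
    summary["sri"] = [
        score(diary_to_grid(diaries[pid], epoch_min=epoch_min)).value
        for pid in summary["participant_id"]
    ]
    return summary


def compute_ages(
    betas_path,
    probes_path,
    clock_path,
    cellref_path=None,
    bmiq: bool = True,
    cell_correct: bool = True,
) -> pd.Series:
    """Beta TSV -> per-sample epigenetic ages through the clock chain."""
    betas = read_beta_tsv(betas_path)
    clock = read_clock_csv(clock_path)
    if bmiq:
        ann = read_probe_annotation(probes_path)
        betas = bmiq_normalize(betas, ann, BmiqParams(allow_passthrough=True))
    if cell_correct:
        if cellref_path is None:
            raise ValidationError("cell correction requested without a cell reference")
        ref = CellReference.from_frame(pd.read_csv(cellref_path, sep="\t", index_col=0))
        props = estimate_cell_proportions(betas, ref)
        betas = celltype_correct(betas, props)
    return clock_age(betas, clock)


def build_report(cohort: pd.DataFrame, eval_at: float = 0.0, seed: int | None = None,
                 input_hashes: dict[str, str] | None = None) -> dict:
    """Cohort table -> validated report dict (grouping, ANOVA, ANCOVA blocks)."""
    df = cohort.reset_index(drop=True)
    idx = df["participant_id"]
    ad1 = pd.Series(age_difference(df["epi_t1"], df["chron_t1"]), index=idx.index)
    ad2 = pd.Series(age_difference(df["epi_t2"], df["chron_t2"]), index=idx.index)
    change = ad2 - ad1

    duration = classify_duration(df["tst"])
    regularity, sri_median = classify_regularity(df["sri"])
    group = cross_groups(duration, regularity)

    participants = [
        {
            "participant_id": str(idx[i]),
            "tst": float(df["tst"][i]),
            "sri": float(df["sri"][i]),
            "duration_class": duration[i],
            "regularity_class": regularity[i],
            "group": group[i],
            "age_diff_t1": float(ad1[i]),
            "age_diff_t2": float(ad2[i]),
            "age_diff_change": float(change[i]),
        }
        for i in df.index
    ]

    desc = {
        "epi_age_t1": descriptives(df["epi_t1"]),
        "epi_age_t2": descriptives(df["epi_t2"]),
        "chron_age_t1": descriptives(df["chron_t1"]),
        "age_diff_t1": descriptives(ad1),
        "age_diff_t2": descriptives(ad2),
        "tst": descriptives(df["tst"]),
        "sri": descriptives(df["sri"]),
    }

    def anova_block(labels):
        r = OneWayANOVA(ad1, labels).fit()
        return {
            "fvalue": r.fvalue,
            "df1": r.df[0],
            "df2": r.df[1],
            "pvalue": r.pvalue,
            "group_means": r.group_means,
        }

    anova = {
        "three_group": anova_block(group),
        "duration": anova_block(duration),
        "regularity": anova_block(regularity),
    }

    def ancova_block(labels, contrasts):
        res = SleepAgingANCOVA(change, ad1, labels).fit(eval_at=eval_at)
        ci = res.conf_int()
        return {
            "outcome": "age_diff_change",
            "covariate": "age_diff_t1",
            "eval_at": res.eval_at,
            "slope": res.slope,
            "slope_se": res.slope_se,
            "fvalue": res.f_group,
            "df1": res.df_group[0],
            "df2": res.df_group[1],
            "pvalue": res.p_group,
            "mse": res.mse,
            "adjusted_means": {
                g: {
                    "estimate": float(res.adjusted_means[g]),
                    "se": float(res.se[g]),
                    "lower": float(ci.loc[g, "lower"]),
                    "upper": float(ci.loc[g, "upper"]),
                    "n": int(res.group_sizes[g]),
                }
                for g in res.group_names
            },
            "contrasts": [
                {"groups": [g1, g2], **{k: v for k, v in res.contrast(g1, g2).items()}}
                for g1, g2 in contrasts
                if g1 in res.group_names and g2 in res.group_names
            ],
        }

    ancova = {
        "three_group": ancova_block(group, [("Poor", "Good"), ("Poor", "Mixed"), ("Mixed", "Good")]),
        "duration": ancova_block(duration, [("Shorter", "Longer")]),
        "regularity": ancova_block(regularity, [("Less", "More")]),
    }

    payload = {
        "report_version": REPORT_VERSION,
        "package_version": __version__,
        "seed": seed,
        "input_hashes": input_hashes or {},
        "sri_median": sri_median,
        "participants": participants,
        "descriptives": desc,
        "anova_t1": anova,
        "ancova": ancova,
    }
    validate_report(payload)
    return payload


def run_full(config: RunConfig) -> dict:
    """Run every configured stage, write outputs under out_dir, return the report."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)

    hashes = {}
    for name in ("cohort", "diaries", "betas_t1", "betas_t2", "probes", "clock", "cellref", "ages"):
        p = getattr(config, name)
        if p is not None:
            hashes[name] = _hash_file(p)
            log.info("input %s: %s sha256/16=%s", name, p, hashes[name])

    cache_file = out / ".cache.json"
    cache_key = hashlib.sha256(
        json.dumps({**hashes, "config": {k: v for k, v in asdict(config).items() if k not in ("force", "log_level")}},
                   sort_keys=True).encode()
    ).hexdigest()
    report_path = out / "report.json"
    if not config.force and cache_file.exists() and report_path.exists():
        try:
            if json.loads(cache_file.read_text()).get("key") == cache_key:
                log.info("inputs unchanged; reusing cached report (--force to rerun)")
                return json.loads(report_path.read_text())
        except (json.JSONDecodeError, OSError):
            pass

    stage = "assemble-cohort"
    try:
        if config.cohort is not None:
            cohort = load_cohort_csv(config.cohort)
        else:
            stage = "sleep-summaries"
            summary = compute_sleep_summaries(
                config.diaries, epoch_min=config.epoch_min, sri_mode=config.sri_mode
            )
            summary.to_csv(out / "participants.csv", index=False)
            log.info("sleep summaries for %d participants", len(summary))

            stage = "ages"
            ages = pd.read_csv(config.ages, dtype={"participant_id": str})
            if config.betas_t1 is not None:
                epi1 = compute_ages(
                    config.betas_t1, config.probes, config.clock, config.cellref,
                    bmiq=config.bmiq, cell_correct=config.cell_correct,
                )
                epi2 = compute_ages(
                    config.betas_t2, config.probes, config.clock, config.cellref,
                    bmiq=config.bmiq, cell_correct=config.cell_correct,
                )
                epi1.index = [s.rsplit("_", 1)[0] for s in epi1.index]
                epi2.index = [s.rsplit("_", 1)[0] for s in epi2.index]
                pd.DataFrame({"epi_t1": epi1, "epi_t2": epi2}).to_csv(out / "ages.csv")
                ages = ages.drop(columns=["epi_t1", "epi_t2"], errors="ignore")
                ages["epi_t1"] = epi1.loc[ages["participant_id"]].to_numpy()
                ages["epi_t2"] = epi2.loc[ages["participant_id"]].to_numpy()

            stage = "assemble-cohort"
            cohort = summary.merge(ages, on="participant_id")[
                ["participant_id", "chron_t1", "chron_t2", "epi_t1", "epi_t2"]
            ].assign(tst=summary["mean_tst_h"], sri=summary["sri"])
            cohort.to_csv(out / "cohort.csv", index=False)

        stage = "inference"
        report = build_report(cohort, eval_at=config.eval_at, seed=config.seed,
                              input_hashes=hashes)
    except SomnoclockError as e:
        log.error("stage %s failed: %s (partial outputs kept in %s)", stage, e, out)
        raise SomnoclockError(f"stage {stage!r} failed: {e}") from e
    finally:
        log.removeHandler(fh)
        fh.close()

    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    cache_file.write_text(json.dumps({"key": cache_key}))

    # 2-dp human-readable companion table
    rows = []
    for name, block in report["ancova"].items():
        for g, am in block["adjusted_means"].items():
            rows.append(
                {
                    "model": name,
                    "group": g,
                    "adjusted_mean": round(am["estimate"], 2),
                    "ci_lower": round(am["lower"], 2),
                    "ci_upper": round(am["upper"], 2),
                }
            )
    pd.DataFrame(rows).to_csv(out / "adjusted_means.csv", index=False)
    return report
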