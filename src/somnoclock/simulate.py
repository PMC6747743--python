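"""Synthetic diaries and paired-timepoint methylation data with known truth.

Every pipeline stage can be exercised and verified without external data:
the diary generator emulates a college-semester sleep log (nightly bed/rise
times with night-to-night jitter, untimed naps and awakenings, missing
days), and the methylation generator builds 450K-style beta matrices whose
clock probes carry an exact linear age signal, whose cell-reference probes
carry mixture-of-cell-type structure, and whose second timepoint applies a
group-dependent aging drift. The generating clock and all latent quantities
are returned in a truth bundle.

Randomness: one child RNG stream per participant/sample is derived from the
master seed via ``np.random.SeedSequence([seed, index])``, so adding or
reordering participants leaves the other streams untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .clock.deconvolution import CellReference
from .clock.model import BetaMatrix, ClockModel, ProbeAnnotation, age_forward
from .diary import Diary, DiaryDay
from .errors import NoDataError, ValidationError

__all__ = [
    "DiarySimConfig",
    "MethylSimConfig",
    "TruthBundle",
    "simulate_diaries",
    "simulate_methylation",
    "simulate_type_shift_batch",
    "make_paper_like_cohort",
]


def _rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


# --------------------------------------------------------------------------
# diaries


@dataclass(frozen=True)
class DiarySimConfig:
    """Conditions for the diary generator.

    Defaults emulate a first-semester college cohort tracked for 9 weeks
    (63 nights): bedtime around 00:45 with ~1 h night-to-night jitter,
    ~8 h in bed, occasional naps and brief night awakenings, and a small
    missing-diary rate.
    """

    n_participants: int = 12
    n_days: int = 63
    bedtime_mean: float = 24.75  # noon-to-noon axis (00:45)
    bedtime_sd: float = 1.0  # night-to-night jitter, hours
    time_in_bed_mean: float = 8.0
    time_in_bed_sd: float = 0.75
    nap_prob: float = 0.3
    nap_min_mean: float = 45.0
    nap_min_sd: float = 20.0
    awakening_rate: float = 1.0  # Poisson mean count per night
    awakening_min_mean: float = 10.0  # per awakening
    missing_prob: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if min(self.bedtime_sd, self.time_in_bed_sd, self.nap_min_sd) < 0:
            raise ValidationError("standard deviations must be >= 0")
        for p in (self.nap_prob, self.missing_prob):
            if not (0.0 <= p <= 1.0):
                raise ValidationError("probabilities must lie in [0, 1]")
        if not (0.0 < self.time_in_bed_mean < 24.0):
            raise ValidationError("time in bed must lie in (0, 24) hours")
        if self.missing_prob >= 1.0:
            raise NoDataError("missing_prob = 1 leaves no observed days")


def simulate_diaries(config: DiarySimConfig) -> tuple[dict[str, Diary], pd.DataFrame]:
    """Generate diaries and a per-day truth table.

    Truth columns: true sleep minutes (the exact TST implied by the sampled
    night plus nap), and the nap's placement inside the wake period — a
    quantity the diary format deliberately discards.
    """
    config.validate()
    diaries: dict[str, Diary] = {}
    truth_rows = []
    for i in range(config.n_participants):
        pid = f"P{i + 1:03d}"
        rng = _rng(config.seed, i)
        days = []
        for d in range(config.n_days):
            if rng.random() < config.missing_prob:
                days.append(
                    DiaryDay(pid, d, float("nan"), float("nan"), missing=True)
                )
                continue
            bed = float(np.clip(rng.normal(config.bedtime_mean, config.bedtime_sd), 21.0, 29.0))
            tib = float(
                np.clip(
                    rng.normal(config.time_in_bed_mean, config.time_in_bed_sd),
                    3.0,
                    min(12.0, 35.5 - bed),
                )
            )
            wake = bed + tib
            n_awk = int(rng.poisson(config.awakening_rate))
            awake_min = float(
                min(
                    rng.gamma(n_awk, config.awakening_min_mean) if n_awk else 0.0,
                    0.4 * 60.0 * tib,
                )
            )
            has_nap = rng.random() < config.nap_prob
            wake_period_min = 60.0 * (24.0 - tib)
            nap_min = 0.0
            nap_start = float("nan")
            if has_nap:
                nap_min = float(
                    np.clip(
                        rng.normal(config.nap_min_mean, config.nap_min_sd),
                        10.0,
                        0.5 * wake_period_min,
                    )
                )
                # afternoon placement: uniform inside the post-rise wake span
                span = 36.0 - wake - nap_min / 60.0
                nap_start = (
                    wake + rng.uniform(0.0, span) if span > 0 else float("nan")
                )
            day = DiaryDay(
                pid, d, bed, wake, n_awk, awake_min, int(has_nap), nap_min
            ).validate(strict=True)
            days.append(day)
            truth_rows.append(
                {
                    "participant_id": pid,
                    "day_index": d,
                    "true_sleep_min": 60.0 * tib - awake_min + nap_min,
                    "nap_start_h": nap_start,
                    "nap_min": nap_min,
                }
            )
        diaries[pid] = Diary(pid, days)
    return diaries, pd.DataFrame(truth_rows)


# --------------------------------------------------------------------------
# methylation


@dataclass(frozen=True)
class MethylSimConfig:
    """Conditions for the paired-timepoint methylation generator.

    Clock probes are built so the generating clock is *exact* at zero noise:
    beta_is = base_i + c_s * w_i with c_s chosen so the weighted sum equals
    the transformed true age. The second draw shifts true age by the study
    interval plus a group-dependent drift (years).
    """

    n_samples: int = 12
    n_clock_probes: int = 30
    n_background_probes: int = 100
    n_cell_probes: int = 120
    type2_fraction: float = 0.5
    weight_scale: float = 0.4
    chron_age_low: float = 18.2
    chron_age_high: float = 19.8
    baseline_accel_mean: float = 2.0  # true age-difference at T1, years
    baseline_accel_sd: float = 3.3
    true_ages_t1: tuple[float, ...] | None = None  # overrides the baseline draw
    group_labels: tuple[str, ...] | None = None  # default 1/3 Good, Mixed, Poor
    drift: tuple[tuple[str, float], ...] = (("Good", -1.5), ("Mixed", 0.0), ("Poor", 3.0))
    interval_years: float = 63.0 / 365.25
    n_cell_types: int = 3
    dirichlet_alpha: float = 5.0
    cell_effect_scale: float = 0.0  # >0 adds composition confounding to clock probes
    noise_sd: float = 0.02
    adult_age: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_clock_probes, self.n_cell_probes, self.n_cell_types, self.n_samples) < 1:
            raise ValidationError("probe/sample/cell-type counts must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (0.0 <= self.type2_fraction <= 1.0):
            raise ValidationError("type2_fraction must lie in [0, 1]")
        if self.group_labels is not None and len(self.group_labels) != self.n_samples:
            raise ValidationError("group_labels length must equal n_samples")
        if self.true_ages_t1 is not None and len(self.true_ages_t1) != self.n_samples:
            raise ValidationError("true_ages_t1 length must equal n_samples")
        if not all(np.isfinite(v) for _, v in self.drift):
            raise ValidationError("drift values must be finite")


@dataclass
class TruthBundle:
    """Latent quantities behind one simulated dataset."""

    chron_t1: pd.Series
    chron_t2: pd.Series
    ages_t1: pd.Series  # true epigenetic ages the clock must recover
    ages_t2: pd.Series
    cell_props_t1: pd.DataFrame
    cell_props_t2: pd.DataFrame
    clock: ClockModel
    group_labels: pd.Series
    config: MethylSimConfig


def _default_groups(n: int) -> list[str]:
    base = ["Good", "Mixed", "Poor"]
    return [base[(3 * i) // n] for i in range(n)]


def simulate_methylation(
    config: MethylSimConfig,
) -> tuple[BetaMatrix, BetaMatrix, ProbeAnnotation, CellReference, TruthBundle]:
    config.validate()
    rng0 = _rng(config.seed, 0)
    n = config.n_samples
    pids = [f"S{i + 1:03d}" for i in range(n)]
    groups = list(config.group_labels or _default_groups(n))
    drift = dict(config.drift)
    missing = sorted(set(groups) - set(drift))
    if missing:
        raise ValidationError(f"groups without a drift entry: {missing}")

    chron1 = rng0.uniform(config.chron_age_low, config.chron_age_high, n)
    if config.true_ages_t1 is not None:
        true1 = np.asarray(config.true_ages_t1, dtype=float)
    else:
        true1 = chron1 + rng0.normal(
            config.baseline_accel_mean, config.baseline_accel_sd, n
        )
    chron2 = chron1 + config.interval_years
    true2 = true1 + config.interval_years + np.array([drift[g] for g in groups])

    # generating clock: base betas + weights; c_s solves the linear system
    pc = [f"cg_clk_{i:05d}" for i in range(config.n_clock_probes)]
    base = rng0.uniform(0.3, 0.7, config.n_clock_probes)
    w = config.weight_scale * rng0.choice([-1.0, 1.0], config.n_clock_probes) * rng0.uniform(
        0.5, 1.0, config.n_clock_probes
    )
    m1 = age_forward(true1, config.adult_age)
    m2 = age_forward(true2, config.adult_age)
    m_all = np.concatenate([m1, m2])
    intercept = float(m_all.mean() - w @ base)
    for _ in range(20):
        c = (m_all - (intercept + w @ base)) / (w @ w)
        dev = np.abs(np.outer(w, c)).max()
        if base.min() - dev > 0.02 and base.max() + dev < 0.98:
            break
        warnings.warn("weight scale saturates clock betas; rescaling weights up")
        w = w * 1.5
        intercept = float(m_all.mean() - w @ base)
    clock = ClockModel(intercept=intercept, weights=dict(zip(pc, w)), adult_age=config.adult_age)

    # cell reference: bimodal probe profiles per cell type
    cellp = [f"cg_cell_{i:05d}" for i in range(config.n_cell_probes)]
    ctypes = [f"CT{k + 1}" for k in range(config.n_cell_types)]
    R = np.where(
        rng0.random((config.n_cell_probes, config.n_cell_types)) < 0.5,
        rng0.beta(2.0, 18.0, (config.n_cell_probes, config.n_cell_types)),
        rng0.beta(18.0, 2.0, (config.n_cell_probes, config.n_cell_types)),
    )
    cellref = CellReference(cellp, ctypes, R)

    bgp = [f"cg_bg_{i:05d}" for i in range(config.n_background_probes)]
    bg_base = rng0.beta(0.8, 0.8, config.n_background_probes) * 0.9 + 0.05

    probes = pc + cellp + bgp
    ann = ProbeAnnotation(
        {
            p: ("II" if u < config.type2_fraction else "I")
            for p, u in zip(probes, rng0.random(len(probes)))
        }
    )
    gamma = config.cell_effect_scale * rng0.normal(
        0.0, 1.0, (config.n_clock_probes, config.n_cell_types)
    )

    alpha = np.full(config.n_cell_types, config.dirichlet_alpha)

    def one_timepoint(m_vec, tag, stream_offset):
        mats = np.empty((len(probes), n))
        props = np.empty((n, config.n_cell_types))
        for j in range(n):
            r = _rng(config.seed, 1000 + stream_offset + j)
            pi = r.dirichlet(alpha)
            props[j] = pi
            c_s = (m_vec[j] - (intercept + w @ base)) / (w @ w)
            clk = base + c_s * w + gamma @ (pi - alpha / alpha.sum())
            cell = R @ pi
            col = np.concatenate([clk, cell, bg_base])
            if config.noise_sd > 0:
                col = col + r.normal(0.0, config.noise_sd, col.size)
            mats[:, j] = np.clip(col, 1e-6, 1 - 1e-6)
        ids = [f"{p}_{tag}" for p in pids]
        return (
            BetaMatrix(probes, ids, mats),
            pd.DataFrame(props, index=ids, columns=ctypes),
        )

    betas1, props1 = one_timepoint(m1, "t1", 0)
    betas2, props2 = one_timepoint(m2, "t2", n)

    truth = TruthBundle(
        chron_t1=pd.Series(chron1, index=betas1.sample_ids),
        chron_t2=pd.Series(chron2, index=betas2.sample_ids),
        ages_t1=pd.Series(true1, index=betas1.sample_ids),
        ages_t2=pd.Series(true2, index=betas2.sample_ids),
        cell_props_t1=props1,
        cell_props_t2=props2,
        clock=clock,
        group_labels=pd.Series(groups, index=pids),
        config=config,
    )
    return betas1, betas2, ann, cellref, truth


def simulate_type_shift_batch(
    n_type1: int, n_type2: int, shift: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw type-I and type-II betas from one 3-state mixture, compressing
    the type-II values toward 0.5 by ``shift`` — the chemistry artefact BMIQ
    removes."""
    rng = np.random.default_rng(seed)

    def draw(size):
        k = rng.integers(0, 3, size)
        a = np.array([2.0, 5.0, 20.0])[k]
        b = np.array([20.0, 5.0, 2.0])[k]
        return rng.beta(a, b)

    t1 = draw(n_type1)
    t2 = 0.5 + (draw(n_type2) - 0.5) * (1.0 - shift)
    return t1, t2


# --------------------------------------------------------------------------
# cohort-shaped end-to-end fixture


def make_paper_like_cohort(
    seed: int = 0, n_days: int = 63, epoch_min: int = 5
) -> pd.DataFrame:
    """Simulate a 12-participant two-timepoint cohort table end to end.

    Four sleep phenotypes (long+regular, long+irregular, short+regular,
    short+irregular; 4/2/2/4 participants) are run through the real diary,
    TST and probabilistic-SRI code; epigenetic ages then follow a
    group-dependent drift (Good decline, Mixed flat, Poor +3 y) on top of a
    dispersed baseline age-difference. Under the default conditions the
    half/median splits recover the design, giving 4/4/4 crossed groups.
    """
    from .diary import average_tst
    from .sri import diary_to_grid, sri_probabilistic

    phenotypes = (
        [(8.4, 0.25)] * 4 + [(8.2, 2.0)] * 2 + [(6.2, 0.25)] * 2 + [(6.0, 2.0)] * 4
    )
    rows = []
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 99]))
    for i, (tib, jitter) in enumerate(phenotypes):
        cfg = DiarySimConfig(
            n_participants=1,
            n_days=n_days,
            bedtime_mean=24.5,
            bedtime_sd=jitter,
            time_in_bed_mean=tib,
            time_in_bed_sd=0.3,
            missing_prob=0.03,
            seed=int(np.random.SeedSequence([int(seed), i]).generate_state(1)[0] % (2**31)),
        )
        diaries, _ = simulate_diaries(cfg)
        diary = next(iter(diaries.values()))
        tst = average_tst(diary)
        sri = sri_probabilistic(diary_to_grid(diary, epoch_min=epoch_min)).value
        rows.append({"participant_id": f"P{i + 1:03d}", "tst": tst, "sri": sri})
    df = pd.DataFrame(rows)

    chron1 = rng.uniform(18.2, 19.8, len(df))
    accel = rng.normal(2.0, 3.3, len(df))
    drift = np.array([-1.5] * 4 + [0.0] * 4 + [3.0] * 4)
    interval = n_days / 365.25
    df["chron_t1"] = chron1
    df["chron_t2"] = chron1 + interval
    df["epi_t1"] = chron1 + accel
    df["epi_t2"] = df["chron_t2"] + accel + drift + rng.normal(0.0, 0.8, len(df))
    return df[["participant_id", "chron_t1", "chron_t2", "epi_t1", "epi_t2", "tst", "sri"]]
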