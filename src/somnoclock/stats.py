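"""Age-difference inference: grouping, descriptives, ANOVA and ANCOVA.

The scientific question is whether sleep duration and regularity over an
interval predict the change in *age-difference* (epigenetic minus
chronological age, positive = epigenetically older). Participants are split
at the within-cohort median/half on mean total sleep time (Longer/Shorter)
and on the Sleep Regularity Index (More/Less Regulated); crossing the splits
gives Good (Longer AND More), Poor (Shorter AND Less) and Mixed (exactly one)
sleep groups.

Inference is a common-slope analysis of covariance fitted from first
principles (within-group least squares): outcome = change in age-difference
(T2 - T1), covariate = Time-1 age-difference, factor = sleep group. Adjusted
("marginal") group means are reported at a stated covariate value — default
0, i.e. the model-predicted change for a participant whose epigenetic age
matched chronology at baseline:

    adj_mean_g(x0) = ybar_g + b (x0 - xbar_g)
    SE_g = sqrt(MSE (1/n_g + (xbar_g - x0)^2 / Sxx_within))

with t-based 95% CIs at n - k - 1 residual df. The group effect is the
partial F against the covariate-only model. Pairwise contrasts
(ybar_1 - ybar_2) - b (xbar_1 - xbar_2) are independent of the evaluation
point.

Model classes follow the Model.fit() -> Results convention: construct from
arrays or a DataFrame, fit, then read estimates, SEs, CIs and a summary()
table off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import NoDataError, UnsplittableTieError, ValidationError

__all__ = [
    "age_difference",
    "classify_duration",
    "classify_regularity",
    "cross_groups",
    "descriptives",
    "pearson_r",
    "OneWayANOVA",
    "OneWayANOVAResults",
    "SleepAgingANCOVA",
    "AncovaResults",
    "load_cohort_csv",
]

COHORT_COLUMNS = ["participant_id", "chron_t1", "chron_t2", "epi_t1", "epi_t2", "tst", "sri"]


def age_difference(epi, chron):
    """Epigenetic minus chronological age (positive = accelerated aging)."""
    epi = np.asarray(epi, dtype=float)
    chron = np.asarray(chron, dtype=float)
    if not (np.isfinite(epi).all() and np.isfinite(chron).all()):
        raise ValidationError("ages must be finite")
    out = epi - chron
    return float(out) if out.ndim == 0 else out


def classify_duration(tst: pd.Series) -> pd.Series:
    """Split participants into Longer/Shorter sleepers at the TST half.

    The top half by mean TST is 'Longer', the bottom half 'Shorter'. An odd
    count or a tie straddling the boundary is an error: such a cohort has no
    well-defined half split.
    """
    tst = pd.Series(tst, dtype=float)
    n = len(tst)
    if n < 2 or n % 2:
        raise ValidationError(f"duration split needs an even count >= 2, got {n}")
    v = np.sort(tst.to_numpy())
    if v[n // 2 - 1] == v[n // 2]:
        raise UnsplittableTieError(
            f"TST value {v[n // 2]} ties across the half-split boundary"
        )
    cut = 0.5 * (v[n // 2 - 1] + v[n // 2])
    return pd.Series(
        np.where(tst.to_numpy() > cut, "Longer", "Shorter"), index=tst.index
    )


def classify_regularity(sri: pd.Series) -> tuple[pd.Series, float]:
    """Median split on SRI: strictly above -> More Regulated, below -> Less.

    Returns (labels, median). The median is the midpoint of the central
    order statistics; a value landing exactly on the boundary median is an
    unsplittable tie.
    """
    sri = pd.Series(sri, dtype=float)
    n = len(sri)
    if n < 2:
        raise ValidationError("regularity split needs at least 2 participants")
    med = float(np.median(sri.to_numpy()))
    if (sri == med).any():
        raise UnsplittableTieError(f"SRI value equal to the median {med}")
    return (
        pd.Series(np.where(sri.to_numpy() > med, "More", "Less"), index=sri.index),
        med,
    )


def cross_groups(duration: pd.Series, regularity: pd.Series) -> pd.Series:
    """Good (Longer & More), Poor (Shorter & Less), Mixed (exactly one)."""
    if not duration.index.equals(regularity.index):
        raise ValidationError("duration and regularity labels index different participants")
    good = (duration == "Longer") & (regularity == "More")
    poor = (duration == "Shorter") & (regularity == "Less")
    return pd.Series(
        np.where(good, "Good", np.where(poor, "Poor", "Mixed")), index=duration.index
    )


def descriptives(values) -> dict[str, float]:
    """mean, sd (n-1), min, max, median."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise NoDataError("descriptives of an empty vector")
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else float("nan"),
        "min": float(v.min()),
        "max": float(v.max()),
        "median": float(np.median(v)),
    }


def pearson_r(x, y) -> float:
    """Product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("pearson_r needs matched vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("pearson_r undefined for a zero-variance vector")
    return float(np.corrcoef(x, y)[0, 1])


# --------------------------------------------------------------------------
# one-way ANOVA


class OneWayANOVA:
    """Between/within decomposition of a single factor."""

    def __init__(self, endog, groups):
        self.endog = np.asarray(endog, dtype=float)
        self.groups = np.asarray(groups)
        if self.endog.size != self.groups.size:
            raise ValidationError("endog and groups differ in length")
        self.group_names = list(dict.fromkeys(self.groups))
        if len(self.group_names) < 2:
            raise ValidationError("need at least two groups")
        if self.endog.size <= len(self.group_names):
            raise ValidationError("need more observations than groups")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str, group: str) -> "OneWayANOVA":
        return cls(df[outcome], df[group])

    def fit(self) -> "OneWayANOVAResults":
        y, g = self.endog, self.groups
        grand = y.mean()
        means = {k: float(y[g == k].mean()) for k in self.group_names}
        ns = {k: int((g == k).sum()) for k in self.group_names}
        ssb = sum(ns[k] * (means[k] - grand) ** 2 for k in self.group_names)
        ssw = sum(((y[g == k] - means[k]) ** 2).sum() for k in self.group_names)
        df1 = len(self.group_names) - 1
        df2 = y.size - len(self.group_names)
        if ssw == 0.0:
            f = float("inf")
            p = 0.0
        else:
            f = (ssb / df1) / (ssw / df2)
            p = float(sps.f.sf(f, df1, df2))
        return OneWayANOVAResults(
            fvalue=float(f), df=(df1, df2), pvalue=p,
            ss_between=float(ssb), ss_within=float(ssw),
            group_means=means, group_sizes=ns,
        )


@dataclass
class OneWayANOVAResults:
    fvalue: float
    df: tuple[int, int]
    pvalue: float
    ss_between: float
    ss_within: float
    group_means: dict[str, float]
    group_sizes: dict[str, int]

    def summary(self) -> str:
        lines = [
            "One-way ANOVA",
            f"  F({self.df[0]},{self.df[1]}) = {self.fvalue:.2f}, p = {self.pvalue:.2f}",
        ]
        for g, m in self.group_means.items():
            lines.append(f"  {g:<8} n={self.group_sizes[g]:<3} mean={m:.2f}")
        return "\n".join(lines)


# --------------------------------------------------------------------------
# common-slope ANCOVA


class SleepAgingANCOVA:
    """Common-slope ANCOVA: outcome ~ group + covariate (no interaction)."""

    def __init__(self, endog, covariate, groups):
        self.endog = np.asarray(endog, dtype=float)
        self.covariate = np.asarray(covariate, dtype=float)
        self.groups = np.asarray(groups)
        n = self.endog.size
        if not (self.covariate.size == n == self.groups.size):
            raise ValidationError("endog, covariate and groups differ in length")
        self.group_names = list(dict.fromkeys(self.groups))
        k = len(self.group_names)
        if k < 2:
            raise ValidationError("need at least two groups")
        if n <= k + 1:
            raise ValidationError("need n > n_groups + 1 observations")
        sxx = sum(
            ((self.covariate[self.groups == g] - self.covariate[self.groups == g].mean()) ** 2).sum()
            for g in self.group_names
        )
        if sxx <= 0:
            raise ValidationError(
                "covariate has no within-group variance; the design is singular"
            )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, outcome: str, covariate: str, group: str
    ) -> "SleepAgingANCOVA":
        return cls(df[outcome], df[covariate], df[group])

    def fit(self, eval_at: float = 0.0, alpha: float = 0.05) -> "AncovaResults":
        if not np.isfinite(eval_at):
            raise ValidationError("eval_at must be finite")
        y, x, g = self.endog, self.covariate, self.groups
        names = self.group_names
        n, k = y.size, len(names)

        ybar = {c: float(y[g == c].mean()) for c in names}
        xbar = {c: float(x[g == c].mean()) for c in names}
        ns = {c: int((g == c).sum()) for c in names}
        sxx = sum(((x[g == c] - xbar[c]) ** 2).sum() for c in names)
        sxy = sum(
            ((x[g == c] - xbar[c]) * (y[g == c] - ybar[c])).sum() for c in names
        )
        slope = float(sxy / sxx)

        df_resid = n - k - 1
        sse = float(
            sum(
                (((y[g == c] - ybar[c]) - slope * (x[g == c] - xbar[c])) ** 2).sum()
                for c in names
            )
        )
        mse = sse / df_resid

        # reduced model: covariate only (group effect tested as partial F)
        xc, yc = x - x.mean(), y - y.mean()
        b_red = float(xc @ yc / (xc @ xc))
        sse_red = float(((yc - b_red * xc) ** 2).sum())
        f_group = ((sse_red - sse) / (k - 1)) / mse if mse > 0 else float("inf")
        p_group = float(sps.f.sf(f_group, k - 1, df_resid))

        tcrit = float(sps.t.ppf(1 - alpha / 2, df_resid))
        adj = {c: ybar[c] + slope * (eval_at - xbar[c]) for c in names}
        se = {
            c: float(np.sqrt(mse * (1.0 / ns[c] + (xbar[c] - eval_at) ** 2 / sxx)))
            for c in names
        }
        slope_se = float(np.sqrt(mse / sxx))

        return AncovaResults(
            group_names=names,
            slope=slope,
            slope_se=slope_se,
            eval_at=float(eval_at),
            adjusted_means=pd.Series(adj),
            se=pd.Series(se),
            t_crit=tcrit,
            f_group=float(f_group),
            df_group=(k - 1, df_resid),
            p_group=p_group,
            mse=mse,
            sse=sse,
            df_resid=df_resid,
            group_means=pd.Series(ybar),
            covariate_means=pd.Series(xbar),
            group_sizes=pd.Series(ns),
            sxx_within=float(sxx),
            alpha=alpha,
        )


@dataclass
class AncovaResults:
    """Common-slope ANCOVA estimates, uncertainties and diagnostics."""

    group_names: list[str]
    slope: float
    slope_se: float
    eval_at: float
    adjusted_means: pd.Series
    se: pd.Series
    t_crit: float
    f_group: float
    df_group: tuple[int, int]
    p_group: float
    mse: float
    sse: float
    df_resid: int
    group_means: pd.Series
    covariate_means: pd.Series
    group_sizes: pd.Series
    sxx_within: float
    alpha: float = 0.05

    def conf_int(self) -> pd.DataFrame:
        lo = self.adjusted_means - self.t_crit * self.se
        hi = self.adjusted_means + self.t_crit * self.se
        return pd.DataFrame({"lower": lo, "upper": hi})

    def contrast(self, g1: str, g2: str) -> dict[str, float]:
        """Adjusted difference g1 - g2 (independent of the evaluation point)."""
        for g in (g1, g2):
            if g not in self.group_names:
                raise ValidationError(f"unknown group {g!r}")
        dy = self.group_means[g1] - self.group_means[g2]
        dx = self.covariate_means[g1] - self.covariate_means[g2]
        est = float(dy - self.slope * dx)
        se = float(
            np.sqrt(
                self.mse
                * (
                    1.0 / self.group_sizes[g1]
                    + 1.0 / self.group_sizes[g2]
                    + dx**2 / self.sxx_within
                )
            )
        )
        return {
            "estimate": est,
            "se": se,
            "lower": est - self.t_crit * se,
            "upper": est + self.t_crit * se,
            "df": self.df_resid,
        }

    def summary(self) -> str:
        ci = self.conf_int()
        pct = int(round((1 - self.alpha) * 100))
        lines = [
            "Common-slope ANCOVA (outcome ~ group + covariate)",
            f"  slope b = {self.slope:.3f} (SE {self.slope_se:.3f}); "
            f"residual MSE = {self.mse:.3f} on {self.df_resid} df",
            f"  group partial F({self.df_group[0]},{self.df_group[1]}) = "
            f"{self.f_group:.2f}, p = {self.p_group:.3f}",
            f"  adjusted means at covariate = {self.eval_at:g} [{pct}% CI]:",
        ]
        for g in self.group_names:
            lines.append(
                f"    {g:<8} {self.adjusted_means[g]:7.2f} "
                f"[{ci.loc[g, 'lower']:7.2f}; {ci.loc[g, 'upper']:7.2f}]  "
                f"(n={self.group_sizes[g]})"
            )
        return "\n".join(lines)


def load_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort table; requires the standard column set."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort file lacks columns: {missing}")
    if df.empty:
        raise NoDataError(f"cohort file {path} contains no rows")
    if (df[["chron_t1", "chron_t2", "epi_t1", "epi_t2"]] <= 0).any().any():
        raise ValidationError("ages must be positive")
    return df
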