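"""Pre/post comparison stage: descriptives, marginal models, effect sizes.

The comparison between baseline and follow-up uses generalized estimating
equations (GEE): a marginal regression of each outcome on a time indicator
with an exchangeable working correlation and robust (sandwich) variance,
so the within-participant dependence of the two repeated measures is
respected without modelling it parametrically.  All enrolled participants
contribute every row they have (intention-to-treat); dropouts contribute
baseline only.

Model family is declared per variable in the analysis plan:

* ``linear`` — Gaussian GEE; the time effect is the marginal mean change.
  On complete balanced data it equals the paired mean difference exactly.
* ``log-linear`` — Gaussian GEE on the log-transformed outcome, for
  right-skewed positive variables; the time effect is a log-ratio.
* ``ordinal-logistic`` — ordinal GEE (global odds ratio association) on
  the declared ordered levels; the time effect is a cumulative log-odds.
* ``binary-logistic`` — binomial GEE; the time effect is a log-odds ratio.

The standardized effect size (SES) quantifies the magnitude of change in
baseline standard-deviation units; by default

    SES = mean(post - pre over complete pairs) / sd(pre over those pairs)

with a seeded nonparametric bootstrap over participants for its 95%
confidence interval, and Cohen-style banding: |SES| < 0.5 small,
0.5 <= |SES| <= 0.8 moderate, > 0.8 large.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.genmod.cov_struct import Exchangeable, Independence
from statsmodels.genmod.generalized_estimating_equations import GEE, OrdinalGEE

from .cohort import CohortTable, SCORE_COLUMNS, VariableSpec

__all__ = [
    "ModelFamily",
    "ComparisonResult",
    "DegenerateFitError",
    "InsufficientDataError",
    "descriptive_summary",
    "fit_prepost",
    "standardized_effect_size",
    "classify_effect_size",
    "analyze_cohort",
]

ModelFamily = Literal["linear", "log-linear", "ordinal-logistic", "binary-logistic"]
FAMILIES = ("linear", "log-linear", "ordinal-logistic", "binary-logistic")

# continuous core/score columns usable without an explicit declaration
_IMPLICIT_CONTINUOUS = {
    "age", "hgs", "bmi", "weight_loss_3mo", "tug", "chair_stand",
    "sit_reach", "balance", "gds15", "moca",
} | {c for c in SCORE_COLUMNS if c != "category"}


class DegenerateFitError(ValueError):
    """Raised when an outcome carries no usable variation for its model."""


class InsufficientDataError(ValueError):
    """Raised when too few participants are available for an estimate."""


@dataclass
class ComparisonResult:
    """One variable's pre/post comparison, one row of the results table."""

    variable: str
    family: ModelFamily | None = None
    baseline_summary: dict = field(default_factory=dict)
    followup_summary: dict = field(default_factory=dict)
    estimate: float | None = None       # time effect on the model's scale
    p_value: float | None = None
    effect_size: float | None = None    # standardized, dimensionless
    es_ci: tuple[float, float] | None = None
    es_band: str | None = None
    error: str | None = None            # set when this row failed in a batch

    def __post_init__(self) -> None:
        if self.p_value is not None and not 0 <= self.p_value <= 1:
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


def classify_effect_size(es: float) -> str:
    """Band a standardized effect size by magnitude: small/moderate/large.

    Thresholds: below 0.5 small, 0.5 to 0.8 (inclusive) moderate, above
    0.8 large; the sign is ignored.
    """
    if not (isinstance(es, (int, float)) and math.isfinite(es)):
        raise ValueError(f"effect size must be finite, got {es!r}")
    a = abs(es)
    if a < 0.5:
        return "small"
    if a <= 0.8:
        return "moderate"
    return "large"


def _variable_spec(table: CohortTable, variable: str) -> VariableSpec:
    if variable in table.variables:
        return table.variables[variable]
    if variable in _IMPLICIT_CONTINUOUS:
        return VariableSpec(variable, "continuous")
    if variable not in table.df.columns:
        raise KeyError(f"unknown variable {variable!r}")
    raise KeyError(
        f"variable {variable!r} present but undeclared; add a VariableSpec"
    )


def _numeric_series(table: CohortTable, variable: str) -> pd.Series:
    """The variable as floats; ordinal levels become their integer codes."""
    spec = _variable_spec(table, variable)
    s = table.df[variable]
    if spec.vtype == "ordinal":
        codes = {lev: i for i, lev in enumerate(spec.levels)}
        return s.map(codes).astype("Float64").astype(float)
    return s.astype(float)


def descriptive_summary(table: CohortTable, variable: str) -> dict[int, dict]:
    """Per-timepoint descriptives in the conventional reporting forms.

    Continuous variables get mean, sd, median and the P25-P75 interquartile
    range (linear-interpolation quantiles); ordinal/binary variables get
    per-level counts with percentages of that timepoint's n.
    """
    spec = _variable_spec(table, variable)
    out: dict[int, dict] = {}
    for tp in (0, 1):
        sub = table.df.loc[table.df["timepoint"] == tp, variable].dropna()
        if spec.vtype in ("continuous", "continuous-skewed"):
            x = sub.astype(float)
            out[tp] = {
                "n": int(x.size),
                "mean": float(x.mean()) if x.size else float("nan"),
                "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
                "median": float(x.median()) if x.size else float("nan"),
                "p25": float(x.quantile(0.25)) if x.size else float("nan"),
                "p75": float(x.quantile(0.75)) if x.size else float("nan"),
            }
        else:
            levels = (
                spec.levels if spec.vtype == "ordinal"
                else ("0", "1")
            )
            counts = sub.astype(str).value_counts()
            n = int(sub.size)
            out[tp] = {
                "n": n,
                "levels": {
                    lev: {
                        "n": int(counts.get(lev, 0)),
                        "pct": 100.0 * counts.get(lev, 0) / n if n else float("nan"),
                    }
                    for lev in levels
                },
            }
    return out


def _long_data(table: CohortTable, variable: str) -> pd.DataFrame:
    y = _numeric_series(table, variable)
    d = pd.DataFrame({
        "y": y,
        "time": table.df["timepoint"].astype(int),
        "pid": table.df["participant_id"].astype(str),
    }).dropna(subset=["y"])
    return d.sort_values(["pid", "time"], kind="stable").reset_index(drop=True)


def fit_prepost(
    table: CohortTable, variable: str, family: ModelFamily
) -> ComparisonResult:
    """Fit the marginal time-effect model for one variable.

    Returns a :class:`ComparisonResult` with the time-effect estimate (on
    the model's scale) and its robust two-sided p-value filled in.  The
    significance convention for reporting is 5%, but significance never
    gates output.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    spec = _variable_spec(table, variable)
    d = _long_data(table, variable)
    if d.loc[d["time"] == 0, "pid"].nunique() < 2:
        raise InsufficientDataError(
            f"{variable!r}: need at least 2 participants with baseline data"
        )
    if d["y"].nunique() < 2:
        raise DegenerateFitError(f"{variable!r}: outcome is constant")

    if family == "log-linear":
        if (d["y"] <= 0).any():
            raise ValueError(
                f"{variable!r}: log-linear family requires strictly positive values"
            )
        d = d.assign(y=np.log(d["y"]))
        family_obj = sm.families.Gaussian()
    elif family == "linear":
        family_obj = sm.families.Gaussian()
    elif family == "binary-logistic":
        vals = set(d["y"].unique())
        if not vals <= {0.0, 1.0}:
            raise ValueError(f"{variable!r}: binary family requires 0/1 values")
        cells = d.groupby("time")["y"].agg(["sum", "count"])
        if ((cells["sum"] == 0) | (cells["sum"] == cells["count"])).any():
            raise DegenerateFitError(
                f"{variable!r}: a timepoint has an empty outcome cell"
            )
        family_obj = sm.families.Binomial()
    else:
        family_obj = None  # ordinal handled below

    exog = sm.add_constant(d[["time"]].astype(float), has_constant="add")
    if family == "ordinal-logistic":
        if d["y"].nunique() < 2:
            raise DegenerateFitError(f"{variable!r}: fewer than 2 observed levels")
        # Independence working structure: the global-odds-ratio association
        # model is unstable when a level is empty at one timepoint (common
        # at n ~ 40); the sandwich variance still accounts for clustering.
        model = OrdinalGEE(
            d["y"].to_numpy(),
            d[["time"]].astype(float),
            groups=d["pid"].to_numpy(),
            cov_struct=Independence(),
        )
        res = model.fit()
        est = float(res.params["time"])
        p = float(res.pvalues["time"])
    else:
        model = GEE(
            d["y"].to_numpy(),
            exog.to_numpy(),
            groups=d["pid"].to_numpy(),
            family=family_obj,
            cov_struct=Exchangeable(),
        )
        res = model.fit()
        est = float(res.params[1])
        p = float(res.pvalues[1])

    if math.isnan(p):
        # degenerate sandwich variance (e.g. post identical to pre for
        # every participant): no evidence against the null unless the
        # estimate itself is nonzero
        p = 1.0 if est == 0 else 0.0

    return ComparisonResult(
        variable=variable, family=family, estimate=est, p_value=min(max(p, 0.0), 1.0)
    )


def _complete_pairs(table: CohortTable, variable: str) -> tuple[np.ndarray, np.ndarray]:
    y = _numeric_series(table, variable)
    wide = pd.DataFrame({
        "pid": table.df["participant_id"].astype(str),
        "time": table.df["timepoint"].astype(int),
        "y": y,
    }).pivot(index="pid", columns="time", values="y").dropna()
    if wide.shape[1] < 2:
        return np.array([]), np.array([])
    return wide[0].to_numpy(float), wide[1].to_numpy(float)


def standardized_effect_size(
    table: CohortTable,
    variable: str,
    sd_mode: Literal["baseline", "pooled", "change"] = "baseline",
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Standardized effect size of the pre/post change, with bootstrap CI.

    SES = mean(post - pre) / scale over complete pairs, where the scale is
    the baseline sd (default), the pooled baseline/follow-up sd, or the sd
    of the change scores.  The CI is a seeded percentile bootstrap over
    participants (default 2000 resamples).
    """
    pre, post = _complete_pairs(table, variable)
    n = pre.size
    if n < 2:
        raise InsufficientDataError(
            f"{variable!r}: need at least 2 complete pairs, have {n}"
        )

    def _scale(a: np.ndarray, b: np.ndarray) -> float:
        if sd_mode == "baseline":
            return a.std(ddof=1)
        if sd_mode == "pooled":
            return math.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        if sd_mode == "change":
            return (b - a).std(ddof=1)
        raise ValueError(f"unknown sd_mode {sd_mode!r}")

    s = _scale(pre, post)
    if s == 0:
        raise DegenerateFitError(f"{variable!r}: zero variance, SES undefined")
    ses = float((post - pre).mean() / s)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    bpre, bpost = pre[idx], post[idx]
    if sd_mode == "baseline":
        bscale = bpre.std(ddof=1, axis=1)
    elif sd_mode == "pooled":
        bscale = np.sqrt((bpre.var(ddof=1, axis=1) + bpost.var(ddof=1, axis=1)) / 2)
    else:
        bscale = (bpost - bpre).std(ddof=1, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bses = (bpost - bpre).mean(axis=1) / bscale
    bses = bses[np.isfinite(bses)]
    alpha = (1 - ci_level) / 2
    lo, hi = np.quantile(bses, [alpha, 1 - alpha])
    return ses, (float(lo), float(hi))


def analyze_cohort(
    table: CohortTable,
    plan: Sequence[tuple[str, ModelFamily] | dict],
    seed: int = 0,
    n_boot: int = 2000,
    sd_mode: Literal["baseline", "pooled", "change"] = "baseline",
) -> list[ComparisonResult]:
    """Run the full pre/post comparison for every variable in the plan.

    Per-variable failures (degenerate outcomes, missing columns) are
    recorded on that variable's result row; the batch always completes.
    Bootstrap seeds are derived per variable from ``seed`` so results do
    not depend on plan order.
    """
    results: list[ComparisonResult] = []
    for i, item in enumerate(plan):
        if isinstance(item, dict):
            variable, family = item["variable"], item["family"]
        else:
            variable, family = item
        res = ComparisonResult(variable=variable, family=family)
        try:
            res.baseline_summary = descriptive_summary(table, variable)[0]
            res.followup_summary = descriptive_summary(table, variable)[1]
            fit = fit_prepost(table, variable, family)
            res.estimate, res.p_value = fit.estimate, fit.p_value
            sub_seed = (seed * 1000 + i) % (2**31 - 1)
            es, ci = standardized_effect_size(
                table, variable, sd_mode=sd_mode, n_boot=n_boot, seed=sub_seed
            )
            res.effect_size, res.es_ci = es, ci
            res.es_band = classify_effect_size(es)
        except (KeyError, ValueError) as exc:
            res.error = str(exc)
        results.append(res)
    return results
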