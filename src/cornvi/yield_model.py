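"""Single-VI yield regression, model comparison, LSD treatment grouping.

Each candidate VI is related to plot yield by ordinary least squares,
y = b0 + b1 * VI, fitted separately per growth stage and year.  Models are
scored by the coefficient of determination R^2 and the mean absolute
percentage error MAPE = 100 * mean(|y - yhat| / y); significance stars
follow the usual convention (* p<0.05, ** p<0.01, *** p<0.001, ns).
Within a stage the best VI is the highest R^2, ties broken by lower MAPE
then name, and per-VI win counts over the season are tallied.

Treatment comparisons use a randomized-complete-block one-way ANOVA
(treatment + block, both fixed) with Fisher's least significant difference
LSD = t(1-a/2, df_error) * sqrt(2 * MSE / r) and a compact letter display:
treatments sharing a letter do not differ at level alpha.

Grain yields are normalized to the standard 15.5% moisture basis by
yield_15.5 = wet_yield * (100 - moisture) / (100 - 15.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "RegressionFit",
    "LsdGrouping",
    "fit_simple_lm",
    "mape",
    "significance_stars",
    "select_best",
    "lsd_letters",
    "moisture_adjust",
]

REFERENCE_MOISTURE_PCT = 15.5


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of yield on one VI at one stage of one year."""

    vi_name: str
    year: int
    stage: str
    slope: float
    intercept: float
    n: int
    r_squared: float
    mape_pct: float
    p_slope: float
    stars: str
    slope_se: float = float("nan")
    intercept_se: float = float("nan")

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def mape(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Mean absolute percentage error, in percent; observed values must be > 0."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted must have the same length")
    if np.any(y <= 0):
        raise ValueError("MAPE requires strictly positive observed values")
    return float(100.0 * np.mean(np.abs(y - yhat) / y))


def fit_simple_lm(x: Sequence[float], y: Sequence[float], *, vi_name: str = "",
                  year: int = 0, stage: str = "") -> RegressionFit:
    """OLS of y on x with R^2, MAPE and the two-sided slope t-test.

    Pairs with a missing value in either variable are dropped first; at
    least 3 complete pairs and non-degenerate x are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need at least 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor: slope undefined")
    fit = stats.linregress(x, y)
    yhat = fit.intercept + fit.slope * x
    sst = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if sst == 0 else 1.0 - float(np.sum((y - yhat) ** 2)) / sst
    # MAPE is only defined for positive observations (yields always are);
    # report it as missing rather than refusing the fit otherwise
    mape_value = mape(y, yhat) if np.all(y > 0) else float("nan")
    return RegressionFit(
        vi_name=vi_name, year=year, stage=stage,
        slope=float(fit.slope), intercept=float(fit.intercept), n=int(x.size),
        r_squared=float(r_squared), mape_pct=mape_value,
        p_slope=float(fit.pvalue), stars=significance_stars(fit.pvalue),
        slope_se=float(fit.stderr), intercept_se=float(fit.intercept_stderr),
    )


def select_best(fits: Iterable[RegressionFit], per: str = "stage"
                ) -> tuple[pd.DataFrame, pd.Series]:
    """Best VI per group and season win counts.

    per="stage" groups by (year, stage); per="year" groups by year.  Within
    a group, rank by R^2 descending, break ties by lower MAPE, then
    alphabetically.  Returns (winners frame, per-VI win counts).
    """
    rows = [
        {"vi_name": f.vi_name, "year": f.year, "stage": f.stage,
         "r_squared": f.r_squared, "mape_pct": f.mape_pct, "stars": f.stars}
        for f in fits
    ]
    if not rows:
        raise ValueError("no fits supplied")
    frame = pd.DataFrame(rows)
    keys = {"stage": ["year", "stage"], "year": ["year"]}[per]
    frame = frame.sort_values(
        ["r_squared", "mape_pct", "vi_name"], ascending=[False, True, True])
    winners = frame.groupby(keys, sort=True).head(1).reset_index(drop=True)
    win_counts = winners["vi_name"].value_counts().sort_index()
    return winners, win_counts


@dataclass(frozen=True)
class LsdGrouping:
    """Per-treatment means with Fisher-LSD letter labels at level alpha."""

    alpha: float
    lsd: float
    means: pd.DataFrame  # treatment, mean, sd, n, letters (desc. mean order)

    def letters(self) -> dict[str, str]:
        return dict(zip(self.means["treatment"], self.means["letters"]))


def _letter_display(means: pd.Series, lsd: float) -> dict[str, str]:
    """Compact letter display: maximal runs of sorted means spanning < lsd."""
    ordered = means.sort_values(ascending=False)
    names = list(ordered.index)
    values = ordered.to_numpy()
    k = len(names)
    intervals = []
    for start in range(k):
        end = start
        while end + 1 < k and values[start] - values[end + 1] < lsd:
            end += 1
        intervals.append((start, end))
    # keep only intervals not contained in another (maximal cliques)
    maximal = [iv for iv in intervals
               if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1]
                          for o in intervals)]
    maximal = sorted(set(maximal))
    letters = {name: "" for name in names}
    for letter_index, (lo, hi) in enumerate(maximal):
        letter = chr(ord("a") + letter_index)
        for i in range(lo, hi + 1):
            letters[names[i]] += letter
    return letters


def lsd_letters(data: pd.DataFrame, alpha: float = 0.05,
                response: str = "yield_mg_ha") -> LsdGrouping:
    """RCBD ANOVA (treatment + block) with Fisher-LSD letter grouping.

    Expects one year's plot table with columns treatment, block and the
    response.  Requires >= 2 treatments with >= 2 replicates each.  When
    every observation is identical (MSE = 0 and equal means) all treatments
    share "a" without attempting the degenerate t quantile arithmetic.
    """
    for column in ("treatment", "block", response):
        if column not in data.columns:
            raise ValueError(f"missing column {column!r}")
    counts = data.groupby("treatment")[response].count()
    if len(counts) < 2:
        raise ValueError("need at least two treatments")
    if (counts < 2).any():
        raise ValueError("need at least two replicates per treatment")
    frame = data.rename(columns={response: "y"})[["treatment", "block", "y"]].copy()
    stats_frame = (frame.groupby("treatment")["y"].agg(["mean", "std", "count"])
                   .rename(columns={"mean": "mean", "std": "sd", "count": "n"})
                   .sort_values("mean", ascending=False).reset_index())

    if np.ptp(frame["y"].to_numpy()) == 0:
        letters = {t: "a" for t in stats_frame["treatment"]}
        lsd_value = 0.0
    else:
        model = smf.ols("y ~ C(treatment) + C(block)", data=frame).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        mse = float(anova.loc["Residual", "sum_sq"] / anova.loc["Residual", "df"])
        df_error = float(anova.loc["Residual", "df"])
        replicates = float(counts.min())
        t_crit = stats.t.ppf(1 - alpha / 2, df_error)
        lsd_value = float(t_crit * np.sqrt(2.0 * mse / replicates))
        letters = _letter_display(frame.groupby("treatment")["y"].mean(), lsd_value)

    stats_frame["letters"] = stats_frame["treatment"].map(letters)
    return LsdGrouping(alpha=alpha, lsd=lsd_value, means=stats_frame)


def moisture_adjust(wet_yield: float, measured_moisture_pct: float) -> float:
    """Normalize a wet yield (Mg/ha) to the 15.5% grain-moisture basis."""
    if not 0 <= measured_moisture_pct < 100:
        raise ValueError(
            f"moisture {measured_moisture_pct}% outside [0, 100)")
    return wet_yield * (100.0 - measured_moisture_pct) / (100.0 - REFERENCE_MOISTURE_PCT)
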