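"""Model-performance statistics for paired simulated/observed series.

Implements the statistics conventionally used to evaluate field-scale
biogeochemical models against replicated plot measurements: Pearson
correlation (r), percentage root-mean-square error (RMSE) with its 95%
confidence threshold (RMSE95), Nash-Sutcliffe modelling efficiency (EF),
signed mean relative error (RE) with its 95% threshold (RE95), and the
coefficient of determination

    CD = sum_i (Oi - Obar)^2 / sum_i (Si - Obar)^2,

where Oi are observed means, Si simulated values and Obar the grand
observed mean.  CD can exceed 1, indicating the simulation spreads less
about the observed mean than the data do.

The 95% thresholds are a reconstruction (the defining methods paper is
not redistributable): each sampling date contributes the t-based 95%
half-width of its replicate mean, t_{0.975, n_i - 1} * SD_i / sqrt(n_i);
RMSE95 aggregates these half-widths exactly as RMSE aggregates the
residuals, and RE95 as RE aggregates the relative residuals.

Sign convention: RE = (100/n) * sum (Oi - Si)/Oi, so positive RE means
under-simulation.

If all simulated values equal the observations: r = 1, EF = 1, CD = 1,
RE = 0 and RMSE = 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class UndefinedStatisticError(ArithmeticError):
    """The statistic's denominator is zero for this series."""


@dataclass
class PairedSeries:
    """Simulated values paired with replicated observations per date."""

    simulated: np.ndarray  # (n,)
    observed_reps: list  # list of 1-D arrays, replicates per date
    dates: Optional[Sequence] = None

    def __post_init__(self) -> None:
        self.simulated = np.asarray(self.simulated, dtype=float)
        self.observed_reps = [np.asarray(r, dtype=float) for r in self.observed_reps]
        if len(self.observed_reps) != self.simulated.size:
            raise ValueError("simulated and observed lengths differ")
        if self.simulated.size < 2:
            raise ValueError("need at least two paired points")
        if not np.all(np.isfinite(self.simulated)):
            raise ValueError("simulated values must be finite")

    @classmethod
    def from_frames(
        cls, sim: pd.DataFrame, obs: pd.DataFrame, *, value: str = "value",
        date: str = "date", rep: str = "rep",
    ) -> "PairedSeries":
        """Pair a simulated series with a replicated observed series by date."""
        obs_groups = obs.groupby(date)[value]
        sim_by_date = sim.set_index(date)[value]
        dates = [d for d in obs_groups.groups if d in sim_by_date.index]
        if len(dates) < 2:
            raise ValueError("fewer than two common dates between series")
        reps = [obs_groups.get_group(d).to_numpy() for d in dates]
        simulated = sim_by_date.loc[dates].to_numpy()
        return cls(simulated=simulated, observed_reps=reps, dates=dates)

    @property
    def observed_means(self) -> np.ndarray:
        return np.array([r.mean() for r in self.observed_reps])

    @property
    def observed_sds(self) -> np.ndarray:
        return np.array(
            [r.std(ddof=1) if r.size > 1 else np.nan for r in self.observed_reps]
        )

    @property
    def rep_counts(self) -> np.ndarray:
        return np.array([r.size for r in self.observed_reps])

    @property
    def n(self) -> int:
        return self.simulated.size


def _ci95_half_widths(series: PairedSeries) -> Optional[np.ndarray]:
    """t-based 95% half-widths of the per-date replicate means, or None."""
    counts = series.rep_counts
    if np.any(counts < 2):
        return None
    sds = series.observed_sds
    tval = stats.t.ppf(0.975, counts - 1)
    return tval * sds / np.sqrt(counts)


def pearson_r(series: PairedSeries) -> float:
    o, s = series.observed_means, series.simulated
    if np.std(o) == 0 or np.std(s) == 0:
        raise UndefinedStatisticError("zero variance in one of the series")
    return float(stats.pearsonr(o, s).statistic)


def modelling_efficiency(series: PairedSeries) -> float:
    """Nash-Sutcliffe EF = 1 - SSE / SST; 1 is a perfect match, <= 1 always."""
    o, s = series.observed_means, series.simulated
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0:
        raise UndefinedStatisticError("constant observations")
    return 1.0 - float(np.sum((o - s) ** 2)) / sst


def coefficient_of_determination(series: PairedSeries) -> float:
    """CD = sum(Oi - Obar)^2 / sum(Si - Obar)^2; may exceed 1."""
    o, s = series.observed_means, series.simulated
    denom = float(np.sum((s - o.mean()) ** 2))
    if denom == 0:
        raise UndefinedStatisticError("simulated values all equal the observed mean")
    return float(np.sum((o - o.mean()) ** 2)) / denom


def rmse_percent(series: PairedSeries) -> float:
    """RMSE as a percentage of the observed grand mean."""
    o, s = series.observed_means, series.simulated
    obar = o.mean()
    if obar == 0:
        raise UndefinedStatisticError("observed mean is zero")
    return 100.0 / abs(obar) * math.sqrt(float(np.mean((s - o) ** 2)))


def rmse95(series: PairedSeries) -> Optional[float]:
    """95% confidence threshold for RMSE from replicate scatter; None if unavailable."""
    hw = _ci95_half_widths(series)
    if hw is None or np.any(~np.isfinite(hw)):
        return None
    obar = series.observed_means.mean()
    if obar == 0:
        raise UndefinedStatisticError("observed mean is zero")
    return 100.0 / abs(obar) * math.sqrt(float(np.mean(hw**2)))


def relative_error(series: PairedSeries) -> float:
    """Signed mean relative bias, %: positive means under-simulation.

    Dates with a zero observed mean are excluded with a warning.
    """
    o, s = series.observed_means, series.simulated
    mask = o != 0
    if not np.all(mask):
        warnings.warn(
            f"excluding {int((~mask).sum())} point(s) with zero observed mean from RE",
            stacklevel=2,
        )
    if mask.sum() == 0:
        raise UndefinedStatisticError("all observed means are zero")
    return 100.0 / mask.sum() * float(np.sum((o[mask] - s[mask]) / o[mask]))


def re95(series: PairedSeries) -> Optional[float]:
    """95% confidence threshold for |RE| from replicate scatter; None if unavailable."""
    hw = _ci95_half_widths(series)
    if hw is None or np.any(~np.isfinite(hw)):
        return None
    o = series.observed_means
    mask = o != 0
    if mask.sum() == 0:
        raise UndefinedStatisticError("all observed means are zero")
    return 100.0 / mask.sum() * float(np.sum(hw[mask] / np.abs(o[mask])))


@dataclass
class EvalReport:
    """All evaluation statistics for one paired series."""

    r: float
    rmse: float
    rmse95: Optional[float]
    ef: float
    cd: float
    re: float
    re95: Optional[float]
    n: int
    label: str = ""
    notes: dict = field(default_factory=dict)

    def summary(self) -> str:
        rows = [
            ("Correlation coefficient (r)", self.r),
            ("Modelling efficiency (EF)", self.ef),
            ("Coefficient of determination (CD)", self.cd),
            ("Relative error (RE, %)", self.re),
            ("RMSE (%)", self.rmse),
            ("RMSE95%", self.rmse95),
            ("RE95%", self.re95),
        ]
        width = max(len(name) for name, _ in rows)
        lines = [f"Model evaluation ({self.label or 'series'}, n={self.n})"]
        for name, v in rows:
            val = "n/a" if v is None else f"{v:.4g}"
            lines.append(f"  {name:<{width}}  {val}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "r": self.r, "RMSE_pct": self.rmse, "RMSE95": self.rmse95,
            "EF": self.ef, "CD": self.cd, "RE_pct": self.re, "RE95": self.re95,
            "n": self.n, "label": self.label,
        }


def evaluate(series: PairedSeries, label: str = "") -> EvalReport:
    """Compute the full statistics suite for one paired series.

    Statistics whose denominator vanishes are reported as NaN rather than
    raising, so one degenerate series does not abort a batch evaluation.
    """

    def guard(fn):
        try:
            return fn(series)
        except UndefinedStatisticError:
            return float("nan")

    return EvalReport(
        r=guard(pearson_r),
        rmse=guard(rmse_percent),
        rmse95=guard(rmse95),
        ef=guard(modelling_efficiency),
        cd=guard(coefficient_of_determination),
        re=guard(relative_error),
        re95=guard(re95),
        n=series.n,
        label=label,
    )
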