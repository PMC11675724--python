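"""Cost-effectiveness statistics: ICER, NMB/INMB, summary tables, CEAC.

Conventions
-----------
* The ICER is computed on mean increments (ratio of means), the standard
  decision-analytic convention.
* Summary statistics use the n-1 standard deviation, the midpoint median for
  even n, and a normal-approximation 95% CI (mean +/- 1.96 SD/sqrt(n)).
* The cost-effectiveness acceptability curve (CEAC) at willingness-to-pay w
  is the fraction of incremental samples with positive incremental net
  monetary benefit, delta_effect * w - delta_cost > 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "DOMINANT",
    "DOMINATED",
    "UNDEFINED",
    "ICEPoint",
    "SummaryStats",
    "CEASummary",
    "CEACCurve",
    "nmb",
    "inmb",
    "icer",
    "summarize",
    "ceac",
    "default_wtp_grid",
    "build_cea_summary",
    "write_summary_json",
    "write_ceac_csv",
    "write_ice_csv",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class ICEPoint:
    """One sample's incremental cost and effect (CXL minus conventional)."""

    delta_cost: float
    delta_effect: float


def nmb(effect: float, cost: float, wtp: float) -> float:
    """Net monetary benefit: effect x WTP - cost (USD)."""
    if wtp <= 0:
        raise ValueError("wtp must be > 0")
    return effect * wtp - cost


def inmb(nmb_cxl: float, nmb_conventional: float) -> float:
    """Incremental net monetary benefit of CXL over conventional management."""
    if not (math.isfinite(nmb_cxl) and math.isfinite(nmb_conventional)):
        raise ValueError("NMB inputs must be finite")
    return nmb_cxl - nmb_conventional


def icer(delta_cost: float, delta_effect: float) -> Union[float, str]:
    """Incremental cost-effectiveness ratio, or a dominance label.

    Returns the ratio when it is informative, ``"dominant"`` when CXL is
    cheaper and more effective, ``"dominated"`` when costlier and less
    effective, and ``"undefined"`` when the effect increment is zero (never
    divides by zero).
    """
    if delta_effect == 0.0:
        return UNDEFINED
    if delta_effect > 0 and delta_cost <= 0:
        return DOMINANT
    if delta_effect < 0 and delta_cost >= 0:
        return DOMINATED
    return delta_cost / delta_effect


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    minimum: float
    median: float
    maximum: float
    ci_lower: float
    ci_upper: float
    n: int

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "minimum": self.minimum,
            "median": self.median,
            "maximum": self.maximum,
            "ci_lower_95": self.ci_lower,
            "ci_upper_95": self.ci_upper,
            "n": self.n,
        }


def summarize(samples: Sequence[float]) -> SummaryStats:
    """Mean/SD/min/median/max and normal 95% CI of a sample (n >= 2)."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("summarize requires at least 2 samples")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    half = 1.96 * sd / math.sqrt(x.size)
    return SummaryStats(
        mean=mean,
        sd=sd,
        minimum=float(np.min(x)),
        median=float(np.median(x)),
        maximum=float(np.max(x)),
        ci_lower=mean - half,
        ci_upper=mean + half,
        n=int(x.size),
    )


@dataclass
class CEASummary:
    """Per-arm cost/effect/NMB summary rows plus ICER and INMB.

    ``rows`` holds a :class:`SummaryStats` per statistic: ``cost_conventional``,
    ``cost_cxl``, ``effect_conventional``, ``effect_cxl``, ``nmb_conventional``,
    ``nmb_cxl``, ``inmb``.
    """

    wtp: float
    rows: dict[str, SummaryStats] = field(default_factory=dict)
    icer: Union[float, str] = UNDEFINED
    mean_inmb: float = 0.0

    def to_dict(self) -> dict:
        return {
            "wtp_per_qaly": self.wtp,
            "icer": self.icer,
            "mean_inmb": self.mean_inmb,
            "statistics": {k: v.to_dict() for k, v in self.rows.items()},
        }


def build_cea_summary(
    cost_conventional: Sequence[float],
    cost_cxl: Sequence[float],
    effect_conventional: Sequence[float],
    effect_cxl: Sequence[float],
    wtp: float,
) -> CEASummary:
    """Summarize per-sample arm outcomes into the standard results table.

    The four inputs are aligned per-sample vectors (per-patient values for a
    first-order run, per-simulation per-capita means for a PSA).  The ICER is
    the ratio of mean increments; the mean INMB equals the difference of mean
    NMBs exactly, by linearity.
    """
    cc = np.asarray(cost_conventional, dtype=float)
    cx = np.asarray(cost_cxl, dtype=float)
    ec = np.asarray(effect_conventional, dtype=float)
    ex = np.asarray(effect_cxl, dtype=float)
    if not (cc.size == cx.size == ec.size == ex.size):
        raise ValueError("arm sample vectors must have equal length")
    nmb_c = ec * wtp - cc
    nmb_x = ex * wtp - cx
    inmb_samples = nmb_x - nmb_c
    summary = CEASummary(wtp=wtp)
    summary.rows = {
        "cost_conventional": summarize(cc),
        "cost_cxl": summarize(cx),
        "effect_conventional": summarize(ec),
        "effect_cxl": summarize(ex),
        "nmb_conventional": summarize(nmb_c),
        "nmb_cxl": summarize(nmb_x),
        "inmb": summarize(inmb_samples),
    }
    summary.icer = icer(float(np.mean(cx) - np.mean(cc)), float(np.mean(ex) - np.mean(ec)))
    summary.mean_inmb = float(np.mean(inmb_samples))
    return summary


@dataclass
class CEACCurve:
    wtp: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability": self.probability})


def ceac(ice_points: Iterable[ICEPoint], wtp_grid: Sequence[float]) -> CEACCurve:
    """Probability that CXL is cost-effective at each willingness-to-pay."""
    points = list(ice_points)
    grid = np.asarray(wtp_grid, dtype=float)
    if not points or grid.size == 0:
        raise ValueError("ceac requires non-empty points and WTP grid")
    dc = np.array([p.delta_cost for p in points])
    de = np.array([p.delta_effect for p in points])
    prob = np.array([float(np.mean(de * w - dc > 0)) for w in grid])
    return CEACCurve(wtp=grid, probability=prob)


def default_wtp_grid(gdp_per_capita: float = 8449.50, n: int = 100) -> np.ndarray:
    """Default CEAC grid: 0 to three times GDP per capita."""
    return np.linspace(0.0, 3.0 * gdp_per_capita, n)


def write_summary_json(summary: CEASummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2) + "\n")


def write_ceac_csv(curve: CEACCurve, path: str | Path) -> None:
    curve.to_frame().to_csv(path, index=False)


def write_ice_csv(points: Iterable[ICEPoint], path: str | Path) -> None:
    frame = pd.DataFrame(
        [{"delta_cost": p.delta_cost, "delta_effect": p.delta_effect} for p in points]
    )
    frame.to_csv(path, index=False)
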