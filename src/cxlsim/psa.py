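"""Second-order probabilistic sensitivity analysis (PSA) and tornado analysis.

PSA samples parameter values from assigned distributions (beta for
probabilities, gamma for costs, uniform for ranged complication costs,
discrete uniform for the integer CXL effect duration), reruns the paired
microsimulation per sample, and records the incremental cost, incremental
effect, and incremental net monetary benefit (INMB).  All samples share one
first-order seed so between-sample variation reflects parameter uncertainty
only, not Monte Carlo resampling noise.

The tornado analysis perturbs one parameter at a time to its low and high
extreme with everything else at base values, evaluating the INMB at a common
seed, and ranks parameters by the width |INMB_high - INMB_low|.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import model_validator

from .cea import ICEPoint
from .engine import run_trial
from .parameters import ConfigurationError, ModelParams, _StrictModel

__all__ = [
    "ParamDistribution",
    "PSASample",
    "TornadoBar",
    "beta_from_mean",
    "gamma_from_mean",
    "sample_params",
    "run_psa",
    "tornado",
    "default_psa_distributions",
    "default_tornado_ranges",
    "write_psa_csv",
    "write_tornado_csv",
]


class ParamDistribution(_StrictModel):
    """A sampling distribution attached to one scalar field of ModelParams.

    ``path`` is a dotted path into the bundle; integer components index into
    list fields (e.g. ``transitions.progression_prob.0`` or
    ``complications.entries.2.cost``).
    """

    path: str
    kind: Literal["beta", "gamma", "uniform", "discrete"]
    alpha: Optional[float] = None
    beta: Optional[float] = None
    shape: Optional[float] = None
    scale: Optional[float] = None
    low: Optional[float] = None
    high: Optional[float] = None
    values: Optional[list[float]] = None

    @model_validator(mode="after")
    def _check(self) -> "ParamDistribution":
        need = {
            "beta": ("alpha", "beta"),
            "gamma": ("shape", "scale"),
            "uniform": ("low", "high"),
            "discrete": ("values",),
        }[self.kind]
        for name in need:
            if getattr(self, name) is None:
                raise ValueError(f"{self.kind} distribution for {self.path} needs {name}")
        if self.kind == "uniform" and self.low > self.high:
            raise ValueError(f"uniform low must be <= high for {self.path}")
        if self.kind == "discrete" and not self.values:
            raise ValueError(f"discrete distribution for {self.path} needs values")
        return self

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "beta":
            return float(rng.beta(self.alpha, self.beta))
        if self.kind == "gamma":
            return float(rng.gamma(self.shape, self.scale))
        if self.kind == "uniform":
            return float(rng.uniform(self.low, self.high))
        return float(rng.choice(self.values))


def beta_from_mean(path: str, mean: float, rel_sd: float = 0.10) -> ParamDistribution:
    """Beta distribution by method of moments.

    The SD is ``rel_sd * min(mean, 1-mean)`` so that distributions near the
    edges of [0, 1] stay unimodal and within support by construction.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError("beta mean must lie in (0, 1)")
    sd = rel_sd * min(mean, 1.0 - mean)
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    if nu <= 0:
        raise ValueError("relative SD too large for a beta distribution")
    return ParamDistribution(path=path, kind="beta", alpha=mean * nu, beta=(1.0 - mean) * nu)


def gamma_from_mean(path: str, mean: float, rel_sd: float = 0.20) -> ParamDistribution:
    """Gamma distribution by method of moments (shape = 1/rel_sd^2)."""
    if mean <= 0:
        raise ValueError("gamma mean must be > 0")
    shape = 1.0 / rel_sd**2
    return ParamDistribution(path=path, kind="gamma", shape=shape, scale=mean / shape)


def _walk(params: ModelParams, path: str):
    """Resolve a dotted path to (container, final key/index)."""
    parts = path.split(".")
    obj = params
    for part in parts[:-1]:
        if part.lstrip("-").isdigit():
            if not isinstance(obj, (list, tuple)):
                raise ConfigurationError(f"cannot index non-list with {part!r} in {path!r}")
            try:
                obj = obj[int(part)]
            except IndexError as exc:
                raise ConfigurationError(f"index {part} out of range in {path!r}") from exc
        elif hasattr(obj, part):
            obj = getattr(obj, part)
        else:
            raise ConfigurationError(f"cannot resolve {part!r} in path {path!r}")
    return obj, parts[-1]


def _set_path(params: ModelParams, path: str, value: float) -> None:
    obj, last = _walk(params, path)
    try:
        current = get_path(params, path)
    except ConfigurationError:
        current = None
    # integer-valued fields (e.g. effect_duration) keep their type
    if isinstance(current, int) and not isinstance(current, bool):
        if float(value) != int(value):
            raise ConfigurationError(
                f"{path!r} holds an integer; cannot assign non-integral {value!r}"
            )
        value = int(value)
    if last.lstrip("-").isdigit():
        if not isinstance(obj, list):
            raise ConfigurationError(f"cannot index non-list with {last!r} in {path!r}")
        try:
            obj[int(last)] = value
        except IndexError as exc:
            raise ConfigurationError(f"index {last} out of range in {path!r}") from exc
    else:
        if not hasattr(obj, last):
            raise ConfigurationError(f"cannot resolve {last!r} in path {path!r}")
        setattr(obj, last, value)


def get_path(params: ModelParams, path: str) -> float:
    """Read the scalar at a dotted path (tornado/base-value lookups)."""
    obj, last = _walk(params, path)
    if last.lstrip("-").isdigit():
        return obj[int(last)]
    if not hasattr(obj, last):
        raise ConfigurationError(f"cannot resolve {last!r} in path {path!r}")
    return getattr(obj, last)


def _revalidate(params: ModelParams) -> ModelParams:
    return ModelParams.model_validate(params.model_dump())


def sample_params(
    base: ModelParams, dists: Sequence[ParamDistribution], seed: int
) -> ModelParams:
    """Deep variant of ``base`` with each listed field replaced by a draw.

    The variant is revalidated in full, so a draw that violates a field
    invariant raises a validation error rather than being clipped post hoc
    (it signals a mis-specified distribution).
    """
    variant = base.model_copy(deep=True)
    if not dists:
        return variant
    rng = np.random.default_rng(seed)
    for dist in dists:
        _set_path(variant, dist.path, dist.draw(rng))
    return _revalidate(variant)


@dataclass
class PSASample:
    index: int
    sampled_values: dict[str, float]
    ice: ICEPoint
    inmb: float
    cost_conventional: float
    cost_cxl: float
    effect_conventional: float
    effect_cxl: float
    transplants_conventional: int
    transplants_cxl: int


def run_psa(
    base: ModelParams,
    dists: Sequence[ParamDistribution],
    n_samples: int = 1000,
    trials_per_sample: Optional[int] = None,
    seed: int = 0,
    wtp: Optional[float] = None,
) -> list[PSASample]:
    """Second-order PSA: one paired microsimulation per parameter sample.

    ``trials_per_sample`` overrides the number of first-order patients per
    sample (defaults to the bundle's cohort size).  Deterministic given
    ``(base, dists, seed)``.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if trials_per_sample is not None and trials_per_sample < 1:
        raise ValueError("trials_per_sample must be >= 1")
    wtp = base.econ.wtp_per_qaly if wtp is None else wtp
    ss = np.random.SeedSequence(seed)
    trial_ss, *sample_ss = ss.spawn(n_samples + 1)
    # One common first-order seed across all samples: between-sample spread
    # reflects parameter uncertainty only.
    trial_seed = int(trial_ss.generate_state(1)[0])
    results: list[PSASample] = []
    for i in range(n_samples):
        sample_seed = int(sample_ss[i].generate_state(1)[0])
        variant = sample_params(base, dists, sample_seed)
        if trials_per_sample is not None:
            variant.econ.n_patients = trials_per_sample
        trial = run_trial(variant, trial_seed)
        dc = trial.delta_cost
        de = trial.delta_effect
        results.append(
            PSASample(
                index=i,
                sampled_values={d.path: get_path(variant, d.path) for d in dists},
                ice=ICEPoint(delta_cost=dc, delta_effect=de),
                inmb=de * wtp - dc,
                cost_conventional=trial.conventional.mean_cost,
                cost_cxl=trial.cxl.mean_cost,
                effect_conventional=trial.conventional.mean_qaly,
                effect_cxl=trial.cxl.mean_qaly,
                transplants_conventional=trial.conventional.total_transplants,
                transplants_cxl=trial.cxl.total_transplants,
            )
        )
    return results


@dataclass
class TornadoBar:
    path: str
    low: float
    high: float
    inmb_low: float
    inmb_high: float

    @property
    def width(self) -> float:
        return abs(self.inmb_high - self.inmb_low)


def tornado(
    base: ModelParams,
    ranges: Sequence[tuple[str, float, float]],
    wtp: Optional[float] = None,
    trials: Optional[int] = None,
    seed: int = 0,
) -> list[TornadoBar]:
    """One-way sensitivity analysis of the INMB.

    Each parameter is set to its low and its high value with all others at
    base; every evaluation reuses the same first-order seed so bar widths
    reflect the parameter change, not resampling noise.  Bars are sorted by
    width descending, ties broken by path name.
    """
    wtp = base.econ.wtp_per_qaly if wtp is None else wtp

    def _inmb_at(path: str, value: float) -> float:
        variant = base.model_copy(deep=True)
        _set_path(variant, path, value)
        variant = _revalidate(variant)
        if trials is not None:
            variant.econ.n_patients = trials
        trial = run_trial(variant, seed)
        return trial.delta_effect * wtp - trial.delta_cost

    bars = []
    for path, low, high in ranges:
        if low > high:
            raise ConfigurationError(f"tornado range for {path!r} has low > high")
        get_path(base, path)  # fail fast on unresolvable paths
        bars.append(
            TornadoBar(
                path=path,
                low=low,
                high=high,
                inmb_low=_inmb_at(path, low),
                inmb_high=_inmb_at(path, high),
            )
        )
    return sorted(bars, key=lambda b: (-b.width, b.path))


def default_psa_distributions(base: ModelParams) -> list[ParamDistribution]:
    """Shipped second-order distributions.

    Beta on probabilities (10% relative SD on the side nearer the boundary),
    gamma on costs (20% relative SD), uniform over the printed complication
    cost ranges, discrete uniform on the CXL effect duration (5..15 years).
    Utilities are held fixed by default: independent marginals cannot
    guarantee the non-increasing ordinal profile.
    """
    tr = base.transitions
    dists: list[ParamDistribution] = [
        beta_from_mean("cxl.effectiveness", base.cxl.effectiveness),
        ParamDistribution(
            path="cxl.effect_duration",
            kind="discrete",
            values=[float(v) for v in range(5, 16)],
        ),
        gamma_from_mean("costs.routine_annual", base.costs.routine_annual),
        gamma_from_mean("costs.cxl", base.costs.cxl),
        gamma_from_mean("costs.transplant", base.costs.transplant),
        gamma_from_mean(
            "costs.transplant_followup_annual", base.costs.transplant_followup_annual
        ),
    ]
    for i, p in enumerate(tr.progression_prob):
        if p > 0:
            dists.append(beta_from_mean(f"transitions.progression_prob.{i}", p))
    for i, p in enumerate(tr.transplant_prob):
        if p > 0:
            dists.append(beta_from_mean(f"transitions.transplant_prob.{i}", p))
    for i, p in enumerate(tr.graft_failure_prob):
        dists.append(beta_from_mean(f"transitions.graft_failure_prob.{i}", p))
    for i, entry in enumerate(base.complications.entries):
        if entry.cost_low < entry.cost_high:
            dists.append(
                ParamDistribution(
                    path=f"complications.entries.{i}.cost",
                    kind="uniform",
                    low=entry.cost_low,
                    high=entry.cost_high,
                )
            )
    return dists


def default_tornado_ranges(base: ModelParams) -> list[tuple[str, float, float]]:
    """Shipped one-way ranges: CXL duration from 5 years to lifetime, CXL
    effectiveness 0.90-1.0, +/-25% bands on costs and transition
    probabilities, and the printed complication cost ranges."""
    lifetime = base.econ.horizon_age - base.econ.start_age
    ranges: list[tuple[str, float, float]] = [
        ("cxl.effect_duration", 5, lifetime),
        ("cxl.effectiveness", 0.90, 1.0),
    ]
    for path in (
        "costs.routine_annual",
        "costs.cxl",
        "costs.transplant",
        "costs.transplant_followup_annual",
    ):
        v = get_path(base, path)
        ranges.append((path, 0.75 * v, 1.25 * v))
    tr = base.transitions
    for i, p in enumerate(tr.progression_prob):
        if p > 0:
            ranges.append((f"transitions.progression_prob.{i}", 0.75 * p, min(1.25 * p, 1.0)))
    for i, p in enumerate(tr.transplant_prob):
        if p > 0:
            ranges.append((f"transitions.transplant_prob.{i}", 0.75 * p, min(1.25 * p, 1.0)))
    ranges.append(
        (
            "transitions.graft_failure_prob.0",
            0.75 * tr.graft_failure_prob[0],
            min(1.25 * tr.graft_failure_prob[0], 1.0),
        )
    )
    for i, entry in enumerate(base.complications.entries):
        if entry.cost_low < entry.cost_high:
            ranges.append((f"complications.entries.{i}.cost", entry.cost_low, entry.cost_high))
    return ranges


def write_psa_csv(samples: Sequence[PSASample], path: str | Path) -> None:
    rows = []
    for s in samples:
        row = {"sample": s.index}
        row.update(s.sampled_values)
        row.update(
            {
                "cost_conventional": s.cost_conventional,
                "cost_cxl": s.cost_cxl,
                "effect_conventional": s.effect_conventional,
                "effect_cxl": s.effect_cxl,
                "delta_cost": s.ice.delta_cost,
                "delta_effect": s.ice.delta_effect,
                "inmb": s.inmb,
                "transplants_conventional": s.transplants_conventional,
                "transplants_cxl": s.transplants_cxl,
            }
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_tornado_csv(bars: Sequence[TornadoBar], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "parameter": b.path,
                "low": b.low,
                "high": b.high,
                "inmb_low": b.inmb_low,
                "inmb_high": b.inmb_high,
                "width": b.width,
            }
            for b in bars
        ]
    ).to_csv(path, index=False)
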