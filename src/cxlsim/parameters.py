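"""Parameter data model for the keratoconus cost-effectiveness microsimulation.

The model compares corneal collagen crosslinking (CXL) against conventional
(untreated) management of progressive keratoconus from a public-payer
perspective.  Everything the simulation needs is gathered into a single
validated bundle, :class:`ModelParams`:

* economic settings (discount rate, willingness-to-pay, horizon, cohort size),
* a cost schedule in USD (annual consultation, CXL procedure, penetrating
  transplant, post-transplant follow-up),
* post-transplant complication probabilities and cost ranges,
* CXL effect parameters (effectiveness, duration of effect),
* ordinal visual-acuity (VA) state dynamics (progression, transplant risk,
  graft failure, initial VA distribution),
* per-cycle utilities indexed by the better eye's VA category,
* an age-indexed life table of annual death probabilities.

Configuration lives in a single YAML or JSON document plus a separate
two-column life-table CSV (``age,qx``) so the externally sourced mortality
table stays swappable.
"""

from __future__ import annotations

import json
import math
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "ConfigurationError",
    "EconSettings",
    "CostSchedule",
    "ComplicationEntry",
    "ComplicationTable",
    "CXLParams",
    "TransitionParams",
    "UtilityMap",
    "LifeTableRow",
    "LifeTable",
    "ModelParams",
    "load_model_params",
    "write_model_params",
    "usd_from_brl",
]


class ConfigurationError(ValueError):
    """Raised when a configuration file is missing, malformed, or invalid."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EconSettings(_StrictModel):
    """Economic and cohort settings.

    Defaults follow Brazilian public-payer (SUS) conventions: a 5% annual
    discount rate on both costs and QALYs, a willingness-to-pay of one GDP
    per capita (USD 8449.50), a fixed BRL/USD exchange rate of 5.00, and a
    cohort of 5000 patients aged 18 followed until age 90.
    """

    discount_rate: float = 0.05
    wtp_per_qaly: float = 8449.50
    exchange_rate: float = 5.00
    start_age: int = 18
    horizon_age: int = 90
    n_patients: int = 5000
    eyes_per_patient: Literal[2] = 2

    @model_validator(mode="after")
    def _check(self) -> "EconSettings":
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValueError("discount_rate must satisfy 0 <= discount_rate < 1")
        if self.wtp_per_qaly <= 0:
            raise ValueError("wtp_per_qaly must be > 0")
        if self.exchange_rate <= 0:
            raise ValueError("exchange_rate must be > 0")
        if self.start_age >= self.horizon_age:
            raise ValueError("start_age must be < horizon_age")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        return self

    @property
    def n_cycles(self) -> int:
        """Number of annual cycles simulated (ages start_age .. horizon_age-1)."""
        return self.horizon_age - self.start_age


class CostSchedule(_StrictModel):
    """Per-event and per-cycle costs, USD.

    ``transplant_followup_annual`` defaults to three times the routine annual
    consultation cost: once any eye is transplanted, the patient's annual
    maintenance cost triples and replaces the routine consultation.
    """

    routine_annual: float = 19.98
    cxl: float = 78.52
    transplant: float = 414.00
    transplant_followup_annual: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "CostSchedule":
        if self.transplant_followup_annual is None:
            self.transplant_followup_annual = round(3.0 * self.routine_annual, 10)
        for name in ("routine_annual", "cxl", "transplant", "transplant_followup_annual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        return self


class ComplicationEntry(_StrictModel):
    """A post-keratoplasty complication: annual probability while grafted is
    irrelevant here — the probability applies once, in the cycle of the
    transplant — plus a cost range in USD.

    ``cost`` is an optional realized cost override; when unset, deterministic
    runs use the midpoint of ``(cost_low, cost_high)`` and probabilistic
    sensitivity analysis may sample it uniformly over the range.
    """

    name: str
    probability: float
    cost_low: float
    cost_high: float
    cost: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "ComplicationEntry":
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability of {self.name!r} must lie in [0, 1]")
        if self.cost_low < 0:
            raise ValueError(f"cost_low of {self.name!r} must be >= 0")
        if self.cost_low > self.cost_high:
            raise ValueError(f"cost_low of {self.name!r} must be <= cost_high")
        if self.cost is not None and self.cost < 0:
            raise ValueError(f"cost of {self.name!r} must be >= 0")
        return self

    @property
    def cost_point(self) -> float:
        """Realized cost: explicit override, else the range midpoint."""
        if self.cost is not None:
            return self.cost
        return 0.5 * (self.cost_low + self.cost_high)


def _default_complications() -> list[ComplicationEntry]:
    rows = [
        ("acute_glaucoma", 0.043, 248.00, 248.00),
        ("suture_dehiscence", 0.046, 54.40, 54.40),
        ("retinal_detachment", 0.010, 289.00, 730.90),
        ("cataract", 0.024, 177.41, 177.41),
        ("endophthalmitis", 0.0038, 39.55, 730.90),
        ("expulsive_bleeding", 0.004, 140.59, 140.59),
    ]
    return [
        ComplicationEntry(name=n, probability=p, cost_low=lo, cost_high=hi)
        for n, p, lo, hi in rows
    ]


class ComplicationTable(_StrictModel):
    """Complications of penetrating keratoplasty, each drawn independently in
    the cycle an eye is grafted (or regrafted)."""

    entries: list[ComplicationEntry] = Field(default_factory=_default_complications)


class CXLParams(_StrictModel):
    """Crosslinking effect: the fraction of treated eyes stabilized
    (effectiveness) and how many years the stabilization lasts."""

    effectiveness: float = 0.99
    effect_duration: int = 10

    @model_validator(mode="after")
    def _check(self) -> "CXLParams":
        if not 0.0 <= self.effectiveness <= 1.0:
            raise ValueError("effectiveness must lie in [0, 1]")
        if self.effect_duration < 0:
            raise ValueError("effect_duration must be >= 0")
        return self


class TransitionParams(_StrictModel):
    """Ordinal VA-state dynamics for a single eye.

    States are 0..K-1 with 0 the best ("good vision") category.  An untreated
    eye in state v worsens one category per year with probability
    ``progression_prob[v]`` and receives a penetrating transplant with
    probability ``transplant_prob[v]``.  A grafted eye fails with annual
    probability ``graft_failure_prob[min(graft_age, len)-1]`` (the last entry
    applies to all older grafts) and is immediately regrafted.  A successful
    graft places the eye in ``post_transplant_va``.
    """

    n_va_states: int = 4
    progression_prob: list[float]
    transplant_prob: list[float]
    graft_failure_prob: list[float]
    post_transplant_va: int = 0
    initial_va_marginal: list[float]
    initial_va_between_eye_corr: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "TransitionParams":
        k = self.n_va_states
        if k < 2:
            raise ValueError("n_va_states must be >= 2")
        for name in ("progression_prob", "transplant_prob", "initial_va_marginal"):
            vec = getattr(self, name)
            if len(vec) != k:
                raise ValueError(f"{name} must have length n_va_states = {k}")
            for v in vec:
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"entries of {name} must lie in [0, 1]")
        if self.progression_prob[k - 1] != 0.0:
            raise ValueError(
                f"progression_prob[{k - 1}] must be 0: the worst VA state has no worse state"
            )
        if not self.graft_failure_prob:
            raise ValueError("graft_failure_prob schedule must be non-empty")
        for v in self.graft_failure_prob:
            if not 0.0 <= v <= 1.0:
                raise ValueError("entries of graft_failure_prob must lie in [0, 1]")
        if abs(sum(self.initial_va_marginal) - 1.0) > 1e-9:
            raise ValueError("initial_va_marginal must sum to 1 within 1e-9")
        if not 0 <= self.post_transplant_va < k:
            raise ValueError("post_transplant_va must be a valid VA state index")
        if not 0.0 <= self.initial_va_between_eye_corr <= 1.0:
            raise ValueError("initial_va_between_eye_corr must lie in [0, 1]")
        return self


class UtilityMap(_StrictModel):
    """Per-cycle utility weights indexed by the better eye's VA state.

    Death carries utility 0.  Utilities must be non-increasing in the VA
    index (worse vision cannot be preferred to better vision).
    """

    utility_by_better_eye_va: list[float]

    @model_validator(mode="after")
    def _check(self) -> "UtilityMap":
        u = self.utility_by_better_eye_va
        if not u:
            raise ValueError("utility_by_better_eye_va must be non-empty")
        for v in u:
            if not 0.0 <= v <= 1.0:
                raise ValueError("utilities must lie in [0, 1]")
        for a, b in zip(u, u[1:]):
            if b > a:
                raise ValueError("utilities must be non-increasing in VA-state index")
        return self


class LifeTableRow(_StrictModel):
    age: int
    qx: float

    @model_validator(mode="after")
    def _check(self) -> "LifeTableRow":
        if not 0.0 <= self.qx <= 1.0:
            raise ValueError(f"qx at age {self.age} must lie in [0, 1]")
        return self


class LifeTable(_StrictModel):
    """Age-indexed annual death probabilities (qx), contiguous in age."""

    rows: list[LifeTableRow]

    @model_validator(mode="after")
    def _check(self) -> "LifeTable":
        if not self.rows:
            raise ValueError("life table must be non-empty")
        ages = [r.age for r in self.rows]
        for prev, cur in zip(ages, ages[1:]):
            if cur != prev + 1:
                raise ValueError(
                    f"life table ages must be contiguous; gap after age {prev}"
                )
        return self

    @property
    def min_age(self) -> int:
        return self.rows[0].age

    @property
    def max_age(self) -> int:
        return self.rows[-1].age

    def qx_at(self, age: int) -> float:
        if not self.min_age <= age <= self.max_age:
            raise KeyError(f"life table does not cover age {age}")
        return self.rows[age - self.min_age].qx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": [r.age for r in self.rows], "qx": [r.qx for r in self.rows]}
        )

    def to_csv(self, path: str | Path) -> None:
        # %.17g guarantees binary round-trip of the qx doubles
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        try:
            frame = pd.read_csv(path, float_precision="round_trip")
        except Exception as exc:  # pragma: no cover - I/O detail
            raise ConfigurationError(f"cannot read life table {path}: {exc}") from exc
        if list(frame.columns) != ["age", "qx"]:
            raise ConfigurationError(
                f"life table {path} must have header 'age,qx', got {list(frame.columns)}"
            )
        rows = [
            LifeTableRow(age=int(a), qx=float(q))
            for a, q in zip(frame["age"], frame["qx"])
        ]
        return cls(rows=rows)


class ModelParams(_StrictModel):
    """The full, mutually consistent parameter bundle for one model run.

    ``include_complication_costs`` defaults to off: the baseline scenario is
    the minimum-cost (most conservative) one, with complication costs
    reserved for sensitivity analysis.  ``provenance`` optionally records,
    per dotted field path, whether a value is a published figure or a
    synthetic stand-in.
    """

    econ: EconSettings = Field(default_factory=EconSettings)
    costs: CostSchedule = Field(default_factory=CostSchedule)
    complications: ComplicationTable = Field(default_factory=ComplicationTable)
    cxl: CXLParams = Field(default_factory=CXLParams)
    transitions: TransitionParams
    utilities: UtilityMap
    life_table: LifeTable
    include_complication_costs: bool = False
    provenance: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "ModelParams":
        k = self.transitions.n_va_states
        if len(self.utilities.utility_by_better_eye_va) != k:
            raise ValueError(
                "utility_by_better_eye_va length must equal transitions.n_va_states "
                f"({len(self.utilities.utility_by_better_eye_va)} != {k})"
            )
        for age in range(self.econ.start_age, self.econ.horizon_age + 1):
            if not self.life_table.min_age <= age <= self.life_table.max_age:
                raise ValueError(f"life table does not cover age {age}")
        return self


def _read_config_document(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    # YAML is the default dialect (and a JSON superset).
    return yaml.safe_load(text)


def load_model_params(config_path: str | Path, life_table_path: str | Path) -> ModelParams:
    """Read and validate the full parameter bundle.

    Parameters
    ----------
    config_path
        YAML or JSON document (auto-detected by extension) whose keys are the
        ``ModelParams`` fields except ``life_table``.
    life_table_path
        Two-column CSV with header ``age,qx``, one row per integer age.

    Raises
    ------
    ConfigurationError
        On unreadable files, unknown or missing keys, invariant violations
        (the message names the offending field and bound), or a life table
        that fails to cover the simulated age range (the message names the
        first missing age).
    """
    config_path = Path(config_path)
    life_table_path = Path(life_table_path)
    if not config_path.exists():
        raise ConfigurationError(f"config file not found: {config_path}")
    if not life_table_path.exists():
        raise ConfigurationError(f"life table file not found: {life_table_path}")
    try:
        doc = _read_config_document(config_path)
    except Exception as exc:
        raise ConfigurationError(f"cannot parse {config_path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{config_path} must contain a mapping at top level")
    if "life_table" in doc:
        raise ConfigurationError(
            "life_table belongs in the CSV file, not the config document"
        )
    doc = dict(doc)
    doc["life_table"] = LifeTable.from_csv(life_table_path).model_dump()
    try:
        return ModelParams.model_validate(doc)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ConfigurationError(f"invalid model configuration: {details}") from exc


def write_model_params(
    params: ModelParams, config_path: str | Path, life_table_path: str | Path
) -> None:
    """Write the bundle back to a config document plus life-table CSV.

    Round-trip guarantee: ``load_model_params`` on the written files yields a
    bundle equal to ``params``.
    """
    config_path = Path(config_path)
    doc = params.model_dump()
    doc.pop("life_table")
    if config_path.suffix.lower() == ".json":
        config_path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        config_path.write_text(yaml.safe_dump(doc, sort_keys=False))
    params.life_table.to_csv(life_table_path)


def usd_from_brl(amount_brl: float, rate: float) -> float:
    """Convert BRL to USD at a fixed exchange rate, rounded half-up to cents.

    >>> usd_from_brl(42247.52, 5.00)
    8449.5
    """
    if not rate > 0:
        raise ValueError("exchange rate must be > 0")
    if not math.isfinite(amount_brl):
        raise ValueError("amount must be finite")
    quotient = Decimal(str(amount_brl)) / Decimal(str(rate))
    return float(quotient.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
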