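"""Patient-level annual-cycle Monte Carlo microsimulation of both arms.

Two identical cohorts of 18-year-old patients with progressive keratoconus
are followed until age 90 in one-year cycles: one arm receives corneal
collagen crosslinking (CXL) in both eyes at the outset, the other remains
untreated.  Each eye moves through ordinal visual-acuity (VA) states, may
receive a penetrating transplant, and a failed graft is immediately
regrafted.  Utilities accrue by the better eye's VA state; costs and QALYs
are discounted to the start of the simulation.

Common random numbers
---------------------
Both arms consume the *same* per-cycle event draws (one substream per
decision type — mortality, progression, transplant, graft failure,
complications — each with a fixed draw shape per cycle).  Trajectories
therefore diverge only where the CXL effect changes an outcome, which makes
the incremental comparison a low-variance paired contrast and makes the
degenerate arm (effectiveness 0 or duration 0) bit-identical to the
conventional arm apart from the cycle-0 CXL outlay.

Within a cycle the event order is fixed: mortality, then per eye graft
aging/failure, VA progression, transplant, complications, then accrual.
Patients drawn to die this cycle skip eye events but still accrue their
final cycle's cost and utility.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .parameters import ModelParams

__all__ = [
    "EngineStateError",
    "EyeState",
    "PatientState",
    "EyeDraws",
    "CycleEvents",
    "ArmResult",
    "TrialResult",
    "discount_factor",
    "init_cohort",
    "apply_cxl",
    "step_eye",
    "accrue_cycle",
    "run_trial",
]

CONVENTIONAL = "conventional"
CXL = "cxl"


class EngineStateError(RuntimeError):
    """Raised when an operation is applied in an invalid simulation state."""


@dataclass
class EyeState:
    """State of a single eye.

    ``cxl_expiry_cycle`` is ``None`` until the eye is treated; after
    treatment it holds the first cycle index at which protection has lapsed
    (treatment at cycle 0 with a 10-year effect protects cycles 0..9).
    """

    va_state: int
    transplanted: bool = False
    graft_age: int = 0
    graft_count: int = 0
    cxl_responder: bool = False
    cxl_expiry_cycle: Optional[int] = None

    @property
    def cxl_treated(self) -> bool:
        return self.cxl_expiry_cycle is not None

    def cxl_protected(self, cycle: int) -> bool:
        return (
            self.cxl_responder
            and self.cxl_expiry_cycle is not None
            and cycle < self.cxl_expiry_cycle
        )


@dataclass
class PatientState:
    age: int
    alive: bool
    eyes: list[EyeState]

    @property
    def better_eye_va(self) -> int:
        return min(e.va_state for e in self.eyes)

    @property
    def any_transplanted(self) -> bool:
        return any(e.transplanted for e in self.eyes)


@dataclass
class EyeDraws:
    """Uniform(0,1) draws consumed by one eye in one cycle.

    The defaults (1.0) never trigger an event, so a default-constructed
    ``EyeDraws`` steps the eye deterministically with no stochastic events.
    """

    progression: float = 1.0
    transplant: float = 1.0
    graft_failure: float = 1.0
    complications: Optional[Sequence[float]] = None


@dataclass
class CycleEvents:
    """Costs and transplant events booked by one eye in one cycle (pre-discount)."""

    cost: float = 0.0
    transplants: int = 0
    first_transplant: bool = False


@dataclass
class ArmResult:
    """Per-arm simulation output.

    ``cost`` and ``qaly`` are per-patient lifetime discounted totals;
    ``good_vision_fraction[t]`` is the fraction of patients alive at cycle t
    whose better eye is in the best VA state (measured after that cycle's
    events).
    """

    arm: str
    cost: np.ndarray
    qaly: np.ndarray
    total_transplants: int
    first_transplants: int
    bilateral_patients: int
    good_vision_fraction: np.ndarray

    @property
    def mean_cost(self) -> float:
        return float(np.mean(self.cost))

    @property
    def mean_qaly(self) -> float:
        return float(np.mean(self.qaly))

    @property
    def regrafts(self) -> int:
        return self.total_transplants - self.first_transplants

    def transplants_per_10k_eyes(self, n_patients: int) -> float:
        return self.total_transplants / (2 * n_patients) * 10_000.0


@dataclass
class TrialResult:
    conventional: Optional[ArmResult] = None
    cxl: Optional[ArmResult] = None

    @property
    def delta_cost(self) -> float:
        return self.cxl.mean_cost - self.conventional.mean_cost

    @property
    def delta_effect(self) -> float:
        return self.cxl.mean_qaly - self.conventional.mean_qaly


def discount_factor(cycle: int, rate: float) -> float:
    """Discount factor (1+rate)^(-cycle); cycle 0 is undiscounted."""
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must satisfy 0 <= rate < 1")
    return (1.0 + rate) ** (-cycle)


def init_cohort(params: ModelParams, seed: int) -> list[PatientState]:
    """Draw the initial cohort; the same seed yields a bit-identical cohort.

    Per-eye initial VA states are drawn from ``initial_va_marginal``.  With
    between-eye correlation rho, the second eye copies the first with
    probability rho and is drawn independently otherwise (a common-shock
    construction; rho=0, the default, gives i.i.d. eyes).
    """
    tr = params.transitions
    n = params.econ.n_patients
    rng = np.random.default_rng(seed)
    cum = np.cumsum(tr.initial_va_marginal)
    k = tr.n_va_states
    u = rng.random((n, 2))
    u_corr = rng.random(n)
    va = np.minimum(np.searchsorted(cum, u, side="right"), k - 1)
    copy_mask = u_corr < tr.initial_va_between_eye_corr
    va[copy_mask, 1] = va[copy_mask, 0]
    return [
        PatientState(
            age=params.econ.start_age,
            alive=True,
            eyes=[EyeState(va_state=int(va[i, 0])), EyeState(va_state=int(va[i, 1]))],
        )
        for i in range(n)
    ]


def apply_cxl(
    patient: PatientState, params: ModelParams, rng: np.random.Generator
) -> float:
    """Treat both eyes with CXL at cycle 0 and return the cost booked.

    Each eye's responder status is drawn once with probability
    ``effectiveness``; protection lasts ``effect_duration`` cycles.  The cost
    is the per-eye CXL cost times two, booked at cycle 0 (undiscounted).
    """
    if any(e.cxl_treated for e in patient.eyes):
        raise EngineStateError("CXL already applied to this patient")
    duration = params.cxl.effect_duration
    eff = params.cxl.effectiveness
    for eye in patient.eyes:
        eye.cxl_responder = bool(rng.random() < eff)
        eye.cxl_expiry_cycle = duration
    return 2.0 * params.costs.cxl


def step_eye(
    eye: EyeState, cycle: int, params: ModelParams, draws: EyeDraws
) -> CycleEvents:
    """Advance one eye of a living patient by one annual cycle (in place).

    Event order: (1) a grafted eye ages one year and may fail, triggering an
    immediate regraft; (2) an ungrafted eye progresses one VA category unless
    CXL-protected; (3) an ungrafted eye may receive a transplant based on its
    (post-progression) VA state; (4) in a cycle with a graft or regraft, each
    complication is drawn independently if complication costs are enabled.
    Event costs are returned pre-discount.
    """
    tr = params.transitions
    events = CycleEvents()
    grafted_this_cycle = False

    if eye.transplanted:
        eye.graft_age += 1
        schedule = tr.graft_failure_prob
        p_fail = schedule[min(eye.graft_age, len(schedule)) - 1]
        if draws.graft_failure < p_fail:
            # Immediate regraft: cost booked, graft age reset, VA restored.
            events.cost += params.costs.transplant
            events.transplants += 1
            eye.graft_count += 1
            eye.graft_age = 0
            eye.va_state = tr.post_transplant_va
            grafted_this_cycle = True
    else:
        if not eye.cxl_protected(cycle):
            if draws.progression < tr.progression_prob[eye.va_state]:
                eye.va_state += 1
        if draws.transplant < tr.transplant_prob[eye.va_state]:
            events.cost += params.costs.transplant
            events.transplants += 1
            events.first_transplant = True
            eye.transplanted = True
            eye.graft_count = 1
            eye.graft_age = 0
            eye.va_state = tr.post_transplant_va
            grafted_this_cycle = True

    if (
        grafted_this_cycle
        and params.include_complication_costs
        and draws.complications is not None
    ):
        for entry, u in zip(params.complications.entries, draws.complications):
            if u < entry.probability:
                events.cost += entry.cost_point
    return events


def accrue_cycle(
    patient: PatientState, cycle: int, params: ModelParams, event_cost: float = 0.0
) -> tuple[float, float]:
    """Discounted (cost, utility) accrued by one patient this cycle.

    Utility is the better-eye utility; the maintenance cost is the transplant
    follow-up cost if any eye is grafted, else the routine consultation cost.
    Event costs booked this cycle are discounted with the same factor.  Dead
    patients accrue (0, 0).
    """
    if not patient.alive:
        return 0.0, 0.0
    disc = discount_factor(cycle, params.econ.discount_rate)
    maintenance = (
        params.costs.transplant_followup_annual
        if patient.any_transplanted
        else params.costs.routine_annual
    )
    utility = params.utilities.utility_by_better_eye_va[patient.better_eye_va]
    return (maintenance + event_cost) * disc, utility * disc


@dataclass
class _ArmAccumulator:
    n: int
    n_cycles: int
    cost: np.ndarray = field(init=False)
    qaly: np.ndarray = field(init=False)
    total_tx: int = 0
    first_tx: int = 0
    good_fraction: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.cost = np.zeros(self.n)
        self.qaly = np.zeros(self.n)
        self.good_fraction = np.full(self.n_cycles, np.nan)


def run_trial(
    params: ModelParams,
    seed: int,
    arms: Sequence[str] = (CONVENTIONAL, CXL),
) -> TrialResult:
    """Run one first-order microsimulation trial of the requested arms.

    Both arms start from a bit-identical cohort and consume the same event
    draws (common random numbers); mortality follows the life table at the
    patient's current age.  Fully deterministic given ``(params, seed)``.
    """
    econ = params.econ
    n = econ.n_patients
    n_cycles = econ.n_cycles
    n_comp = len(params.complications.entries)

    ss = np.random.SeedSequence(seed)
    init_ss, cxl_ss, death_ss, prog_ss, tx_ss, graft_ss, comp_ss = ss.spawn(7)
    init_seed = int(init_ss.generate_state(1)[0])

    base = init_cohort(params, init_seed)
    cohorts: dict[str, list[PatientState]] = {}
    for arm in arms:
        if arm not in (CONVENTIONAL, CXL):
            raise ValueError(f"unknown arm {arm!r}")
        cohorts[arm] = copy.deepcopy(base)
    accums = {arm: _ArmAccumulator(n, n_cycles) for arm in cohorts}

    if CXL in cohorts:
        rng_cxl = np.random.default_rng(cxl_ss)
        acc = accums[CXL]
        for i, patient in enumerate(cohorts[CXL]):
            acc.cost[i] += apply_cxl(patient, params, rng_cxl)

    rng_death = np.random.default_rng(death_ss)
    rng_prog = np.random.default_rng(prog_ss)
    rng_tx = np.random.default_rng(tx_ss)
    rng_graft = np.random.default_rng(graft_ss)
    rng_comp = np.random.default_rng(comp_ss)

    draw_complications = params.include_complication_costs and n_comp > 0
    qx_by_cycle = [
        params.life_table.qx_at(econ.start_age + t) for t in range(n_cycles)
    ]

    for t in range(n_cycles):
        qx = qx_by_cycle[t]
        u_death = rng_death.random(n)
        u_prog = rng_prog.random((n, 2))
        u_tx = rng_tx.random((n, 2))
        u_graft = rng_graft.random((n, 2))
        u_comp = rng_comp.random((n, 2, n_comp)) if draw_complications else None

        for arm, cohort in cohorts.items():
            acc = accums[arm]
            alive_at_start = 0
            good = 0
            for i, patient in enumerate(cohort):
                if not patient.alive:
                    continue
                alive_at_start += 1
                dying = u_death[i] < qx
                event_cost = 0.0
                if not dying:
                    for j, eye in enumerate(patient.eyes):
                        draws = EyeDraws(
                            progression=u_prog[i, j],
                            transplant=u_tx[i, j],
                            graft_failure=u_graft[i, j],
                            complications=u_comp[i, j] if u_comp is not None else None,
                        )
                        ev = step_eye(eye, t, params, draws)
                        event_cost += ev.cost
                        acc.total_tx += ev.transplants
                        acc.first_tx += ev.first_transplant
                cost, utility = accrue_cycle(patient, t, params, event_cost)
                acc.cost[i] += cost
                acc.qaly[i] += utility
                if patient.better_eye_va == 0:
                    good += 1
                if dying:
                    patient.alive = False
                else:
                    patient.age += 1
            acc.good_fraction[t] = good / alive_at_start if alive_at_start else np.nan

    result = TrialResult()
    for arm, cohort in cohorts.items():
        acc = accums[arm]
        bilateral = sum(1 for p in cohort if all(e.transplanted for e in p.eyes))
        arm_result = ArmResult(
            arm=arm,
            cost=acc.cost,
            qaly=acc.qaly,
            total_transplants=acc.total_tx,
            first_transplants=acc.first_tx,
            bilateral_patients=bilateral,
            good_vision_fraction=acc.good_fraction,
        )
        setattr(result, arm, arm_result)
    return result
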