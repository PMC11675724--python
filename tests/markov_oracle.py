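"""Independent analytic oracle for the microsimulation engine.

Computes the exact expected discounted cost and QALYs of the *conventional*
arm of a small model by iterating the patient-level Markov chain
distribution: the patient state is the ordered pair of independent eye
states, an eye state is its VA category or 'transplanted' (absorbing when
graft failure is zero), and mortality is an age-dependent exit.

The recursion mirrors the engine's accrual convention: mortality is drawn at
cycle start; a dying patient skips eye events but accrues the cycle at the
pre-step state; survivors step both eyes and accrue at the post-step state,
including the expected transplant event cost.  All rewards at cycle t carry
the discount factor (1+r)^-t.
"""

from __future__ import annotations

import numpy as np

from cxlsim.parameters import ModelParams


def _eye_chain(params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-eye transition matrix over states 0..K-1 plus K='transplanted',
    and the expected number of transplant events per step from each state.

    Valid only when graft_failure_prob is all zero (transplant absorbing).
    """
    tr = params.transitions
    assert all(p == 0.0 for p in tr.graft_failure_prob), "oracle needs absorbing grafts"
    k = tr.n_va_states
    m = np.zeros((k + 1, k + 1))
    tx_events = np.zeros(k + 1)
    for s in range(k):
        p_prog = tr.progression_prob[s]
        # progression first, then the transplant draw at the post-progression state
        for s2, w in ((s, 1.0 - p_prog), (min(s + 1, k - 1), p_prog)):
            if w == 0.0:
                continue
            p_tx = tr.transplant_prob[s2]
            m[s, k] += w * p_tx
            m[s, s2] += w * (1.0 - p_tx)
            tx_events[s] += w * p_tx
    m[k, k] = 1.0
    return m, tx_events


def expected_costs_and_qalys(params: ModelParams) -> tuple[float, float]:
    """Exact per-patient expected discounted (cost, QALYs), conventional arm."""
    tr = params.transitions
    econ = params.econ
    k = tr.n_va_states
    m_eye, tx_eye = _eye_chain(params)
    n_eye = k + 1

    # ordered pair of independent eyes
    m_pair = np.kron(m_eye, m_eye)
    n_pair = n_eye * n_eye

    def va_of(s: int) -> int:
        return tr.post_transplant_va if s == k else s

    utility = np.zeros(n_pair)
    maintenance = np.zeros(n_pair)
    tx_rate = np.zeros(n_pair)
    for s1 in range(n_eye):
        for s2 in range(n_eye):
            idx = s1 * n_eye + s2
            utility[idx] = params.utilities.utility_by_better_eye_va[
                min(va_of(s1), va_of(s2))
            ]
            maintenance[idx] = (
                params.costs.transplant_followup_annual
                if (s1 == k or s2 == k)
                else params.costs.routine_annual
            )
            tx_rate[idx] = tx_eye[s1] + tx_eye[s2]

    init_eye = np.zeros(n_eye)
    init_eye[:k] = tr.initial_va_marginal
    pi = np.kron(init_eye, init_eye)  # alive mass over pair states

    rate = econ.discount_rate
    total_cost = 0.0
    total_qaly = 0.0
    for t in range(econ.n_cycles):
        qx = params.life_table.qx_at(econ.start_age + t)
        disc = (1.0 + rate) ** (-t)
        stepped = pi @ m_pair
        # dying patients accrue pre-step, survivors post-step (with event costs)
        total_qaly += disc * (qx * pi @ utility + (1.0 - qx) * stepped @ utility)
        total_cost += disc * (
            qx * pi @ maintenance
            + (1.0 - qx)
            * (stepped @ maintenance + params.costs.transplant * pi @ tx_rate)
        )
        pi = (1.0 - qx) * stepped
    return float(total_cost), float(total_qaly)
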