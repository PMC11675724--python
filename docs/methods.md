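# Methods

## Model structure

`cxlsim` implements a patient-level (first-order Monte Carlo) state-transition
model in annual cycles. The unit of simulation is the patient; each patient
carries two eye records. Eye state is an ordinal visual-acuity (VA) category
0..K−1 (0 best, default K = 4) plus a grafted flag, graft age, graft count,
and CXL responder/expiry fields. The model deliberately stays ordinal: VA
cut-points in logMAR/Snellen units are not modeled, only ordered categories,
which is what the better-eye utility accrual and "good vision" reporting
need.

Cycle order is fixed and documented rather than configurable, because event
ordering is otherwise a silent source of irreproducibility:

1. **Mortality.** One uniform per patient against the life-table `qx` at the
   patient's current age. A patient drawn to die skips eye events but still
   accrues the cycle's cost and utility, then dies at cycle end. (With
   `qx = 1` at the start age the cohort accrues exactly one cycle — the
   boundary case that pins the convention.)
2. **Graft aging and failure** per grafted eye: failure probability
   `graft_failure_prob[min(graft_age, len) - 1]`, i.e. a graft-age schedule
   whose last entry applies to all older grafts. A failed graft is regrafted
   immediately in the same cycle (transplant cost booked, graft count
   incremented, VA restored to `post_transplant_va`). No cap on regrafts and
   no upper age limit for surgery.
3. **Progression** per ungrafted eye, one category per year with
   `progression_prob[v]`, suppressed entirely while the eye is a CXL
   responder within the effect window. Non-responders (1% at default
   effectiveness) progress as untreated from cycle 0. After the effect
   lapses the eye resumes untreated progression from its current state; no
   retreatment is modeled.
4. **Transplant** per ungrafted eye with `transplant_prob[v]` evaluated at
   the post-progression state. The default confines transplant risk to the
   worst VA state; the vector form leaves it configurable.
5. **Complications.** In a cycle with a graft or regraft, each complication
   in the table is drawn independently and its cost booked — only when
   `include_complication_costs` is enabled. The baseline scenario keeps it
   off (minimum-cost, most conservative reading); the tornado analysis
   enables it, which is where complication costs belong in the source
   analysis.
6. **Accrual.** Utility is `utility[min_e v_e]` (better-eye rule; a grafted
   eye counts at `post_transplant_va`). The maintenance cost is the
   transplant follow-up cost if any eye is grafted (the "tripling rule":
   3 × routine when unset), else the routine consultation cost — follow-up
   *replaces* routine at the patient level; consultations are read as
   per-patient, procedures as per-eye. Cost and utility are discounted by
   `(1+r)^(-t)`; cycle 0 is undiscounted. There is no half-cycle correction:
   with annual cycles over a 72-year horizon the correction is a uniform
   ~2.5% level shift on both arms that nearly cancels in the increments,
   and omitting it keeps the accrual identities exact.

CXL is applied to both eyes at cycle 0 in the treatment arm only:
responder status drawn once per eye (probability `effectiveness`, default
0.99), protection for `effect_duration` cycles (default 10), cost
2 × 78.52 USD booked at cycle 0.

## Common random numbers

Both arms are stepped from a bit-identical initial cohort and consume the
same event draws. Each decision type (mortality, progression, transplant,
graft failure, complications) has its own seeded substream with a fixed
draw shape per cycle — `n` or `n × 2` (× number of complications) uniforms —
so draw alignment between arms cannot drift no matter which events fire.
Responder draws use a separate substream touched only by the CXL arm.
Consequences, both verified by tests: with an ineffective treatment
(effectiveness 0 or duration 0) the two arms produce *identical* per-patient
QALY vectors and a cost difference of exactly the cycle-0 outlay; and the
incremental comparison is a paired contrast with much smaller variance than
independent arms would give. This is why the engine derives all streams
from the trial seed alone rather than from (seed, arm).

## Parameters

| parameter | default | units | provenance |
|---|---|---|---|
| discount rate | 0.05 | /yr | published |
| WTP | 8449.50 (1× GDP pc; upper bound 25,348.51) | USD/QALY | published |
| exchange rate | 5.00 | BRL/USD | published |
| cohort | 5000 patients, ages 18→90 | — | published |
| routine consultation | 19.98 | USD/yr | published |
| CXL procedure | 78.52 | USD/eye | published |
| penetrating transplant | 414.00 | USD/event | published |
| transplant follow-up | 59.94 (3× routine) | USD/yr | published |
| complication table | six entries, probabilities 0.38–4.6% | USD ranges | published |
| CXL effectiveness / duration | 0.99 / 10 | — / yr | published |
| progression prob. | 0.06, 0.07, 0.08, 0 | /yr by VA state | synthetic |
| transplant prob. | 0, 0, 0, 0.06 | /yr by VA state | synthetic |
| graft failure | 0.012, 0.01, 0.008, 0.006, 0.003 | /yr by graft age | synthetic |
| utilities | 0.92, 0.84, 0.73, 0.60 | per cycle | synthetic |
| life table | Gompertz–Makeham a=5e-4, b=6e-5, c=1.094 | qx /yr | synthetic |
| initial VA marginal | calibrated, p₀ = 1−√0.201 ≈ 0.552 | — | synthetic |

Every bundle records these labels in `ModelParams.provenance` so reports can
disclose which inputs are stand-ins.

## What the synthetic generator emulates — and what it does not

The generator reproduces the *structure* the published analysis describes,
not its unpublished numbers:

* **Life table**: qx = 1 − exp(−(a + b·cᵃᵍᵉ)), strictly increasing, ~8×10⁻⁴
  at 18 and ~0.18 at 90 — a plausible middle-income national table, not the
  2022 IBGE table itself.
* **Initial VA**: per-eye mass on the best state solves 1−(1−p)² = 0.799 so
  that 79.9% of patients start with good vision in at least one eye
  (i.i.d. eyes by default; a common-shock correlation knob
  `initial_va_between_eye_corr` is exposed, and nonzero values deliberately
  shift the two-eye fraction — the calibration assumes independence). The
  residual mass decreases geometrically (ratio 0.6) over worse states.
* **Dynamics**: calibrated once so the conventional arm sees roughly
  three-quarters of its 10,000 eyes transplanted over a lifetime (counting
  regrafts), the CXL arm distinctly fewer, and the incremental cost is
  mildly positive — the same regime as the published result (a positive,
  very small ICER rather than dominance).

Passing tests under these defaults therefore demonstrate that the
machinery — transition logic, accrual identities, discounting, paired
design, CEA layer, PSA and tornado plumbing — is correct, and that the
qualitative conclusions (positive INMB at 1× GDP per capita, fewer
transplants with CXL, effect duration as the dominant sensitivity) are
robust in this regime. They do **not** validate the published magnitudes
(ICER 58.26 USD/QALY, the per-capita cost/QALY table, 84.1% vs 72.8% good
vision at year 10): those depend on transition inputs that are cited from
earlier keratoconus Markov models but not printed, and `cxlsim` makes no
attempt to reverse-engineer them.

## Cost-effectiveness layer

* ICER is the ratio of mean increments (never a mean of per-sample ratios);
  quadrant guards return `dominant` / `dominated` / `undefined` instead of
  dividing by a non-positive effect increment.
* Summary tables report mean, SD (n−1), min, median (midpoint for even n),
  max, and a normal-approximation 95% CI (mean ± 1.96·SD/√n) over whatever
  samples are summarized — per-patient values for a base-case run,
  per-simulation means for a PSA. `n` is always the number of samples
  actually summarized.
* CEAC: fraction of incremental samples with ΔE·λ − ΔC > 0 on a grid of 0 to
  3× GDP per capita (100 points) by default.
* INMB is computed per sample and averaged; by linearity it equals the
  difference of mean NMBs to machine precision (asserted in tests).

## Sensitivity analysis

**PSA** (second order): beta distributions for probabilities, with the SD
set to 10% of min(p, 1−p) by method of moments — the boundary-respecting
reading of a "10% relative SD" convention that keeps distributions for
near-certain events (e.g. effectiveness 0.99) unimodal and inside [0, 1] by
construction; gamma for costs (20% relative SD); uniform over the printed
cost ranges for ranged complications; discrete uniform over 5..15 years for
the CXL effect duration. Utilities are *not* sampled by default: independent
marginals cannot guarantee the non-increasing ordinal profile, and sampled
bundles are revalidated rather than clipped, so an ordering violation is an
error by design. Users can supply their own (e.g. decrement-parameterized)
utility distributions. All PSA samples share one first-order seed, so
between-sample spread is parameter uncertainty only; each sampled bundle is
fully revalidated before use.

**Tornado**: each parameter evaluated at its low/high extreme with the rest
at base and a common first-order seed, ranked by |INMB_high − INMB_low|,
ties broken by name. Shipped ranges: effect duration 5 years to lifetime
(72 years), effectiveness 0.90–1.0, ±25% on costs and transition
probabilities, and the printed complication cost ranges. The tornado base
scenario enables complication costs (they exist for exactly this analysis);
the `run`/`psa` baseline keeps them off.

## Numerical and degenerate-input choices

* Seeds: a single integer seed drives a `SeedSequence` tree; per-purpose
  substreams are spawned children, so adding an arm or a decision type never
  perturbs the others' draws.
* Validation is total and front-loaded: probabilities in [0,1], worst state
  cannot progress, the initial marginal sums to 1 within 1e−9, the life
  table must contiguously cover the simulated ages (errors name the first
  missing age), K must agree between transitions and utilities.
* Currency conversion rounds half-up to cents via decimal arithmetic (so
  42,247.52 BRL / 5.00 = 8449.50 exactly, and 1.005 → 1.01 rather than
  banker's 1.00).
* The empty graft-failure schedule, inverted ranges, unresolvable parameter
  paths, <2 summary samples, and empty CEAC inputs all raise immediately
  with named errors rather than propagating NaNs.

## Problem sizes

Default cohort size mirrors the source analysis (5000 patients; 1000-sample
PSA). The shipped tests and the acceptance script use desk-scale sizes —
5000 patients for the single-run oracle and calibration checks, 2000 for
the base case, 50 × 200 for the PSA, 200 patients per tornado evaluation —
chosen so the whole suite runs in well under a minute on one core while
keeping Monte-Carlo error far smaller than the effects being asserted.

## Known limitations

* Transition inputs are synthetic; absolute outputs are illustrative.
* No retreatment of CXL non-responders; no intracorneal ring segments,
  epithelium-on CXL, CXL-plus, lens provision, medication, or indirect
  costs — all outside the payer perspective modeled.
* Whether consultations are per eye or per patient is not settled by the
  source tables; per-patient is the package's reading, and the cost
  parameters are exposed for sensitivity analysis on that choice.
* The better-eye utility rule ignores any residual disutility of a bad
  fellow eye.
* First-order (sampling) and second-order (parameter) uncertainty are the
  only stochastic layers; no structural uncertainty analysis.
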