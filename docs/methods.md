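# Methods

## Scope and units

`citradose` models citrate-anticoagulated therapeutic plasma exchange on a
Ci-Ca pump module: circuit flow balance, the hematocrit-aware citrate dose
equations, the regression pipeline that turns paired session observations
into an individualized cubic dose curve, a safety/monitoring layer, and a
mechanistic simulator that generates synthetic patients and whole sessions.
Internally all concentrations are mmol/L, flows mL/min, times minutes,
pressures mmHg, hematocrit a fraction; the CLI converts percent hematocrit
and reports pump rates in both mL/min and mL/h.

## Circuit model

The effluent pump is slaved to the sum of the substitution, citrate and
calcium pumps, so the circuit is volume-neutral by construction
(`balance_effluent`). Citrate enters pre-filter as predilution; calcium
returns post-filter and is therefore excluded from filter inflow but
included in the effluent slaving. Two filtration-fraction conventions are
exposed: substitution flow over patient plasma flow (which reproduces the
headline 25–32% range over hematocrit 0.20–0.375 at blood flow 200 and
substitution 40 mL/min) and effluent over filter inflow. The first is the
default. Note the second is *larger* whenever predilution runs with no
calcium return — `(sub+ci)/(plasma+ci) > sub/plasma` for `sub < plasma` —
because the slaved effluent removes the predilution volume again; the two
coincide without predilution. Citrate leaves the filter convectively with a
sieving coefficient of 1.0 by default (small solute); single-pass removal at
cohort-typical settings is ≈0.30, which is why TPE-RCA carries a systemic
citrate load.

## Dose model

The pipeline has three stages:

1. **Conversion.** `pCi = WBCi/(1−Ht)`: citrate distributes in plasma only.
2. **Preliminary linear protocol.** `pCi = 4.6 · pCai(t0)` — the empirical
   constant ratio of plasma citrate to pre-treatment ionized calcium.
3. **Final cubic protocol.** The requirement per chelated millimole,
   `q = pCi/ΔCai` with `ΔCai = pCai(t0) − cCai(t5)`, is regressed on
   `pCai(t0)` as a quadratic by pooled OLS over sessions whose `cCai(t5)`
   lies in the therapeutic window 0.24–0.33 mmol/L (out-of-window sessions
   are excluded and reported). Setting the target circuit calcium to the
   window midpoint, stored on the curve as `anchor_ccai` (default 0.285,
   always the configured-window midpoint rather than a hard-coded constant),
   yields `pCi(x) = q(x)·(x − anchor)` and, after hematocrit scaling, the
   whole-blood prescription.

The quadratic's coefficients are never shipped as constants: the curve is
always derived from data (site data or the synthetic calibration), persisted
as JSON together with its R², point counts and fitted domain. Doses
requested outside the fitted domain are computed but flagged with an
extrapolation warning (calibration data are sparse at high calcium);
negative doses (pCai below the anchor) clamp to zero with a warning.

Supporting operations: window classification with inclusive endpoints
(failures in the source definitions are strict inequalities on both sides);
a one-step curve-based dose adaptation (`Δpci = q(pcai0)·(observed −
anchor)`, whole-blood step capped at ±1.2 mmol/L — the adaptation rule in
the source protocol is descriptive only, so a deterministic, conservative
Newton-style step was chosen); and affine per-site ionometer recalibration,
since many ionometers are not validated in the low circuit-calcium range.

A pooled fit was chosen over per-patient fits: the per-patient variant in
the source is a visualization of the same relation, and pooled OLS is the
estimator that the available (session-level) synthetic data identify. The
massic-flow representation (concentrations × plasma inflow) is provided as a
reporting view (`to_massic_points`) of the identical regression, not a
second model.

## Simulator mechanism

The simulator is engineered to reproduce the empirical structure the dosing
model relies on; it is a synthetic stand-in, not a physiological claim.

**Circuit chelation equilibrium.** Plasma citrate `L` binds ionized calcium
1:1 with effective dissociation constant `kd` (default 0.5 mmol/L). The
calcium actually chelated exceeds the observed ionized drop by a
buffer-release factor `β(c0)` (quadratic in the pre-treatment ionized
calcium `c0`): protein-bound stores release calcium as the ionized level
falls, relatively more in hypercalcemic plasma. The circuit calcium `x`
solves `β(c0)·(c0−x)·(kd+x) = L·x`, a quadratic with one positive root
(solved in the numerically stable product form). Limits: `L=0 → x=c0`,
`L→∞ → x→0`.

**Calibration.** `calibrate_chelation` pins `β` so that (a) plasma citrate
4.6 mmol/L at `c0 = 1.0` yields exactly `x = 0.285`, and (b) the implied
requirement curve `q(c) = pci_required(c)/(c−0.285) = β(c)·(kd+anchor)/anchor`
is strictly decreasing on the physiological domain. The curvature is taken
from the constant-ratio heuristic `g(c) = 4.6·c/(c−0.285)` — what a constant
plasma-citrate-to-calcium ratio implies per *chelated* millimole, itself a
decreasing function — interpolated at c ∈ {0.85, 1.0, 1.25}. Because `β` is
quadratic in `c`, the mechanism's requirement curve is exactly a quadratic,
so the regression pipeline recovers it to machine precision from noise-free
sessions and the dose→simulate→observe loop closes exactly at the anchor.
(An earlier design with `β(c) = β0 + β1/c` was discarded: its requirement
curve is not representable by the quadratic the dose model fits, which
breaks closed-loop exactness by construction.) Infeasible calibration
targets raise with diagnostics.

**Cohort generation.** Deterministic in the seed: hematocrit uniform on
0.22–0.40, pre-treatment ionized calcium normal(1.0, 0.1) truncated to
[0.6, 1.5] mmol/L (the source cohort spans 0.83–1.27 with mean 1.00 ± 0.1),
weight uniform 55–90 kg, total calcium offset +1.04 mmol/L over ionized, and
a lognormal per-patient citrate-sensitivity multiplier with σ =
`response_noise_sd` (default 0.10) that scales `β` — i.e. multiplicative
noise on the citrate requirement.

**Session integration** (1-minute steps, deterministic):

* *Circuit leg:* the chelation equilibrium is evaluated on the prescribed
  plasma citrate against the session's **pre-treatment** ionized calcium —
  the clinical 5-minute feedback signal is referenced to the pre-treatment
  state, and intra-session drift of circuit inflow calcium is second-order.
  Modelling that drift would also break the exact closed-loop property the
  test bed needs.
* *Systemic citrate:* one compartment of volume 0.25 L/kg, input = infused
  citrate net of single-pass effluent removal plus the FFP citrate in the
  replacement mix, first-order elimination with half-life 35 min (external
  pharmacokinetic knowledge; configurable).
* *Systemic calcium:* a perturbation model around the pre-treatment state —
  a citrate-free, calcium-free exchange is calcium-neutral by convention
  (replacement is assumed calcium-matched at baseline), so the tracked
  fluxes are the calcium pump (slaved at 2.0 mmol per litre of effluent via
  a 100 mmol/L Ca/Mg solution, Mg:Ca 0.36), replacement-fluid calcium (FFP
  2.2 mmol/L), and the citrate-induced excess effluent loss
  `q_eff·(ccai + β·(c0−ccai) − c0)`. Cumulative in/out/pool ledgers close to
  float precision (the mass-balance invariant). Systemic ionized calcium
  partitions the pool against systemic citrate with a weaker effective
  dissociation constant (5.0 mmol/L): systemically, competing binding and
  continuous buffer mobilization blunt chelation relative to the 5-minute
  circuit transit. Total calcium is the pool plus the fixed protein-bound
  offset, which makes the accumulation ratio rise as citrate and calcium
  load in — by ~0.4–0.6 mmol/L total calcium per session at FFP-heavy
  settings, the same magnitude as the source cohort's pre/post shift.
* *Acid–base:* each metabolized millimole of alkali-carrying citrate yields
  3 mmol bicarbonate (weighted by the citric-acid fraction of ACD-A, 0.66
  alkali by default, vs 1.0 for FFP citrate) into a 0.5 L/kg space; pH via
  Henderson–Hasselbalch at fixed pCO₂ 40 mmHg (no respiratory
  compensation).
* *Clotting proxy:* TMP starts at 100 mmHg and rises 1 mmHg/min while the
  circuit calcium is ≥ 0.35 mmol/L; a rise beyond 100 mmHg terminates the
  session early (treatment failure). Deterministic by design for
  reproducibility.

Measurements are emitted at 5/30/60/90 min and end of treatment, plus any
extra requested times.

**Virtual trials** dose a cohort under a policy — fixed whole-blood dose,
preliminary linear, or final cubic — simulate every session, and aggregate
in-window counts, hypocalcemia, PTF/TF, accumulation ratio and bicarbonate
shift. At the study conditions (38 sessions, 10% noise) the final protocol
keeps ~34–36 of 38 sessions in window, versus ~25 for a fixed 3.6 mmol/L
dose, and the bicarbonate shift grows monotonically with the FFP fraction.

## Safety layer

Thresholds: hypocalcemia < 0.85 mmol/L systemic ionized calcium (with an
optional symptoms flag separating biochemical from symptomatic events);
citrate accumulation at total/ionized ratio strictly > 2.5; clotting threat
at circuit calcium ≥ 0.35; PTF at a TMP rise strictly > 50 mmHg with the
session completed; TF when the session terminates early (early termination
dominates TMP magnitude). The calcium-titration band table is a
**reconstructed** default (< 0.85 large step up; 0.85–0.99 small step up;
1.00–1.20 hold; > 1.20 step down) — the original supplementary step tables
are not reproduced, so the algorithm slot is configurable site policy.
Checks whose inputs are missing report "not evaluable" instead of failing.
Audit percentages are `100·count/total` rounded to one decimal.
FFP-heavy-plan advisories (blood flow 120–150 mL/min, replacement ≤
1600 mL/h) are linter warnings, not hard constraints.

## Numerical choices

Quadratic/affine fits use `numpy.linalg.lstsq` / `polyfit`; rank-deficient
designs (all pCai0 equal) raise. R² is clipped to [0, 1]. The equilibrium
root uses the subtraction-free quadratic form. Window boundaries classify as
in-range; accumulation and PTF thresholds are strict. Fitting requires ≥ 4
in-window points with positive calcium drop. All randomness flows through
one `numpy.random.Generator` seeded per run; sessions are bit-reproducible
given (seed, inputs).

## What passing tests do and do not show

The simulator reproduces the *structure* the dosing model exploits — the
4.6 anchor ratio, the decreasing requirement curve, in-window improvement of
individualized over fixed dosing, bicarbonate proportional to FFP volume,
single-pass citrate removal ≤ ~30% — under idealized conditions: stationary
circuit chemistry, one noise source, deterministic TMP, no inter-session
kinetics (multi-day bicarbonate drift under daily FFP-heavy exchanges
depends on unmodelled renal handling and is out of scope), no magnesium
physiology, no pressure hydraulics. Passing tests therefore validate the
pipeline's internal consistency and its behaviour under the stated synthetic
conditions, not clinical performance; the clinical cohort's regression
R² = 0.723 is a property of its data and is represented here only by the
analogous noisy-fit checks. Local, prospective validation remains a
prerequisite for any clinical use.
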