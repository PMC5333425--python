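"""Mechanistic simulator of Ci-Ca plasma-exchange sessions.

This module is the synthetic test bed for the dosing pipeline. Its core is a
minimal calcium-citrate chelation equilibrium with a hypocalcemia-dependent
buffer-release factor:

* In the circuit, plasma citrate ``L`` binds ionized calcium with an
  effective 1:1 dissociation constant ``kd``; the calcium made available for
  chelation exceeds the observed ionized drop by a factor ``beta(c0)``
  (protein-bound stores release calcium as the ionized level falls, and they
  release relatively more in hypocalcemic plasma). The circuit ionized
  calcium ``x`` solves

      beta(c0) * (c0 - x) * (kd + x) = L * x,

  a quadratic with a unique positive root.
* ``beta`` is quadratic in the pre-treatment ionized calcium and is
  *calibrated*, not asserted: :func:`calibrate_chelation` pins the anchor
  case (plasma citrate 4.6 mmol/L at pCai 1.0 mmol/L gives circuit calcium
  0.285 mmol/L) and shapes the curvature from the constant-ratio heuristic
  ``pCi = 4.6 * pCai0``, which already implies a citrate-per-chelated-calcium
  ratio that falls with pCai0. With this construction the mechanism's implied
  requirement curve is itself a quadratic, so the regression pipeline can
  recover it exactly from noise-free sessions.

Systemic kinetics are a single citrate compartment with first-order
elimination, a perturbation model of the systemic calcium pool (a citrate- and
calcium-free exchange is calcium-neutral by convention), bicarbonate gain from
metabolized alkali-carrying citrate, and a deterministic TMP proxy for
clotting risk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .circuit import (
    balance_effluent,
    citrate_pump_rate,
    single_pass_citrate_removal,
)
from .domain import (
    ACD_A,
    ALBUMIN_5,
    CALCIUM_MAGNESIUM,
    DEFAULT_TARGET_WINDOW,
    CircuitSettings,
    Measurement,
    PatientState,
    Prescription,
    Protocol,
    SessionRecord,
    Solution,
)
from .dosing import (
    DoseResponsePoint,
    RatioCurve,
    final_whole_blood_dose,
    fit_ratio_curve,
    plasma_citrate_from_whole_blood,
    preliminary_whole_blood_dose,
)

__all__ = [
    "ChelationParams",
    "SimConfig",
    "SyntheticPatient",
    "circuit_equilibrium",
    "pci_required",
    "calibrate_chelation",
    "implied_ratio_curve",
    "calibration_curve",
    "generate_cohort",
    "generate_dose_response_points",
    "build_settings",
    "simulate_session",
    "FixedDose",
    "PreliminaryProtocol",
    "FinalProtocol",
    "TrialSummary",
    "run_virtual_trial",
]

#: Measurement schedule, minutes from session start (plus end of treatment).
MEASUREMENT_SCHEDULE = (5.0, 30.0, 60.0, 90.0)


@dataclass(frozen=True)
class ChelationParams:
    """Calibrated parameters of the circuit chelation equilibrium.

    ``beta(c) = beta0 + beta1*c + beta2*c**2`` is the buffer-release factor:
    the chelated calcium per unit of observed ionized drop at pre-treatment
    ionized calcium ``c`` (mmol/L). ``kd`` is the effective citrate-calcium
    dissociation constant (mmol/L); ``anchor`` is the circuit ionized calcium
    the calibration targeted.
    """

    kd: float
    beta0: float
    beta1: float = 0.0
    beta2: float = 0.0
    anchor: float = 0.285

    def beta(self, c) -> np.ndarray | float:
        c = np.asarray(c, dtype=float)
        out = self.beta0 + self.beta1 * c + self.beta2 * c**2
        return float(out) if out.ndim == 0 else out


def circuit_equilibrium(
    pcai0: float, pci: float, params: ChelationParams, sensitivity: float = 1.0
) -> float:
    """Circuit ionized calcium at chelation equilibrium, mmol/L.

    Solves ``beta_eff * (c0 - x) * (kd + x) = L * x`` for the unique root in
    ``(0, c0]``, with ``beta_eff = sensitivity * beta(c0)``. A sensitivity
    above 1 means the patient needs more citrate than the population curve
    predicts (relative citrate resistance).
    """
    if pcai0 < 0 or pci < 0:
        raise ValueError("pcai0 and pci must be non-negative")
    if pcai0 == 0:
        return 0.0
    bm = sensitivity * params.beta(pcai0)
    if bm <= 1e-12:
        return 0.0 if pci > 0 else pcai0
    # bm*x^2 + (L + bm*(kd - c0))*x - bm*c0*kd = 0; stable positive root.
    b = pci + bm * (params.kd - pcai0)
    disc = b * b + 4.0 * bm * bm * pcai0 * params.kd
    x = 2.0 * bm * pcai0 * params.kd / (b + math.sqrt(disc))
    return min(x, pcai0)


def pci_required(
    pcai0: float,
    params: ChelationParams,
    target_ccai: Optional[float] = None,
    sensitivity: float = 1.0,
) -> float:
    """Plasma citrate needed to bring the circuit calcium to ``target_ccai``.

    Closed-form inverse of :func:`circuit_equilibrium`:
    ``L = beta_eff * (c0 - x) * (kd + x) / x`` at ``x = target``.
    """
    x = params.anchor if target_ccai is None else target_ccai
    if not 0 < x <= pcai0:
        raise ValueError("target_ccai must lie in (0, pcai0]")
    bm = sensitivity * params.beta(pcai0)
    return bm * (pcai0 - x) * (params.kd + x) / x


def calibrate_chelation(
    target_ratio: float = 4.6,
    anchor: float = 0.285,
    at_pcai0: float = 1.0,
    kd: float = 0.5,
    knots: tuple[float, float] = (0.85, 1.25),
    monotone_domain: tuple[float, float] = (0.8, 1.4),
) -> ChelationParams:
    """Calibrate the chelation mechanism to the anchor dosing case.

    The buffer-release factor is constructed so that

    * ``circuit_equilibrium(at_pcai0, target_ratio * at_pcai0) == anchor``
      (the anchor case: 4.6 mmol/L plasma citrate at pCai 1.0 gives a
      circuit calcium of 0.285), and
    * the implied requirement curve ``q(c) = pci_required(c) / (c - anchor)``
      is strictly decreasing on ``monotone_domain`` (higher pre-treatment
      calcium needs relatively less citrate; pre-treatment hypocalcemia means
      relative citrate resistance).

    The curvature comes from interpolating the constant-ratio heuristic
    ``g(c) = target_ratio * c / (c - anchor)`` at the two ``knots`` and at
    ``at_pcai0``; ``g`` is what a constant plasma-citrate-to-calcium ratio
    implies for the requirement per *chelated* millimole, and it is already a
    decreasing function of ``c``.
    """
    nodes = np.array([knots[0], at_pcai0, knots[1]], dtype=float)
    if len(set(nodes.tolist())) != 3:
        raise ValueError("knots and at_pcai0 must be three distinct abscissae")
    g = target_ratio * nodes / (nodes - anchor)
    # q(c) interpolating quadratic, low order first
    qc = np.linalg.solve(np.vander(nodes, 3, increasing=True), g)
    scale = anchor / (kd + anchor)
    params = ChelationParams(
        kd=kd,
        beta0=float(qc[0] * scale),
        beta1=float(qc[1] * scale),
        beta2=float(qc[2] * scale),
        anchor=anchor,
    )
    # --- feasibility diagnostics ---
    x_check = circuit_equilibrium(at_pcai0, target_ratio * at_pcai0, params)
    if abs(x_check - anchor) > 1e-9:
        raise ValueError(
            f"calibration failed: anchor case gives ccai={x_check:.9f}, "
            f"expected {anchor}"
        )
    grid = np.linspace(*monotone_domain, 201)
    q = params.beta(grid) / scale
    if not np.all(np.diff(q) < 0):
        raise ValueError(
            "calibration failed: implied ratio curve is not strictly "
            f"decreasing on {monotone_domain}; knots {knots} are infeasible"
        )
    if np.any(params.beta(np.linspace(0.3, 1.6, 131)) <= 0):
        raise ValueError("calibration failed: buffer-release factor not positive")
    return params


def implied_ratio_curve(
    params: ChelationParams, domain: tuple[float, float] = (0.4, 1.4)
) -> RatioCurve:
    """The mechanism's exact requirement curve as a :class:`RatioCurve`.

    By construction the requirement per chelated millimole at the anchor is
    ``beta(c) * (kd + anchor) / anchor`` — a quadratic in ``c`` — so the
    curve is exact, not fitted (``fit_r2 = 1``).
    """
    s = (params.kd + params.anchor) / params.anchor
    return RatioCurve(
        coefficients=(params.beta0 * s, params.beta1 * s, params.beta2 * s),
        anchor_ccai=params.anchor,
        domain=domain,
        fit_r2=1.0,
        n_points=0,
        created_from="mechanism",
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for synthetic cohorts and sessions.

    Cohort defaults follow the source cohort: hematocrit uniform on
    0.22-0.40, pre-treatment ionized calcium normal(1.0, 0.1) truncated to
    [0.6, 1.5] mmol/L, and a lognormal per-patient citrate-sensitivity
    multiplier with 10% coefficient of variation. The citrate half-life
    default (35 min) is external pharmacokinetic knowledge, configurable.
    """

    n_patients: int = 38
    seed: int = 0
    ht_range: tuple[float, float] = (0.22, 0.40)
    pcai0_mean: float = 1.0
    pcai0_sd: float = 0.1
    pcai0_bounds: tuple[float, float] = (0.6, 1.5)
    response_noise_sd: float = 0.10
    citrate_half_life: float = 35.0  # minutes
    distribution_volume_fraction: float = 0.25  # L/kg, citrate & calcium pool
    hco3_volume_fraction: float = 0.5  # L/kg, bicarbonate space
    pco2: float = 40.0  # mmHg, fixed for pH computation
    kd_systemic: float = 5.0  # mmol/L, effective systemic dissociation constant
    ca_per_l_effluent: float = 2.0  # mmol Ca replaced per litre of effluent
    sieving: float = 1.0  # citrate sieving coefficient
    tmp_baseline: float = 100.0  # mmHg
    tmp_rise_rate: float = 1.0  # mmHg/min while circuit calcium >= clotting_ccai
    clotting_ccai: float = 0.35  # mmol/L
    tf_tmp_rise: float = 100.0  # mmHg rise forcing early termination
    default_weight: float = 70.0  # kg, used when the patient has no weight
    params: ChelationParams = field(default_factory=calibrate_chelation)

    def __post_init__(self):
        if not 0 <= self.response_noise_sd < 0.5:
            raise ValueError("response_noise_sd: must lie in [0, 0.5)")
        if self.n_patients <= 0 or self.citrate_half_life <= 0:
            raise ValueError("n_patients and citrate_half_life must be positive")


class SyntheticPatient(PatientState):
    """A generated patient carrying its citrate-sensitivity multiplier."""

    sensitivity: float = 1.0


def generate_cohort(config: SimConfig) -> list[SyntheticPatient]:
    """Draw a deterministic synthetic cohort under the configured conditions."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.pcai0_bounds
    cohort: list[SyntheticPatient] = []
    for i in range(config.n_patients):
        ht = rng.uniform(*config.ht_range)
        pcai0 = rng.normal(config.pcai0_mean, config.pcai0_sd)
        while not lo <= pcai0 <= hi:
            pcai0 = rng.normal(config.pcai0_mean, config.pcai0_sd)
        sens = float(np.exp(rng.normal(0.0, config.response_noise_sd)))
        weight = rng.uniform(55.0, 90.0)
        cohort.append(
            SyntheticPatient(
                patient_id=f"S{i + 1:03d}",
                hematocrit=float(ht),
                pcai0=float(pcai0),
                weight=float(weight),
                pca_total0=float(pcai0 + 1.04),
                hco3_0=26.4,
                ph0=7.47,
                sensitivity=sens,
            )
        )
    return cohort


def generate_dose_response_points(
    params: ChelationParams,
    pcai0_values: Sequence[float],
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> list[DoseResponsePoint]:
    """Simulated paired dosing observations for curve fitting.

    Each virtual session doses the population requirement
    ``pci_required(pcai0)`` and observes the 5-minute circuit calcium under a
    lognormal per-session sensitivity multiplier of width ``noise_sd``. With
    no noise every point lies exactly on the mechanism's requirement curve at
    the anchor.
    """
    if noise_sd > 0 and rng is None:
        raise ValueError("noisy generation requires an explicit rng")
    pts = []
    for c0 in pcai0_values:
        pci = pci_required(c0, params)
        sens = float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd > 0 else 1.0
        ccai = circuit_equilibrium(c0, pci, params, sensitivity=sens)
        pts.append(DoseResponsePoint(pcai0=float(c0), pci=float(pci), ccai_t5=float(ccai)))
    return pts


def calibration_curve(
    params: ChelationParams,
    domain: tuple[float, float] = (0.4, 1.4),
    n: int = 30,
    window: tuple[float, float] = DEFAULT_TARGET_WINDOW,
) -> RatioCurve:
    """Fit the ratio curve on a noise-free titrated calibration set.

    The calibration sessions are dosed exactly to the anchor (as a site
    would titrate before adopting the protocol), so the fitted quadratic
    reproduces the mechanism's requirement curve to numerical precision.
    """
    pts = generate_dose_response_points(params, np.linspace(*domain, n))
    curve = fit_ratio_curve(pts, window=window, anchor=params.anchor,
                            created_from="noise-free calibration")
    return curve


# ---------------------------------------------------------------------------
# session integration


def build_settings(
    prescription: Prescription,
    config: SimConfig,
    q_blood: float = 200.0,
    q_substitution: float = 40.0,
    anticoagulant: Solution = ACD_A,
    calcium_solution: Solution = CALCIUM_MAGNESIUM,
    replacement_mix: tuple[tuple[Solution, float], ...] = ((ALBUMIN_5, 1.0),),
) -> CircuitSettings:
    """Assemble balanced circuit settings realizing a prescription.

    The citrate pump is slaved to the blood pump; the calcium pump delivers
    ``ca_per_l_effluent`` mmol per litre of effluent (the Ci-Ca coupling),
    which makes its rate the solution of a small fixed point with the slaved
    effluent pump.
    """
    q_ci = citrate_pump_rate(prescription.wbci, q_blood, anticoagulant)
    f = config.ca_per_l_effluent
    if calcium_solution.calcium_conc <= f:
        raise ValueError(
            "calcium_solution.calcium_conc must exceed ca_per_l_effluent"
        )
    q_ca = f * (q_substitution + q_ci) / (calcium_solution.calcium_conc - f)
    return balance_effluent(
        CircuitSettings(
            q_blood=q_blood,
            q_substitution=q_substitution,
            q_citrate=q_ci,
            q_calcium=q_ca,
            anticoagulant=anticoagulant,
            calcium_solution=calcium_solution,
            replacement_mix=replacement_mix,
        )
    )


def simulate_session(
    patient: PatientState,
    prescription: Prescription,
    settings: CircuitSettings,
    config: SimConfig,
    duration: float = 105.0,
    extra_times: Sequence[float] = (),
) -> SessionRecord:
    """Integrate one TPE session in 1-minute steps.

    The circuit leg evaluates the chelation equilibrium on the *prescribed*
    plasma citrate against the session's pre-treatment ionized calcium (the
    clinical 5-minute feedback signal); the systemic leg integrates citrate
    kinetics, the calcium pool, bicarbonate and pH; TMP rises at a fixed rate
    while the circuit calcium sits at or above the clotting threshold and the
    session terminates early once the rise exceeds ``tf_tmp_rise``.
    Deterministic given its inputs.
    """
    net = settings.q_substitution + settings.q_citrate + settings.q_calcium - settings.q_effluent
    if abs(net) > 1e-9:
        raise ValueError(
            f"unbalanced settings (net fluid balance {net:.3f} mL/min); "
            "call balance_effluent first"
        )
    if duration <= 0:
        raise ValueError("duration: must be positive")
    params = config.params
    sens = getattr(patient, "sensitivity", 1.0)
    weight = patient.weight if patient.weight is not None else config.default_weight
    v_dist = config.distribution_volume_fraction * weight  # L
    v_hco3 = config.hco3_volume_fraction * weight  # L
    k_elim = math.log(2.0) / config.citrate_half_life  # 1/min

    # circuit leg (stationary while the prescription is unchanged)
    ccai_circ = circuit_equilibrium(patient.pcai0, prescription.pci, params, sens)
    beta_eff = sens * params.beta(patient.pcai0)
    complex_circ = beta_eff * (patient.pcai0 - ccai_circ)  # mmol/L circuit plasma
    removal = single_pass_citrate_removal(settings, patient, config.sieving)

    # constant rates, mmol/min
    citrate_infused = settings.q_citrate * settings.anticoagulant.citrate_conc / 1000.0
    ffp_citrate = settings.q_substitution * settings.replacement_citrate_conc() / 1000.0
    citrate_returned = citrate_infused * (1.0 - removal) + ffp_citrate
    ca_in = (
        settings.q_calcium * settings.calcium_solution.calcium_conc / 1000.0
        + settings.q_substitution * settings.replacement_calcium_conc() / 1000.0
    )
    # net citrate-induced calcium removal vs the calcium-neutral exchange
    # baseline: effluent carries (ccai + complex) instead of pcai0.
    ca_out = settings.q_effluent * max(0.0, ccai_circ + complex_circ - patient.pcai0) / 1000.0
    if citrate_infused + ffp_citrate > 0:
        salt_fraction = (
            citrate_infused * settings.anticoagulant.citrate_salt_fraction
            + ffp_citrate * settings.replacement_citrate_salt_fraction()
        ) / (citrate_infused + ffp_citrate)
    else:
        salt_fraction = 1.0

    # state
    ci_sys = 0.0  # systemic citrate, mmol/L
    ca_pool = patient.pcai0  # ionizable systemic calcium, mmol/L
    bound_offset = (
        patient.pca_total0 - patient.pcai0 if patient.pca_total0 is not None else 1.04
    )
    hco3 = patient.hco3_0 if patient.hco3_0 is not None else 26.4
    tmp = config.tmp_baseline
    cum_ca_in = cum_ca_out = 0.0

    def systemic_state() -> tuple[float, float, float]:
        pcai = _plain_equilibrium(ca_pool, ci_sys, config.kd_systemic)
        pca_total = bound_offset + ca_pool
        ph = 6.1 + math.log10(hco3 / (0.03 * config.pco2))
        return pcai, pca_total, ph

    schedule = sorted({t for t in (*MEASUREMENT_SCHEDULE, *extra_times) if t <= duration})
    measurements: list[Measurement] = []

    def record(t: float) -> None:
        pcai, pca_total, ph = systemic_state()
        measurements.append(
            Measurement(
                t=t, pcai=round(pcai, 9), ccai=round(ccai_circ, 9),
                pca_total=round(pca_total, 9), hco3=round(hco3, 9),
                ph=round(ph, 9), tmp=round(tmp, 9),
            )
        )

    n_steps = int(math.ceil(duration - 1e-9))
    completed = True
    t_end = duration
    next_sched = 0
    for step in range(1, n_steps + 1):
        t = min(float(step), duration)
        dt = t - (step - 1)
        # systemic citrate: returned input, first-order elimination
        metabolized = k_elim * ci_sys * v_dist  # mmol/min
        ci_sys += (citrate_returned - metabolized) * dt / v_dist
        ci_sys = max(ci_sys, 0.0)
        # bicarbonate from metabolized alkali-carrying citrate (3 mmol each)
        hco3 += 3.0 * salt_fraction * metabolized * dt / v_hco3
        # calcium pool
        ca_pool += (ca_in - ca_out) * dt / v_dist
        ca_pool = max(ca_pool, 0.0)
        cum_ca_in += ca_in * dt
        cum_ca_out += ca_out * dt
        # TMP proxy
        if ccai_circ >= config.clotting_ccai:
            tmp += config.tmp_rise_rate * dt
        while next_sched < len(schedule) and schedule[next_sched] <= t + 1e-9:
            record(schedule[next_sched])
            next_sched += 1
        if tmp - config.tmp_baseline > config.tf_tmp_rise:
            completed = False
            t_end = t
            break
    if not measurements or abs(measurements[-1].t - t_end) > 1e-9:
        record(t_end)

    mass_balance = (
        patient.pcai0 * v_dist + cum_ca_in - cum_ca_out - ca_pool * v_dist
    )
    return SessionRecord(
        patient=patient,
        settings=settings,
        prescription=prescription,
        measurements=measurements,
        duration=t_end,
        completed=completed,
        diagnostics={
            "ccai_circuit": ccai_circ,
            "ca_infused_mmol": cum_ca_in,
            "ca_removed_mmol": cum_ca_out,
            "calcium_mass_balance_mmol": mass_balance,
            "citrate_single_pass_removal": removal,
            "sensitivity": sens,
        },
    )


def _plain_equilibrium(total: float, citrate: float, kd: float) -> float:
    """Root of ``x + citrate*x/(kd + x) = total`` in ``(0, total]``."""
    if total <= 0:
        return 0.0
    if citrate <= 0:
        return total
    b = citrate + kd - total
    return 2.0 * total * kd / (b + math.sqrt(b * b + 4.0 * total * kd))


# ---------------------------------------------------------------------------
# virtual trials


@dataclass(frozen=True)
class FixedDose:
    """Fixed whole-blood citrate concentration for every patient."""

    wbci: float


@dataclass(frozen=True)
class PreliminaryProtocol:
    """Linear protocol: plasma dose = ratio * pCai0, hematocrit-scaled."""

    ratio: float = 4.6


@dataclass(frozen=True)
class FinalProtocol:
    """Cubic protocol from a fitted requirement curve."""

    curve: RatioCurve


Policy = Union[FixedDose, PreliminaryProtocol, FinalProtocol]


@dataclass
class TrialSummary:
    """Aggregated outcomes of a simulated cohort under one dosing policy."""

    policy: str
    n_sessions: int
    in_window: int
    underdosed: int
    overdosed: int
    hypocalcemia: int
    ptf: int
    tf: int
    mean_accumulation_ratio: float
    mean_delta_hco3: float
    ffp_fraction: float
    ccai_t5: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "ccai_t5"}
        d["ccai_t5"] = [round(v, 6) for v in self.ccai_t5]
        return d


def _prescribe(patient: PatientState, policy: Policy, q_blood: float) -> Prescription:
    if isinstance(policy, FixedDose):
        return Prescription(
            wbci=policy.wbci,
            pci=plasma_citrate_from_whole_blood(policy.wbci, patient.hematocrit),
            citrate_pump=citrate_pump_rate(policy.wbci, q_blood, ACD_A),
            protocol=Protocol.FIXED,
        )
    if isinstance(policy, PreliminaryProtocol):
        wbci = preliminary_whole_blood_dose(patient.pcai0, patient.hematocrit, policy.ratio)
        return Prescription(
            wbci=wbci,
            pci=plasma_citrate_from_whole_blood(wbci, patient.hematocrit),
            citrate_pump=citrate_pump_rate(wbci, q_blood, ACD_A),
            protocol=Protocol.PRELIMINARY,
        )
    if isinstance(policy, FinalProtocol):
        return final_whole_blood_dose(patient, policy.curve, q_blood=q_blood)
    raise TypeError(f"unknown policy {policy!r}")


def run_virtual_trial(
    cohort: Sequence[PatientState],
    policy: Policy,
    config: SimConfig,
    q_blood: float = 200.0,
    q_substitution: float = 40.0,
    replacement_mix: tuple[tuple[Solution, float], ...] = ((ALBUMIN_5, 1.0),),
    duration: float = 105.0,
    window: tuple[float, float] = DEFAULT_TARGET_WINDOW,
) -> TrialSummary:
    """Dose every cohort patient under one policy, simulate, and aggregate.

    Deterministic given the cohort and configuration (all randomness lives in
    cohort generation). Safety outcomes use the standard thresholds of
    :mod:`citradose.safety`.
    """
    import warnings as _warnings

    from . import safety

    cfg = safety.SafetyConfig()
    records = []
    for patient in cohort:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            presc = _prescribe(patient, policy, q_blood)
        settings = build_settings(
            presc, config, q_blood=q_blood, q_substitution=q_substitution,
            replacement_mix=replacement_mix,
        )
        records.append(simulate_session(patient, presc, settings, config, duration))

    low, high = window
    ccai_t5 = [r.ccai_t5 for r in records]
    in_window = sum(1 for c in ccai_t5 if c is not None and low <= c <= high)
    under = sum(1 for c in ccai_t5 if c is not None and c > high)
    over = sum(1 for c in ccai_t5 if c is not None and c < low)
    hypo = 0
    ptf = tf = 0
    ratios = []
    dhco3 = []
    for r in records:
        outcome, _ = safety.classify_session(r, cfg)
        ptf += outcome == safety.SessionOutcome.PTF
        tf += outcome == safety.SessionOutcome.TF
        if any(m.pcai is not None and m.pcai < cfg.hypocalcemia_threshold for m in r.measurements):
            hypo += 1
        last = r.measurements[-1]
        if last.pca_total is not None and last.pcai:
            ratios.append(last.pca_total / last.pcai)
        if last.hco3 is not None and r.patient.hco3_0 is not None:
            dhco3.append(last.hco3 - r.patient.hco3_0)
    ffp_frac = sum(
        frac for sol, frac in replacement_mix if sol.citrate_conc > 0
    )
    name = type(policy).__name__
    return TrialSummary(
        policy=name,
        n_sessions=len(records),
        in_window=in_window,
        underdosed=under,
        overdosed=over,
        hypocalcemia=hypo,
        ptf=ptf,
        tf=tf,
        mean_accumulation_ratio=float(np.mean(ratios)) if ratios else float("nan"),
        mean_delta_hco3=float(np.mean(dhco3)) if dhco3 else float("nan"),
        ffp_fraction=float(ffp_frac),
        ccai_t5=[c for c in ccai_t5 if c is not None],
    )
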