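# citradose

Individualized **regional citrate anticoagulation (RCA)** prescription
modelling for **therapeutic plasma exchange (TPE)** on a Ci-Ca pump module.

## The problem

TPE removes and replaces the plasma fraction of blood across a plasmafilter.
Anticoagulating only the extracorporeal circuit with pre-filter citrate —
which chelates the ionized calcium the coagulation cascade needs — avoids
systemic anticoagulation in bleeding-prone patients, but the therapeutic
window is narrow: too little citrate clots the filter, too much exposes the
patient to hypocalcemia and acid–base disturbances. The convective nature of
TPE sharpens the problem (no more than ~30% of pre-filter citrate leaves in
the effluent per pass) and fresh frozen plasma (FFP) replacement adds its own
citrate load of 17–21 mmol/L.

`citradose` implements an individualized prescription model for this setting,
aimed at clinicians and clinical engineers running citrate-anticoagulated
plasma exchange, plus a mechanistic session simulator so every stage of the
pipeline can be exercised and validated without patient data.

## The model

Two pre-treatment values drive the prescription: the hematocrit Ht (citrate
does not enter the erythrocyte, so a whole-blood dose concentrates into
plasma as `pCi = WBCi / (1 − Ht)`) and the systemic ionized calcium
`pCai(t0)`. Writing `ΔCai = pCai(t0) − cCai(t5)` for the calcium chelated per
litre of plasma (with `cCai(t5)` the circuit ionized calcium at 5 minutes,
the dosing feedback signal), the citrate requirement per chelated millimole

    q(x) = pCi / ΔCai,   x = pCai(t0)

falls with `x`: hypocalcemic patients are relatively resistant to citrate. A
quadratic `q(x) = a0 + a1·x + a2·x²` is fitted by ordinary least squares to
sessions whose `cCai(t5)` lies inside the therapeutic window
(0.24–0.33 mmol/L). Anchoring the desired circuit calcium at the window
midpoint (0.285 mmol/L) gives the cubic plasma dose equation

    pCi(x) = q(x) · (x − 0.285)

and the whole-blood prescription `WBCi = pCi(x) · (1 − Ht)`, converted to a
pump rate through the anticoagulant concentration (ACD-A, 113 mmol/L
citrate). A preliminary linear protocol (`pCi = 4.6 · pCai(t0)`) is also
provided, as are circuit flow balance, safety monitoring (hypocalcemia
< 0.85 mmol/L, citrate accumulation at total/ionized calcium ratio > 2.5,
TMP-based treatment-failure classification) and per-site ionometer
recalibration. **Local validation of the curve against the site's own
ionometer and data is a prerequisite before clinical use; the packaged
defaults are synthetic calibrations, not clinical ground truth.**

## Worked example

Fit a requirement curve on (here: simulated) paired session data and
prescribe:

```python
import numpy as np
from citradose import RatioCurveModel, PatientState
from citradose.simulator import calibrate_chelation, generate_dose_response_points

params = calibrate_chelation()          # synthetic mechanism, anchor-calibrated
rng = np.random.default_rng(0)
pts = generate_dose_response_points(params, np.linspace(0.8, 1.3, 30),
                                    noise_sd=0.10, rng=rng)
res = RatioCurveModel(pts).fit()
print(res.summary())
```

```
Citrate requirement curve (OLS quadratic)
=============================================
q(x) = +13.7578 -11.7385*x +4.3986*x^2   [mmol/mmol]
cubic dose: pCi(x) = q(x)*(x - 0.285)
R^2                 0.839
n (in window)       29
n excluded          1
fitted domain       [0.800, 1.300] mmol/L
target window       [0.24, 0.33] mmol/L
```

One of 30 sessions fell outside the therapeutic window and was excluded; the
quadratic explains 84% of the ratio variance on this noisy draw. Prescribing
for a patient with Ht 0.31 and pCai 1.08 mmol/L:

```python
p = res.prescribe(PatientState(patient_id="P7", hematocrit=0.31, pcai0=1.08))
print(f"wbci {p.wbci:.3f}  pci {p.pci:.3f}  pump {p.citrate_pump:.2f} mL/min")
# wbci 3.407  pci 4.938  pump 6.03 mL/min
```

i.e. 4.94 mmol citrate per litre of plasma, 3.41 mmol per litre of whole
blood, delivered at 6.03 mL/min of ACD-A at a blood flow of 200 mL/min.

The same is available from the shell:

```bash
$ citradose prescribe --pcai0 1.14 --hematocrit 40 --preliminary
protocol            preliminary
plasma citrate pCi  5.244 mmol/L
whole blood WBCi    3.146 mmol/L
citrate pump        5.57 mL/min = 334 mL/h
target cCai t5'     0.24-0.33 mmol/L
```

Other subcommands: `fit` (curve JSON + diagnostics from a sessions CSV),
`simulate` (synthetic cohort sessions), `trial` (fixed vs preliminary vs
final dosing arms), `monitor` / `audit` (safety events and cohort
percentages), `fixtures` (packaged study tables).

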