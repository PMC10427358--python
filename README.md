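# perfusense

Real-time spectrofluorometric biomarker quantification for organ machine
perfusion and dialysis monitoring.

During hypothermic oxygenated perfusion (HOPE) of a donor liver, flavin
mononucleotide (FMN) released from damaged mitochondrial complex I
accumulates in the perfusate and is a surrogate marker of ischemic
reperfusion injury: grafts whose FMN trajectory plateaus are good
candidates for transplant, while rising trajectories signal progressive
damage. `perfusense` implements the full measurement chain of a
flow-cell fluorometer for this setting — and for creatinine monitoring
in waste dialysate via a reagent mixing/delay-line assay — together with
a synthetic instrument + perfusion simulator that stands in for the
hardware, so every stage can be exercised and validated end to end.

## What it computes

* **Spectral core** — dark-frame subtraction (an LED-off frame is paired
  with every measurement, cancelling ambient light and dark current
  exactly), emission-band readout (mean counts over emission ± 10 nm,
  normalised per second of integration), and inversion of the linear
  calibration `I = slope·c + intercept` with blank-offset correction,
  non-negativity clipping and LOD flagging.
* **Calibration** — steady-state averaging of circulated standards
  (trailing 5-min window with a slope t-test), ordinary least squares
  fitting, the ten-blank run offset, limit of detection as
  `3·σ_blank/slope`, a cross-talk matrix check, agreement statistics
  against a reference method, and nominal [M+H]⁺ adduct masses for
  LC-MS identity confirmation (FMN C17H21N4O9P → 457 Da, creatinine
  C4H7N3O → 114 Da).
* **Streaming quantification** — LED/dark scheduling (two channels at
  2 s integration and 0.75 s overhead give one concentration every
  11 s), per-cycle quantification with quality flags, a trailing
  median-of-5 filter, and crash-tolerant CSV persistence.
* **Flow chemistry** — the creatinine assay train: 20:5:5 mL/h
  dialysate:NaOH:reagent mixing (dilution 2/3), a 30-min plug-flow
  delay line, and the inverse chain from cuvette signal back to
  dialysate and blood concentrations.
* **Simulator** — Gaussian fluorophore library with dark current, shot
  noise and ambient drift (blank noise anchored so its 3σ concentration
  equivalent equals the instrument's 4.4 nM FMN LOD); closed-form HOPE
  loop mass balance `c(t) = (1/V)·∫₀ᵗ r(s) ds` in a 3 L circuit;
  RK4-integrated dialysis clearance `dc/dt = (G − CL·c)/V_b`; labelled
  good/bad graft cohorts.
* **Assessment** — trapezoidal AUC, pointwise mean ± 1.96·SD reference
  bands, band/slope trajectory classification, the discrete
  plate-reader discard rule (3000–4000 A.U. at ≥ 30 min), exponential
  transaminase-decay fits `y = A·e^(−k·t) + b`, interpolation at
  clinical timepoints, and correlation reports.

## Worked example

```sh
perfusense calibrate --out cal --analytes FMN --seed 2
perfusense monitor --curves cal/curves.json --out run \
    --simulate good --seed 2 --duration-min 62
perfusense assess --trajectory run/records.csv --out report
```

The calibrate step prints the fitted curve, e.g.

```
FMN: slope=19430.1 counts/s per µg/mL, R²=1.00000, LOD=1.77e-03 µg/mL, offset=2.45e-04 µg/mL
```

i.e. the channel responds with ≈1.9·10⁴ counts·s⁻¹ per µg/mL of FMN,
the blank-derived detection limit is ≈1.8·10⁻³ µg/mL (≈3.9 nM), and the
pre-connection blank offset is far below the 0.02 µg/mL acceptance
bound. The assess step classifies the monitored trajectory against the
reference band of good grafts and prints, for a healthy simulated organ:

```
Graft records: WITHIN
  FMN @30 min: 0.0350 µg/mL
  FMN @60 min: 0.0446 µg/mL
  AUC 0-60 min: 1.8406 µg·mL⁻¹·min
  Band classification: WITHIN
```

`WITHIN` means the trajectory stays inside the 95% envelope of the
reference cohort and its 30–60 min slope is compatible with a plateau —
the signature of acceptable mitochondrial damage. A progressive-release
run (`--simulate bad`) is reported `DEVIATING` with the triggering rules
listed.

`perfusense simulate-dialysis --out dia` writes the blood and
waste-dialysate creatinine series and the delayed/diluted cuvette
signal for the dialysis monitoring scenario.

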