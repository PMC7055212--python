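# betargs

Feasibility analysis of **β⁻ radioguided surgery** (RGS) for pancreatic
neuroendocrine tumors (pNETs).

In radioguided surgery the patient receives a tumor-avid radiopharmaceutical
and the surgeon localizes residual tumor tissue with a handheld probe.
Conventional γ-probes struggle near organs with high physiological uptake —
the pancreas being the canonical offender. Pure β⁻ emitters change the game:
electrons travel only millimetres in tissue, so the probe sees only the few
mm directly in front of it. This package asks, quantitatively: *given the
uptake contrast measured on a pre-operative ⁶⁸Ga-DOTATOC PET scan, would a
p-terphenyl β-probe discriminate a small tumor remnant from healthy pancreas
after injecting ⁹⁰Y-DOTATOC the day before surgery?*

It is aimed at medical physicists and nuclear-medicine researchers
evaluating β-RGS protocols: sizing the administered activity, the probing
time per spot, and patient eligibility from routine PET quantities.

## What it computes

1. **PET quantification** (`pet_quant`): threshold-isocontour VOI
   segmentation of NIfTI uptake maps and SUV/TNR with decay correction,
   SUV = μW / (A_adm·e^(−0.693Δt/T½)), σ_SUV = Δ_SUV/√N.
2. **Activity bookkeeping** (`activity_model`): ⁹⁰Y decay (T½ = 64 h,
   τ ≈ 92 h), the 1.5 MBq/kg injection protocol, and the tissue specific
   activity at surgery time implied by an SUV.
3. **Monte Carlo probe simulation** (`probe_mc`): ⁹⁰Y β-spectrum sampling,
   straight-line CSDA electron transport through tissue and the probe's
   lateral shield, detection efficiency of the 2.55 mm × 3 mm p-terphenyl
   cylinder, and expected count rates R_T (on a ⌀6×7 mm remnant) and R_H
   (on healthy tissue).
4. **Detection statistics** (`detection_stats`): Poisson
   false-positive/false-negative rates at an integer count threshold,
   the minimum probing time achieving FN < 5% with FP ≤ 1%, and the
   ROC/AUC at a fixed 3 s dwell with Good/Bad labeling at AUC > 0.95.
5. **Synthetic data** (`synthetic_data`): a cohort sampler calibrated to
   the published uptake summaries (tumor SUV median 12.4, IQR 5.5–23.2;
   TNR median 4.9, IQR 2.2–12.2) and a voxel phantom builder with known
   ground truth.
6. **Pipeline + CLI** (`pipeline`, `betargs` command): end-to-end cohort →
   rates → detection plan → ROC report, fully seeded and reproducible.

See `docs/methods.md` for the models, assumptions and limitations.

## Worked example

A median patient (SUV_tumor 12.4, SUV_healthy 2.4, 70 kg) under the
reference protocol — 1.5 MBq/kg of ⁹⁰Y-DOTATOC injected 24 h before
surgery:

```python
from betargs import *

plan = InjectionPlan()          # 1.5 MBq/kg, 70 kg, 24 h delay, 90Y
print("administered:", total_administered_activity(plan), "MBq;",
      "at surgery:", round(activity_at_surgery(plan), 1), "MBq")

rec = PatientRecord("P001", mass=70.0, suv_tumor=12.4, suv_tumor_err=0.6,
                    suv_healthy=2.4, suv_healthy_err=0.1)
rates = predict_rates(rec, plan,
                      config=TransportConfig(n_particles=1_000_000, rng_seed=1))
print(f"R_T = {rates.rate_tumor:.1f} cps, R_H = {rates.rate_healthy:.1f} cps")

det = min_probing_time(rates)
print(f"t_min = {det.t_min:.1f} s at threshold {det.mu_th} counts "
      f"(FN = {det.fn:.3%}, FP = {det.fp:.3%})")

roc = roc_curve(rates, t_probe=3.0)
print(f"AUC(3 s) = {roc.auc:.6f} -> {roc.label}")
```

Output:

```
administered: 105.0 MBq; at surgery: 81.0 MBq
R_T = 248.6 cps, R_H = 80.6 cps
t_min = 0.1 s at threshold 16 counts (FN = 2.368%, FP = 0.878%)
AUC(3 s) = 1.000000 -> Good
```

Reading: of the 105 MBq administered, ~81 MBq remain after 24 h of ⁹⁰Y
decay. The probe would register ~249 cps over the remnant versus ~81 cps
over healthy pancreas — enough that a 0.1 s dwell with a 16-count threshold
already keeps false negatives below 5% and false positives at ~1%, and at
the surgeon's natural 3 s dwell the tumor/healthy discrimination is
essentially perfect (AUC ≈ 1), so the patient is labeled Good.

The same analysis for a whole (synthetic) cohort, from the shell:

```bash
betargs cohort --seed 1 --n 30 --out cohort.csv
betargs rates  --cohort cohort.csv --out rates.csv
betargs plan   --rates rates.csv --out plans.csv
betargs roc    --rates rates.csv --out roc.csv
betargs report --seed 1 --out report.csv     # everything in one pass
```

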