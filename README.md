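# gaitmode

Locomotion-intent prediction from wearable sensors: gait-phase-gated
linear-discriminant recognition of six locomotion modes, posterior-weighted
majority-vote smoothing, and advance detection of locomotion transitions.

Powered lower-limb prostheses must know the wearer's locomotion intent —
level walking (W), stair ascent/descent (SA/SD), ramp ascent/descent
(RA/RD) or standing (S) — *before* committing to a control mode for the
next stance. `gaitmode` implements a complete recognition pipeline for a
20-channel wearable suite sampled at 100 Hz: two 4-sensor plantar-pressure
insoles (both feet) and three IMUs (thigh, shank, foot of one *measured*
leg, each reporting pitch, roll and two accelerations). Because no public
recording of this sensor suite exists, the package ships a synthetic gait
simulator that emulates the standard continuous protocol (stand → walk →
stairs → walk → ramp → … → stand, with turn-backs), so every stage is
testable end to end. The package is aimed at researchers prototyping
intent-recognition pipelines and at anyone who needs a fully synthetic,
fully labeled multi-sensor gait benchmark.

## Method

1. **Gait events and phases.** Foot contact is detected per insole by
   hysteresis thresholding of the 4-sensor sum. A state machine anchored
   on the measured leg segments the cycle into four adjacent phases —
   initial double stance (DS1), single stance (SS), terminal double stance
   (DS2) and swing (SW): measured contact → DS1, contralateral off → SS,
   contralateral contact → DS2, measured off → SW. Standing holds the
   current double-stance state.

2. **Windows and features.** Overlapped sliding windows (150 ms, 10 ms
   increment, right-aligned so the decision timestamp is causal) yield six
   time-domain features per channel — maximum, minimum, mean, waveform
   length Σ|xₖ₊₁−xₖ|, population standard deviation and RMS — concatenated
   into a 120-dimensional vector.

3. **Phase-gated LDA.** One linear discriminant classifier per gait phase,
   with z-scored features, pooled within-class covariance
   Σ̂ = (M−K)⁻¹ Σₖ Σ_{x∈k}(x−μₖ)(x−μₖ)ᵀ, shrinkage
   Σ = (1−λ)Σ̂ + λ(tr Σ̂/d)I, and class posteriors via a softmax over the
   discriminants δₖ(x) = xᵀΣ⁻¹μₖ − ½μₖᵀΣ⁻¹μₖ + ln πₖ.

4. **Posterior-weighted majority voting.** Each of the last N = 5 raw
   decisions gets weight Wᵢ = (pᵢ−p₀)/(1−p₀) if pᵢ ≥ p₀ (p₀ = 0.5), else 0;
   per-mode voting values Vⱼ = Σᵢ Wᵢ·[Rᵢ = Mⱼ] update the output only when
   V_max > γ·N (γ = 0.75), otherwise the previous decision is held. The
   classical unweighted vote over 15 decisions is included as a baseline.

5. **Evaluation.** Trials split into steady periods, scored by
   classification accuracy CA = N_cor/N_total × 100% and a row-percentage
   confusion matrix, and transition periods, scored against the critical
   moment t_c (the measured foot's contact ending the transition): a
   transition is detected when more than 30 consecutive decisions of the
   new mode start inside the period with no later contradiction; the
   prediction time is T_pre = t_c − t_pre and the adjusted prediction time
   APD = Σ T_pre − 2000 ms × N_miss. Cohorts are evaluated by
   leave-one-pair-out cross-validation (one Set-A + one Set-B trial per
   fold) with subject-personalized classifiers.

## Worked example

```python
from gaitmode import SimConfig, generate_cohort
from gaitmode.pipeline import PipelineConfig, evaluate_cohort_loocv

cohort = generate_cohort(n_subjects=2, n_pairs_per_subject=3,
                         config=SimConfig(seed=42))
report = evaluate_cohort_loocv(cohort, PipelineConfig())
print(f"steady-period accuracy: {report['ca_mean']:.2f}% +/- {report['ca_sem']:.2f}%")
print(f"adjusted prediction time: {report['apd_ms_mean']:.0f} ms")
print(f"missed detections: {report['n_missed']} of {report['n_transitions']}")
print(f"mean T_pre, measured leg leading: {report['mean_t_pre_ms_measured_leading']:.0f} ms")
print(f"mean T_pre, unmeasured leg leading: {report['mean_t_pre_ms_unmeasured_leading']:.0f} ms")
```

prints

```
steady-period accuracy: 99.26% +/- 0.03%
adjusted prediction time: 3662 ms
missed detections: 0 of 144
mean T_pre, measured leg leading: 104 ms
mean T_pre, unmeasured leg leading: 506 ms
```

Each of the 144 simulated locomotion transitions is detected, most in
advance of the measured foot's landing on the new terrain (positive
T_pre). Transitions led by the unmeasured leg are predicted much earlier
because the deadline — the measured foot's next contact — falls a full
step later, the asymmetry that motivates pooling both leading-leg variants
(Set-A and Set-B trials) for training.

The same pipeline is available from the shell:

```bash
gaitmode simulate --subjects 2 --pairs 3 --seed 42 --out data/
gaitmode train    --in data/ --out model.bank
gaitmode predict  --model model.bank --trial data/S0_p0A.csv --out stream.csv
gaitmode evaluate --data data/ --report report.json
gaitmode sweep    --data data/ --parameter window_size_ms --out sweep.json
```

Trials are stored as plain CSV (time column plus the 20 canonical
channels) with a JSON sidecar `<stem>.gt.json` holding mode segments,
per-foot contact/off events and the Set-A/Set-B variant.

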