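# physiomatrix

Simultaneous cardiac/respiratory analysis of real-time venous blood flow.

## The problem

In the Fontan circulation (total cavopulmonary connection, the palliation
for univentricular hearts) the caval veins drain directly into the
pulmonary arteries with no subpulmonary ventricle, and it is clinically
important whether the heart beat or respiration drives systemic venous
return: respiration-driven retrograde flow in the inferior vena cava (IVC)
is a marker of hepatic afterload. Conventional gated flow MRI averages over
one of the two cycles — exclusive ECG gating averages out respiratory flow
variation, exclusive respiratory gating averages out cardiac variation — so
neither can see the other component's contribution.

This package analyzes *real-time* flow series (one flow value in ml/s per
dynamic acquisition, e.g. 8000 dynamics at 48 ms) together with the
scanner's physiological monitoring record (respiratory belt curve at 2 ms,
R-wave event times, scan-onset marker). It is aimed at researchers in
cardiovascular MR and hemodynamics who have such paired recordings (or want
to study the method itself on synthetic subjects).

## Method

1. **Physio-matrix.** Respiratory cycle onsets are detected as belt-curve
   maxima (sliding 800 ms window, plateaus resolved to their midpoint);
   cardiac cycles start at R-wave peaks. Each flow sample gets a pair of
   phase indices (i, j) — its elapsed-time fraction within the current
   respiratory and cardiac cycle, discretized into n_i = 40 and n_j = 10
   equidistant phases — and samples sharing (i, j) are averaged into the
   matrix P_ij.
2. **Net and gated retrograde volumes.** Net flow volume per cardiac cycle
   is V_net = Σ_ij P_ij Δt_j / n_i with Δt_j the cardiac phase interval.
   Retrograde volume restricts the sum to negative entries, either of P_ij
   itself (simultaneous gating) or of the marginals P^c_j = Σ_i P_ij /
   P^r_i = Σ_j P_ij, which emulate what an exclusively ECG- or
   respiratory-gated acquisition would measure.
3. **Functional-ANOVA GAM.** The matrix is decomposed as
   P_ij = Q + R_i + E_j + I_ij with periodic (cyclic P-spline) smooth
   main components R (respiratory) and E (cardiac), each summing to zero
   over its phase grid, a doubly-centered tensor-product interaction I, and
   the constant net-flow level Q. Smoothing is selected by GCV; each
   component gets a Wald-type significance test. Flow amplitudes
   (max − min), pulsatility indices (amplitude / Q) and the
   respiratory-to-cardiac amplitude ratio A_r/A_c follow from the fit.
4. **Resting-state partition.** The respiratory resting state is the flow
   plateau of the cardiac-averaged waveform Q + R_i (8-point cyclic
   least-squares slope below 5% of the mean inter-extremum slope); the flow
   there estimates the purely cardiac contribution to net flow, and
   Q − plateau flow the respiratory contribution.

A fully seeded synthetic generator produces Fontan-like
(respiration-dominated, early-expiration retrograde dip, resting plateau,
narrow inspiratory peak) and normal (cardiac-dominated triphasic) subjects
with cycle-length jitter, noise, belt curve and R-wave events, so the whole
pipeline is testable against known ground truth.

## Worked example

```sh
$ physiomatrix simulate --preset fontan --seed 42 --out subj/
wrote synthetic fontan subject (seed 42) to subj
$ physiomatrix analyze --flow subj/flow.csv --pmu subj/pmu.csv \
      --events subj/events.csv --out summary.json
net volume: 16.16 ml per cardiac cycle
retrograde (simultaneous): -0.785 ml (4.9% of net)
retrograde (ecg): 0.000 ml (0.0% of net)
retrograde (resp): -0.772 ml (4.8% of net)
respiratory-to-cardiac amplitude ratio: 2.58
summary written to summary.json
```

Reading: this synthetic Fontan subject returns 16.2 ml to the lungs per
cardiac cycle. 4.9% of that volume flows backwards (toward the liver), and
a simulated exclusively ECG-gated measurement of the same data sees *zero*
retrograde flow while respiratory gating recovers nearly all of it — the
retrograde flow is respiration-driven. The amplitude ratio 2.58 (> 1) says
respiration, not the heart beat, dominates flow pulsatility, as expected
for this preset (generator truth 52.1/20.7 ≈ 2.52). A normal-circulation
subject shows the mirrored pattern: ratio well below 1 and retrograde flow
visible to ECG but not respiratory gating.

The same pipeline is available from Python:

```python
from physiomatrix import generate_subject, run_pipeline

subject = generate_subject("fontan", seed=42)
result = run_pipeline(subject.samples, subject.record)
print(result.summary.pulsatility["resp_to_cardiac_ratio"])
```

`physiomatrix cohort --group-a fontan_dir/ --group-b normal_dir/ --out c.json`
compares two directories of subject summaries (Mann-Whitney U, Wilcoxon
signed rank, Spearman's rho; exact small-sample methods where ties allow).

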