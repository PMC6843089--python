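# madc

Multidimensional signal-detection analysis of cued multialternative change
detection.

## The problem

In a probabilistically cued attention task the observer monitors several
locations, one of which is cued; on each trial a stimulus change of magnitude
θ occurs at one location (or at none) and the observer must report where —
or that nothing changed. Such tasks are *multialternative*: a single decision
compares evidence across all locations, so they cannot be analyzed as a bank
of independent Yes/No detection models. The m-ADC model places one
unit-variance Gaussian decision variable Ψ_k per location, shifts its mean by
the sensitivity d′_k(θ) when a change occurs there, and applies the rule

    respond argmax_k (Ψ_k − c_k)   if the max exceeds 0,   else "no change",

with one criterion c_k per location. Sensitivity (d′) and spatial choice bias
(criterion) are thereby estimated jointly from the full stimulus-response
contingency table — hits, misses, mislocalizations, false alarms and correct
rejections — by maximum likelihood. Derived quantities include the bias
measures b_CC = c − d′_av/2 and b_LR = exp(−d′_av·b_CC), Naka-Rushton
psychophysical functions d(θ) = d_max·θ²/(θ² + θ50²), attention modulation
indices (ADI/AMI), decision-optimality indices built on Bayes risk
(β_obs, β^s_opt, SI_O/SI_G/SI_L), and the differential risk curvature ΔR_C —
an expectation-free index of spatial bias based on how sharply the risk
function curves around each location's optimal criterion.

The package is for psychophysicists and computational-neuroscience analysts
working with multialternative detection/localization data. Because no human
dataset ships with it, a first-class synthetic-cohort generator reproduces
the task's probabilistic design (288 trials = 6 blocks × 48, 25% catch
trials, conditional cue validities 2/3 : 1/6 : 1/12 : 1/12) so every stage of
the pipeline can be exercised and validated end to end.

## Worked example

```python
import numpy as np
from madc import (TaskDesign, ModelParams, simulate_observer_trials,
                  build_contingency_table, fit_madc, bias_metrics_from_fit,
                  count_free_parameters)

design = TaskDesign.collapsed()          # cued/opposite/adjacent, 6 magnitudes
observer = ModelParams.from_naka_rushton(
    [(2.5, 12.0), (1.4, 20.0), (1.2, 24.0)],   # (d_max, θ50) per location
    design.magnitudes, criteria=[1.0, 1.15, 1.35])

trials = simulate_observer_trials(observer, design, 288 * 20, seed=7)
table = build_contingency_table(trials, design)
fit = fit_madc(table, design, seed=0)

print("free parameters:", count_free_parameters(design))
print("d'_av:", np.round(fit.params.d_av, 2))
print("criteria:", np.round(fit.params.criteria, 2))
for label, b in zip(design.location_labels, bias_metrics_from_fit(fit)):
    print(f"{label}: b_CC={b.b_cc:+.2f}  b_LR={b.b_lr:.2f}")
```

Output:

```
free parameters: 21
d'_av: [1.54 0.7  0.55]
criteria: [0.97 1.2  1.38]
cued: b_CC=+0.20  b_LR=0.73
opposite: b_CC=+0.85  b_LR=0.55
adjacent: b_CC=+1.10  b_LR=0.55
```

The fit recovers the generating structure: sensitivity is highest at the
cued location (the spotlight pattern), and bias is graded — b_CC rises
(b_LR falls) from cued through opposite to adjacent, i.e. the observer is
most liberal toward the cued location. The 21 free parameters are the 6
sensitivities at each of 3 locations plus one criterion each.

## Analysis pipeline

The numbered drivers under `analysis/` run the full study pipeline on the
canonical 30-subject synthetic cohort and write their tables to `results/`:

1. `01_simulate_cohort.py` — simulate the cohort (trial CSVs to `scratch/`)
2. `02_fit_models.py` — per-subject fits, goodness of fit, AIC comparison of
   the eq-d / eq-c constrained variants
3. `03_psychometrics.py` — pooled psychometric and Naka-Rushton curves with
   jackknife errors; sensitivity-bias (non-)covariation
4. `04_optimality.py` — observed cost ratios, β^s_opt, suboptimality indices,
   ΔRisk surface
5. `05_risk_curvature.py` — simulated curvature tables, per-subject ΔR_C and
   σ(b_CC), their correlations with bias and sensitivity modulations
6. `06_rt_analysis.py` — RT normalization, robust/partial correlations,
   regression with permutation coefficient comparison, motor-bias control

Each script prints a short summary of what it found; they are independent
(each regenerates the deterministic cohort).

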