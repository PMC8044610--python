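# echosdt

Signal-detection-theory analysis of human echolocation psychophysics:
**echo-detection** ("is a sound-reflecting object present?") versus
**echo-localization** ("is the reflection coming from the left or the
right?"), measured in the same listeners across a range of reflector
distances.

The package is for psychophysicists and hearing researchers running (or
simulating) two-task yes/no click-echo experiments. It provides:

* a **generative simulator** of the full constant-stimulus experiment —
  10 reflector distances (1.00–4.25 m), 4 days × 10 sessions × 50 trials
  per task, stimulus probabilities 0.25/0.25/0.5 (left/right/none) for
  detection and 0.5/0.5 for localization, day 1 treated as practice —
  with responses drawn from the same observation model the estimators fit;
* **closed-form equal-variance SDT**: d′ = Φ⁻¹(H) − Φ⁻¹(F) and
  c = −(Φ⁻¹(H) + Φ⁻¹(F))/2 from hit/false-alarm rates;
* **Bayesian trial-level models** with Normal(0, 3) priors and the
  Bernoulli-probit likelihood
  pᵢ = (1 − Sᵢ)[1 − Φ(c + d′/2)] + Sᵢ[1 − Φ(c − d′/2)]:
  a *categorical* model (separate d′, c per task × distance; 40
  parameters) and an *exponential* model
  (d′(X) = α₀·e^{α₁X} for detection, β₀·e^{β₁X} for localization, one
  bias per task; 6 parameters), each summarised by posterior medians and
  95% highest-posterior-density (HPD) intervals with split-R̂/ESS
  diagnostics — well defined even for cells with H = 1 or F = 0, where
  the closed forms diverge;
* draw-wise **task contrasts** (per-distance detection − localization d′)
  and a two-model **response-bias table**;
* a group-level **2 (task) × 10 (distance) repeated-measures ANOVA** on
  d′ point estimates with partial η²;
* the idealized **echo-delay geometry** (≈5.8 ms of delay per meter of
  reflector distance at 343 m/s).

## Worked example

Simulate one participant through the full design (2 × 2,000 trials) from
an exponential observer with d′_det(X) = 3·e^(−0.4X),
d′_loc(X) = 2·e^(−0.6X), biases c₀ = 0.1, c₁ = −0.2, then fit the
6-parameter model to the 3,000 post-practice trials:

```python
import echosdt as es

design = es.make_design()
observer = es.ObserverParams.exponential(3.0, -0.4, 2.0, -0.6, 0.1, -0.2)
table = es.simulate_experiment(design, observer, ["p01"], seed=7)
trials = es.analysis_subset(table, design)          # 3,000 trials
fit = es.fit_exponential(trials, es.SamplerConfig.for_exponential(seed=0))
print(fit.summaries[["median", "hpd_low", "hpd_high"]].round(2))
```

```
        median  hpd_low  hpd_high
alpha0    3.53     2.68      4.44
alpha1   -0.47    -0.60     -0.36
beta0     1.99     0.99      3.15
beta1    -0.59    -0.90     -0.29
c0        0.09     0.03      0.15
c1       -0.23    -0.29     -0.17
```

Every generating value sits inside its 95% HPD interval: the observer
loses about 47% of detection sensitivity per simulated wall-clock meter
(α₁ ≈ −0.47) and is slightly yes-leaning in the detection task (c₀ > 0),
slightly left-leaning in localization (c₁ < 0). The categorical fit
yields the per-distance contrasts and the bias table:

```python
fc = es.fit_categorical(trials, es.SamplerConfig.for_categorical(seed=0))
print(es.task_contrasts(fc).round(2).head(3))
```

```
   distance_m  median  hpd_low  hpd_high
0        1.00    1.17     0.51      1.81
1        1.36    0.73     0.17      1.33
2        1.72    1.12     0.52      1.69
```

At 1 m this observer detects much better than they localize (d′
difference ≈ 1.2, interval excluding 0), and
`es.bias_table(fc, fit)` shows both models agreeing on a between-task
bias difference of ≈ 0.32.

The same pipeline runs from the shell:

```bash
echosdt simulate --participants p01,p02 --seed 1 --out trials.csv
echosdt fit --trials trials.csv --out fits/
echosdt summarize --fits fits/ --out tables/
echosdt anova --estimates tables/estimates.csv --out anova.json
```

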