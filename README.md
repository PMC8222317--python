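# clickchange

Psychophysics of auditory change-point detection: task simulation,
model-free analysis, and Ornstein–Uhlenbeck sequential-sampling modeling
of how listeners detect a change in the rate of a Poisson click train.

## The problem

A listener hears clicks generated at 60 Hz and must report, in real time,
when the generative rate steps up or down (by ±10/±30/±50 Hz, at an
unpredictable, flat-hazard time). A cue beforehand either names the
direction of the impending change ("increase"/"decrease") or is
uninformative ("either"). The scientific questions this package supports:
how does advance knowledge of the change dimension reshape the decision
process — the evidence threshold, the timescale of evidence evaluation,
the noise — and can listeners apply *different* timescales of evidence
evaluation to the same click stream simultaneously?

The package is aimed at decision-psychophysics researchers who want a
tested, self-contained implementation of this paradigm: a synthetic
task/observer simulator (no subject data required), the standard
model-free estimators, and the model-based pipeline.

## The model

The decision variable `a` (in Hz) is a leaky estimate of the click rate,

> da = (c − a/τ) dt + σ_process dW,  with  c = C/(dt·τ),

where `C` counts the clicks in each `dt = 0.02 s` bin (optionally scaled
by short-term depression), `τ` is the exponential filter width, and
`σ_process` is diffusion noise. A change is reported when `a` crosses a
sticky (absorbing) detection bound — an upper bound for increases, a lower
bound for decreases, both for the uninformed condition (two racing
processes, optionally with separate filter widths). Bounds are inactive
for the first 0.8 s; a Gaussian non-decision time (μ_NDT, σ_NDT) separates
bound crossing from the overt response. Per-trial response-time
distributions come from propagating the discretized DV distribution with
the exact one-step OU transition (a Fokker–Planck solution with
Brownian-bridge bound crossing); fitting maximizes the summed log
likelihood of response times (0.2 s windows) and misses, followed by a
Laplace posterior with credible intervals and a log-model-evidence
estimate used with BIC/AIC for model comparison. See `docs/methods.md`.

## Worked example

```python
import numpy as np
from clickchange.params import TaskConfig, ObserverParams, SolverConfig
from clickchange.task import generate_dataset
from clickchange import metrics as met
from clickchange import revcorr as rc
from clickchange.fitting import FitSpec, fit_mle

# one synthetic session: 3000 trials from the default OU observer
trials, clicks = generate_dataset(TaskConfig(), ObserverParams(), 3000, seed=9)

for cond in ("informed_increase", "uninformed_increase"):
    s = met.fit_threshold(trials, cond, n_boot=200)
    rt, _, _ = met.reaction_times(trials, cond, n_boot=200)
    amp, *_ = rc.kernel_amplitude((trials, clicks), cond, n_boot=200)
    print(cond, round(s.threshold, 1), "Hz;",
          round(rt, 3), "s;", round(amp, 1), "Hz")
```

prints (numbers from this exact seed):

```
informed_increase 20.6 Hz; 0.528 s; 11.7 Hz
uninformed_increase 30.2 Hz; 0.577 s; 15.0 Hz
```

i.e. with an informative cue the synthetic observer detects smaller rate
changes (psychometric threshold 20.6 vs 30.2 Hz), responds faster after
the change (0.528 vs 0.577 s), and needs a smaller stimulus fluctuation to
trigger a false alarm (reverse-correlation amplitude 11.7 vs 15.0 Hz above
baseline) — the behavioral signature of a lowered decision bound. A model
fit recovers the bound directly:

```python
spec = FitSpec(condition="informed_increase", solver=SolverConfig(n_grid=201))
fit = fit_mle((trials, clicks), spec)
print({k: round(v, 3) for k, v in fit.mle_params.items()})
```

giving estimates close to the observer's generating values
(τ = 0.4 s, bound 78.3 Hz, σ_process 4, μ_NDT 0.35 s).

There is also a CLI: `clickchange simulate|analyze|revcorr|fit|compare|
recover|report` (each takes `--seed` and `--out`; see `--help`).

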