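# gliderpsych

Tools for studying visual sensitivity to local multipoint correlations in
binary textures: maximum-entropy texture synthesis, a Bayesian
ideal-observer psychometric model fitted by maximum likelihood, simulation
of the 2AFC behavioral experiment (including the adaptive staircase used in
training), and a Monte Carlo test for the correspondence between
sensitivity profiles.

## The science

Binary textures can carry structure invisible to pixel-wise statistics:
*multipoint correlations* defined by small templates ("gliders") of 1–4
cells inside a 2×2 box. The intensity of a statistic is the expected parity
of glider placements, expressed on a spin scale (white = +1, black = −1):
0 is white noise, ±1 forces the parity of every placement. An observer —
animal or human — discriminating such textures from white noise yields a
psychometric curve whose slope measures perceptual sensitivity to that kind
of correlation.

The package models the observer as Bayesian and ideal. A texture with
statistic level *s* evokes a percept *x* ~ truncated-Normal(*s*, σ²) on
[−1, 1]; the observer knows the K-level testing grid and holds prior
log-odds α = ln p(noise)/p(texture), and reports "noise" when the posterior
log-odds

D(x) = α + ln p(x | s = 0) − ln [ (1/K) Σₖ p(x | sₖ) ]

is positive. D is strictly decreasing, so behavior is a threshold rule at
the root x\* of D, and

p(report noise | s) = [Φ((x\* − s)/σ) − Φ((−1 − s)/σ)] / [Φ((1 − s)/σ) − Φ((−1 − s)/σ)].

Fitting (α, σ) to per-level response counts by maximum likelihood gives the
sensitivity 1/σ. Sensitivity profiles across statistics (e.g. 2-, 3- and
4-point) are compared through their cosine similarity, the *degree of
correspondence* c ∈ [0, 1], with significance from a Monte Carlo null of
random direction pairs in the positive orthant.

## Worked example

```python
from gliderpsych import (ObserverParams, SessionConfig, simulate_session,
                         IdealObserverModel, SensitivityVector,
                         correspondence_test)

# simulate a 3000-trial session of an observer with known parameters
true = ObserverParams(prior_logodds=0.1, noise_sd=0.4)
records, dataset = simulate_session(SessionConfig(3000, true, seed=7))

res = IdealObserverModel(dataset).fit()
print(res.summary())
```

```
Ideal observer psychometric fit
===============================================
levels                                       16
total trials                               3000
log-likelihood                         -42.9771
converged                                  True
at parameter bound                        False
-----------------------------------------------
prior log-odds (alpha)                 0.134564
perceptual noise SD (sigma)            0.411979
sensitivity (1/sigma)                  2.427310
===============================================
```

The fit recovers the generating parameters (α = 0.1, σ = 0.4) up to
sampling noise in 3000 trials; 1/σ̂ ≈ 2.43 is the observer's estimated
sensitivity. Comparing two sensitivity triplets:

```python
rat = SensitivityVector(("beta", "theta", "alpha"), [4.9, 1.0, 1.8])
human = SensitivityVector(("beta", "theta", "alpha"), [5.1, 0.9, 2.1])
out = correspondence_test(rat, human, n=1_000_000, seed=0)
print(f"c = {out.c:.3f}, p = {out.p_value:.4f}")   # c = 0.999, p = 0.0074
```

Here c ≈ 1 says the two profiles are nearly proportional, and the p-value
is the fraction of random positive-orthant direction pairs that are at
least as aligned.

A command-line interface mirrors the library:

```
gliderpsych textures --glider beta_h --intensity 0.85 --n 10 --seed 7 --out stim/
gliderpsych simulate --alpha 0.1 --sigma 0.4 --n-trials 3000 --seed 1 --out trials.csv
gliderpsych fit trials.csv --out fit.json
gliderpsych staircase --sigma 0.3 --seed 2 --out trajectory.csv
gliderpsych correspond a.csv b.csv --n 10000000 --seed 1
gliderpsych recover --config subjects.json --out report/
```

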