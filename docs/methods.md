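# Methods

## Texture model

A texture is a height × width binary lattice (default 22 × 39, the
landscape stimulus frame) with a spin view z = 2·pixel − 1, white = +1.
Each glider statistic is the mean over all fully in-bounds placements of
the product of spins at the glider cells. Ten gliders are defined inside a
2×2 bounding box: the single cell (1-point), four 2-point pairs
(horizontal, vertical, two diagonals), four 3-point "L" shapes named by the
omitted corner of the box, and the full 2×2 (4-point).

Sampling targets the maximum-entropy ensemble at a fixed statistic value g:

- **1-point** — i.i.d. pixels, P(white) = (1 + g)/2.
- **2-point** — independent ±1 Markov chains along the glider axis (rows,
  columns, or diagonals; each diagonal chain is seeded with a fair coin at
  its first in-bounds cell) where each spin repeats its predecessor with
  probability (1 + g)/2. The anti-diagonal ensemble is generated as a
  column-flip of the main-diagonal one (the flip is a relabeling and
  preserves entropy and statistics).
- **3- and 4-point** — first row and first column are fair coins; the
  remaining cells are filled in raster order so that the spin product over
  each glider placement equals an independent sign r with
  P(r = +1) = (1 + g)/2. The three L-orientations that contain the (1,1)
  cell admit this construction directly; the fourth is a column-flip of the
  orientation it mirrors.

Because every placement parity is an independent coin, the ensemble mean of
the matching statistic equals g exactly, |g| = 1 forces every placement,
and lower-order statistics vanish. One explicit integer seed drives a
single random stream per texture, so textures are bit-reproducible.

What the generator does *not* emulate: joint control of two statistics,
gray levels, monitor calibration, or the finite-pool stimulus rotation used
in a real rig. A passing calibration therefore says the ensembles have the
stated correlation structure, not that they reproduce any particular
physical stimulus set.

Files are written as plain PBM (P1; note PBM's 1 = black) or 8-bit
grayscale PNG (white = 255).

## Ideal observer

Percepts are truncated-Normal(s, σ²) on [a, b] = [−1, 1]; the truncation
encodes that a statistic value cannot leave this range, and σ lumps
finite-texture sampling noise together with perceptual noise. The observer
knows the K positive test levels, splits the texture prior uniformly over
them, and holds prior log-odds α for noise vs texture. The decision
variable D(x) (posterior log-odds) is strictly decreasing in x, so the
response rule is a threshold at the root x* of D, found by Brent's method
on [a, b] to 1e−12 after an endpoint sign check; when D does not change
sign the boundary clamps to the endpoint, making the response probabilities
0 or 1 in the degenerate regimes. Gaussian quantities are computed through
`scipy.stats.truncnorm`'s log-density and a log-sum-exp mixture so the
pipeline survives σ down to ~1e−6; if the truncated CDF still degenerates
numerically, the vanishing-noise limit (step function at x*) is used.

Default level grid: 0.02 to 0.93 in steps of 0.07 plus 1.0 (15 levels),
configurable. With a single level and the truncation bounds pushed out, the
model collapses analytically to a cumulative-Normal psychometric curve;
this equivalence is tested to 1e−6.

## Fitting

Data are per-level counts (T_s trials, N_s "noise" reports), including the
level-0 row; trial-level tables are reduced to counts first (binomial
sufficiency). The log likelihood is the sum of binomial terms with success
probability given by the psychometric function, evaluated on the dataset's
own positive levels as the observer's grid. Maximization is bounded
Nelder-Mead over (α, log σ) from the standard initial condition
(α, σ) = (0.1, 0.4), with α ∈ [−10, 10] and σ ∈ [1e−3, 10]; the log-σ
parameterization keeps the search scale-free and the optimum is invariant
to it. Non-convergence and boundary solutions are flagged on the result,
never raised; complete separation (all responses identical) is flagged
explicitly because the α estimate is then unbounded and the likelihood
plateaus. No confidence intervals are computed by default (a nonparametric
binomial bootstrap over trials is available on the results object).

## Correspondence test

Sensitivity triplets are compared by cosine similarity. The null draws the
four spherical angles of two positive-orthant directions independently and
uniformly on [0, π/2] — the literal angular construction, not area-uniform
sampling on the sphere octant — and the p-value is the fraction of null
cosines strictly exceeding the observed value (ties have measure zero).
Default 10⁷ samples, computed in 10⁶-sample blocks to bound memory.

## Behavioral simulation

Sessions: categories are i.i.d. fair coins subject to a cap (default 3) on
consecutive same-category trials, enforced by forcing the opposite category
after a maximal run — the simplest scheme honoring the cap, which preserves
the 50/50 balance; structured levels are uniform over the grid. Responses
are generated by sampling a percept and thresholding at x*, which is
distributionally identical to a Bernoulli draw from the psychometric
function (tested). Ignored/aborted trials, reaction times and reward
dynamics are not modeled.

Staircase: structured levels are drawn from a geometric distribution over
the discretized range (minimum … maximum in 0.05 steps) with success
probability 0.5 over level indices ascending from the current minimum,
renormalized — the mode sits at the minimum so most structured trials probe
it. Every 10 trials, the fraction correct on minimum-level structured
trials within the window moves the minimum: down one step above 70%
correct, up one step below 50%, clipped to [floor, maximum]; windows with
no minimum-level trial leave it unchanged. The simulated observer's
internal grid is the full discretized range, fixed over the run, so its
decision boundary is computed once. Defaults: maximum 0.95, floor 0.02
(the lowest testing level), start at the maximum. The asymptote is the mean
minimum level over the last quarter of trials.

## Problem sizes and test design

Stochastic checks use seeded streams and 3-SE tolerances against analytic
or brute-force oracles. The heavier end-to-end checks use 50 replicate
sessions of 3000 trials per parameter condition for parameter recovery, 20
replicates for the group-ranking and staircase-monotonicity checks, and 200
textures per calibration cell (each cell on its own seed stream so the 33
cells are independent; a single ≤3.9-SE excursion is tolerated familywise).
Null-tail reproduction uses 10⁶ samples in the test suite and 10⁷ in
`scripts/acceptance.py`.

For the group-ranking check the four synthetic groups use true σ = 0.25,
0.25, 1.2 and 0.6 for 1-, 2-, 3- and 4-point observers — values chosen to
respect the observed ordering of texture discriminability (1 ≈ 2-point
easiest, then 4-point, then 3-point) with realistic separations; they are a
package choice, not estimates from any dataset.

## Known limitations

- The ideal observer has no lapse/guess parameters; real subjects'
  asymptotic errors inflate σ̂ rather than being absorbed separately.
- The staircase performance-accounting rule (which trials count toward the
  10-trial window) admits variants; the implemented rule uses minimum-level
  structured trials only.
- The correspondence null is the angular construction above; an
  area-uniform octant null would concentrate slightly differently.
- Texture ensembles control exactly one statistic; pairwise joint control
  is out of scope.
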