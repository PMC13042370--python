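# Methods

## Model

The package implements a static (equilibrium) mechanism model of ecosystem
hysteresis. A system with two alternative stable states `C0 < C1` (state
units; `C0 > 0`) is described by the curve

    x = f(Y) = (Y − C0)/(C1 − Y) · exp(K/Y),

read as "the driver value at which state `Y` is an equilibrium". The
rational factor is the positive feedback (increasing in `Y`, zero at `C0`,
divergent at `C1`); the exponential factor is the negative feedback
(decreasing in `Y`); `K ≥ 0` (dimensionless, the *irreversible potential*)
scales the negative feedback. `f′(Y) = 0` reduces to the quadratic
`(C1−C0+K)Y² − K(C0+C1)Y + K·C0·C1 = 0`, whose discriminant is positive iff
`K > K* = 4·C0·C1/(C1−C0)`. The two roots `Y− < Y+` are the fold states:
the lower stable branch is `[C0, Y−]`, the upper `[Y+, C1)`, and the
segment between them is unstable. The forward (low→high) transition jumps
at `(Y−, f(Y−))`, the backward at `(Y+, f(Y+))`, with `f(Y−) > f(Y+)`.

Assumptions worth stating explicitly:

- The model is **quasi-static**: the driver changes slowly enough that the
  system tracks the stable branch, and jumps occur exactly at the fold.
  No rates, time lags, or stochastic early transitions are represented.
- The state is the independent variable; the driver is single-valued in
  the state but the state is double-valued in the driver inside the loop.
- The force decomposition is the product-rule split
  `f′ = g′h + gh′`: `g′h > 0` on `(C0, C1)` (inertial/positive-feedback
  force), `gh′ = −(K/Y²)f ≤ 0` (conservative/negative-feedback force).
  Their zero-sum points are exactly the tipping states, which is the
  property that makes this particular split the meaningful one.

## Normalized space and transfer functions

Analysis works in the standardized form `C0 = 1, C1 = e` (then
`K* = 4e/(e−1) ≈ 6.33`). A sweep in a given direction follows a one-sided
transfer function `α`: equal to `f` on the pre-jump branch, constant at the
tipping driver across the vertical jump interval, and equal to `f` again on
the post-jump branch. Boundary convention: the fold state itself maps to
its branch value `f(Y∓)`; the open interval strictly between the fold state
and the jump target maps to the plateau. For `K ≤ K*` the transfer
functions are defined as `f` itself, so the family is continuous in `K` and
non-hysteretic data can be fitted with the same machinery.

## Estimating K

Observed loops live in arbitrary units, so two affine maps connect data to
the normalized model: φ (states → `[1, e]`) and an alignment (drivers →
model drivers). Both are nuisance parameters; `K` is the target.

**Anchoring.** For data whose sweeps show an abrupt jump, the jump records
carry the most information. The detector sorts each direction by driver
(ascending forward, descending backward) and takes the largest consecutive
state change exceeding 25% of the state range; the record before it is the
observed tipping point. The candidate transforms at a given `K` map the two
observed pre-jump states onto the model fold states `Y−(K), Y+(K)` and the
two observed tipping drivers onto the model tipping drivers. With one-sided
data, the pre-jump/post-jump pair anchors onto the fold state and its jump
target instead.

**Risk.** The empirical risk is the squared *state-axis* distance, in data
state units, between each observation and the one-sided transfer curve at
the observation's aligned driver (branch chosen by the driver's side of the
tipping driver; points at the tipping driver are measured against the
vertical jump segment). Two deliberate choices here:

- *State-axis residuals.* The driver is the controlled variable in sweep
  experiments, so the measurement error lives in the state. Driver-axis
  residuals would be dominated by the steep branch segments, where a small
  state error projects onto an enormous driver error; worse, a
  near-critical `K` — which collapses the loop onto one smooth curve —
  can produce deceptively small driver-axis residuals on loop data and act
  as a spurious minimum.
- *Residuals in data units.* Normalized-space residuals shrink with the
  transform scale, so a compressing transform could deflate the risk of a
  degenerate candidate; dividing by the φ scale removes that freedom.

For evaluating residuals of noisy states slightly outside the anchored
range, the curve `(Y−1)/(e−Y)·exp(K/Y)` is continued below `Y = 1` (it is
smooth and increasing there, with weakly negative drivers); the pole at
`Y = e` remains a hard boundary.

**Optimization.** Deterministic and derivative-free at the top level:
a 240-point grid on `K ∈ (K*, 60]` with the detected anchors held fixed,
golden-section refinement (tolerance 1e−3) around the grid argmin, then a
joint trust-region least-squares polish of `(K, anchors)` from several
deterministic starts. Freeing the anchors matters because they are single
noisy records; the multi-start guards against the fixed-anchor grid having
chosen the wrong basin. Ties in the grid argmin break toward smaller `K`
(the weaker hysteresis claim). Grid search rather than a general solver
because the risk is only piecewise-smooth in `K` (plateau boundaries move
with `K`).

Branch inversion inside the risk uses 256-point monotone lookup tables
(densified near the fold, where the inverse has a square-root singularity)
followed by three vectorized Newton steps — machine-precision inverses at
vector cost, cached per `K`.

**Non-hysteretic data.** Without a detectable jump there is nothing to
anchor on: φ maps the observed state range onto `[1, e]` inset by a 2%
margin (the curve diverges at `e`, so data extremes must not land there),
the driver alignment is profiled by ordinary least squares with residuals
in data driver units, and the search may extend below `K*` via a
configuration switch. `RMSE = sqrt(loss/n)` in both paths (data state
units when anchored, data driver units otherwise).

**Confidence interval.** A 95% percentile bootstrap: records are resampled
with replacement within each direction and the entire pipeline (detection,
anchoring, optimization) is re-run per replicate; seeded, hence
reproducible. This is the package's own interval construction.

## Predicting the unobserved branch

Given one-sided data and a `K` (assigned or estimated), the observed
pre/post-jump pair anchors φ; the driver map back to data units averages
two anchored affine maps — one matching the data/model driver maxima, one
the minima, both fixing the tipping-driver anchor — falling back to the
single well-defined map (with a warning) if an extreme coincides with the
anchor. The opposite branch's tipping point and a sampled trajectory
(200 states per branch segment, restricted to the observed state range)
are mapped through the inverse transforms. The construction is exactly
self-consistent on model-generated data and equivariant under affine
rescaling of either column.

## Synthetic data

The generator emulates driver-controlled sweep experiments: drivers
stepped linearly from half the backward tipping driver to 1.2× the forward
one (defaults), states on the active stable branch, and a deterministic
vertical jump at the tipping driver. Both fold endpoints are recorded at
the tipping driver — the fold state ending one branch and the jump target
beginning the other — matching the idealized vertical jump of a
quasi-static sweep and giving noiseless sweeps the exact jump geometry.
Gaussian noise (default SD: zero; tests use 2% of the normalized state
range) is added to states only — the driver is the controlled variable —
and clipped to keep states strictly inside `(C0, C1)`.

What the generator does *not* emulate, and hence what passing tests do not
show about field data: driver measurement error, rate-dependent or early
(noise-induced) transitions, minor loops from partial reversals, uneven or
sparse driver coverage, and autocorrelated observation noise. Tests
demonstrate internal consistency of the machinery under the model's own
assumptions, not robustness to violations of them.

## Numerical choices

- Tipping roots via the cancellation-free quadratic formula; `K = K*`
  within relative tolerance 1e−9 is classified critical (exact float
  equality would be fragile).
- Public branch inversion by Brent bracketing (guaranteed on a monotone
  segment), relative tolerance 1e−12; the upper branch is capped at
  `C1 − 1e−6·(C1−C0)` since `f` diverges at `C1`.
- Jump targets just above `K*` degenerate to the fold itself; the solver
  returns the bracket edge when roundoff erases the jump.
- Jump detection ties break toward the earliest (lowest forward driver)
  jump; records tied on driver keep sweep order.
- Problem sizes in the test suite: loops of 50 points per branch; 20 noisy
  replicates per `K` for recovery checks; 25 loops with 50-replicate
  bootstraps for the interval-coverage check. These sizes make the full
  suite a routine desktop run while keeping the Monte-Carlo assertions
  stable across seeds.

## Known limitations

- `K` is estimated in normalized space; it is not translated back into a
  raw-units `(C0, C1, K)` triple (the exponential factor is not invariant
  under affine state maps, so the normalized `K` is the comparable,
  reported quantity).
- The anchored estimator requires both sweeps to show a detectable jump;
  loops that straddle the critical regime (jump in one direction only)
  fall back to the profiled path, which is less accurate.
- The bootstrap conditions on the detected jump structure per replicate;
  with very few points per branch the resampled detection can fail, and
  replicates that cannot be fitted are dropped (an error is raised if more
  than half fail).
- No time dimension: the model cannot say *when* a transition will occur,
  only at which driver value.
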