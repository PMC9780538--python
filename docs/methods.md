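# Methods

This note documents the model as implemented: the pinned functional
forms, the calibration of their free parameters, the solver and
simulator semantics, numerical choices, and known limitations.

## State, actions, time

Awareness `s` and analyticity `u` both live on the open-interval grid
{0.01, …, 0.99} (step 0.01); the horizon is finite with decisions at
epochs `0 … T−1` and a terminal reward at `T`. The state moves at most
one grid step per epoch; out-of-range moves are clamped (an impossible
move behaves as "stay" in realised dynamics, and backups use the
clamped neighbour's value). Off-grid inputs are snapped to the nearest
level with a warning rather than rejected, so serialized runs can be
resumed tolerantly.

## Transition curves and their calibration

The model's narrative pins only qualitative features of the two base
forward-probability curves: the analytical curve rises from a low value
to a maximum at high analyticity and then declines (overfitting); the
intuitive curve peaks at low analyticity, declines as `u` grows, and
needs a minimum of analyticity near `u = 0`. We realise both as
normalised beta bumps

    p(u) = p_floor + (p_peak − p_floor) · u^a (1−u)^b / max_u [u^a (1−u)^b],

with `(a, b) = (peak·sharpness, (1−peak)·sharpness)` so the maximiser
is exactly `peak`. Defaults: `p_floor = 0.05`, `p_peak = 0.85`, peaks at
0.8 (analytical) and 0.2 (intuitive), `sharpness = 5` for the
analytical curve (exponents (4, 1)) and `0.72` for the intuitive curve
(a much broader hump). `p_peak + P0 = 0.95 < 1` keeps the probability
budget valid for every action.

The two sharpness values are the model's only calibrated quantities,
fixed once from two drift conditions implied by the published ensemble
outcomes, not fitted to simulation output:

1. *Habitual drift.* The `p_r = 0.6` autopilot (decisions ≈ N(0.6,
   0.08)) must climb from `s0 = 0.2` to ≈ 0.5 within `T = 100`, i.e.
   the mixed curve must satisfy `M(0.6) ≈ 0.6` so that the per-step
   drift `M − (1 − M − P0) ≈ 0.3` accumulates to ≈ +0.3 over the
   horizon.
2. *Optimal plateau.* The same individual's optimal late-horizon
   decision sits near 0.8, i.e. `argmax M ≈ 0.8`.

A narrow intuitive hump (e.g. exponents (1, 4)) violates both: it gives
`M(0.6) ≈ 0.41` (downward drift — the habitual ensemble would sink to
the lower clamp) and pushes `argmax M` to ≈ 0.6. Broadening the
intuitive curve (sharpness 0.72, exponents ≈ (0.14, 0.58)) yields
`M(0.6) ≈ 0.60` and `argmax M ≈ 0.78`, satisfying both conditions while
preserving every qualitative feature, including the decline of the
intuitive curve over (0.2, 1) and its limits `p_floor` at both
endpoints. With these defaults the mirror identity
`intuitive(u) = analytical(1−u)` no longer holds; it is recovered (and
tested) when both sharpness values are set equal.

## Rewards and discounting

Stage reward `r(s, u) = α·s − β·u` exactly as specified. The terminal
reward is the normalised exponential `R·(e^{k·s} − 1)/(e^k − 1)` with
defaults `R = 10`, `k = 5`: it spans a decisively different reward
between low and high end states while remaining commensurate with
cumulative stage rewards at the experiments' α, β scales (`k → 0`
degenerates to the linear `R·s`).

The emotion profile is `δ(s) = 1 − c·e^{−k_e·s}`, the minimal smooth
form that is negative at low awareness and near 1 at high awareness.
Defaults `c = 4`, `k_e = 4` place the zero crossing at
`s = ln(4)/4 ≈ 0.347` and give `δ(0.99) ≈ 0.92`. The crossing location
is behaviourally load-bearing: the published emotion experiments start
at `s0 = 0.2` and show harmful dynamics there (collapse for the
analytical individual, oscillation for the intuitive one), which
requires `δ(0.2) < 0`; a shallow profile with the crossing near 0.1
(e.g. `c = 1.5`) would place those runs in the benign regime and
produce neither behaviour. Both parameters are config-exposed.

In emotion mode the future weight of the backup at stage `τ` is
`D(s, τ) = δ(s)·τ/T`, read at the recursion's own stage index: the
weight grows linearly from 0 at the first epoch to ≈ `δ(s)` at the
horizon (an older individual weighs the future more). Emotions affect
only the planner; realised stage rewards are always reported
unweighted, and the habitual policy is unaffected.

## Solver semantics

Backward induction from `τ = T−1` to 0 with the direction-weighted
backup

    V_τ(s) = max_u r(s,u) + D(s,τ)·[γ1·V_{τ+1}(s⁺)·p_up(u)
             + γ2·V_{τ+1}(s)·p_stay + γ3·V_{τ+1}(s⁻)·p_down(u)].

Choices made here:

- The γ weights are applied exactly as written — a distorted,
  *non-normalised* expectation. They are not rescaled even though the
  experiment values (3, 1, 0.1) and (3.7, 1, 0.01) exceed the (0, 1)
  range the model text states for them; renormalising would change the
  optima. Consequence: whenever `D·(γ1·p_up + γ2·p_stay + γ3·p_down) > 1`
  the value function grows geometrically backward from the horizon.
  With `γ1 ≈ 3–3.7` and the experiments' discounts this factor is ≈ 1.7
  per stage, so values reach ~1e20 over 100 epochs; float64 absorbs
  this without overflow for every bundled preset, and the argmax is
  scale-invariant.
- Ties in the argmax break toward the smallest `u`: analyticity is
  costly, so the cheaper action wins; deterministic and reproducible.
- `V_T` is fixed to the terminal reward exactly.
- The habitual policy draws a clipped Gaussian (not a re-drawn
  truncated one) and snaps to the action grid; at `σ = 0.08` the
  clipping bias is ≈ 0 and at `σ = 0.3` it remains below half a grid
  step.

With `γ = (1, 1, 1)` and constant `δ` the backup reduces to the
textbook finite-horizon expectation; an independently coded
plain-expectation evaluator cross-checks that case in the tests, and an
exhaustive policy enumeration on tiny instances verifies the solver's
optimality under the distorted semantics. Backward induction is a
guaranteed global maximiser only when all backup coefficients are
nonnegative; with emotion mode at low awareness `D < 0` and the
procedure is the model's defined computation rather than a certified
optimum, so the enumeration instances keep `δ(s) ≥ 0`.

## Simulation

Trajectories realise the walk with a single uniform per step compared
against the cumulative (up, stay) thresholds. Per-run generators are
spawned as `SeedSequence(master_seed).spawn(N)`; within a run the
stream order is: uniform initial-state draw (only when `s0 =
"uniform"`), the `T` habitual decision normals (habitual runs only),
then the `T` shock uniforms. A (config, master seed) pair therefore
fully determines every output, and ensemble run `i` is bit-identical to
a single-trajectory run with child seed `i`. Paired habitual/self-aware
comparisons reuse the same child seeds (common random numbers).

Ensemble sizes follow the published experiments (`N = 3000`); the
bundled presets run in seconds on one CPU, so no scaling-down was
needed. Exact distribution propagation (pushing the full occupancy
vector through the kernel) provides the infinite-`N` limit for tests;
for the habitual policy the state-independent action distribution is
marginalised out of the kernel in closed form (Gaussian band masses
with clipped tails), which is exact because decisions are independent
of state and shock.

## What the experiments do and do not show

The bundled presets are self-generating: no external data enters. They
emulate the published ensemble experiments — habitual vs self-aware
dynamics for a moderately analytical individual, and emotion-modulated
self-aware dynamics for analytical and intuitive individuals from low
and high starts. With the calibrated defaults the package reproduces:
the habitual endpoint ≈ 0.5; the self-aware advantage (final mean state
≈ 0.73 > 0.5); the late-horizon optimal decision plateau ≈ 0.77; the
low-start emotion collapse of the analytical individual (final mean
state ≈ 0.02); and the low-start emotion oscillation of the intuitive
individual (alternating high/low decisions with the mean state stalled
≈ 0.35 — the policy alternates push/avoid across adjacent states around
the δ zero crossing, which acts as a trap).

One published outcome is *not* reproduced, and we believe it cannot be
under the model's own printed equations: the high-start analytical
emotion run is reported to stabilise near 0.7, but under the
non-normalised γ-weighted recursion the value function explodes
backward from the horizon, so wherever `δ(s) > 0` the late-horizon
policy simply maximises the forward probability (the stage cost βu is
negligible against the future term) and the ensemble is absorbed at the
top clamp (measured plateau ≈ 0.99). The absorption is robust: the
habitual-drift calibration (condition 1 above) forces the `p_r = 0.8`
mixture to have maximum forward probability ≥ 0.52, i.e. up-drift
≥ +0.13 at the chosen action, for *any* curve shapes in the family —
and the literal uncalibrated shapes give the same ≈ 0.99 plateau. The
corresponding acceptance check is left failing rather than adjusted.

## Known limitations

- The base curves, terminal reward and emotion profile are pinned
  parametric forms chosen to match described qualitative features; none
  is estimated from behavioural data.
- The kernel is state-independent (the same transition row at every
  state), so stabilisation at interior states can only arise from the
  policy's state dependence, which the exploding value recursion mostly
  removes (see above).
- Single-step shocks only; no multi-step moves, no continuous state or
  action, no inter-individual network effects.
- The habitual policy is memoryless noise around `p_r`; no learning or
  habit formation is modelled.
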