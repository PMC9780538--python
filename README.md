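# awaremdp

A finite-horizon Markov decision model of the dynamics of *awareness* in
human decision-making, built for computational cognitive / behavioural
modelling: it lets you ask what happens to an individual's awareness
level when decisions are made on autopilot versus under metacognitive
self-observation, and how visceral emotions reshape that picture.

## The model

The decision-maker's awareness is a scalar state `s_t` on the grid
{0.01, 0.02, …, 0.99}. At each epoch `t = 0, …, T−1` they choose a
degree of analyticity `u_t ∈ (0, 1)` (higher = more deliberate,
data-driven, and costly). The state then takes one step of a
birth/stay/death walk, `s_{t+1} = s_t + w_t·0.01` with `w_t ∈ {+1, 0, −1}`:

- `P(w = +1) = P1(u) = p_r·P1_analytical(u) + (1 − p_r)·P1_intuitive(u)`,
  a mixture of two unimodal curves weighted by the individual's
  *reasoning propensity* `p_r ∈ [0, 1]` (0 = intuitive, 1 = analytical).
  The analytical curve peaks at `u = 0.8` and declines beyond it —
  excessive analyticity overfits the available information; the
  intuitive curve peaks at `u = 0.2` and declines as reasoning becomes
  more analytical, reflecting confidence in tacit knowledge.
- `P(w = 0) = P0 = 0.1`, a constant inertia term.
- `P(w = −1)` is the residual.

Rewards are `r(s, u) = α·s − β·u` per stage (awareness is good,
deliberation is costly) plus an increasing exponential terminal reward
`R·(e^{k·s_T} − 1)/(e^k − 1)`. Two policies are compared:

- **habitual** — `u_t = e_t ~ N(p_r, σ)`, clipped and grid-snapped:
  noisy autopilot, blind to the state;
- **self-aware (optimal)** — computed by backward induction on the
  direction-weighted Bellman recursion

  `V_τ(s) = max_u r(s, u) + D(s, τ)·[γ1·V_{τ+1}(s⁺)·P1 + γ2·V_{τ+1}(s)·P0 + γ3·V_{τ+1}(s⁻)·P−1]`

  where `γ = (γ1, γ2, γ3)` weights up/stay/down moves and `D` is the
  future weight: a constant `δ`, or — with the emotion extension — the
  state- and time-dependent `δ(s)·t/T` with `δ(s) = 1 − c·e^{−k_e·s}`,
  negative at low awareness (harmful immediacy) and near 1 at high
  awareness.

Monte Carlo ensembles (`N` seeded trajectories) reproduce the model's
published experiments as data tables; exact distribution propagation
and a brute-force policy-enumeration oracle back the test suite.

## Worked example

Compare habitual and self-aware behaviour for a moderately analytical
individual (`p_r = 0.6`, `σ = 0.08`, `s0 = 0.2`, `α = 1`, `β = 1.5`,
`γ = [3, 1, 0.1]`, `δ = 0.75`, `T = 100`, `N = 3000`):

```
$ awaremdp compare --preset fig6 --seed 1 --out demo/
final mean state: habitual 0.505, self-aware 0.727
```

The habitual ensemble drifts up from 0.2 and ends near 0.5 — the noisy
autopilot around `u ≈ 0.6` has modest upward drift. The self-aware
policy instead holds the decision near the mixture's sweet spot
(`u ≈ 0.77–0.8`), ending near 0.73: the feedback loop of
self-observation converts the same individual traits into a markedly
higher final awareness (difference ≈ 0.22, standard errors ≈ 0.002).
`demo/summary.json` holds the per-epoch means and standard errors, the
configuration echo and its hash.

Other subcommands: `awaremdp solve` (policy/value matrices as CSV),
`awaremdp simulate` (one ensemble), `awaremdp curves` (transition and
reward/discount curve diagnostics), `awaremdp run` (full bundle),
`awaremdp presets`. Presets `fig7a/b/c` and `fig8a/b/c` bind the
emotion experiments (`α = 10`, `β = 20`, `γ = (3.7, 1, 0.01)`,
`T = 300`, `p_r = 0.8` or `0.2`, `s0 = 0.2` or `0.9`).

Everything is reproducible: a configuration plus a master seed fully
determines every reported number (per-run seeds are spawned
deterministically from the master seed).

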