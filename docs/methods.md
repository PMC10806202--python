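# Methods

## Models

Four nested Q-learning variants over the three-action space
{ALP, MNP, ILP}.  All carry per-action values `Q[a]`, initialized at free
parameters `q0[a] ∈ [−1, 1]`; the trace models additionally carry choice
traces `C[a]`, initialized at 0.  Per event:

- reward prediction error `δ = r − Q[chosen]`, with the outcome binarized
  (r = 1 food reward, 0 otherwise);
- `Q[chosen] += α_eff · δ`, where `α_eff` is `α` (SimpleQ, perseverance),
  `α₊` if δ ≥ 0 else `α₋` (asymmetry; the tie at δ = 0 is assigned to `α₊`,
  which is inert since a zero δ changes nothing), or 0 (NoLearn);
- for the trace models, all three traces update
  `C[a] += τ·(1[a = chosen] − C[a])`: the chosen trace moves toward 1,
  unchosen traces decay toward 0.  The indicator rule is applied to every
  action each step, not only the chosen one.
- choice probabilities are softmax over logits `β·Q[a] + φ[a]·C[a]`
  (trace term absent for SimpleQ/asymmetry), evaluated with
  max-subtraction so extreme logits cannot overflow.

`τ ∈ [−1, 1]` is accepted for completeness; negative values make traces
diverge and are covered only by a smoke test.  The generator and fitting
starts use τ ∈ (0, 1).

## Task environment

PR requirement `round(5·exp(0.2·R) − 5)` with round-half-away-from-zero —
the only rounding that reproduces the canonical 15-element escalation
(plain floor fails at R = 5, where 8.59 must give 9).  Breakpoint =
requirement(number of rewards earned), 0 for rewardless sessions.

Reward collection is modeled as a *forced* magazine nosepoke: it updates
`Q[MNP]` and the traces with r = 1 but is not a free choice and therefore
contributes no likelihood term.  The active press that completes a ratio is
itself updated with r = 0 like any other choice; the reward is a separate
subsequent event crediting the magazine check.

Session rules (defaults): 30-s inter-trial interval after each reward,
0.5-s post-press refractory period, termination at 60 min, 100 rewards, or
5 min without an active press.  Timing affects only synthetic timestamps;
the models are event-indexed.

## Likelihood and fitting

One likelihood term per free choice (ALP/MNP/ILP).  The per-event recursion
is strictly sequential, so the inner loop is JIT-compiled (numba); a pure
Python reference path and the compiled kernel are held to 1e-10 agreement
against a third, independently written brute-force recursion in the tests.

Optimization: L-BFGS-B over transformed coordinates — learning rates via
logit (natural scale (0, 1)), β via softplus capped at 100, `q0` and τ
box-constrained to [−1, 1], φ box-constrained to [−30, 30].  The φ and β
caps are deliberate regularization: beyond `|φ·C| ≈ 20` the softmax is
saturated and the likelihood flat, so whenever a session happens to contain
no repeat of an avoided action (separation) the unconstrained MLE diverges
to infinity while fitting the data no better.  Multi-start (default 10):
the first start is a data-driven heuristic (initial values proportional to
observed choice frequencies), the rest seeded uniform draws over the
plausible natural ranges.  Fits are deterministic given the seed.

Free-parameter accounting: literal enumeration gives 5 (SimpleQ),
6 (asymmetry), 9 (perseverance: α, β, 3×q0, τ, 3×φ) and 8 (NoLearn).  A
widely used alternative convention charges the trace models 8 and 7;
`FitConfig(paper_param_counts=True)` applies that penalty instead.  The
discrepancy is one parameter and affects only the AIC constant, never the
likelihood or the ranking between the two trace models.

AIC winner: lowest AIC, ties resolved to the first model in canonical
order (SimpleQ, asymmetry, perseverance, NoLearn) and visible in the table.

## Free-run simulation and RPE trends

Free runs sample choices from the softmax policy inside the task loop,
with one seeded generator driving both policy and timing.  Inter-choice
intervals are lognormal with median 0.9 s and log-scale SD 1.0, floored at
the refractory period; the heavy tail stands in for natural pauses and
yields realistic 60-min sessions (~1,500–2,000 choices, reward counts in
the empirically observed 8–22 band).  The ITI follows each reward; the
reward event is stamped 0.05 s after the completing press.

RPE trends are ordinary least squares with a two-sided t-test on the
slope: |δ| at void magazine checks against event ordinal, and δ at rewards
against reward ordinal.  A constant series (e.g. NoLearn, where `Q[MNP]`
never moves) reports exactly zero slope with p = 1.

## Parameter recovery

Default "true" sampler, centered on the regime fitted mouse behavior
occupies: α logit-uniform on (1e−4, 0.1), β ~ U(5, 30), q0 ~ U(0, 1) per
action, τ ~ U(0.3, 0.95), φ_ALP ~ U(−3, 3), φ_MNP ~ U(−25, −5),
φ_ILP ~ U(−3, 5).  Each simulation free-runs one session (the acceptance
protocol fixes 1,000 choices per session), refits, and records the
true/recovered pair; the report carries per-parameter Pearson correlations
and the cross-correlation matrix of recovered values.  Simulations whose
sampled agent never earns a reward are skipped and counted: such runs end
by the 5-min inactivity rule, are not PR sessions in any meaningful sense,
and their fits are ill-posed.

## Photometry chain

1. **Ratiometry** — 465/405 elementwise; frames with a non-positive
   reference are invalid (NaN).  Multiplicative artifacts shared by both
   channels cancel exactly.
2. **High-pass** (~0.0167 Hz, 1-min wavelength) — default is subtraction of
   a 60-s centered moving average (constants and linear drift vanish;
   few-second transients pass with ≤ ~3% attenuation); a 2nd-order
   zero-phase Butterworth alternative is available.  Invalid frames are
   interpolated for filtering and restored to NaN.
3. **z-scoring** — one pooled mean/SD from the last 20 s of every
   inter-trial interval, applied session-wide (the early ITI is
   contaminated by consumption dopamine).  Pooling across ITIs, rather
   than per-trial baselines, is a deliberate reading of the procedure.
   Zero pooled variance is an error.
4. **Peri-event extraction** — 100-ms bins over a (−2, +5) s window;
   per-event amplitude is the signed minimum (magazine dips) or maximum
   (reward surges) over (0, 3] s post-event.  Events without full 3-s
   coverage are excluded with a warning.
5. **Trend regression** — OLS of amplitude on event ordinal.  Because dip
   amplitudes are signed (negative), a shrinking dip appears as a
   *positive* slope toward zero.

## Synthetic photometry generator

Two channels at 20 Hz: shared exponential bleaching (default time constant
1200 s on both channels, so ratiometry cancels it exactly; per-channel
overrides exercise the high-pass stage), white fractional noise split
across the channels so the reconstructed ratio has fractional noise SD
`noise_sd` (default 0.005), and event-locked gamma-shaped transients:
reward surges peaking 1.0 s post-event (default +5.2 z, growing
+5.2e−2 z/reward) and magazine dips troughing at 1.5 s (default −0.57 z,
attenuating +5.4e−3 z/event, clamped at zero — a dip shrinks to nothing,
it does not invert).  Kernels are confined to (0, 3] s.

Amplitudes are specified in z units — multiples of the post-filter baseline
SD — so the analysis chain's z-scored output is directly comparable to the
injected truth.  With zero noise the ITI baseline has no variance and
z-scoring is undefined by construction; noiseless calibration therefore
fixes `signal_scale` explicitly and checks recovery on the filtered ratio
divided by that known scale.

What the generator does *not* emulate: motion artifacts beyond shared
multiplicative terms, sensor kinetics and saturation, anticipatory ramps
near ITI end (a pre-event bump is available but off by default),
correlated noise, or hemodynamic-like slow oscillations.  Passing tests
show the chain recovers what it is defined to recover — not that these
omitted features would be handled gracefully in vivo.

## Cross-condition comparison

`condition_compare` reduces each cohort of fits to per-parameter mean ±
SEM and a two-sided t-test (paired or unpaired), reporting raw p-values;
an optional Holm correction can be applied by the caller.  This is the
operation by which a drug effect expressed purely through initial action
values — higher `q0` across actions without changes in α, β, τ, φ —
becomes visible.  Constant parameters in both cohorts (e.g. pinned by a
bound) report t = 0, p = 1 rather than NaN.

## Problem sizes and numerical choices

Validation problem sizes, chosen once as adequate-but-economical study
conditions: 120 random logs for oracle equivalence (tolerance 1e−10); 50
free-run sessions for the choice-ordering check (≥ 80% must order
ALP > MNP > ILP); 50 recovery simulations at 1,000 choices with 10
optimizer starts; 20 sessions for four-model AIC selection and 10 for the
NoLearn nesting gap; 16 sessions per condition for the initial-value shift
and 10 replicates of 8-vs-8 null cohorts; 5 seeds for photometry
trend-sign recovery.  Bulk fitting uses 5 optimizer starts; single-fit
default is 10.

Known limitations: β is weakly identified when α is tiny (a β·Δq0 ridge;
its recovery correlation is positive but modest), AIC inherits the
parameter-accounting ambiguity above, the behavioral generator produces
more total choices than a typical mouse session at matched duration, and
the free-run model has no mechanism to *stop* responding — it describes
choice allocation, not the breakpoint itself.
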