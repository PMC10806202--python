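# prtrace

Choice-trace reinforcement-learning analysis of progressive-ratio (PR)
lever-press sessions, with a companion fiber-photometry dopamine-signal
pipeline.

## The problem

The PR schedule is the workhorse assay of operant motivation: the number of
active lever presses (ALP) required per food reward escalates after every
reinforcer as `round(5·exp(0.2·R) − 5)` — 1, 2, 4, 6, 9, 12, 15, 20, 25, …
— and the largest ratio completed, the *breakpoint*, is the classical
readout.  The breakpoint discards the entire within-session stream of
choices.  Mice in these sessions actually distribute behavior over three
choices — the reinforced lever (ALP), *void* magazine nosepokes (MNP,
checking the food port before the ratio is done), and the inactive lever
(ILP) — and that stream carries information the breakpoint cannot.

`prtrace` models the stream with four nested Q-learning variants over the
three-action space:

| model | value update | policy logits | free params |
|---|---|---|---|
| SimpleQ | `Q[a] += α(r − Q[a])` | `β·Q[a]` | 5 |
| asymmetry | `α₊` for δ ≥ 0, `α₋` for δ < 0 | `β·Q[a]` | 6 |
| perseverance | as SimpleQ, plus choice traces | `β·Q[a] + φ[a]·C[a]` | 9 |
| NoLearn | perseverance with α ≡ 0 | `β·Q[a] + φ[a]·C[a]` | 8 |

Choice traces decay as `C[a] += τ·(1[a chosen] − C[a])`; per-action weights
`φ[a]` produce perseverance (φ > 0) or avoidance of repetition (φ < 0).
Initial action values `Q₀[a]` are free parameters — pretraining leaves real
animals with strong priors.  Rewards update the magazine-check value
(collecting the pellet is a forced nosepoke with r = 1) and contribute no
likelihood term; every free choice contributes `log P(choice)`.  Models are
fitted by multi-start bounded maximum likelihood and compared by
`AIC = −2 log L + 2k`.

The package also includes: generative *free-run* simulation of full PR
sessions (with reward-prediction-error trajectories: at a reward
δ = 1 − Q[MNP], at a void check δ = −Q[MNP]); a parameter-recovery harness;
a photometry chain (465/405 ratiometry → 1-min high-pass → pooled late-ITI
z-scoring → 100-ms peri-event binning → amplitude/trend regression); and
synthetic generators for both behavior and session-locked photometry, so
everything is testable without animal data.

## Worked example

```python
import prtrace as pt

# one full simulated session in the fitted-mouse parameter regime
run = pt.free_run(pt.REFERENCE_PERSEVERANCE_PARAMS, "perseverance", seed=5)
print(run.counts, run.breakpoint)
# {'ALP': 1315, 'MNP': 561, 'ILP': 76, 'REWARD': 19} 219

cmp = pt.compare_models(run.log, config=pt.FitConfig(n_starts=5, seed=0))
print(cmp.table)
#        model  loglik  n_free_params    aic  delta_aic  winner
#      simpleq -1415.2              5 2840.5     1045.3   False
#    asymmetry -1403.8              6 2819.6     1024.5   False
# perseverance  -888.6              9 1795.1        0.0    True
#      nolearn -1009.1              8 2034.3      239.2   False

mnp_trend, reward_trend = pt.rpe_trends(run)
print(mnp_trend.slope, reward_trend.slope)
# -4.10e-04  +7.97e-03
```

Reading the output: the session shows the characteristic ALP > MNP > ILP
frequency ordering and a breakpoint of 219 presses from 19 rewards.  AIC
picks the generating perseverance model by a wide margin (ΔAIC > 200
against its own no-learning reduction).  The trend lines are the model's
physiological prediction: the magazine-check RPE magnitude shrinks over the
session (slope < 0) while the reward RPE grows (slope > 0), because the
small positive learning rate slowly drains `Q[MNP]` between rewards — the
pattern mirrored by striatal dopamine dips and surges.

The same flows are scriptable from the shell:

```bash
prtrace synth session --seed 5 --out session.csv
prtrace fit --events session.csv --model perseverance --starts 10 --seed 1 --out fit.json
prtrace compare --events session.csv --models all --seed 1
prtrace synth photometry --events session.csv --seed 5 --out da.csv
prtrace photometry --trace da.csv --events session.csv --event-type MNP
prtrace recover --model perseverance --n-sims 50 --seed 7
```

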