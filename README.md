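# twostep

Simulation and analysis of the **two-stage Markov decision task** ("magic
carpet" task), the standard behavioral paradigm for separating
**model-based** from **model-free** reinforcement-learning control. The
package is aimed at computational-psychiatry researchers who want to (a)
generate realistic synthetic trial logs from hybrid RL agents under a
clinical-study design — group (control vs PTSD) × exercise condition
(light vs moderate) × delay (short vs long) × visit — and (b) run the
stay/switch logistic-regression machinery that quantifies model-based
control from such logs, real or simulated.

## The task and the statistic

On each trial a first-stage choice between two options leads with
probability 0.7 to that option's preferred second-stage state ("common"
transition) and with probability 0.3 to the other ("rare"); the two
options prefer opposite states. A second-stage choice then pays a unit
reward with probability drifting trial-to-trial as a reflected Gaussian
random walk inside [0.25, 0.75]. Sessions are 250 trials in 5 blocks.

Behavior is scored by whether the first-stage choice on trial *t* repeats
the choice on trial *t − 1* (*stay*). With previous reward and previous
transition effect-coded ±0.5, the stay model

```
logit P(stay) = β0 + βr·reward + βt·transition + βrt·(reward × transition) + …
```

separates the two controllers: a **model-free** learner stays after reward
regardless of transition (βr > 0, βrt ≈ 0), while a **model-based**
learner inverts its preference after rare transitions (βrt > 0). The
fitted **βrt is the model-based index**. The omnibus model crosses
reward × transition with condition, delay, group and visit, adds site,
mean-centered age (fully interactive with the behavioral family) and IQ,
and is fit by maximum likelihood (IRLS) with cluster-robust standard
errors by subject; only omnibus effects with p < .001 are interpreted.

## Worked example

```python
from twostep import CohortSpec, TaskConfig, generate_cohort, omnibus_model, significance_gate
from twostep.stay_switch import features_from_logs, qc_invariant_responders

logs = generate_cohort(CohortSpec(n_per_cell=15, seed=1), TaskConfig())
logs, excluded = qc_invariant_responders(logs)
features = features_from_logs(logs)           # 29,880 lagged trials
fit = omnibus_model(features)                 # 98-term logistic fit
print(fit["prev_reward:prev_transition"])
print(significance_gate(fit, alpha=0.001)[["term", "estimate", "statistic", "p"]].head(3))
```

Output:

```
{'estimate': 0.7448, 'se': 0.0766, 'statistic': 9.7227, 'p': 0.0}
                       term  estimate  statistic            p
                  intercept  0.808496  18.555545 7.355797e-77
                prev_reward  0.531306  15.295495 8.193509e-53
prev_reward:prev_transition  0.744753   9.722728 2.412303e-22
```

The reward × transition coefficient (0.74 log-odds) is the cohort's mean
model-based index; the positive intercept is the overall tendency to
repeat choices, and the reward main effect the model-free component. The same pipeline is
available from the shell:

```bash
twostep simulate --config config.yaml --out runs/sim
twostep analyze runs/sim/trials.csv --config config.yaml --out runs/analysis
twostep recover --config config.yaml --out runs/recovery
```

`analyze` writes the lagged-feature CSV, the omnibus and simple-effects
fit tables, per-cell 2×2 stay-probability tables with Cohen's d support,
and a plain-text report; every stage writes a JSON manifest with its
resolved configuration and row counts.

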