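# rcirt

Reliable change indices from graded-response IRT models, with empirical
latent-trait priors.

## The problem

Clinicians and applied researchers often need to decide whether a *specific
person* has changed between a pre-test and a post-test on a polytomous
questionnaire — not just whether the group average moved. The classical
reliable change index (RCI) answers this with sum scores and a constant
standard error of the difference,

    RCI_CTT = (X_post − X_pre) / SE_d,      SE_d = √2 · SD(X) · √(1 − α),

referred to N(0,1). Because SE_d is constant, the CTT form is too liberal in
the middle of the score range and too conservative at the extremes. The
model-based alternative scores each occasion with an item response theory
(IRT) model and lets precision vary over the trait range:

    RCI_IRT = (θ̂_post − θ̂_pre) / √(SE²(θ̂_post) + SE²(θ̂_pre)).

This package implements `RCI_IRT` under the graded response model (GRM) with
a scoring toolbox — maximum likelihood, Warm's weighted maximum likelihood
(WML), EAP, MAP, and summed-score EAP via the Lord–Wingersky recursion — and
adds the *empirical-prior* augmentation: when post-test data are available,
the post-test latent distribution N(μ_post, σ²_post) is estimated by marginal
maximum likelihood with item parameters held fixed on the pre-test N(0,1)
metric, and EAP scoring of the post-test uses that fitted prior. When the
group really changes, this borrows group-level strength for each person's
change decision, trading a small shrinkage bias for lower sampling variance
and higher power.

A Monte Carlo module replicates the accompanying simulation study: Type I
error, power, and bias/RMSD of Δθ̂ = θ̂_post − θ̂_pre across test lengths
J ∈ {5, 10, 20}, true changes Δθ ∈ {0, −0.5, −1, −1.5}, conditional θ values
from −2.5 to 3.5, homogeneous/heterogeneous item designs, and post-test EAP
priors N(0,1), N(−0.2,1), N(−0.5,1), N(−0.8,1).

The GRM uses the pure logistic metric (no 1.7 scaling constant), matching
modern IRT software defaults.

## Worked example

Score a 500-person pre/post cohort (10 five-category items, true group
change −0.5) through the empirically-augmented pipeline:

```python
import numpy as np
import rcirt as rc

rng = np.random.default_rng(42)
bank = rc.sample_item_bank(rc.ItemDesign.homogeneous(), 10, rng)
theta_pre = rng.normal(0, 1, 500)
pre = rc.simulate_responses(bank, theta_pre, rng)
post = rc.simulate_responses(bank, theta_pre - 0.5, rng)

frame, fit = rc.augmented_rci_pipeline(bank, pre, post, level=0.10)
print(fit.prior)             # GaussianPrior(mean=-0.522..., var=1.0)
print(frame.reject.mean())   # 0.31
print(frame.head(3).round(3))
```

```
   person_id  theta_pre  se_pre  theta_post  se_post  statistic  p_value  reject
0          0     -0.249   0.261      -0.346    0.295     -0.248    0.804   False
1          1     -0.998   0.359      -1.916    0.581     -1.345    0.179   False
2          2      1.152   0.302       0.316    0.270     -2.064    0.039    True
```

The fitted post-test prior mean (−0.52) recovers the simulated group shift;
the pipeline flags 31% of persons as reliably changed at α = .10, versus 26%
when both occasions are scored with prior-free WML — the power gain from the
empirical prior. Per person, `statistic` is `RCI_IRT` and negative values
mean improvement (lower severity).

The same analyses are available from the shell:

```sh
rcirt score --items items.csv --responses pre.csv --method wml --out scores.csv
rcirt calibrate-prior --items items.csv --post post.csv --out prior.json
rcirt rci --items items.csv --pre pre.csv --post post.csv --method eap --out rci.csv
rcirt sumscore-table --items items.csv --prior-mean -0.5 --out table.csv
rcirt calibrate-ctt --items items.csv --n-cal 100000 --seed 1 --out cal.csv
rcirt simulate --config sim.yaml --out-dir sim_out/
```

## Layout

| module | contents |
| --- | --- |
| `rcirt.grm` | GRM probabilities, likelihoods, Fisher information, response simulation |
| `rcirt.estimators` | ML / WML / EAP / MAP / summed-score EAP, batch scoring |
| `rcirt.ctt` | sum scores, coefficient α, SEM, SE_d calibration |
| `rcirt.rci` | the two RCI statistics and the significance decision |
| `rcirt.empirical_prior` | g(θ_post) moment estimation, augmented pipeline |
| `rcirt.simulation` | item-bank samplers, condition runner, aggregation |
| `rcirt.io`, `rcirt.cli` | delimited-text formats and the `rcirt` command |

See `docs/methods.md` for the model, estimation details, and the design
choices behind the simulation profiles.
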