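# percross

Analysis pipeline for **perceptual-crossing** experiments: a minimal
two-player paradigm in which partners search for each other in an invisible
1D circular space (600 units, wrapping) using only a binary tactile sensor.
Each player feels three indistinguishable objects — the partner's avatar, a
"shadow" decoy rigidly attached to the partner at a 150-unit offset, and a
static object — and may click once per trial to signal "this is the other
person", then rates the clarity of the other's perceived presence on the
4-point Perceptual Awareness Scale (PAS: no / ambiguous / almost clear /
clear experience).

The package is for behavioural scientists running or re-analysing this
paradigm. It provides:

* **environment** — torus geometry, overlap/sensor mechanics, and a
  scriptable trial simulator;
* **trial_data** — a validated data model and CSV/JSON I/O for sessions
  (`events.csv`, `trajectories.csv`, `session.json`);
* **click_classification** — deterministic distance-based click-target
  assignment with ambiguity flagging (replacing manual trajectory review);
* **descriptives** — count tables, conditional PAS cross-tabs, team scores,
  inter-click-interval densities and the analytic uniform-independence null;
* **bayes_model** — a hierarchical Bayesian probit **path model** linking
  individual success, joint success, click synchrony and PAS;
* **synthetic_data** — generators with known ground truth at two fidelity
  levels (event-level, exactly matching the model; and full behavioural
  trajectories from stochastic controllers);
* a `percross` CLI (`simulate | classify | describe | fit | recover | report`).

## The model

For player *i* of dyad *j* in trial *t*, with `D_jt` the synchrony
indicator (both clicks within 3 s):

```
individual success   S ~ Bernoulli( Φ( a_i + b_i (min(t, τS_i) − 1) + λS D ) )
joint success        G ~ Bernoulli( Φ( c_j + λG D ) )
PAS rating           Y ~ OrdinalProbit( u_i + v_i (min(t, τP_i) − 1)
                                        + γS S + γG G + γD D ;  κ1<κ2<κ3 )
```

Learning is piecewise: improvement with non-negative slope up to an
individual breakpoint (τ), then consolidation. Random intercepts, slopes
and breakpoints are hierarchical across individuals/dyads; the latent PAS
residuals of the two dyad members in the same trial share a correlation ρ.
The posterior is sampled by an adaptive Metropolis-within-Gibbs scheme
(vectorised across dyads) with split-R̂/ESS diagnostics, and summarised by
means and 95% highest-posterior-density intervals (HPDI), including the
indirect synchrony → joint success → clarity pathway λG·γG.

## Worked example

```python
import percross as px

# a study-design synthetic session: 10 dyads x 20 trials x 60 s
ds, truth = px.generate_events(px.SyntheticConfig(seed=1))
outcomes = px.trial_outcomes(ds)          # per-trial outcomes, 3-s window
cs = px.count_summary(outcomes)
print(f"clicks: {cs.n_clicks}/{cs.n_possible_clicks} ({100*cs.click_rate:.0f}%), "
      f"correct: {100*cs.correct_rate:.0f}%, joint trials: {100*cs.joint_rate:.0f}%")
print("null P(interval < 3 s) =", px.null_interval_cdf(3.0, 60.0))

data = px.ModelData.from_outcomes(outcomes)
res = px.fit(data, seed=1)
print(px.posterior_summary(res)[["parameter", "mean", "hpdi_lower", "hpdi_upper"]].round(2))
```

prints (elided):

```
clicks: 313/400 (78%), correct: 78%, joint trials: 38%
null P(interval < 3 s) = 0.0975
  parameter   mean  hpdi_lower  hpdi_upper
   lambda_S   0.47        0.00        0.96
   lambda_G   1.23        0.67        1.81
    gamma_S  -0.06       -0.34        0.25
    gamma_G   0.85        0.57        1.16
 mean_tau_S   5.70        3.10        9.29
 mean_tau_P   4.13        1.66        7.69
    ...
```

i.e. roughly 80% of possible clicks are produced, ~3 in 4 are correct, and
the refit recovers a clear positive effect of *joint* success on perceptual
clarity (`gamma_G`) together with a strong synchrony → joint-success link
(`lambda_G`), while the individual-success effect (`gamma_S`) straddles
zero — the dyad-level, not the individual-level, explains clarity.
`mean_tau_S` / `mean_tau_P` are the average learning breakpoints (the trial
at which the success and clarity curves flatten).

The same pipeline runs from the shell:

```bash
percross simulate --out session --teams 10 --trials 20 --seed 3
percross report --events session --out report --seed 3
```

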