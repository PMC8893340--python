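# conformity

Simulation and analysis of **informational vs. normative social
conformity** in a circular advice-taking task, for computational
cognitive neuroscientists who want to validate this family of analyses
— circular revision statistics, mixed-effects revision models, and
event-locked ROI time-course fMRI statistics — against synthetic data
with known ground truth.

## The problem

When someone revises a judgement after seeing another's opinion, two
forces are confounded: *informational* conformity (revising because
one's own confidence is low) and *normative* conformity (revising to
reciprocate the influence one previously exerted on the partner).  The
task this package simulates separates them.  Participants estimate an
angular location, report confidence c ∈ {1..6}, and on alternating
trials either revise towards a simulated partner or watch the partner
revise towards them.  Partner susceptibility is experimentally
controlled — insusceptible partners draw their influence from
U[0, 0.2], susceptible ones from a mixture with half its mass on
[0.7, 1] — and a computer-partner condition removes the normative
channel while leaving the informational one intact.

The behavioural quantity is the shift fraction on the circle,
revision r_t = arc(initial, revised) / arc(initial, partner initial),
modelled with linear mixed effects.  Per condition:

    r_t = β1s + β2s·c_t + β3s·inf_{t−1} + β4·c_t·inf_{t−1} + ε

with c_t = confidence/6, inf_{t−1} the influence exerted on the partner
on the preceding observation trial, random intercept and slopes per
subject (b_ks ~ N(0, σ_k²)), REML estimation and Satterthwaite degrees
of freedom.  A pooled model adds a partner-type dummy (1 = human,
2 = computer) and its interactions.  On the neural side, synthetic ROI
BOLD with injected linear encodings is pushed through the
time-course pipeline: nuisance residualisation, 0.2 s upsampling,
75-point epochs locked 1 s before event onset, a per-timepoint GLM

    BOLD = β0 + β1·c_t + β2·inf_{t−1} + β3·c_t·inf_{t−1} + β4·rt_t + β5·r

(rt = log reaction time, r = block number), leave-one-out peak
inference, and a psychophysiological-interaction (PPI) analysis with a
connectivity surface over (confidence, influence) z-scores.  See
`docs/methods.md` for every model, default and numerical choice —
including why the leave-one-out peak test is referred to a sign-flip
null rather than the Wilcoxon table.

## Worked example

Generate a cohort of 30 synthetic participants from the per-condition
revision model and recover its coefficients
(`python examples/03_mixed_model_recovery.py`):

```
--- human condition (generating betas (0.5, -0.3, 0.17, -0.21)) ---
                          estimate      se    df_den    p  p_holm
term
intercept                   0.4965  0.0062   67.7014  0.0     NaN
conf_norm                  -0.2975  0.0093   72.7533  0.0     0.0
prev_influence              0.1747  0.0108  322.7919  0.0     0.0
conf_norm:prev_influence   -0.2163  0.0156  845.1773  0.0     0.0

--- computer condition (generating betas (0.55, -0.37, 0.01, -0.03)) ---
                          estimate      se    df_den       p  p_holm
term
intercept                   0.5525  0.0074   58.8749  0.0000     NaN
conf_norm                  -0.3772  0.0082   97.3693  0.0000  0.0000
prev_influence             -0.0043  0.0114  301.8702  0.7075  0.7075
conf_norm:prev_influence   -0.0168  0.0158  866.0334  0.2871  0.5743
```

Reading: confidence lowers revision in both conditions (informational
conformity), while the positive influence effect and the negative
confidence × influence interaction — the signatures of normative
reciprocity — appear only with believed-human partners.  The recovered
estimates sit on the generating coefficients; `df_den` are Satterthwaite
denominator degrees of freedom and `p_holm` the Holm–Bonferroni-adjusted
p-values within the fit.

The other scripts in `examples/` walk the remaining capabilities:
circular geometry (01), session simulation (02), sliding-window
reciprocity dynamics (04), the synthetic-BOLD ROI analysis with
leave-one-out inference (05), and PPI with the connectivity surface
(06).  A thin CLI wraps the same calls (`conformity simulate`,
`conformity cohort`, `conformity analyse-behaviour`, `conformity
analyse-roi`, `conformity analyse-ppi`, `conformity run-all`); the
library API is the primary interface.

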