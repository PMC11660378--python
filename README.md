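# dyadscan

Bayesian multilevel analysis of scan-sampled dyadic social behaviour in
animal groups.

## The problem

Scan sampling records, at fixed instants, which visible members of a group
are engaged in a social behaviour (close proximity within 1 m, distant
proximity 1–2 m, social play, directional grooming) and with whom.
Comparing *groups* on such data is statistically delicate: apparent group
differences can be manufactured by a handful of sociable individuals or
strongly bonded pairs, by unequal sampling effort, and by the fact that a
dyad seen interacting at one scan is very likely still interacting at the
next.  `dyadscan` implements a hierarchical Bayesian treatment of this
problem for multi-group studies (the motivating setting is six captive
bonobo groups of 8–16 individuals scanned daily for about three months),
and propagates full posterior uncertainty into social-network metrics and
group comparisons instead of reducing each dyad to a single association
index.

## The model

For dyad (i, j) in group k at scan l on day m, with y = 1 when the dyad is
engaged in the behaviour:

    y_ijklm ~ Bernoulli(p_ijklm)
    logit(p_ijklm) = alpha + beta_last * y_ijk(l-1)m + B_ijk [+ x_ij' delta]

    B_ijk = a_k + b_ik + b_jk + c_ijk            (undirected behaviours)
    B_ijk = a_k + b_ik + d_jk + c_ijk            (grooming, i grooms j)

with a_k ~ N(0, sigma_group²) group effects, b_ik ~ N(0, sigma_ind²)
individual effects (groomer propensity for grooming), d_jk ~ N(0,
sigma_rec²) recipient effects, c_ijk ~ N(0, sigma_dyad²) dyad bond effects
(shared by both grooming directions), and vague priors N(0, 100²) on fixed
effects and U(0, 10) on every SD.  `beta_last` absorbs interaction bouts
persisting across successive scans within a day (the lag outcome resets at
each day's first scan); dyad-level covariates x are maternal/paternal
kinship, sex combination (female–female reference), and standardized age
difference (absolute for undirected behaviours, groomer − groomed for
grooming).

Derived quantities:

* **Variance decomposition** — sigma_within = sqrt(2·sigma_ind² +
  sigma_dyad²) (undirected; the individual component counts twice, once per
  member) or sqrt(sigma_ind² + sigma_rec² + sigma_dyad²) (grooming), and
  the ratios sigma_group/sigma_within (between- vs within-group variation)
  and sigma_dyad/sigma_IND (bond- vs individual-driven variation),
  summarized per posterior draw with 95% highest-posterior-density
  intervals (HPDIs).
* **Posterior networks** — per draw, each dyad's edge weight is the
  stationary probability p0/(1 − p1 + p0) of its fitted two-state chain
  (p0, p1 the interaction probabilities after a quiet/active scan): the
  probability the dyad is engaged at a random point in time, with the scan
  autocorrelation controlled.  Node strength (total connection; out + in
  for grooming) and a probabilistic clustering coefficient are averaged
  within groups per draw, giving posterior uncertainty on every group mean
  and every pairwise group contrast.
* **Clique test** — the observed fraction of scans containing a connected
  set of ≥ 3 simultaneously interacting individuals is compared with its
  posterior-predictive distribution under dyadic independence, flagging
  groups that congregate beyond what their dyadic rates explain.

A seeded synthetic-data generator emulates the full study design (groups,
ages, sexes, pedigree, visibility censoring, within-day Markov outcome
chains) with known ground truth, so the entire chain is testable without
any field data.

## Worked example

```python
from dyadscan import (
    make_fixture, build_dyad_scan_table, ModelSpec, fit, diagnostics,
    variance_summary, odds_effects, derive_networks, group_metric_posterior,
)

dataset = make_fixture("paper_like", days=20, scans_per_day=10,
                       behaviours=("close_proximity",), seed=7)
table = build_dyad_scan_table(dataset.events["close_proximity"],
                              dataset.individuals, "close_proximity")
spec = ModelSpec(behaviour="close_proximity", iterations=3000, warmup=1000, seed=1)
sample = fit(table, spec)
print("max R-hat:", round(float(diagnostics(sample)["rhat"].max()), 3))
print(variance_summary(sample).table.round(3).to_string(index=False))
print(odds_effects(sample).table.round(2).to_string(index=False))
```

prints (107,949 dyad-scan rows, 6 groups, ~25 s on one core):

```
max R-hat: 1.026
    quantity  mean  hpdi_lo  hpdi_hi
 sigma_group 0.457    0.008    1.039
   sigma_ind 0.452    0.326    0.579
  sigma_dyad 0.938    0.831    1.043
sigma_within 1.138    1.012    1.271
 ratio_group 0.405    0.007    0.921
  ratio_dyad 1.500    1.063    1.985
   covariate  multiplier  hpdi_lo  hpdi_hi  evidence
    age_diff        0.80     0.71     0.90      True
maternal_kin        9.67     4.98    14.50      True
paternal_kin        2.00     0.67     3.80     False
   mixed_sex        0.59     0.41     0.78      True
   male_male        0.34     0.15     0.54      True
```

The generating truth for this simulation had sigma_group = 0.5, sigma_ind
= 0.5, sigma_dyad = 1.0, a maternal-kin odds multiplier of 6.1 and an age
multiplier of 0.75 per SD — every 95% HPDI above covers its target except
where a single realized study is entitled to miss.  `ratio_dyad` ≈ 1.5
says dyadic bonds, not individual sociability, dominate within-group
variation; `ratio_group`'s wide interval reflects that six groups bound
between-group inference.  Group network metrics follow the same pattern:

```python
nets = derive_networks(sample)
gm = group_metric_posterior(nets, "strength")
print(gm.means.round(3).to_string(index=False))   # per-group mean strength + HPDI
print(int(gm.contrasts["evidence"].sum()), "of", len(gm.contrasts),
      "pairwise contrasts evident")                # -> 11 of 15
```

## Command line

```bash
dyadscan simulate --fixture paper_like --out data/
dyadscan fit --data data/ --behaviour grooming --out post/ --seed 1
dyadscan report --posterior post/ --out report/
dyadscan cliques --posterior post/ --data data/ --out cliques.csv --seed 1
```

Every stage writes a manifest (config hash, seeds, input digests,
runtimes); exit codes are 0 (success), 2 (validation error), 3
(convergence failure: any split-R-hat > 1.05, unless
`--allow-unconverged`).

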