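# symptomnet

Network analysis of binary depressive-symptom panels: cross-sectional
Ising networks, a two-wave cross-lagged panel network (CLPN), and the
accuracy / stability / comparison machinery around them.

## Who this is for

Psychometric and epidemiological researchers who model depressive
symptoms (e.g. the 10-item CES-D in ageing cohorts) as a network of
mutually interacting items rather than reflections of a single latent
cause, and who need a reproducible, testable pipeline from raw 0–3
Likert responses to network estimates, centrality indices, bootstrap
stability and between-wave comparisons.

## The models

**Cross-sectional (Ising).** Binarised items x ∈ {0,1}^p follow a
pairwise Markov random field

P(x) ∝ exp(τᵀx + ½ xᵀWx),

estimated by nodewise ℓ1-penalised logistic regression (eLasso): each
item is regressed on all others along a descending λ path, the Extended
Bayesian Information Criterion

EBIC = −2ℓ + k·log n + 2γ·k·log(p−1),  γ = 0.5,

selects each node's penalty, and the directed coefficients are
symmetrised with the AND rule (edge kept only when both coefficients
are nonzero; weight = their mean).

**Longitudinal (CLPN).** Each Wave-2 item is regressed on all ten
Wave-1 items with ℓ1-penalised logistic regression; 10-fold
cross-validated deviance plus the one-standard-error rule picks λ_1SE
per outcome. The coefficient matrix B (log-odds scale) is directed:
diagonal entries are autoregressive effects, off-diagonal entries are
cross-lagged effects. Node importance is summarised by out-/in-expected
influence (signed row/column sums excluding the loop), strength
s_i = Σⱼ|W_ij|, and a global strength S = Σ_{i<j}|W_ij|; all reported
both raw and z-standardised.

**Inference machinery.** Nonparametric bootstrap CIs for edges and
centrality differences; the case-dropping bootstrap CS coefficient
(largest drop proportion keeping corr(subset, full) ≥ 0.7 with 95%
probability); permutation tests for the maximum edge difference M and
the global-strength difference ΔS; replicability via the edge-presence
φ correlation and the edge-weight Spearman ρ.

A calibrated synthetic generator (`cohort_preset`) provides ground
truth: an exact-enumeration-calibrated 10-item Ising wave with
endorsement rates in the empirical 0.20–0.67 band, plus sparse
autoregressive and cross-lagged effects with a designated
"lack of happiness" driver node.

## Worked example

```python
import symptomnet as sn

params = sn.cohort_preset()           # ground-truth generator
w1, w2 = sn.sample_two_wave(params, 5000, seed=1)

res = sn.IsingModel(w1).fit()
print(res.summary())
```

prints

```
Ising network (nodewise logistic LASSO, EBIC selection)
  nodes: 10   n: 5000   gamma: 0.5   rule: AND
  nonzero edges: 13 / 45   global strength: 8.511

  strongest edges:
    D5: hopelessness  --  D8: lack of happiness: +1.306
    D9: felt lonely  --  D10: could not get going: +1.279
    D1: bothered by things  --  D3: felt depressed: +0.873
    D3: felt depressed  --  D4: everything an effort: +0.780
    D8: lack of happiness  --  D10: could not get going: +0.686
```

All 12 true edges are recovered (one extra weak false positive here),
with the two strongest estimated pairs matching the generator's
hopelessness–lack-of-happiness (true 1.4) and lonely–cannot-get-going
(true 1.3) edges, shrunk slightly toward zero by the LASSO penalty.
The longitudinal side:

```python
clpn = sn.CrossLaggedModel(w1, w2, k_folds=10).fit(seed=3)
tab = clpn.centrality()                    # out-EI / in-EI per node
print(tab[tab.metric == "out_ei"].nlargest(2, "raw"))
```

ranks "D8: lack of happiness" first on out-expected-influence
(raw out-EI 1.130, z = 2.837; the true value 2.2 is shrunk by the 1SE
penalty), i.e. the generator's designated driver node, followed by
"D3: felt depressed" (0.376).

A full pipeline run (descriptives → Ising per wave → stability →
comparison → CLPN) from one config:

```bash
symptomnet simulate --n 1000 --seed 1 --out panel.csv
symptomnet run --config examples/run_simulated.yaml --out results/
```

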