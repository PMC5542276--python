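# dirgenerank

Directed gene-dependency networks and damped fixed-point gene ranking for
prognostic signature discovery from expression + survival cohorts.

## The problem

Univariate survival screens rank genes by how strongly each one's expression
predicts outcome on its own. That misses *modulators*: genes whose own
expression is only weakly prognostic but which control how strongly *other*
genes associate with outcome. This package implements a pipeline that finds
such genes:

1. **Discretize.** Expression is binarized per gene at its median
   (1 = strictly above). The outcome is binarized with a cutoff rule
   (default 1200 days): patients who died before the cutoff are poor-outcome
   (1), patients observed past it are good-outcome (0), and patients censored
   before it are dropped from the network stage.

2. **Directed dependency network.** For every pair (A, B) adjacent in a
   protein–protein interaction (PPI) scaffold, the conditional mutual
   information

   CMI(A; P | B) = Σ_{a,p,b} f(a,p,b) · log₂ [ f(a,p,b) f(b) / ( f(a,b) f(p,b) ) ]

   measures how much A's association with the phenotype P depends on the
   state of B. Significance is assessed against a permutation null (B
   shuffled across samples, default 1000 permutations); a significant test
   (p ≤ 0.05) adds the directed edge **B → A** ("A depends on B"). Both
   directions of every PPI pair are tested.

3. **Initial importance.** Each gene's univariate Cox association with
   survival is refit on R = 400 random 90% subsamples; the *stability*
   (number of fits with p < 0.05) is the gene's initial importance, and the
   averaged coefficient records its direction of effect.

4. **DirGenerank ranking.** Importance flows through the network by a damped
   fixed-point iteration (a PageRank relative):

   r_j ← (1 − d) · imp_j + d · Σ_{i : i depends on j} w_ij · r_i / deg_i

   with damping d = 0.7, iterated until the L1 change is below 1e-5.
   Genes that many dependent genes rely on accumulate rank even when their
   own marginal association is modest. The top 1% of ranked genes is the
   signature.

5. **Validation.** A cohort is scored per sample as
   Σ(expression of positive-coefficient genes) − Σ(negative-coefficient
   genes), split at the median score (≤ median → low risk), and the groups
   are compared by log-rank test and Cox hazard ratio. Signature overlap
   with external gene sets uses the hypergeometric upper tail; positional
   enrichment in the ranking uses a one-sided Kolmogorov–Smirnov test.

A first-class synthetic-data module (`dirgenerank.simulate`) generates
cohorts with *planted* modulator → dependent structure, so the whole
pipeline can be exercised and power-checked without external data.

## Worked example

Simulate a 400-sample, 300-gene cohort with three planted driver genes
(G001–G003), each modulating eight dependents, embedded in a decoy PPI
scaffold; then run the full pipeline:

```bash
$ dirgenerank simulate --preset planted --seed 7 --out cohort
wrote cohort to cohort

$ dirgenerank network --expr cohort/expression.tsv --clin cohort/clinical.tsv \
      --ppi cohort/ppi.tsv --n-perm 1000 --seed 17 --out net.tsv
59 nodes, 63 edges -> net.tsv

$ dirgenerank score --expr cohort/expression.tsv --clin cohort/clinical.tsv \
      --resamples 400 --seed 29 --out stab.tsv
scored 300 genes (400 resamples) -> stab.tsv

$ dirgenerank rank --net net.tsv --stab stab.tsv --top-frac 0.05 --out rank.tsv
ranked 59 genes in 31 iterations; signature of 3 genes -> rank.signature.tsv

$ head -4 rank.tsv
gene_id	rank_score	rank_position	stability	mean_coef
G002	0.12166080737487941	1	400	0.2950138908161436
G001	0.1152806548955823	2	400	0.190229260251139
G003	0.0823906090320427	3	400	0.2662321065606974

$ dirgenerank validate --expr cohort/expression.tsv --clin cohort/clinical.tsv \
      --signature rank.signature.tsv --out strat.tsv
low n=200, high n=200, threshold=-0.07976
log-rank chi2=34.6, p=4.054e-09
HR=1.95 (95% CI 1.555-2.446)
```

The three planted drivers come out ranked 1–3, the 3-gene signature is
exactly the planted set, and the median risk split separates survival
(HR ≈ 2, log-rank p ≈ 4e-9).

The same pipeline is available as scikit-learn style estimators:

```python
import dirgenerank as dg

expr, clin, ppi, truth = dg.generate_cohort(dg.SimConfig(seed=7))
model = dg.DirGenerankPipeline(ppi=ppi, random_state=17).fit(expr, clin)
model.signature_.genes          # top-ranked genes with Cox-coefficient signs
model.predict(expr)             # 1 = above the fitted median-risk threshold
model.stratify(expr, clin)      # log-rank / hazard-ratio separation stats
```

Stage estimators `DependencyNetworkInference`, `CoxStabilitySelector` and
`DirGenerankRanker` expose the individual steps; plain functions
(`build_network`, `resample_stability`, `dirgenerank`, `stratify`, …) sit
underneath.

A published 40-gene ovarian-cancer signature (19 positive / 21 negative
Cox coefficients) ships as package data: `dg.load_ovarian_signature()`.

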