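# microstates

Community-state dynamics of longitudinal, multi-body-site microbiomes.

Early-life microbiomes of hospitalised preterm neonates — gut, oral
cavity, and skin sampled repeatedly over the first weeks of life — are
low-diversity, volatile communities that nonetheless fall into a small
number of discrete **community states** (e.g. states mono-dominated by a
*Staphylococcus*, an *Escherichia/Shigella*, or a *Lactobacillus* ASV,
plus a mixed higher-evenness state). `microstates` is a tested, reusable
pipeline for analysing such cohorts, aimed at microbial ecologists and
computational biologists working with longitudinal 16S ASV tables:

- **Pre-processing** (`microstates.tables`): negative-control-driven
  contaminant removal (genera with > 10 control reads; genera with
  Pearson *r* > 0.9 to a contaminant across the dataset; reagent lists),
  rarefaction without replacement to a common depth (default 600 reads),
  and Good's coverage `1 − singletons/reads`.
- **Diversity and association** (`microstates.diversity`): richness,
  Shannon *H* (nats), Pielou evenness; Bray-Curtis dissimilarity
  `1 − 2Σmin(x,y)/(Σx+Σy)`; PCoA; single-factor PERMANOVA and an
  ordination variable fit, both with permutations restricted to blocks
  (patients) so repeated measures are never shuffled across infants;
  Cohen's *d*; within-/between-site and founder-distance contrasts.
- **State discovery** (`microstates.states`): k-means on the full PCoA
  embedding of the Bray-Curtis matrix (PAM on the matrix itself as an
  alternative), *k* chosen by mean-silhouette maximisation with
  Calinski-Harabasz as tie-break, clusters named by their dominant ASV.
- **Markov models** (`microstates.markov`): per-site transition matrices
  estimated from pooled adjacent-occasion state pairs, stationary
  frequencies solving `πP = π`, recurrent/transient classification from
  closed communicating classes, and cross-site conditional detection
  probabilities obeying `P(s₁|s₂)P(s₂) = P(s₂|s₁)P(s₁)` exactly.
- **Assembly processes** (`microstates.processes`): abundance-weighted
  βMNTD; βNTI against a tip-shuffling null (999 replicates); Raup-Crick
  on Bray-Curtis with richness-preserving, occupancy-weighted
  reassembly; the five-way partition (variable selection βNTI > +2,
  homogeneous selection βNTI < −2, dispersal limitation RC > 0.95,
  homogenizing dispersal RC < −0.95, drift otherwise); chi-square
  contrasts of process counts across sites; odds ratios of each state's
  contribution to deterministic turnover with log-normal 95% CIs.
- **Co-occurrence networks** (`microstates.networks`): Spearman
  correlations against a 1000-shuffle permutation null with
  Benjamini-Hochberg correction.
- **Synthetic cohorts** (`microstates.synth`): a generator producing
  cohorts with known latent states, per-site transition matrices, a
  birth–death phylogeny with tunable habitat signal, planted
  correlations, and reagent contamination — every downstream stage can
  be validated against ground truth.

## Worked example

```python
from microstates.synth import SynthConfig, generate_cohort
from microstates import tables, diversity, states, markov

table, meta, truth = generate_cohort(SynthConfig(seed=7))
filtered, report = tables.filter_contaminants(table, truth.negative_controls)
rarefied = tables.rarefy(filtered, depth=600, seed=7)
meta = meta[meta.sample_id.isin(rarefied.sample_ids)]

bc = diversity.bray_curtis(rarefied)
k, scores = states.select_k(bc, range(2, 9), seed=7, table=rarefied)
assignment = states.assign_states(bc, k, seed=7, table=rarefied)
print(f"chosen k = {k}, mean silhouette = {assignment.mean_silhouette:.2f}")
print(f"recovery vs truth = {states.label_agreement(assignment.labels, truth.state_per_sample):.3f}")

gut = markov.estimate_transitions(assignment.labels, meta, "gut",
                                  states=sorted(assignment.labels.unique()))
print("gut transition probabilities:")
print(gut.probabilities.round(2))
print("stationary:", gut.stationary[0].round(2).to_dict())
```

prints

```
chosen k = 4, mean silhouette = 0.50
recovery vs truth = 1.000
gut transition probabilities:
      EC    IC    LC    SC
EC  0.86  0.00  0.00  0.14
IC  0.00  0.95  0.00  0.05
LC  0.00  0.00  0.93  0.07
SC  0.40  0.20  0.20  0.20
stationary: {'EC': 0.27, 'IC': 0.37, 'LC': 0.27, 'SC': 0.1}
```

The clustering finds the four planted community states exactly
(agreement 1.0 after relabeling). The fitted gut chain shows the EC, IC
and LC states as sticky (self-transition ≥ 0.86 in this realisation)
while SC transitions away with high probability; the stationary vector
gives the long-run fraction of occasions expected in each state, and all
four states are recurrent (revisited with probability one).

A command-line interface mirrors the library: `microstates simulate`,
`microstates preprocess`, per-stage subcommands, and `microstates run`
for the full pipeline (`--config`, `--seed`, `--outdir`); each run
writes stage-namespaced TSV outputs plus a machine-readable
`run_report.json`, and reruns with the same config and seed are
byte-identical.

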