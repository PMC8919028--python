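# Methods

This note documents the models, estimators, and numerical choices behind
`microstates`, and what the synthetic cohorts its tests run on do and do
not establish about real data.

## The data model

The pipeline's currency is an integer sample × ASV count table with a
semicolon-delimited taxonomy string per ASV (genus = 6th field), plus
per-sample metadata (patient, body site, sampling occasion, day of life,
clinical covariates). Sampling occasions are treated as equally spaced
steps of a discrete-time process even though the nominal sampling days
(1, 3, 7, 14 by default) are not equispaced; the nominal day is carried
in the metadata but never enters the transition model. This
occasion-indexed view is the standard simplification for short clinical
time series with a fixed sampling schedule; it is an assumption, not an
inference.

## Pre-processing

Contaminant removal applies four rules in order, attributing each taxon
to the first rule that removes it: (1) genera with strictly more than
`read_threshold` (default 10) reads in pooled negative controls; (2)
genera whose relative-abundance profile across samples has Pearson
r > `r_threshold` (default 0.9) with any rule-1 genus; (3) a
user-supplied reagent-contaminant genus list; (4) an explicit ASV
exclusion list (the hook for run-level cross-contamination, which needs
external information this artifact does not model). Rule 2 uses relative
abundances: correlation of raw counts across samples of very different
depth mostly measures depth. Unclassified-genus reads are exempt from
rule 2 because they aggregate unrelated organisms. The report's read
accounting reconciles exactly: reads before = reads after + Σ removed.

Rarefaction subsamples each library to `depth` (default 600) reads
without replacement (multivariate hypergeometric); shallower samples
are dropped and logged. Good's coverage `1 − singletons/total` is the
post-rarefaction completeness check.

## Diversity and permutation inference

Shannon diversity is in nats by default (`base` flag available);
evenness is H/ln S and undefined (missing, not zero) for single-ASV
samples. Bray-Curtis, PCoA (Gower double-centering; axes with
eigenvalues ≤ 0 are dropped), and k-means/silhouette/Calinski-Harabasz
go through scipy, scikit-bio, and scikit-learn respectively.

PERMANOVA and the ordination variable fit are implemented in-package
because the study design needs **block-restricted permutations**:
repeated measures from one patient are only ever permuted within that
patient. Both use the +1 p-value convention,
p = (1 + #{stat_perm ≥ stat_obs}) / (n_perm + 1), so p is never 0 and
the smallest attainable value is 1/(n_perm+1). PERMANOVA is
single-factor (marginal fits per variable); the pseudo-F agrees with an
independent implementation (scikit-bio's) to 1e-9 in the tests. For the
variable fit, a continuous variable's r² is its squared multiple
correlation with the first two PCoA axes (configurable), a factor's is
1 − SS_within/SS_total of the coordinates.

## Community states

k-means cannot consume a dissimilarity matrix directly, so "clustering
on Bray-Curtis" is realised as k-means in the full positive-eigenvalue
PCoA embedding; PAM on the matrix itself is available via
`method="pam"`. Silhouettes are always computed on the original
Bray-Curtis matrix; Calinski-Harabasz (which needs coordinates) on the
embedding. k is chosen by mean-silhouette maximisation with CH as
tie-break over k ∈ [2, 8] by default, with `n_init = 100` k-means
restarts. A cluster is named after its top ASV's genus (initial + "C",
e.g. SC for a Staphylococcus-dominated state) when that ASV's in-cluster
mean relative abundance reaches 0.4 (configurable); below the threshold
the cluster gets an intermediate "IC"-style label.

## Markov models of state dynamics

Per body site, every pair of samples from the same patient at adjacent
occasions (time-index difference exactly 1; gaps left by dropped samples
do not form steps) contributes one observed transition. Counts are
pooled across patients — the maximum-likelihood estimate of a shared
site-level chain — and row-normalised after optional additive
smoothing. States never observed as a step origin get a uniform row and
a loud warning rather than a failure, keeping steady states computable.

Stationary distributions are solved per closed communicating class
(strongly connected components of the positive-transition digraph with
no outgoing edge) by a dense linear solve of πP = π, Σπ = 1; residuals
above 1e-10 raise. A state is recurrent iff it lies in a closed class —
for finite chains this is exactly "return probability one". The matrix
power P^1024 serves as an independent oracle in the tests.

Cross-site detection is summarised by P(detected at s₁ | detected at
s₂) per ASV over occasions matched on (patient, time); both directions
are estimated from the same matched set, which makes the Bayes identity
P(s₁|s₂)P(s₂) = P(s₂|s₁)P(s₁) an algebraic fact checked to machine
precision. ASVs never detected at the conditioning site are missing,
not zero. Aggregates are unweighted means over defined ASVs
(an abundance-weighted variant would be a one-line change; unweighted
is the default because no aggregation rule is canonical).

## Assembly-process inference

βMNTD(k, m) = ½[Σ_{i∈k} f_ik · min_{j∈m} d_ij + Σ_{j∈m} f_jm · min_{i∈k} d_ij]
with patristic distances d from the input tree and f the relative
abundances (abundance-weighted, the default) or 1/S (unweighted). The
implementation is vectorised: per null replicate, the nearest-taxon
distance matrix G[m, i] = min_{j∈m} d(i, j) is built once and the full
pairwise βMNTD matrix follows from one matrix product, because absent
taxa carry zero weight. An exhaustive double-loop oracle verifies exact
agreement (1e-12) on small instances.

βNTI standardises observed βMNTD against a null that re-assigns taxa to
tree tips by a uniform permutation across the whole tree (999
replicates by default) — the convention of the null-modelling framework
this class of analysis descends from. βNTI is invariant under uniform
branch-length rescaling (βMNTD scales linearly; the z-score does not).
When the null SD is zero and the observed value equals the null mean
(e.g. a star tree, where shuffling is a no-op), βNTI is 0; a zero SD
with a deviating observation is reported missing. Pairs are restricted
to the same body site by default.

RC-Bray reassembles each community per replicate preserving its
observed richness and read total: species drawn without replacement
weighted by metacommunity occupancy (exponential-race sampling), one
read each, remaining reads multinomial by metacommunity relative
abundance over the drawn species. RC = ((#null < obs) + ½·ties)/n_null
rescaled to [−1, 1].

**A calibration caveat worth knowing.** The occupancy-weighted,
richness-preserving null flattens species-inclusion probabilities
relative to multinomial sampling. For communities that are iid
multinomial draws from one strongly heavy-tailed metacommunity profile
at ~600 reads, observed pairs are systematically *more* similar than
the null (RC near −1) even though no ecological process differentiates
them. The null is faithful when data are generated by its own two-step
assembly process, which is also the cleanest operationalisation of
neutrality (species equivalence): `synth.neutral_metacommunity_counts`
draws each sample's species uniformly and its reads from a shared
abundance vector. Even then a positive RC bias of order 1/n_samples
remains because occupancy and abundance weights are re-estimated from
the finite cohort (≈ +0.25 at 25 samples, ≈ +0.07 at 80); the
calibration test uses 80 samples. Interpreting RC values from small
cohorts should keep both effects in mind.

Process partitioning applies selection first (βNTI > +2 variable
selection, < −2 homogeneous selection), then splits the stochastic
remainder by RC (> 0.95 dispersal limitation, < −0.95 homogenizing
dispersal, else drift). Fractions are over classified pairs and sum to
1 exactly; pairs missing a needed statistic are counted separately.
Site contrasts use Pearson chi-square without continuity correction
(one process vs the rest, plus an overall site × category test); low
expected counts are logged. Odds ratios of a state's contribution to
deterministic turnover (|βNTI| > 2) use "involves the state at either
endpoint" as the default margin (a both-endpoints variant is a flag),
the Haldane 0.5 correction when any cell is zero, and log-normal 95%
CIs; significance means the lower bound exceeds 1.

## Co-occurrence networks

Within a sample group (typically one community state), Spearman
correlations (average ranks for ties) between all ASVs present in at
least 2 samples are tested against a null that shuffles each ASV's
abundances across samples independently (preserves marginals, destroys
all dependence), recomputing all correlations per replicate (1000 by
default). Two-sided permutation p-values get BH correction; edges are
kept at adjusted q < 0.01 by default, with `filter_on="p"` reproducing
a raw-p threshold. Note a discreteness interaction: with 1000
permutations the smallest attainable p is ≈ 0.001, so over m tested
pairs the smallest attainable q is ≈ m/1000 × 0.001 per rank — for
large m the q-filter at 0.01 is deliberately conservative.

## The synthetic cohort generator

Defaults emulate the study conditions the pipeline targets: 15 patients
× 3 body sites × 4 occasions (180 samples), 300 ASVs, four latent
states — SC, EC, LC with dominant-ASV Dirichlet means 0.61, 0.60, 0.91
and a mixed IC state (the three dominants at 0.20 each) — with
Dirichlet concentrations 40–60 chosen so states are distinct but
noticeably noisy, and negative-binomial library sizes (mean 3000)
truncated at ≥ 600 so default rarefaction drops nothing (a flag allows
sub-depth libraries to exercise the drop path). Per-site transition
matrices were calibrated to the dynamics the framework is meant to
recover — gut the most stable site (mean self-transition 0.625), skin
volatile (0.225) with a strong pull toward SC (stationary ≈ 0.67), the
oral cavity SC-stable with LC sporadic — and are frozen as defaults.
The phylogeny is a birth–death tree (birth 1.0, death 0.5) spanning all
emitted ASVs, with ASV ids assigned to tips by a random permutation; a
habitat-signal parameter in [0, 1] moves each state's tail abundance
from a shared tree-independent profile (0) toward state-specific clades
(1). At signal 0, tip labels are exchangeable with respect to
abundance, the regime in which the βNTI null is exact. Reagent
contamination is injected at genus level into negative controls and
real samples from a shared lognormal per-sample intensity, so
co-occurring reagent genera are strongly correlated — exactly what the
correlation-removal rule must catch. Planted monotone ASV pairs (for
network validation) overwrite two tail ASVs with near-deterministic
monotone functions of a shared latent.

One global seed drives everything through labelled substreams
(CRC-32-keyed `numpy.random.SeedSequence` spawn keys), so identical
configs are bit-identical end to end and stages are independently
reproducible.

**What the generator does not emulate:** real cross-site dispersal
(latent states are independent across sites given the patient), strain
dynamics, compositional sequencing artefacts beyond multinomial
sampling, time-varying library quality, or clinically structured
covariate effects (covariates are plausible noise). Tests passing on
these cohorts demonstrate the estimators' correctness and calibration,
not that any particular biological conclusion transfers to real
cohorts.

## Problem sizes used in the checks

The test suite and the acceptance script size their simulations to run
comfortably on one CPU: 100 random 4-state chains for the Markov
oracles; 200 series × 50 steps per site for transition recovery; 50
random ≤ 10-taxon instances for the βMNTD oracle; ~60 independent
2-patient cohorts (150 ASVs, zero habitat signal, 999 nulls) pooled for
βNTI calibration — pooling is essential because all pairs within one
cohort share a single taxon-to-tip assignment, leaving the per-cohort
mean βNTI with Monte-Carlo spread ≈ 0.34; an 80-sample
species-equivalent metacommunity for RC-Bray; 1000 replicates at 99
permutations each for the type-I-error checks (the p-grid then contains
0.05 exactly); and the full 180-sample default cohort, run twice, for
byte-level determinism.
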