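# Methods

This note documents the models, defaults, and design decisions behind
`immunet`: what the synthetic generator emulates, how each analysis stage
is computed, and what passing the test suite does and does not show about
real cytometry data.

## Synthetic cohort model

### Compositions

Each subject carries a vector of true subset abundances over K = 20
population archetypes (11 differential — 4 enriched, 7 depleted in
sepsis — 8 stable fillers, and 1 doublet-like mixed population). The
abundance model is **logistic-normal**: a log-ratio vector is drawn from
a group-specific Gaussian, x ~ N(μ_g, Σ_g), and closed onto the simplex
by a softmax. A Dirichlet cannot encode correlations beyond the weak
negative ones closure induces; the logistic-normal supports the planted
positive *and* negative inter-subset covariance the network stage must
recover.

Baseline mean frequencies span 0.8–11% (naive and memory T cells, B
cells, NK, monocytes at realistic PBMC proportions; the mixed population
at 1.4%). Per-subset log-ratio dispersion is 0.35 — roughly a 1.4-fold
inter-subject coefficient of variation, typical of immune subset
frequencies across children.

**Group covariance.** Healthy: one rank-one factor with loading
magnitude √0.8 over ten small-to-medium subsets spanning all lineages
(|ρ| = 0.8 within the block, a connected cross-lineage web), with
*negative* loadings on the naive Treg, central-memory CD4 and
PD1⁺CD152⁺TIGIT⁺ effector-memory CD4 subsets — these plant the negative,
regulatory-type edges. Sepsis: two disjoint all-positive equicorrelated
modules (ρ = 0.8), one CD4-centric and one CD8-centric, and no
correlation elsewhere — sparse, modular, no negative edges. Loading
signs within the healthy factor are approximately mass-balanced and the
factor is restricted to low-abundance subsets: closure couples all
frequencies through the normalising denominator in proportion to the
composition mass involved, and an unbalanced factor over heavy subsets
would attenuate the planted correlations below the 0.6 edge threshold.

**Effect sizes.** Sepsis shifts are specified as Cohen's d on the
*observed frequency scale* (the scale on which d is later estimated):
+1.5, +1.4, +1.3, +1.2 for the enriched subsets (CD15⁺CD14⁺ monocytes
largest, matching the study's effect-size ordering) and −0.8…−1.2 for
the depleted seven. Because the softmax makes the map from log-ratio
shift to frequency-scale d nonlinear, shifts are calibrated by a
deterministic internal Monte-Carlo fixed-point iteration (8,000 draws
per group with common random numbers, fixed internal seed, ~10
iterations). The calibration is part of the scenario definition and
independent of any cohort seed. Effect magnitudes sit in the upper part
of the plausible 0.8–1.5 band deliberately: with n = 39/19 and
Bonferroni correction over 20 subsets, per-subset power at d = 0.8 is
only ~50%, and the generator is meant to represent a regime where the
enriched panel is reliably detectable (all four recovered in ≥80% of
cohorts), as it was in the study that motivates the package.

### Events

Event-level intensities are **zero-inflated lognormal** per marker: an
event expresses a marker with probability 1 − dropout (0.95 for markers
the population is positive for, 0.30 for background), and the expressed
intensity is LogNormal(log(level), σ) with level 180 (bright markers
400, background 0.6) and σ = 0.45 (background 0.8). This mimics the
zero-inflation and right-skew of mass-cytometry dual counts without
modelling instrument physics; after asinh5 the populations are
nearest-centroid separable (pairwise centroid distance > 2), which the
archetype invariant enforces. Events are assigned to populations by a
multinomial draw from the subject's composition; true labels are kept
for recovery tests. The doublet-like CD3⁺CD19⁺ population is modelled
tighter (half dispersion, reduced dropout) than true populations — a
doublet contributes a stereotyped two-cell signature — which also keeps
it confined to a single metacluster.

### Clinical covariates

Severity scores are discretized Gaussians matched to the cohort table's
medians/IQRs (pSOFA 8 (5, 11) clipped at ≥2 so every sepsis subject
satisfies the organ-dysfunction-based sepsis definition; PELOD-2 6 (3,
8); PIM-3 lognormal around 3.4), mildly loaded on a latent severity
composed of the three non-proliferative enriched subsets — only rank
structure matters downstream. Labs are **linear-in-frequency**:
lab = loc + scale·(r·z(f) + √(1−r²)·ε) with z(f) standardised by the
calibrated population moments, so the population Pearson correlation
with the coupled subset equals the target exactly (monocyte–PCT 0.68,
Th17–lactate 0.57). Locations/scales are chosen so negative draws are
negligible (<0.1%) and floored at 0.05 without distorting the
correlation. Outcomes (severe sepsis, septic shock, multi-organ
dysfunction, PICU mortality) follow a logistic link on the standardized
frequencies of the three enriched subsets, with intercepts calibrated by
Monte-Carlo root-finding to the cohort prevalences (74.6%, 72.9%, 69.5%,
13.6%). Ages are drawn from the cohort's age-band frequencies (~74% of
sepsis subjects >1 year). Healthy subjects carry missing severity and
lab fields.

What the generator does **not** emulate: staining chemistry, barcoding,
bead drift, doublet formation (beyond one stylised mixed population),
batch effects, heavy-tailed outlier subjects, or any relationship
between infection site/pathogen and the immunome. Passing tests shows
the analysis chain recovers planted structure under a well-specified
logistic-normal world; it does not certify performance on real CyTOF
data.

## Preprocessing

asinh(x/5) with a validation guard against double transformation;
random downsampling **without replacement** to 50,000 events/subject
(with replacement would duplicate events and tighten clusters
artificially). Subjects with fewer events are kept in full (dropping
them would silently change n); downstream frequencies always use each
subject's retained event count as denominator, so unequal retention does
not bias percentages.

## Clustering

The SOM is batch-trained on a 10×10 rectangular grid: codebook
initialised from a seeded random sample of events, then 20 epochs of
batch updates with a Gaussian grid neighbourhood decaying linearly from
half the grid width to 0.4. Batch training is deterministic given the
seed and orders of magnitude faster in numpy than online updates; 20
epochs with a 0.4 final neighbourhood were chosen so that node
allocation tracks density closely enough for every archetype —
including percent-scale ones — to own at least one node. Event
assignment is nearest-codebook (Euclidean; ties resolve to the lowest
node index).

Metaclustering is average-linkage hierarchical clustering of codebook
vectors cut at 47 groups. Nodes holding fewer than 0.1% of events (grid
interpolators stranded between populations) are absorbed into the
metacluster of their nearest well-occupied node instead of being merged
on their own — otherwise they surface as singleton junk metaclusters.
Mixed-cluster exclusion is **rule-based** rather than by-eye: a
metacluster is flagged when its scaled median expression exceeds 0.5 on
both members of a mutually exclusive lineage pair (CD3/CD19, CD3/CD14,
CD14/CD56). Manual inspection is not reproducible in software; the rule
formalises the same judgement. Frequencies are % of all CD45⁺ events —
excluded clusters leave the columns but stay in the denominator.

Phenotype labels are generated from the heatmap rule (markers with
scaled median > 0.5 appended as "+"); no attempt is made to reproduce
any specific published label set.

## Dimensionality reduction

Subject-level PCA standardises subset columns by default (a
zero-variance guard leaves constant columns unscaled with a warning);
scores, loadings, and variance fractions are exposed, and any component
pair can be extracted — group separation often appears on non-leading
components (e.g. PC1 vs PC3). Event-level t-SNE is a seeded black box
(sklearn, perplexity 30, PCA initialisation, pre-reduction to 10 PCs);
embedding quality is asserted only through label statistics (per-class
silhouette), never through coordinates.

## Differential abundance

scipy's Mann–Whitney U with method="auto": exact for small tie-free
samples, otherwise the tie- and continuity-corrected normal
approximation. Bonferroni with m = number of retained subsets. The
significance threshold 0.1 applies to the **adjusted** p (the correction
and the cutoff are quoted together in the source convention); raw p is
reported alongside so either reading can be audited. Cohen's d uses the
classical pooled SD (Hedges' correction behind a flag) with the standard
normal-approximation CI. The age cut for the sensitivity analysis is 1
year; strata with <2 subjects per group are skipped with a warning.
Clinical correlations use Pearson for continuous labs (CRP, PCT,
lactate, WBC) and Spearman for ordinal severity scores (pSOFA, PELOD-2,
PIM-3), pairwise-complete, sepsis subjects only.

## Networks

Edges require |r| > 0.6 **strictly** and unadjusted two-sided p < 0.05
(the source convention states edges are statistically significant
without naming a procedure; the α is configurable). Correlating
proportions is knowingly compositional — closure induces weak negative
dependence among large subsets; the package implements the literal
procedure and leaves closure-aware inference out of scope. Density
counts isolated nodes in n (all retained subsets are nodes), which is
what makes a density of 0.103 on 46 nodes correspond to 107 edges.
Modularity is Newman's Q on the sign-stripped unweighted graph; the
partition is the exact maximum over all partitions when ≤8 nodes carry
edges (exhaustive enumeration, used by the oracle tests) and
deterministic greedy agglomeration above that. Signed-modularity and
Spearman-edge variants exist behind flags but are off by default. The
"restricted communication module" observation is made computable as the
fraction of edges whose endpoints share a lineage.

## Classifiers

Logistic regression is the minimal model family consistent with
reporting an age-adjusted combined-subset AUC with CI. Perfect
separation (likely at n = 58 with planted d ≈ 1.5 predictors) falls back
to a deterministic L2-penalised fit and is flagged; scores remain
probabilities. AUC is computed by the trapezoidal rule over all
thresholds and equals the Mann–Whitney rank estimator to machine
precision (an invariant under test); CIs are DeLong-style asymptotic.
The operating point is Youden's J (ties broken toward higher
sensitivity, deterministically); PPV/NPV always recompute from the
confusion matrix. Comparator models use the raw clinical variable as the
score — AUC is invariant to monotone rescaling, so fitting a
single-variable logistic model would change nothing. Prognostic outcomes
are evaluated among sepsis subjects only.

## Pipeline

One master seed; per-stage child seeds via `SeedSequence.spawn` in fixed
stage order, recorded in a manifest together with the config hash,
per-stage output checksums (sha256) and wall times. Stage toggles skip a
stage's outputs; dependent stages are skipped with a logged warning.
Reruns with the same config and seed are bit-identical for deterministic
stages.

## Problem sizes in the test suite

Statistical simulations (effect-size recovery, power, family-wise error,
coupling calibration) run at the study's subject counts (39/19, with
n = 200–1,000 where a calibration check demands it) on composition-level
frequency tables — event-level sampling adds only binomial noise that is
negligible at 50,000 events and irrelevant to those claims. Event-level
stages (SOM, exclusion, purity, t-SNE) run on cohorts scaled to
1,500–2,000 events/subject; the clustering geometry is scale-free in the
event count once every population holds a few hundred pooled events.
Seeds are fixed throughout.

## Known limitations

- The marker panel is reconstructed from subset phenotype labels and is
  approximate; a real instrument panel has more channels and isotope-
  specific spillover structure.
- The qualitative network contrast at n = 39/19 is a property of sample
  correlation matrices near the 0.6 threshold; a small fraction of
  cohort draws (~3%) produce a stray negative edge in the sepsis network
  or drop all negative healthy edges. The planted structure is recovered
  essentially perfectly at n = 200.
- Exact modularity is exponential in the number of connected nodes and
  capped at 8; larger graphs use greedy agglomeration, which can be
  slightly suboptimal.
- The 4-subset classifier is evaluated by refitting per cohort
  (mirroring the validation-by-independent-technique workflow), not by
  frozen-coefficient transfer; both modes exist, only refitting is
  exercised by default.
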