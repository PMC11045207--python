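# Methods

## Model

`stemscore` treats stemness as a weighted accessibility index. The cell's
raw score is a linear functional of its gene-level accessibility profile,

    score(c) = Σ_{i∈G} w_i · x_i(c),

followed by per-sample min-max normalization to [0, 1]. Everything else in
the package exists to construct *G*, *w* and *x*:

1. **Consensus gene list G.** Three multiclass tree ensembles — random
   forest, gradient boosting, extreme gradient boosting — are fit on
   repeated stratified splits (default 70% train) of a labeled scRNA-seq
   matrix of neural stem/progenitor populations. Per repetition, each
   learner's top-k genes by native feature importance are recorded
   (default k = 100); a gene is *selected* by a learner when it appears in
   at least `min_votes` of `n_reps` repetitions (defaults 50 of 100), and
   G is the intersection of the learners' selected sets (union available).
   Repetition r derives its seed as `seed + r` for both split and learner,
   so any repetition can be replayed alone.
2. **Gene accessibility x.** A gene region (promoter or enhancer) is
   linked to a scATAC peak iff the region's midpoint — floor((start+end)/2)
   in 0-based half-open coordinates — satisfies `peak.start ≤ mid <
   peak.end` on the same chromosome, ignoring strand. A gene's raw value
   per cell is the sum of counts over its distinct mapped peaks (a peak
   reachable through several regions of one gene counts once). Per gene,
   cells with z < −1 (mean/sd across cells, sd with denominator n−1) are
   zeroed so lowly accessible cells contribute nothing, then values are
   log2(x+1)-transformed.
3. **Weights w.** Each gene's ML importance and its mean gene-association
   power over mapped regions are normalized across G and multiplied.

## Learner presets

| learner | preset |
|---|---|
| rf  | 500 trees, √(n_genes) features per split |
| gb  | 2,500 trees, learning rate 0.001, depth 5, ≥ 5 obs per leaf |
| xgb | 2,500 rounds, depth 15, eta 0.001, column subsample 0.5 |

The gradient-boosting learner is backed by LightGBM, whose histogram-based
trees make the 2,500-tree preset tractable on a single CPU; the classical
exact-split implementation is two orders of magnitude slower at the same
hyperparameters without changing what the preset expresses. Importances
are the learners' native impurity/gain measures; per-learner mean
importances are min-max rescaled within each learner before cross-learner
averaging so learners with different importance scales are commensurable
(`importance_from` selects a single learner's importances instead).

## Weight normalization: why min-max is the default

Both weight factors are normalized across G before the product. Two modes
exist:

* `rescale` (default): min-max to [0, 1]. All weights are non-negative,
  so raising accessibility at a consensus gene can only raise the score.
* `center`: z-standardize each factor (mean 0, sd with denominator n−1).

Centered factors are a faithful reading of normalizing with a `scale()`-
style transform, but they make the score's *direction* an accident of the
data: when importance and association power are uncorrelated (they come
from unrelated sources, so generically they are), the centered weights sum
to ≈ 0 and the score shift of a uniformly more-accessible cell is `Δ·Σw_i`
— a quantity whose sign is essentially a coin flip per dataset. A
stemness index whose sign flips between samples is not interpretable, so
the sign-safe rescaled weights are the default; the centered mode remains
available and is exercised by the tests. The count of negative final
weights is logged in either mode.

## State labeling

* **Signature states.** Per state, the promoters (optionally enhancers) of
  its signature genes are mapped and aggregated as above — without the
  z-filter, which is a scoring-specific device — log-transformed, and the
  cells are clustered (agglomerative, Ward linkage on Euclidean distances
  by default; both configurable). The cluster with the highest mean
  accessibility is flagged as the state's population; ties go to the
  smaller cluster id. A cell flagged by several states takes the state
  with the larger per-cell mean signature accessibility. k is a required
  user parameter: the choice is a judgment call made per sample in
  practice, and silently guessing it would hide that.
* **GSC functional states.** Cells below the stemness cutoff (default
  0.5) stay unassigned. For the rest, each state's signal is the summed
  count of peaks whose midpoints fall in that state's discriminating
  regions, divided by the state's region count (total-sum and
  length-normalized variants are flag-selectable); the cell takes the
  argmax, and exact ties stay unassigned.

## Synthetic data

The generator (`stemscore.simulate`) emulates every input: labeled
scRNA-seq counts, a promoter/enhancer annotation with gamma-distributed
association scores (shape 2, scale 5), a peaks/barcodes/counts scATAC
bundle, signature lists and GSC regions. Counts in both modalities are
negative binomial (mean m, dispersion θ, variance m + m²/θ; θ = 2 by
default — moderate overdispersion).

Planted structure:

* scRNA-seq: informative genes (default 20 of 500) carry a `fold_effect`
  (default 8) mean shift in exactly one state each, states assigned
  round-robin over 4 states × 100 cells.
* scATAC-seq: one peak is generated around every gene-region midpoint;
  decoy peaks (placed ≥ 2 kb from any region midpoint, so they map to
  nothing) fill the bundle to 5,000 peaks. A 20% stem-like cell fraction
  receives the fold shift at all informative-gene peaks. With
  `plant_states=True`, each stem cell gets a second fold shift at its own
  signature state's peaks and a GSC state derived from it, which the
  labeling recovery tests exploit.

Deliberate non-features, which bound what passing tests show about real
data: no per-cell sequencing-depth variation (the scoring pipeline applies
no depth normalization either — a known limitation), no fragment-length,
GC or TSS-enrichment structure, no doublets, and **no per-gene baseline
heterogeneity in the scRNA-seq noise genes** (one shared baseline mean of
2.0). The last point is substantive: impurity-based importances are
scale-biased, so genes with larger baseline variance are stably top-ranked
even under label-free noise. With heterogeneous baselines the consensus
protocol's false-selection rate under shuffled labels is ~14–16%, not the
near-zero a binomial independence argument suggests; the guarantee that
label-free noise selects (almost) nothing is a property of exchangeable
noise genes. On real data, the protocol's selections should therefore be
read as "stably top-ranked", not as "significant at a calibrated false
positive rate". For the same reason, label shuffling alone is not a clean
null on planted data — the planted genes' marginal bimodality survives
shuffling and keeps them top-ranked — so the null control runs on a
matched signal-free simulation with labels additionally reshuffled within
every repetition.

## Numerical and edge-case policy

* Coordinates are 0-based half-open everywhere internally; 1-based
  inclusive inputs are converted by `start − 1` at the boundary, and the
  conversion round-trips exactly.
* Midpoint uses floor division; containment is `start ≤ mid < end`.
* sd uses denominator n−1 throughout (z-filter, centered weights).
* z-filter rows with sd = 0 pass through unchanged; `log2(x+1)` keeps
  zeros at zero.
* Min-max over a constant raw-score vector returns all zeros with a
  warning; classification at the 0.5 cutoff is strict (exactly 0.5 is
  "low" — the boundary must fall somewhere, and the conservative side is
  chosen).
* Consensus genes with no mapped peaks are dropped from G with a warning
  (both weight factors require mapped regions); fewer than 2 survivors is
  fatal.
* An empty cross-learner intersection is a warning at selection time and
  fatal at scoring time, with `combine_mode="union"` as the escape hatch.
* All estimators run single-threaded with explicit seeds; pipeline stage
  seeds derive from one top-level seed via SHA-256, recorded in the run
  manifest, so outputs are byte-reproducible.

## Validation protocol and problem sizes

The original study's per-patient numbers depend on controlled-access
accessions, so validation is by planted-structure recovery and
independent oracles: brute-force all-pairs interval mapping and naive
score arithmetic on random instances, z-filter calibration against the
normal tail (zeroed fraction ≈ Φ(−1) = 0.1587), exact min/max endpoints of
the normalization, ≥ 80% consensus recovery of planted genes per learner
with the null control ≤ 2%, end-to-end AUROC > 0.9 against planted stem
labels in ≥ 9/10 seeds (1,000 cells, 5,000 peaks), ≥ 95% cluster-then-flag
state recovery, and byte-identical pipeline reruns. Recovery runs use a
scaled-down consensus protocol — 20 repetitions, 10 votes, top-100, with
the boosting learners at 400 rounds (RF keeps 500 trees) — chosen so the
whole validation completes in minutes on one CPU while exercising the full
voting scheme.

## Known limitations

* No sequencing-depth normalization: cells with more reads score higher,
  mirroring the upstream method definition rather than correcting it.
* The consensus protocol's selections are not calibrated false-positive
  rates (see above).
* Signature-state assignment flags exactly one cluster per state; diffuse
  states spanning clusters will be under-called.
* Whether enhancers should contribute to signature accessibility is
  ambiguous in the upstream description; promoters-only is the default,
  `include_enhancers=True` opts in.
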