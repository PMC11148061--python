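# Methods

## Setting and model

The pipeline analyses a perturbation screen in which cells are pre-treated
with one kinase inhibitor (or vehicle) and stimulated, and H3K27ac is
quantified at a fixed catalog of stimulus-regulated cis-regulatory elements
(CREs) over a short time course (default grid 0, 0.5, 1, 2, 4 h). The data
for one stimulus are a set of aligned CRE × time count tables, one per
condition, with the vehicle flagged.

### Multiple Factor Analysis

All tables are row-standardized jointly: each CRE's values are centered and
scaled over the concatenation of every condition's columns, using the
population standard-deviation convention (divide by n). Rows with zero
spread are dropped with a warning. Each standardized table is then divided
by its first singular value σ₁ — equivalently weighted by 1/σ₁² — which
makes the first eigenvalue of every reweighted table exactly 1, so no
single condition dominates the joint analysis. The reweighted tables are
concatenated and decomposed by a plain SVD with no further column
centering (the rows are already centered; a column-centering switch exists
for sensitivity analysis). Compromise factor scores are F = UΔ; the partial
factor scores of table k are F_k = K·(X_k/σ₁ₖ)·V_k with V_k the block of
right singular vectors belonging to table k's columns, and mean_k F_k = F
exactly (verified to 1e-8 in the tests). Each dimension is oriented so its
largest-magnitude loading is positive, making outputs deterministic.

Significant dimensions are selected by permutation: values are shuffled
independently within each column of each table, the analysis — including
the row standardization — is refit, and dimension d gets
p = (1 + #{permuted eigenvalue_d ≥ observed_d}) / (1 + n_perm); dimensions
with p < α (default 0.01, n_perm ≥ 100) are retained. Re-applying the row
standardization inside the permutation loop matters: permuting breaks the
unit-row-norm constraint of the observed data and otherwise shifts the
whole null spectrum low by ~1–2%, which is enough to select many coupled
dimensions spuriously. With the refit, pure-noise fixtures select on
average fewer than one dimension at α = 0.01.

### Perturbation-likelihood score

For each CRE and inhibitor, the Euclidean distance between the inhibitor's
and the vehicle's partial factor scores is computed over the selected
dimensions. The natural logs of all inhibitor × CRE distances of a stimulus
are pooled and standardized by a maximum-likelihood normal fit; the
upper-tail probability CCDF = 1 − Φ(z) expresses how extreme a displacement
is. The score is −log₁₀(CCDF) signed by ΔZ, the difference of the summed
per-time-point z-scores (all time points, including t = 0) between
inhibitor and vehicle; ΔZ = 0 forces a zero score. |score| > 1 (i.e.
CCDF < 0.1 with a definite direction) calls an event.

Two deliberate choices here:

- The normal null is fitted **pooled across all inhibitors**, not per
  inhibitor. A per-inhibitor fit would force every inhibitor to have
  roughly the same number of extreme cells, erasing genuine differences in
  effect budgets; with the pooled fit, per-inhibitor call counts vary
  widely (a property the tests assert).
- Zero distances are replaced by 10⁻³ times the smallest positive distance
  before the log, and the CCDF is floored at 10⁻³⁰⁰, keeping scores finite.

### Inhibitor comparisons

Inhibitor proximity is computed by PCA of the inhibitor × CRE signed-score
matrix, with components selected by the same within-column permutation
test; Euclidean distances in the selected-component space drive a
k-nearest-neighbour network (k = 3, ties broken lexicographically by
inhibitor id) and a Ward dendrogram (Ward linkage on the Euclidean
distances, the ward.D2 convention). If the permutation test retains no
component — possible on near-null inputs — the model falls back to the
first component and flags it, rather than failing. The family test
compares the mean pairwise distance among same-family inhibitors with a
label-shuffle null, p = (1 + #{null ≤ observed}) / (1 + n_shuffle), and
reports a Kruskal–Wallis rank test of intra- vs inter-family pair
distances alongside.

Angular profiles place each CRE at θ = atan2(dim2, dim1) of its compromise
coordinates, bin affected CREs into 72 five-degree bins and min–max scale
the per-direction counts. The SES-Jaccard standardizes the overlap of two
affected CRE sets against 1000 same-size uniform resamples (without
replacement) from the CRE universe; a zero null sd yields SES = 0 with a
flag. Readout comparison reports the Spearman correlation of two pairwise
distance tables and the distribution of one grouped by quintiles of the
other (quintiles by value, ties broken by pair id, sizes differing by at
most one).

### TF association

A CRE counts as bound by a TF when any peak shares at least one base
(0-based half-open intervals; an interval-tree query, checked against a
brute-force scan in the tests). For each (TF, inhibitor, direction) the
observed number of bound CREs among the affected set is compared with
n_perm same-size uniform resamples from the CRE catalog — the catalog, not
genome-wide random regions, is the relevant universe here and keeps the
test exact at desk scale. z = (obs − mean)/sd, the two-sided empirical p
uses +1 smoothing, and Benjamini–Hochberg correction runs across all tests
of one invocation.

### Direction classifier

Features are MFA components of the source tables (z-scored kinetics and
signed TF-binding indicators in the default pipeline), kept when they
explain ≥1% of variance; tables enter as given, so the caller controls
scaling. Descriptors report each component's correlation with every source
column, plus a group-mean v statistic
v = (x̄_g − x̄)/sqrt(((N − n_g)/(N − 1))·s²/n_g) for categorical labels.
Class imbalance is handled by the custom weights
w₀ = n/(2n₀), w_eff = n/(2(n − n₀)), w_d = w_eff·n_d/(n_d + n_u),
w_u = w_eff·n_u/(n_d + n_u), rescaled to sum to one — half the mass to the
unaffected majority, the affected half apportioned toward the more
populous direction. Training uses a stratified 70/30 split and an XGBoost
multi-class model; by default fixed, documented hyperparameters
(depth 4, learning rate 0.1, 150 trees, subsample and colsample 0.8), with
an optional reduced grid (depth {3,6} × learning rate {0.05,0.1} ×
estimators {100,300}) searched by 3-fold stratified cross-validation
maximizing balanced accuracy. Evaluation reports one-vs-rest ROC-AUC and
PR-AUC per class on the held-out set. Attributions default to the
booster's built-in TreeSHAP contributions; directional importance is the
per-class mean |attribution| per feature, min–max scaled to [0, 1] across
features and multiplied by the sign of the feature–attribution Pearson
correlation (zero-variance guard → 0). The tests check signs and rankings
against exact Shapley values obtained by brute-force coalition enumeration
on 3-feature models.

### Normalization

Samples are brought onto a common scale by invariant-feature selection:
log2(count + pseudocount) differences from a per-feature median
pseudo-reference are modelled per sample with a skew-normal (MLE with
method-of-moments initialization; fallback to a normal fit on
non-convergence, and to the median difference on degenerate input);
features within 1σ of the fitted mean — mean and sd of the skew-normal,
not location/scale — are invariant, and each sample is scaled so the
median ratio over its invariant set to the reference is 1. The pseudocount
(default 1) and the σ window are configuration. Two practical notes: the
median pseudo-reference includes each sample, biasing factors toward 1 by
roughly offset/n_samples, negligible at realistic screen sizes (tens to
hundreds of samples); and invariant-feature selection presupposes that
most features are unchanged between samples — on a catalog consisting
exclusively of stimulus-responsive CREs the invariant set is strained, so
in real use the fit belongs on the full peak catalog before restricting to
dynamic CREs.

## Synthetic data: what it emulates, and what it does not

`epiperturb.synthetic` generates the study conditions the pipeline assumes:

- **Kinetics**: four induced clusters with log-signal bumps of amplitude 2
  (natural log, ≈7-fold induction) peaking at 0.5/1/2/4 h over a baseline;
  t = 0 is the pre-stimulation state.
- **Wiring**: `n_programs` TF programs, each driven by one kinase and
  owning a disjoint CRE subset (40% of the universe in total; the rest is
  responsive background). Inhibitor i's intended target cycles through the
  program kinases — inhibitors sharing an intended target form a family —
  plus Binomial(n_kinases − 1, 0.15) off-targets. Potencies are uniform:
  intended U(0.7, 1.0), off-target U(0.4, 0.8).
- **Effects**: an inhibitor shifts the log-mean of every CRE of a program
  wired to its inhibited kinases by −(Σ potencies)·effect_scale at induced
  time points, times a per-CRE responsiveness drawn U(0.5, 1.5); 20% of
  programs are up-regulatory. effect_scale defaults to 2.0, so a
  full-potency hit abolishes the induced amplitude.
- **Noise**: negative binomial with mean exp(log-signal)·depth and size
  (dispersion) parameter 50 — Var = m + m²/50, a clean-screen regime with
  mean counts of roughly 100–700 — plus per-sample log-normal(0, 0.15)
  depth multipliers so normalization has real work to do. Large size
  recovers the Poisson limit (tested).
- **TF peaks**: the TF of each program carries a peak inside member CREs
  with probability 1 − fnr (default 0.9) and inside non-members with
  probability fpr (default 0.05), placed in the central half of the CRE
  interval.

The generator returns machine-readable truth (per-(CRE, inhibitor) signed
effects, cluster memberships, wiring), which the recovery tests score
against. What the fixtures do **not** emulate: replicate structure and
batch effects, GC/length biases, peak-calling uncertainty, correlated
noise between neighbouring CREs, partially overlapping TF programs, and
secondary (indirect) transcriptional effects. Passing the recovery tests
therefore shows the machinery is correct and calibrated under its own
assumptions, not that real screens of arbitrary quality will reach the
same operating characteristics.

## Known behaviour and limitations

- **Detection vs grading.** On the default fixture, ranking cells by
  |score| separates perturbed from unperturbed pairs with AUROC > 0.9, and
  within an inhibitor |score| grades with injected |effect|
  (Spearman ≈ 0.8). Pooled across inhibitors the grading is weaker
  (≈0.6–0.8 depending on the draw): the partial-score displacement along an
  effect dimension is scaled by the table's loading weight on that
  dimension, which itself grows with the inhibitor's own effect strength —
  a convex distortion inherent to the compromise projection. The raw
  z-space distance does not show it, so cross-inhibitor score magnitudes
  should be compared with care; within-inhibitor rankings and event calls
  are unaffected.
- The permutation selection compares raw per-dimension eigenvalues, which
  remain weakly coupled through the σ₁ weights; on pure noise the expected
  number of selected dimensions stays below one, but occasional fixtures
  select several at once.
- Scores depend on the selected-dimension set; a config switch restricts
  the distance to any dimension subset for sensitivity analysis.
- Default problem sizes (2,000 CREs, 12 inhibitors, 200 permutations for
  dimension selection, 1,000 for overlaps, 5,000 for associations) keep a
  full pipeline run on one CPU in the minutes range; all are configuration.

## Numerical conventions

0-based half-open genomic coordinates throughout, strand ignored.
Population sd for row standardization. Eigenvalues are squared singular
values of the matrices as analysed (no 1/n factor). All randomness flows
through explicit integer seeds via `numpy.random.default_rng`; fixtures
are byte-identical under a fixed seed. Degenerate cases (zero tables,
zero-sd rows, empty invariant or affected sets, zero null sd) raise or
flag explicitly rather than propagating NaNs.
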