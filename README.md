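# epiperturb

Functional profiling of kinase inhibitors from epigenomic time courses.

Chromatin marks such as H3K27ac respond within minutes to signalling
perturbations, so the acetylation time course of stimulus-regulated
cis-regulatory elements (CREs) is an information-rich, unbiased readout of
what a kinase inhibitor actually does inside a cell — intended target and
off-targets alike. `epiperturb` implements an end-to-end pipeline that turns
per-condition CRE × time count tables (one table per inhibitor plus a
vehicle control, per stimulus) into:

- **Multiple Factor Analysis (MFA)** of the condition tables. Each
  standardized table X<sub>k</sub> is weighted by 1/σ₁²(X<sub>k</sub>) — the
  inverse of its first squared singular value — so every table's first
  eigenvalue equals 1 and all conditions enter on an equal footing; a joint
  SVD of the reweighted concatenation yields the *compromise* F = UΔ and
  per-table *partial factor scores* F<sub>k</sub> = K·(X<sub>k</sub>/σ₁)·V<sub>k</sub>,
  whose table-average equals F (barycenter identity). Significant dimensions
  are chosen by within-column permutation of the data.
- **Perturbation-likelihood scores.** For each CRE, the Euclidean distance d
  between an inhibitor's and the vehicle's partial scores is standardized on
  the pooled ln d, converted to an upper-tail probability (CCDF), and signed
  by ΔZ = Σ<sub>t</sub> z<sup>inhibitor</sup><sub>t</sub> − Σ<sub>t</sub> z<sup>vehicle</sup><sub>t</sub>:
  score = −log₁₀(CCDF)·sign(ΔZ). |score| > 1 calls an up- or
  down-regulation event.
- **Inhibitor comparisons**: PCA of the signed score matrix with permutation
  component selection, a 3-nearest-neighbour proximity network and Ward
  dendrogram, a label-shuffle test of target-family clustering, angular
  (kinetic) frequency profiles of affected CREs, and the standardized effect
  size (SES) of the Jaccard overlap J = |A∩B|/|A∪B| between affected CRE
  sets, SES = (J − μ<sub>null</sub>)/σ<sub>null</sub> under size-matched
  resampling.
- **TF association**: permutation tests of the overlap between affected CRE
  sets and TF peak intervals (z against a same-size resampling null,
  Benjamini–Hochberg corrected).
- **Direction prediction**: an XGBoost multi-class model (down / unaffected
  / up) on MFA-derived features, with custom class weights
  w₀ = n/(2n₀), w_eff = n/(2(n−n₀)), w_d = w_eff·n_d/(n_d+n_u),
  w_u = w_eff·n_u/(n_d+n_u), rescaled to sum to 1, and a *directional*
  feature importance: mean |SHAP| per feature, min–max scaled to [0, 1] and
  signed by the feature–attribution correlation.

Between-sample normalization selects invariant features by fitting a
skew-normal to each sample's log2 differences from a median pseudo-reference
and keeping features within 1σ of the fitted mean.

A first-class synthetic-data generator (`epiperturb.synthetic`) produces
fixtures with known ground truth — kinetic CRE clusters peaking at
0.5/1/2/4 h, latent kinase → TF-program → CRE wiring, polypharmacological
inhibitor target profiles, negative-binomial count noise — so every stage
can be tested against the truth it is supposed to recover.

## Worked example

```python
import numpy as np
from epiperturb import synthetic, mfa, perturbation, comparative

wiring = synthetic.generate_wiring(n_cres=800, n_inhibitors=12, n_kinases=8,
                                   n_programs=4, seed=1)
mts, truth = synthetic.generate_counts(wiring, seed=1)

std = mfa.standardize(mts, log2_transform=True)
result = mfa.fit_with_selection(std, n_perm=200, alpha=0.01, seed=1)
print("selected dimensions:", [d + 1 for d in result.selected_dims])
print("variance explained:", np.round(result.variance_share[result.selected_dims], 3))

dist = perturbation.cre_distances(result)
scores = perturbation.score_perturbations(dist, std)
calls, summary = perturbation.call_events(scores.score, threshold=1.0)
print(summary.head(4))

model = comparative.proximity_fit(scores, n_perm=100, seed=1)
obs, null, p, _ = comparative.family_distance_test(model, wiring.family, seed=1)
print(f"intra-family mean distance {obs:.1f} vs null {null.mean():.1f} (p = {p:.4f})")
```

prints

```
selected dimensions: [1, 2, 3, 4, 5, 6]
variance explained: [0.424 0.253 0.105 0.066 0.045 0.038]
           up  down
inhibitor
CKI00       1    78
CKI01      80     0
CKI02      29    92
CKI03       1    80
intra-family mean distance 7.4 vs null 18.6 (p = 0.0010)
```

Six compromise dimensions carry more variance than any within-column
permutation of the data; the first is the shared stimulus kinetics, the
rest separate the inhibitor programs. Each inhibitor calls tens of events
at |score| > 1, dominated by loss of induced acetylation (CKI01's intended
program is up-regulatory in this fixture, hence its up-dominated calls),
and inhibitors that share an intended target kinase sit much closer in the
proximity space than label-shuffled controls (empirical p = 0.001).

The same stages are exposed on the command line:

```bash
epiperturb simulate --n-cres 800 --n-inhibitors 12 --seed 1 --out fixture/
epiperturb run --seed 1 --out run/          # full pipeline, writes run/manifest.json
```

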