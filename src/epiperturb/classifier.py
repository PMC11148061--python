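"""Multi-class prediction of perturbation direction per CRE.

Features are MFA components of the source data tables (kinetics, TF
binding), kept when they explain at least 1% of variance. Class imbalance
(most CREs are unaffected; down-regulation usually outnumbers
up-regulation) is handled by custom weights that split half the mass
between unaffected and affected CREs, then apportion the affected half in
proportion to class frequency — so among changing CREs the more populous
direction receives the larger weight. Gradient-boosted trees give the
model; per-feature per-class attributions yield a directional importance:
the mean |attribution| min-max scaled to [0, 1] across features and signed
by the feature–attribution correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split

from . import mfa as mfa_mod

CLASS_ORDER = ("down", "none", "up")

DEFAULT_PARAMS = {
    "max_depth": 4,
    "learning_rate": 0.1,
    "n_estimators": 150,
    "subsample": 0.8,
    "colsample_bytree": 0.8,
}
# reduced tuning grid; selection by balanced accuracy, 3-fold stratified CV
DEFAULT_GRID = {
    "max_depth": [3, 6],
    "learning_rate": [0.05, 0.1],
    "n_estimators": [100, 300],
}


@dataclass
class FeatureSpace:
    features: pd.DataFrame  # CRE x kept component
    variance_explained: np.ndarray  # share per kept component
    descriptors: pd.DataFrame  # component x source column correlations
    vtests: pd.DataFrame | None = None  # component x category v statistics


@dataclass
class ClassWeights:
    n_samples: int
    n0: int
    nd: int
    nu: int
    w0s: float
    wds: float
    wus: float

    def per_class(self) -> dict[str, float]:
        return {"none": self.w0s, "down": self.wds, "up": self.wus}


@dataclass
class EvalResult:
    model: Any
    metrics: pd.DataFrame  # class x {roc_auc, pr_auc, n_test}
    classes: tuple = CLASS_ORDER
    best_params: dict = field(default_factory=dict)
    train_index: pd.Index | None = None
    test_index: pd.Index | None = None


def build_feature_space(
    tables: dict[str, pd.DataFrame],
    min_var: float = 0.01,
    categorical: dict[str, pd.Series] | None = None,
) -> FeatureSpace:
    """MFA feature extraction over grouped source tables.

    Tables (one per assay/group, sharing CRE rows, already on the scale the
    caller wants analyzed — e.g. z-scored kinetics, signed binding
    indicators) enter the MFA machinery as given: each group is weighted by
    the inverse of its first squared singular value and the joint SVD
    yields the compromise. Components explaining at least ``min_var`` of
    variance become the features; duplicating a group leaves the variance
    shares unchanged by the equal-footing weighting. Descriptors report
    each component's Pearson correlation with every source column; for
    categorical per-CRE labels the group-mean v statistic
    v = (mean_g - mean) / sqrt(((N - n_g)/(N - 1)) * var / n_g) is added.
    """
    common = None
    for tab in tables.values():
        common = tab.index if common is None else common.intersection(tab.index)
    if common is None or len(common) == 0:
        raise ValueError("tables share no CREs")
    tables = {g: tab.loc[common].astype(float) for g, tab in tables.items()}
    groups = list(tables)
    std = mfa_mod.StandardizedSet(
        tables=tables,
        conditions=groups,
        vehicle=None,
        row_mean=pd.Series(0.0, index=common),
        row_sd=pd.Series(1.0, index=common),
    )
    res = mfa_mod.mfa_fit(std)
    share = res.variance_share
    keep = [d for d in range(len(share)) if share[d] >= min_var]
    if not keep:
        raise ValueError(
            f"no component reaches min_var={min_var}; lower the threshold"
        )
    cols = [res.compromise_scores.columns[d] for d in keep]
    feats = res.compromise_scores[cols]

    zcols = pd.concat({g: tables[g] for g in groups}, axis=1)
    zcols.columns = [f"{g}|{c}" for g, c in zcols.columns]
    desc = pd.DataFrame(
        {
            col: [
                float(np.corrcoef(feats[c], zcols[col])[0, 1])
                if zcols[col].std() > 0
                else 0.0
                for c in cols
            ]
            for col in zcols.columns
        },
        index=cols,
    )
    vtests = None
    if categorical:
        rows = {}
        n = len(feats)
        for name, labels in categorical.items():
            labels = labels[feats.index]
            for cat in sorted(labels.unique()):
                mask = (labels == cat).to_numpy()
                ng = int(mask.sum())
                if ng == 0 or ng == n:
                    continue
                vals = []
                for c in cols:
                    x = feats[c].to_numpy()
                    denom = np.sqrt(((n - ng) / (n - 1)) * x.var() / ng)
                    vals.append(float((x[mask].mean() - x.mean()) / denom))
                rows[f"{name}={cat}"] = vals
        vtests = pd.DataFrame(rows, index=cols) if rows else None
    return FeatureSpace(
        features=feats,
        variance_explained=share[keep],
        descriptors=desc,
        vtests=vtests,
    )


def class_weights(n0: int, nd: int, nu: int) -> ClassWeights:
    """Custom class weights for the unaffected/down/up prediction task.

    w0 = n/(2*n0) and w_eff = n/(2*(n - n0)) split half the weight between
    unaffected and affected observations; within the affected half,
    w_d = nd/(nd + nu) * w_eff and w_u = nu/(nd + nu) * w_eff apportion by
    class frequency. The three weights are then scaled to sum to 1.
    """
    n = n0 + nd + nu
    if n < 3:
        raise ValueError("need at least 3 observations")
    if n0 == 0:
        raise ValueError("no unaffected observations")
    if nd + nu == 0:
        raise ValueError("no affected observations")
    w0 = n / (2.0 * n0)
    w_eff = n / (2.0 * (n - n0))
    wu = nu / (nd + nu) * w_eff
    wd = nd / (nd + nu) * w_eff
    total = w0 + wu + wd
    return ClassWeights(
        n_samples=n,
        n0=n0,
        nd=nd,
        nu=nu,
        w0s=w0 / total,
        wds=wd / total,
        wus=wu / total,
    )


def weights_from_labels(labels: pd.Series) -> ClassWeights:
    counts = labels.value_counts()
    return class_weights(
        int(counts.get("none", 0)), int(counts.get("down", 0)), int(counts.get("up", 0))
    )


def train_eval(
    features,
    labels: pd.Series,
    weights: ClassWeights | None = None,
    split: float = 0.7,
    seed: int = 0,
    backend: str = "xgboost",
    tune: bool = False,
    params: dict | None = None,
    grid: dict | None = None,
) -> EvalResult:
    """Stratified 70/30 train/test with per-observation class weights.

    Reports one-vs-rest ROC-AUC and PR-AUC per class on the held-out set.
    With ``tune=True`` a reduced hyperparameter grid is searched by 3-fold
    stratified CV maximizing balanced accuracy.
    """
    x = features.features if isinstance(features, FeatureSpace) else features
    bad = set(labels.unique()) - set(CLASS_ORDER)
    if bad:
        raise ValueError(f"unknown labels: {bad}")
    labels = labels[x.index]
    if weights is None:
        weights = weights_from_labels(labels)
    y = labels.map({c: i for i, c in enumerate(CLASS_ORDER)}).to_numpy()
    counts = np.bincount(y, minlength=3)
    if (counts < 2).any():
        raise ValueError(
            "every class needs >= 2 observations for a stratified split; "
            f"got counts {dict(zip(CLASS_ORDER, counts))}"
        )
    idx_train, idx_test = train_test_split(
        np.arange(len(y)),
        train_size=split,
        random_state=seed,
        stratify=y,
    )
    for part, name in ((idx_train, "training"), (idx_test, "test")):
        present = np.bincount(y[part], minlength=3)
        if (present == 0).any():
            missing = [CLASS_ORDER[i] for i in np.where(present == 0)[0]]
            raise ValueError(
                f"class(es) {missing} absent from the {name} split; "
                "add observations or adjust the split fraction"
            )
    wmap = weights.per_class()
    sw = np.array([wmap[CLASS_ORDER[c]] for c in y])

    if backend != "xgboost":
        raise ValueError(f"unknown backend {backend!r}")
    from xgboost import XGBClassifier

    base = XGBClassifier(
        objective="multi:softprob",
        num_class=3,
        random_state=seed,
        n_jobs=1,
        eval_metric="mlogloss",
        **(params or DEFAULT_PARAMS),
    )
    best_params = dict(params or DEFAULT_PARAMS)
    xt, yt, swt = x.iloc[idx_train].to_numpy(), y[idx_train], sw[idx_train]
    if tune:
        search = GridSearchCV(
            base,
            grid or DEFAULT_GRID,
            scoring="balanced_accuracy",
            cv=StratifiedKFold(3, shuffle=True, random_state=seed),
            n_jobs=1,
        )
        search.fit(xt, yt, sample_weight=swt)
        model = search.best_estimator_
        best_params.update(search.best_params_)
    else:
        model = base
        model.fit(xt, yt, sample_weight=swt)

    proba = model.predict_proba(x.iloc[idx_test].to_numpy())
    yte = y[idx_test]
    rows = {}
    for i, cls in enumerate(CLASS_ORDER):
        ybin = (yte == i).astype(int)
        rows[cls] = {
            "roc_auc": float(roc_auc_score(ybin, proba[:, i])),
            "pr_auc": float(average_precision_score(ybin, proba[:, i])),
            "n_test": int(ybin.sum()),
        }
    return EvalResult(
        model=model,
        metrics=pd.DataFrame(rows).T,
        best_params=best_params,
        train_index=x.index[idx_train],
        test_index=x.index[idx_test],
    )


def tree_attributions(model, x: pd.DataFrame) -> np.ndarray:
    """Per-class additive tree attributions, shape (n_obs, n_class, n_feat).

    Uses the booster's built-in TreeSHAP contributions; the bias column is
    dropped.
    """
    import xgboost as xgb

    booster = model.get_booster()
    contrib = booster.predict(xgb.DMatrix(x.to_numpy()), pred_contribs=True)
    if contrib.ndim == 2:  # binary/regression: (n, feat+1)
        contrib = contrib[:, None, :]
    return contrib[:, :, :-1]


def directional_importance(
    features: pd.DataFrame,
    attributions: np.ndarray,
    classes=CLASS_ORDER,
) -> pd.DataFrame:
    """Signed, scaled per-feature importance per class.

    For each class: mean |attribution| per feature, min-max scaled across
    features to [0, 1], multiplied by the sign of the Pearson correlation
    between feature values and attributions (0 when either side has zero
    variance). Values therefore lie in [-1, 1] with max |value| = 1.
    """
    attributions = np.asarray(attributions, dtype=float)
    if attributions.ndim != 3 or attributions.shape[0] != len(features) or attributions.shape[2] != features.shape[1]:
        raise ValueError(
            f"attributions shape {attributions.shape} does not match "
            f"(n_obs={len(features)}, n_class, n_feat={features.shape[1]})"
        )
    out = {}
    xv = features.to_numpy()
    for ci, cls in enumerate(classes[: attributions.shape[1]]):
        a = attributions[:, ci, :]
        mag = np.abs(a).mean(axis=0)
        spread = mag.max() - mag.min()
        scaled = (mag - mag.min()) / spread if spread > 0 else np.zeros_like(mag)
        signs = np.zeros(features.shape[1])
        for j in range(features.shape[1]):
            if np.std(xv[:, j]) == 0 or np.std(a[:, j]) == 0:
                continue
            r = stats.pearsonr(xv[:, j], a[:, j]).statistic
            signs[j] = np.sign(r)
        out[cls] = scaled * signs
    return pd.DataFrame(out, index=features.columns)
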