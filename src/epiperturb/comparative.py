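"""Inhibitor-level comparative statistics.

Proximity of inhibitors is assessed in the PCA space of their signed
perturbation-likelihood vectors: significant components are chosen by the
same within-column permutation test used for the MFA compromise, Euclidean
distances in that space drive a 3-nearest-neighbour network and a Ward
dendrogram, and a label-shuffle null tests whether inhibitors targeting
kinases of the same family sit closer than chance. Further utilities cover
the angular (kinetic) frequency profile of affected CREs in the first two
compromise dimensions, the standardized-effect-size Jaccard overlap of
affected CRE sets, and rank comparison of two pairwise-distance readouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform


@dataclass
class ProximityModel:
    pc_scores: pd.DataFrame  # inhibitor x selected component
    eigenvalues: np.ndarray
    perm_pvalues: np.ndarray
    selected: list[int]
    distances: pd.DataFrame  # symmetric inhibitor x inhibitor
    knn_edges: list[tuple[str, str, float]]
    k: int
    linkage_matrix: np.ndarray
    labels: list[str]
    selection_fallback: bool = False


@dataclass
class AngleHistogram:
    inhibitor: str
    direction: str
    bin_edges: np.ndarray  # 73 edges: 0, 5, ..., 360
    counts: np.ndarray
    frequency: np.ndarray  # min-max scaled to [0, 1]
    empty: bool = False


@dataclass
class OverlapStat:
    pair: tuple[str, str, str]  # (A, B, direction)
    jaccard: float
    null_mean: float
    null_sd: float
    ses: float
    degenerate: bool = False


def _perm_select_pca(x: np.ndarray, n_perm: int, alpha: float, rng) -> tuple:
    """Column-permutation selection of PCA components on a centered matrix."""
    xc = x - x.mean(axis=0, keepdims=True)
    k = min(xc.shape[0] - 1, xc.shape[1])

    def eigs(m):
        g = m @ m.T  # n_inhibitors is small
        ev = np.clip(np.linalg.eigvalsh(g)[::-1], 0.0, None)
        return ev[:k]

    obs = eigs(xc)
    exceed = np.zeros(k)
    for _ in range(n_perm):
        p = rng.permuted(x, axis=0)
        pc = p - p.mean(axis=0, keepdims=True)
        exceed += eigs(pc) >= obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    selected = [d for d in range(k) if pvals[d] < alpha]
    return obs, pvals, selected


def proximity_fit(
    scores,
    n_perm: int = 200,
    alpha: float = 0.01,
    seed: int = 0,
    k: int = 3,
) -> ProximityModel:
    """PCA + permutation component selection + k-NN graph + Ward dendrogram.

    ``scores`` is a PerturbationScoreSet or a CRE x inhibitor score
    DataFrame. Distances are Euclidean in the selected-component space;
    nearest-neighbour ties break lexicographically by inhibitor id. If the
    permutation test selects no component the first component is used and
    ``selection_fallback`` is set.
    """
    score = scores.score if hasattr(scores, "score") else scores
    x = score.to_numpy().T  # inhibitor x CRE
    labels = list(score.columns)
    n = len(labels)
    if n < 4:
        raise ValueError("need at least 4 inhibitors")
    if n < k + 1:
        raise ValueError(f"need more inhibitors than k={k}")
    rng = np.random.default_rng(seed)
    eig, pvals, selected = _perm_select_pca(x, n_perm, alpha, rng)
    fallback = False
    if not selected:
        selected = [0]
        fallback = True

    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    for d in range(len(s)):  # deterministic orientation
        j = int(np.argmax(np.abs(vt[d])))
        if vt[d, j] < 0:
            vt[d] = -vt[d]
            u[:, d] = -u[:, d]
    pcs = (u * s)[:, selected]
    pc_scores = pd.DataFrame(
        pcs, index=labels, columns=[f"PC{d + 1}" for d in selected]
    )
    dmat = squareform(pdist(pcs))
    distances = pd.DataFrame(dmat, index=labels, columns=labels)

    edges = []
    for i, a in enumerate(labels):
        # sort others by (distance, label)
        others = sorted(
            (j for j in range(n) if j != i),
            key=lambda j: (dmat[i, j], labels[j]),
        )
        for j in others[:k]:
            edges.append((a, labels[j], float(dmat[i, j])))
    lm = linkage(squareform(dmat, checks=False), method="ward")
    return ProximityModel(
        pc_scores=pc_scores,
        eigenvalues=eig,
        perm_pvalues=pvals,
        selected=selected,
        distances=distances,
        knn_edges=edges,
        k=k,
        linkage_matrix=lm,
        labels=labels,
        selection_fallback=fallback,
    )


def mutual_knn_pairs(model: ProximityModel) -> set[tuple[str, str]]:
    """Unordered pairs that appear in each other's k-nearest lists."""
    neigh: dict[str, set[str]] = {}
    for a, b, _ in model.knn_edges:
        neigh.setdefault(a, set()).add(b)
    out = set()
    for a, bs in neigh.items():
        for b in bs:
            if a in neigh.get(b, set()):
                out.add(tuple(sorted((a, b))))
    return out


def family_distance_test(
    model: ProximityModel,
    family: dict[str, str] | pd.Series,
    n_shuffle: int = 1000,
    seed: int = 0,
):
    """Do same-family inhibitors sit closer than a label-shuffle null?

    Returns (observed intra-family mean distance, null distribution array,
    empirical p, Kruskal–Wallis p comparing intra vs inter pair distances).
    p = (1 + #{null <= observed}) / (1 + n_shuffle).
    """
    fam = pd.Series(family)
    labels = model.labels
    fam = fam[labels]
    sizes = fam.value_counts()
    if (sizes >= 2).sum() < 2:
        raise ValueError("need >= 2 families with >= 2 members")
    dmat = model.distances.to_numpy()
    n = len(labels)
    iu = np.triu_indices(n, 1)
    fvals = fam.to_numpy()
    same = fvals[iu[0]] == fvals[iu[1]]
    pair_d = dmat[iu]
    if not same.any():
        raise ValueError("no same-family pair")
    observed = float(pair_d[same].mean())

    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffle)
    for i in range(n_shuffle):
        perm = rng.permutation(fvals)
        m = perm[iu[0]] == perm[iu[1]]
        null[i] = pair_d[m].mean()
    p = float((1 + np.sum(null <= observed)) / (1 + n_shuffle))
    if same.all() or (~same).sum() == 0:
        kw_p = 1.0
    else:
        kw_p = float(stats.kruskal(pair_d[same], pair_d[~same]).pvalue)
    return observed, null, p, kw_p


def angle_frequency(
    mfa,
    calls: pd.DataFrame,
    inhibitor: str,
    bin_width: float = 5.0,
) -> tuple[AngleHistogram, AngleHistogram]:
    """Angular frequency profile of an inhibitor's affected CREs.

    The angle of each CRE is atan2(dim2, dim1) of its compromise
    coordinates, mapped to [0, 360) and binned in 5-degree steps (72 bins);
    per-direction counts are min-max scaled to [0, 1].
    """
    comp = mfa.compromise_scores if hasattr(mfa, "compromise_scores") else mfa
    if comp.shape[1] < 2:
        raise ValueError("need at least 2 compromise dimensions")
    theta = np.degrees(
        np.arctan2(comp.iloc[:, 1].to_numpy(), comp.iloc[:, 0].to_numpy())
    ) % 360.0
    theta = pd.Series(theta, index=comp.index)
    edges = np.arange(0.0, 360.0 + bin_width, bin_width)
    col = calls[inhibitor]
    out = []
    for direction in ("up", "down"):
        members = col.index[col == direction]
        counts, _ = np.histogram(theta[members], bins=edges)
        counts = counts.astype(float)
        spread = counts.max() - counts.min()
        if members.empty or spread == 0:
            freq = np.zeros_like(counts)
            empty = True
        else:
            freq = (counts - counts.min()) / spread
            empty = False
        out.append(
            AngleHistogram(
                inhibitor=inhibitor,
                direction=direction,
                bin_edges=edges,
                counts=counts,
                frequency=freq,
                empty=empty,
            )
        )
    return out[0], out[1]


def ses_jaccard(
    set_a,
    set_b,
    universe,
    n_perm: int = 1000,
    seed: int = 0,
    pair: tuple[str, str, str] = ("A", "B", ""),
) -> OverlapStat:
    """Jaccard overlap of two CRE sets, standardized by a resampling null.

    The null redraws both sets (same sizes, without replacement, uniformly
    from the universe) ``n_perm`` times; SES = (J - mean) / sd of the null.
    """
    universe = list(universe)
    uset = set(universe)
    a, b = set(set_a), set(set_b)
    if not a <= uset or not b <= uset:
        raise ValueError("sets must be subsets of the universe")
    union = a | b
    if not union:
        raise ValueError("empty union; Jaccard undefined")
    j = len(a & b) / len(union)

    rng = np.random.default_rng(seed)
    arr = np.array(universe)
    null = np.empty(n_perm)
    for i in range(n_perm):
        ra = set(rng.choice(arr, size=len(a), replace=False))
        rb = set(rng.choice(arr, size=len(b), replace=False))
        null[i] = len(ra & rb) / len(ra | rb)
    mu, sd = float(null.mean()), float(null.std())
    degenerate = sd == 0
    ses = 0.0 if degenerate else (j - mu) / sd
    return OverlapStat(
        pair=pair,
        jaccard=float(j),
        null_mean=mu,
        null_sd=sd,
        ses=float(ses),
        degenerate=degenerate,
    )


def readout_compare(dist_a: pd.Series, dist_b: pd.Series):
    """Compare two pairwise-distance readouts over the same pairs.

    Returns (Spearman rho, per-quintile DataFrame): pairs are sorted into
    quintiles by ``dist_a`` (ties broken by pair id) and ``dist_b`` is
    summarized within each quintile.
    """
    if len(dist_a) != len(dist_b) or not dist_a.index.sort_values().equals(
        dist_b.index.sort_values()
    ):
        raise ValueError("distance tables must cover the same pairs")
    dist_b = dist_b[dist_a.index]
    rho = float(stats.spearmanr(dist_a.to_numpy(), dist_b.to_numpy()).statistic)
    order = sorted(range(len(dist_a)), key=lambda i: (dist_a.iloc[i], str(dist_a.index[i])))
    chunks = np.array_split(np.array(order), 5)
    rows = []
    for q, idx in enumerate(chunks, start=1):
        vals = dist_b.iloc[idx]
        rows.append(
            {
                "quintile": q,
                "n": len(idx),
                "median": float(vals.median()),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=0)),
            }
        )
    return rho, pd.DataFrame(rows).set_index("quintile")


def pairwise_distance_series(distances: pd.DataFrame) -> pd.Series:
    """Condensed upper-triangle distances keyed by sorted (a, b) pair ids."""
    labels = list(distances.index)
    out = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            out[(a, b)] = float(distances.loc[a, b])
    s = pd.Series(out)
    s.index = pd.MultiIndex.from_tuples(s.index, names=["a", "b"])
    return s
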