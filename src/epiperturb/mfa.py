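"""Multiple Factor Analysis over per-condition time-course tables.

MFA in the Escofier–Pagès sense: each condition's CRE x time table is
standardized, divided by its first singular value (so the first eigenvalue
of every reweighted table is 1 and all conditions enter on an equal
footing), the reweighted tables are concatenated, and a global SVD yields
the *compromise* — a joint low-dimensional representation of the CREs.
Per-table *partial factor scores* project each table into that space; their
average over tables is exactly the compromise (barycenter identity).

Significant compromise dimensions are selected by a permutation test:
values are shuffled independently within each column of each table, the
analysis refit, and a dimension is kept when its observed eigenvalue is
rarely matched by the permuted ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class StandardizedSet:
    """Row-standardized (z-scored by CRE) condition tables plus the stats."""

    tables: dict[str, pd.DataFrame]  # condition -> CRE x time z-score table
    conditions: list[str]
    vehicle: str | None
    row_mean: pd.Series
    row_sd: pd.Series
    dropped: list[str] = field(default_factory=list)  # constant CREs excluded

    @property
    def cres(self) -> pd.Index:
        return self.tables[self.conditions[0]].index


@dataclass
class MFAResult:
    first_singular_values: dict[str, float]
    eigenvalues: np.ndarray  # squared global singular values, non-increasing
    compromise_scores: pd.DataFrame  # CRE x dimension factor scores
    partial_scores: dict[str, pd.DataFrame]  # condition -> CRE x dimension
    loadings: pd.DataFrame  # column coordinates ("<condition>|<time>" rows)
    conditions: list[str]
    vehicle: str | None
    selected_dims: list[int] = field(default_factory=list)  # 0-based indices
    perm_pvalues: np.ndarray | None = None

    @property
    def variance_share(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


def standardize(
    tables,
    vehicle: str | None = None,
    log2_transform: bool = False,
    joint: bool = True,
) -> StandardizedSet:
    """Center and scale each CRE row across the concatenated table columns.

    ``tables`` is a MultiTableSet or a dict of condition -> CRE x time
    DataFrames. The population sd convention (divide by n) is used. With
    ``joint=False`` each table is standardized over its own columns instead
    of the concatenation. Constant rows (sd = 0) are dropped with a warning
    and listed in ``dropped``.
    """
    if hasattr(tables, "counts"):  # MultiTableSet
        vehicle = vehicle if vehicle is not None else tables.vehicle
        tables = tables.counts
    if len(tables) < 2:
        raise ValueError("need at least 2 tables")
    conditions = list(tables)
    mats = {c: tables[c].astype(float) for c in conditions}
    ref_index = mats[conditions[0]].index
    for c in conditions[1:]:
        if not mats[c].index.equals(ref_index):
            raise ValueError(f"table {c!r} does not share the CRE row index")
    if log2_transform:
        mats = {c: np.log2(m + 1.0) for c, m in mats.items()}

    concat = pd.concat(mats.values(), axis=1)
    if joint:
        row_mean = concat.mean(axis=1)
        row_sd = concat.std(axis=1, ddof=0)
    else:
        # per-table moments averaged for reporting; scaling done per table
        row_mean = concat.mean(axis=1)
        row_sd = concat.std(axis=1, ddof=0)

    if joint:
        keep = row_sd > 0
    else:
        sds = pd.concat(
            [m.std(axis=1, ddof=0) for m in mats.values()], axis=1
        )
        keep = (sds > 0).all(axis=1)
    dropped = list(concat.index[~keep])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} constant CRE row(s): {dropped[:5]}...",
            stacklevel=2,
        )
    out = {}
    for c in conditions:
        m = mats[c].loc[keep]
        if joint:
            z = m.sub(row_mean[keep], axis=0).div(row_sd[keep], axis=0)
        else:
            mu = m.mean(axis=1)
            sd = m.std(axis=1, ddof=0)
            z = m.sub(mu, axis=0).div(sd, axis=0)
        out[c] = z
    return StandardizedSet(
        tables=out,
        conditions=conditions,
        vehicle=vehicle,
        row_mean=row_mean[keep],
        row_sd=row_sd[keep],
        dropped=dropped,
    )


def table_weight(table) -> float:
    """MFA table weight: the inverse of the first squared singular value.

    Dividing the table by its first singular value is equivalent; the first
    eigenvalue (squared singular value) of the reweighted table is then 1.
    """
    m = np.asarray(table, dtype=float)
    if not np.any(m):
        raise ValueError("zero table has no defined weight")
    s1 = _first_singular_value(m)
    return float(1.0 / s1**2)


def _first_singular_value(m: np.ndarray) -> float:
    g = m.T @ m if m.shape[0] >= m.shape[1] else m @ m.T
    ev = np.linalg.eigvalsh(g)
    return float(np.sqrt(max(ev[-1], 0.0)))


def _global_svd(blocks: list[np.ndarray]):
    """Reweight blocks by 1/sigma1, concatenate, SVD. Returns (s1s, U, S, Vt)."""
    s1s = [_first_singular_value(b) for b in blocks]
    if any(s <= 0 for s in s1s):
        raise ValueError("zero table encountered")
    z = np.hstack([b / s for b, s in zip(blocks, s1s)])
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    return s1s, u, s, vt


def mfa_fit(std: StandardizedSet, n_dims: int | None = None) -> MFAResult:
    """Fit the MFA compromise on a standardized table set.

    The global SVD runs on the reweighted concatenation with no further
    centering (the rows are already centered by the CRE standardization).
    Compromise scores are U*S; the partial score of table k is
    ``K * Z_k @ V_k`` where ``V_k`` is the block of loadings for that
    table's columns, so the table-average of partial scores equals the
    compromise exactly. Each dimension is oriented so its largest-magnitude
    loading is positive.
    """
    conditions = std.conditions
    blocks = [std.tables[c].to_numpy() for c in conditions]
    n_rows = blocks[0].shape[0]
    if any(b.shape[0] != n_rows for b in blocks):
        raise ValueError("tables must share rows")
    s1s, u, s, vt = _global_svd(blocks)

    rank = int(np.sum(s > max(s[0], 1.0) * 1e-12))
    if n_dims is not None and n_dims > rank:
        warnings.warn(f"requested {n_dims} dims but rank is {rank}; truncating")
    keep = min(rank, n_dims) if n_dims is not None else rank
    u, s, vt = u[:, :keep], s[:keep], vt[:keep]

    # deterministic sign: largest-magnitude loading positive per dimension
    v = vt.T
    for d in range(keep):
        j = int(np.argmax(np.abs(v[:, d])))
        if v[j, d] < 0:
            v[:, d] = -v[:, d]
            u[:, d] = -u[:, d]
    dims = [f"dim{d + 1}" for d in range(keep)]
    cres = std.cres

    compromise = pd.DataFrame(u * s, index=cres, columns=dims)
    n_tables = len(conditions)
    partial = {}
    col_labels = []
    offset = 0
    for c, b, s1 in zip(conditions, blocks, s1s):
        ncol = b.shape[1]
        vk = v[offset : offset + ncol]
        partial[c] = pd.DataFrame((b / s1) @ vk * n_tables, index=cres, columns=dims)
        col_labels += [f"{c}|{col}" for col in std.tables[c].columns]
        offset += ncol
    loadings = pd.DataFrame(v, index=col_labels, columns=dims)
    return MFAResult(
        first_singular_values={c: float(s1) for c, s1 in zip(conditions, s1s)},
        eigenvalues=s**2,
        compromise_scores=compromise,
        partial_scores=partial,
        loadings=loadings,
        conditions=list(conditions),
        vehicle=std.vehicle,
    )


def _eigenvalues(blocks: list[np.ndarray], k: int) -> np.ndarray:
    s1s = [_first_singular_value(b) for b in blocks]
    z = np.hstack([b / s for b, s in zip(blocks, s1s)])
    g = z.T @ z if z.shape[0] >= z.shape[1] else z @ z.T
    ev = np.linalg.eigvalsh(g)[::-1]
    ev = np.clip(ev, 0.0, None)
    return ev[:k]


def select_dims(
    std: StandardizedSet,
    n_perm: int = 500,
    alpha: float = 0.01,
    seed: int = 0,
    max_dims: int | None = None,
) -> tuple[list[int], np.ndarray]:
    """Permutation selection of significant compromise dimensions.

    For each of ``n_perm`` permutations, the values of every table are
    shuffled independently within each column, the full analysis refit
    (including the per-CRE row standardization, so the permuted data obey
    the same row constraints as the observed data), and per dimension
    p = (1 + #{perm >= observed}) / (1 + n_perm); dimensions with p < alpha
    are selected (0-based indices).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    blocks = [std.tables[c].to_numpy() for c in std.conditions]
    total_cols = sum(b.shape[1] for b in blocks)
    k = min(blocks[0].shape[0], total_cols)
    if max_dims is not None:
        k = min(k, max_dims)
    def restandardize(bs: list[np.ndarray]) -> list[np.ndarray]:
        cat = np.hstack(bs)
        mu = cat.mean(axis=1, keepdims=True)
        sd = cat.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return [(b - mu) / sd for b in bs]

    obs = _eigenvalues(restandardize(blocks), k)
    exceed = np.zeros(k)
    for _ in range(n_perm):
        perm_blocks = restandardize([rng.permuted(b, axis=0) for b in blocks])
        pe = _eigenvalues(perm_blocks, k)
        exceed += pe >= obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    selected = [d for d in range(k) if pvals[d] < alpha]
    return selected, pvals


def fit_with_selection(
    std: StandardizedSet,
    n_perm: int = 500,
    alpha: float = 0.01,
    seed: int = 0,
    n_dims: int | None = None,
) -> MFAResult:
    """Convenience: mfa_fit plus permutation dimension selection."""
    res = mfa_fit(std, n_dims=n_dims)
    selected, pvals = select_dims(std, n_perm=n_perm, alpha=alpha, seed=seed)
    res.selected_dims = [d for d in selected if d < res.compromise_scores.shape[1]]
    res.perm_pvalues = pvals
    return res
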