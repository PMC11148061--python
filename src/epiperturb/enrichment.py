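"""Permutation association between affected CRE sets and TF peak sets.

A CRE counts as bound by a TF when any peak shares at least one base with
it (0-based half-open intervals). The association null resamples CRE sets
of the same size uniformly from the CRE universe; the observed overlap is
standardized against that null and assigned a two-sided empirical p-value,
Benjamini–Hochberg corrected across all tests of a run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from statsmodels.stats.multitest import multipletests


@dataclass
class AssociationResult:
    tf: str
    inhibitor: str
    direction: str
    n_affected: int
    observed_overlap: int
    null_mean: float
    null_sd: float
    z: float
    p_empirical: float
    p_adjusted: float | None = None
    degenerate: bool = False


def _validate_intervals(df: pd.DataFrame, what: str) -> pd.DataFrame:
    bad = df.index[df["start"].to_numpy() >= df["end"].to_numpy()]
    if len(bad):
        raise ValueError(f"malformed {what} interval(s) with start >= end: rows {list(bad)[:5]}")
    return df


def interval_overlap(
    cres: pd.DataFrame, peaks: pd.DataFrame
) -> tuple[pd.Series, int]:
    """Per-CRE bound/unbound indicator plus the total overlapped count.

    Both inputs are DataFrames with ``chrom``, ``start``, ``end`` (and for
    CREs a ``name``) in 0-based half-open coordinates. A 1-bp shared base
    counts; a peak starting exactly at a CRE's end does not.
    """
    cres = _validate_intervals(cres, "CRE")
    peaks = _validate_intervals(peaks, "peak")
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in peaks.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(grp["start"].astype(int), grp["end"].astype(int))
        )
    names = cres["name"] if "name" in cres else pd.Index(range(len(cres))).astype(str)
    hits = []
    for chrom, start, end in zip(cres["chrom"], cres["start"], cres["end"]):
        tree = trees.get(chrom)
        hits.append(bool(tree.overlap(int(start), int(end))) if tree else False)
    indicator = pd.Series(hits, index=pd.Index(names, name="cre"), name="bound")
    return indicator, int(indicator.sum())


def permutation_association(
    affected,
    universe,
    peak_indicator: pd.Series,
    n_perm: int = 5000,
    seed: int = 0,
    tf: str = "",
    inhibitor: str = "",
    direction: str = "",
) -> AssociationResult:
    """Standardized overlap of an affected CRE set with a TF's bound CREs.

    The null draws ``n_perm`` same-size CRE sets uniformly (without
    replacement) from the universe; z = (obs - mean) / sd and the two-sided
    empirical p uses +1 smoothing. A zero-sd null is flagged degenerate
    with z = 0 and p = 1.
    """
    universe = list(universe)
    affected = set(affected)
    if not affected <= set(universe):
        raise ValueError("affected set must be a subset of the universe")
    ind = peak_indicator[universe].to_numpy(dtype=bool)
    names = pd.Index(universe)
    obs = int(ind[names.isin(affected)].sum())
    m = len(affected)
    rng = np.random.default_rng(seed)
    n = len(universe)
    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n, size=m, replace=False)
        null[i] = ind[idx].sum()
    mu, sd = float(null.mean()), float(null.std())
    if sd == 0:
        return AssociationResult(
            tf, inhibitor, direction, m, obs, mu, sd, 0.0, 1.0, degenerate=True
        )
    z = (obs - mu) / sd
    p_ge = (1 + np.sum(null >= obs)) / (1 + n_perm)
    p_le = (1 + np.sum(null <= obs)) / (1 + n_perm)
    p = float(min(1.0, 2.0 * min(p_ge, p_le)))
    return AssociationResult(tf, inhibitor, direction, m, obs, mu, sd, float(z), p)


def associate_all(
    affected_sets: dict[tuple[str, str], set],
    tf_peaks: dict[str, pd.DataFrame],
    cre_intervals: pd.DataFrame,
    n_perm: int = 5000,
    seed: int = 0,
    min_set_size: int = 1,
) -> pd.DataFrame:
    """Run every TF x (inhibitor, direction) association with BH correction.

    ``affected_sets`` maps (inhibitor, direction) to CRE id sets (see
    ``perturbation.affected_sets``). The BH family is all tests executed in
    this invocation.
    """
    universe = list(cre_intervals["name"])
    indicators = {
        tf: interval_overlap(cre_intervals, peaks)[0] if len(peaks) else pd.Series(
            False, index=pd.Index(universe, name="cre")
        )
        for tf, peaks in tf_peaks.items()
    }
    rows: list[AssociationResult] = []
    rng = np.random.default_rng(seed)
    for tf in sorted(indicators):
        for (inhibitor, direction), members in sorted(affected_sets.items()):
            if len(members) < min_set_size:
                continue
            res = permutation_association(
                members,
                universe,
                indicators[tf],
                n_perm=n_perm,
                seed=int(rng.integers(0, 2**31 - 1)),
                tf=tf,
                inhibitor=inhibitor,
                direction=direction,
            )
            rows.append(res)
    if not rows:
        return pd.DataFrame(
            columns=[
                "tf", "inhibitor", "direction", "n_affected", "observed_overlap",
                "null_mean", "null_sd", "z", "p_empirical", "p_adjusted", "degenerate",
            ]
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["p_adjusted"] = multipletests(df["p_empirical"], method="fdr_bh")[1]
    return df
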