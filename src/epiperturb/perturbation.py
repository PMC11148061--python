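"""Signed perturbation-likelihood scores from MFA partial factor scores.

For each CRE, the Euclidean distance (over the selected compromise
dimensions) between an inhibitor's partial factor score and the vehicle's
measures how far that condition displaces the CRE from control. The natural
log of all distances is pooled per stimulus, standardized by a fitted
normal, and converted to an upper-tail probability (CCDF). The score is
-log10(CCDF) signed by DeltaZ — the difference between the summed
per-time-point z-scores of the inhibitor and the vehicle — so negative
scores mark loss of induced acetylation and positive scores gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mfa import MFAResult, StandardizedSet

DIRECTIONS = ("down", "none", "up")


@dataclass
class PerturbationScoreSet:
    distance: pd.DataFrame  # CRE x inhibitor Euclidean distances
    log_null: tuple[float, float]  # (mean, sd) of the fitted normal on ln d
    ccdf: pd.DataFrame  # upper-tail probabilities in (0, 1]
    delta_z: pd.DataFrame
    score: pd.DataFrame  # signed -log10(ccdf)
    calls: pd.DataFrame  # {"down", "none", "up"}
    threshold: float


def cre_distances(mfa: MFAResult, vehicle: str | None = None) -> pd.DataFrame:
    """Per-CRE Euclidean distance of each inhibitor from the vehicle.

    Computed between partial factor scores restricted to the selected
    dimensions (``mfa.selected_dims`` must be non-empty).
    """
    vehicle = vehicle if vehicle is not None else mfa.vehicle
    if vehicle not in mfa.partial_scores:
        raise ValueError(f"vehicle {vehicle!r} not among conditions")
    if not mfa.selected_dims:
        raise ValueError("no selected dimensions; run select_dims first")
    dims = [mfa.compromise_scores.columns[d] for d in mfa.selected_dims]
    ref = mfa.partial_scores[vehicle][dims].to_numpy()
    out = {}
    for cond in mfa.conditions:
        if cond == vehicle:
            continue
        diff = mfa.partial_scores[cond][dims].to_numpy() - ref
        out[cond] = np.sqrt((diff**2).sum(axis=1))
    return pd.DataFrame(out, index=mfa.compromise_scores.index)


def delta_z(std: StandardizedSet, vehicle: str | None = None) -> pd.DataFrame:
    """Sum of per-time z-scores, inhibitor minus vehicle, per CRE.

    The sums run over all time points including t = 0.
    """
    vehicle = vehicle if vehicle is not None else std.vehicle
    if vehicle not in std.tables:
        raise ValueError(f"vehicle {vehicle!r} not among conditions")
    ref = std.tables[vehicle].sum(axis=1)
    out = {
        cond: std.tables[cond].sum(axis=1) - ref
        for cond in std.conditions
        if cond != vehicle
    }
    return pd.DataFrame(out)


def score_perturbations(
    dist: pd.DataFrame,
    std: StandardizedSet,
    vehicle: str | None = None,
    clamp: float = 300.0,
    threshold: float = 1.0,
) -> PerturbationScoreSet:
    """Convert distances to signed perturbation-likelihood scores.

    The normal null is fitted by maximum likelihood to the pooled
    ln-distances of every inhibitor x CRE cell (a pooled fit keeps
    inhibitors with larger effect budgets producing more calls). Zero
    distances are replaced by 1e-3 times the smallest positive distance
    before taking logs, and the CCDF is floored at ``10**-clamp`` so scores
    stay finite.
    """
    d = dist.to_numpy(dtype=float).copy()
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    pos = d[d > 0]
    if pos.size == 0:
        raise ValueError("all distances are zero; degenerate input")
    d[d == 0] = pos.min() * 1e-3
    ln = np.log(d)
    mu, sd = float(ln.mean()), float(ln.std())
    if sd == 0:
        raise ValueError("zero spread of ln-distances; degenerate input")
    z = (ln - mu) / sd
    ccdf = np.clip(stats.norm.sf(z), 10.0 ** (-clamp), 1.0)
    ccdf_df = pd.DataFrame(ccdf, index=dist.index, columns=dist.columns)

    dz = delta_z(std, vehicle=vehicle)
    dz = dz.loc[dist.index, dist.columns]
    sign = np.sign(dz.to_numpy())
    score = -np.log10(ccdf) * sign  # score is 0 wherever delta_z is 0
    score_df = pd.DataFrame(score, index=dist.index, columns=dist.columns)
    calls, _ = call_events(score_df, threshold=threshold)
    return PerturbationScoreSet(
        distance=dist,
        log_null=(mu, sd),
        ccdf=ccdf_df,
        delta_z=dz,
        score=score_df,
        calls=calls,
        threshold=threshold,
    )


def call_events(
    score: pd.DataFrame, threshold: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Discretize scores into {down, none, up} and count events per inhibitor."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    arr = score.to_numpy()
    calls = np.where(arr > threshold, "up", np.where(arr < -threshold, "down", "none"))
    calls_df = pd.DataFrame(calls, index=score.index, columns=score.columns)
    summary = pd.DataFrame(
        {
            "up": (calls_df == "up").sum(axis=0),
            "down": (calls_df == "down").sum(axis=0),
        }
    )
    summary.index.name = "inhibitor"
    return calls_df, summary


def affected_sets(calls: pd.DataFrame) -> dict[tuple[str, str], set[str]]:
    """CRE id sets per (inhibitor, direction) for overlap/enrichment use."""
    out = {}
    for inhibitor in calls.columns:
        col = calls[inhibitor]
        for direction in ("down", "up"):
            out[(inhibitor, direction)] = set(col.index[col == direction])
    return out
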