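"""Between-sample normalization by invariant-feature selection.

Per-feature log2 counts are compared against a pseudo-reference (the
per-feature median of log2(count + pseudocount) across samples). The
frequency distribution of each sample's log-differences is modelled with a
skew-normal; features whose difference falls within one standard deviation
of the fitted mean are declared invariant for that sample, and the sample's
scale factor is the one that brings the median ratio over its invariant set
back to the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class InvariantFit:
    reference: pd.Series  # per-feature pseudo-reference log2 counts
    diffs: pd.DataFrame  # feature x sample log2 differences from reference
    skew_params: dict[str, tuple[float, float, float]]  # sample -> (loc, scale, shape)
    fitted_moments: dict[str, tuple[float, float]]  # sample -> (mean, sd) of the fit
    invariant_features: dict[str, pd.Index]
    scale_factors: pd.Series  # per-sample positive multiplier
    pseudocount: float = 1.0
    sigma_window: float = 1.0
    fallback_samples: list[str] = field(default_factory=list)


def _skewnorm_moments(shape: float, loc: float, scale: float) -> tuple[float, float]:
    delta = shape / np.sqrt(1.0 + shape**2)
    mean = loc + scale * delta * np.sqrt(2.0 / np.pi)
    sd = scale * np.sqrt(max(1.0 - 2.0 * delta**2 / np.pi, 1e-12))
    return float(mean), float(sd)


def _fit_skewnorm(d: np.ndarray) -> tuple[tuple[float, float, float], tuple[float, float], bool]:
    """MLE skew-normal fit with method-of-moments start.

    Returns ((loc, scale, shape), (mean, sd), fallback_flag). Falls back to a
    plain normal (shape = 0) on non-convergence, and to (median, 0 spread
    guard) on degenerate input.
    """
    m, s = float(np.mean(d)), float(np.std(d))
    if s < 1e-9:
        med = float(np.median(d))
        return (med, 0.0, 0.0), (med, 0.0), True
    # method-of-moments start from the sample skewness
    g1 = float(np.clip(stats.skew(d), -0.95, 0.95))
    c = (2.0 * abs(g1) / (4.0 - np.pi)) ** (1.0 / 3.0)
    delta = np.sign(g1) * np.clip(c / np.sqrt(1.0 + c**2), -0.99, 0.99)
    shape0 = delta / np.sqrt(max(1.0 - delta**2, 1e-9))
    scale0 = s / np.sqrt(max(1.0 - 2.0 * delta**2 / np.pi, 1e-9))
    loc0 = m - scale0 * delta * np.sqrt(2.0 / np.pi)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, loc, scale = stats.skewnorm.fit(d, shape0, loc=loc0, scale=scale0)
        if not np.all(np.isfinite([a, loc, scale])) or scale <= 0:
            raise ValueError("degenerate skew-normal fit")
        mean, sd = _skewnorm_moments(a, loc, scale)
        return (float(loc), float(scale), float(a)), (mean, sd), False
    except Exception:
        return (m, s, 0.0), (m, s), False


def fit_invariant_model(
    counts: pd.DataFrame,
    pseudocount: float = 1.0,
    sigma_window: float = 1.0,
) -> InvariantFit:
    """Fit the invariant-feature model on a feature x sample count matrix.

    Features with zero counts in every sample are excluded before fitting.
    Requires at least two samples.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    counts = counts.loc[(counts > 0).any(axis=1)]
    log = np.log2(counts + pseudocount)
    reference = log.median(axis=1)
    diffs = log.sub(reference, axis=0)

    skew_params, fitted_moments, invariant, factors = {}, {}, {}, {}
    fallback = []
    for sample in counts.columns:
        d = diffs[sample].to_numpy()
        params, (mean, sd), fell_back = _fit_skewnorm(d)
        skew_params[sample] = params
        fitted_moments[sample] = (mean, sd)
        if fell_back:
            fallback.append(sample)
            inv = diffs.index  # constant diffs: every feature is invariant
        else:
            mask = np.abs(d - mean) <= sigma_window * sd
            inv = diffs.index[mask]
        if len(inv) == 0:
            inv = diffs.index  # degenerate window; keep the sample usable
            fallback.append(sample)
        invariant[sample] = inv
        m = float(np.median(diffs.loc[inv, sample]))
        factors[sample] = float(2.0 ** (-m))
    return InvariantFit(
        reference=reference,
        diffs=diffs,
        skew_params=skew_params,
        fitted_moments=fitted_moments,
        invariant_features=invariant,
        scale_factors=pd.Series(factors, name="scale_factor"),
        pseudocount=pseudocount,
        sigma_window=sigma_window,
        fallback_samples=fallback,
    )


def apply_normalization(counts: pd.DataFrame, fit: InvariantFit) -> pd.DataFrame:
    """Scale each sample by its fitted factor (median invariant ratio -> 1)."""
    missing = [s for s in counts.columns if s not in fit.scale_factors.index]
    if missing:
        raise ValueError(f"no scale factor for samples: {missing}")
    for sample in counts.columns:
        if len(fit.invariant_features[sample]) == 0:
            raise ValueError(
                f"empty invariant set for {sample!r}; widen sigma_window"
            )
    return counts * fit.scale_factors[counts.columns]


def normalize_tables(mts, pseudocount: float = 1.0, sigma_window: float = 1.0):
    """Normalize every sample of a MultiTableSet; returns (new set, fit).

    All ``<condition>_<time>h`` samples are pooled into one feature x sample
    matrix so conditions are brought onto a common scale.
    """
    from .synthetic import MultiTableSet

    wide = mts.as_wide()
    fit = fit_invariant_model(wide, pseudocount=pseudocount, sigma_window=sigma_window)
    normed = apply_normalization(wide.loc[fit.reference.index], fit)
    counts = {}
    for cond in mts.conditions:
        cols = [f"{cond}_{t:g}h" for t in mts.time_points]
        tab = normed[cols].copy()
        tab.columns = list(mts.time_points)
        counts[cond] = tab
    out = MultiTableSet(
        stimulus=mts.stimulus,
        conditions=list(mts.conditions),
        vehicle=mts.vehicle,
        time_points=mts.time_points,
        counts=counts,
        cre_intervals=mts.cre_intervals,
        depth_factors=dict(mts.depth_factors),
    )
    return out, fit
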