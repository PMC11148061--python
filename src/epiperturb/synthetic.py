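"""Synthetic H3K27ac perturbation fixtures with known ground truth.

The generator emulates the statistical structure of a stimulus time-course
inhibitor screen: cis-regulatory elements (CREs) fall into a small number of
kinetic clusters whose acetylation is induced with distinct peak times;
latent "kinase -> TF program -> CRE subset" wiring links each inhibitor,
through its intended target and off-targets, to the subsets of CREs it
perturbs; counts are negative-binomial around the (possibly perturbed)
expected signal, with per-sample sequencing-depth multipliers.

Everything is deterministic under a fixed seed, and the wiring plus the
per-(CRE, inhibitor) signed effect sizes are returned as machine-readable
truth so downstream recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_TIME_POINTS = (0.0, 0.5, 1.0, 2.0, 4.0)


@dataclass
class KineticTemplate:
    """Expected log-signal of one kinetic cluster across the time grid."""

    cluster_id: str
    profile: np.ndarray  # log-scale expected signal, one value per time point
    peak_time: float
    time_points: tuple = DEFAULT_TIME_POINTS

    def __post_init__(self):
        self.profile = np.asarray(self.profile, dtype=float)
        if len(self.profile) != len(self.time_points):
            raise ValueError("profile length must equal number of time points")
        if self.peak_time != 0:
            peak_idx = int(np.argmax(self.profile))
            if self.time_points[peak_idx] != self.peak_time:
                raise ValueError(
                    f"profile maximum at t={self.time_points[peak_idx]} "
                    f"but peak_time={self.peak_time}"
                )


def default_templates(
    time_points: tuple = DEFAULT_TIME_POINTS,
    baseline: float = 0.0,
    amplitude: float = 2.0,
    width: float = 0.8,
) -> list[KineticTemplate]:
    """Four induced kinetic clusters peaking at 0.5, 1, 2 and 4 h.

    Each profile is a Gaussian bump in log2-time around the cluster's peak,
    of height ``amplitude`` (natural-log units) above ``baseline``; the
    t=0 value is pinned at baseline (pre-stimulation state).
    """
    t = np.asarray(time_points, float)
    templates = []
    for peak in (0.5, 1.0, 2.0, 4.0):
        with np.errstate(divide="ignore"):
            lt = np.log2(np.where(t > 0, t, np.nan))
        bump = amplitude * np.exp(-((lt - np.log2(peak)) ** 2) / (2 * width**2))
        profile = baseline + np.where(t > 0, np.nan_to_num(bump), 0.0)
        templates.append(
            KineticTemplate(
                cluster_id=f"peak{peak:g}h",
                profile=profile,
                peak_time=peak,
                time_points=tuple(t),
            )
        )
    return templates


@dataclass
class LatentWiring:
    """Latent kinase -> TF-program -> CRE wiring plus inhibitor target profiles."""

    kinases: list[str]
    programs: dict[str, str]  # kinase -> program id (program-bearing kinases only)
    program_cres: dict[str, list[str]]  # program -> member CRE ids
    inhibitor_targets: dict[str, list[tuple[str, float]]]  # inhibitor -> (kinase, potency)
    family: dict[str, str]  # inhibitor -> target-family label
    cres: list[str] = field(default_factory=list)
    potency_model: str = ""

    @property
    def inhibitors(self) -> list[str]:
        return list(self.inhibitor_targets)

    def to_json(self) -> str:
        payload = {
            "kinases": self.kinases,
            "programs": self.programs,
            "program_cres": self.program_cres,
            "inhibitor_targets": {
                k: [[t, p] for t, p in v] for k, v in self.inhibitor_targets.items()
            },
            "family": self.family,
            "cres": self.cres,
            "potency_model": self.potency_model,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LatentWiring":
        d = json.loads(text)
        d["inhibitor_targets"] = {
            k: [(t, float(p)) for t, p in v] for k, v in d["inhibitor_targets"].items()
        }
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth: signed log-scale effects per (CRE, inhibitor)."""

    effect: pd.DataFrame  # CRE x inhibitor, signed effect on the log-mean
    direction: pd.DataFrame  # CRE x inhibitor in {"down", "none", "up"}
    cluster_of: pd.Series  # CRE -> kinetic cluster id
    up_programs: list[str] = field(default_factory=list)
    tf_peaks: dict[str, pd.DataFrame] = field(default_factory=dict)

    def perturbed_pairs(self) -> pd.DataFrame:
        """Long table of all (cre, inhibitor, effect) with nonzero effect."""
        stacked = self.effect.stack()
        stacked = stacked[stacked != 0]
        out = stacked.rename("effect").reset_index()
        out.columns = ["cre", "inhibitor", "effect"]
        return out


@dataclass
class MultiTableSet:
    """Aligned per-condition CRE x time count tables for one stimulus."""

    stimulus: str
    conditions: list[str]
    vehicle: str
    time_points: tuple
    counts: dict[str, pd.DataFrame]  # condition -> CRE x time-point table
    cre_intervals: pd.DataFrame  # columns chrom, start, end, name
    depth_factors: dict[str, float] = field(default_factory=dict)  # "<cond>_<t>h" -> multiplier

    def __post_init__(self):
        if self.vehicle not in self.conditions:
            raise ValueError(f"vehicle {self.vehicle!r} not among conditions")
        ref_index = self.counts[self.conditions[0]].index
        for cond in self.conditions:
            tab = self.counts[cond]
            if not tab.index.equals(ref_index):
                raise ValueError(f"table {cond!r} has mismatched CRE rows")
            if (np.asarray(tab.values) < 0).any():
                raise ValueError(f"table {cond!r} contains negative counts")

    @property
    def cres(self) -> pd.Index:
        return self.counts[self.conditions[0]].index

    @property
    def inhibitors(self) -> list[str]:
        return [c for c in self.conditions if c != self.vehicle]

    def sample_columns(self) -> list[str]:
        return [
            f"{cond}_{t:g}h" for cond in self.conditions for t in self.time_points
        ]

    def as_wide(self) -> pd.DataFrame:
        """All conditions side by side, columns labelled ``<condition>_<t>h``."""
        blocks = []
        for cond in self.conditions:
            tab = self.counts[cond].copy()
            tab.columns = [f"{cond}_{t:g}h" for t in self.time_points]
            blocks.append(tab)
        wide = pd.concat(blocks, axis=1)
        wide.index.name = "cre_id"
        return wide


def generate_wiring(
    n_cres: int,
    n_inhibitors: int,
    n_kinases: int,
    n_programs: int,
    offtarget_rate: float = 0.15,
    seed: int = 0,
    intended_potency: tuple[float, float] = (0.7, 1.0),
    offtarget_potency: tuple[float, float] = (0.4, 0.8),
    program_coverage: float = 0.4,
) -> LatentWiring:
    """Sample the latent wiring connecting inhibitors to CRE subsets.

    Each of the ``n_programs`` TF programs is driven by a distinct kinase and
    owns a disjoint subset of the CRE universe covering ``program_coverage``
    of it in total (the remainder is stimulus-responsive background wired to
    no program). Inhibitor ``i`` receives intended target kinase number
    ``i mod n_programs`` — so inhibitors sharing an intended target form a
    family — plus ``Binomial(n_kinases - 1, offtarget_rate)`` off-targets.
    Potencies are uniform on the stated ranges, recorded in ``potency_model``.
    """
    if min(n_cres, n_inhibitors, n_kinases, n_programs) < 1:
        raise ValueError("all counts must be >= 1")
    if not 0 <= offtarget_rate <= 1:
        raise ValueError("offtarget_rate must lie in [0, 1]")
    if n_programs > n_kinases:
        raise ValueError("n_programs cannot exceed n_kinases")

    rng = np.random.default_rng(seed)
    cres = [f"CRE{i:05d}" for i in range(n_cres)]
    kinases = [f"K{i:02d}" for i in range(n_kinases)]
    program_kinases = kinases[:n_programs]
    programs = {k: f"P{j}" for j, k in enumerate(program_kinases)}

    shuffled = list(rng.permutation(cres))
    n_wired = int(round(program_coverage * n_cres))
    per_program = n_wired // n_programs
    program_cres = {}
    for j, k in enumerate(program_kinases):
        block = shuffled[j * per_program : (j + 1) * per_program]
        program_cres[programs[k]] = sorted(block)

    inhibitor_targets: dict[str, list[tuple[str, float]]] = {}
    family = {}
    for i in range(n_inhibitors):
        name = f"CKI{i:02d}"
        intended = program_kinases[i % n_programs]
        pot = float(rng.uniform(*intended_potency))
        targets = [(intended, pot)]
        for k in kinases:
            if k == intended:
                continue
            if rng.random() < offtarget_rate:
                targets.append((k, float(rng.uniform(*offtarget_potency))))
        inhibitor_targets[name] = targets
        family[name] = intended
    return LatentWiring(
        kinases=kinases,
        programs=programs,
        program_cres=program_cres,
        inhibitor_targets=inhibitor_targets,
        family=family,
        cres=cres,
        potency_model=(
            f"intended~U{intended_potency}, offtarget~U{offtarget_potency}, "
            f"offtargets~Binomial(n_kinases-1, {offtarget_rate})"
        ),
    )


def _cre_program_map(wiring: LatentWiring) -> dict[str, str]:
    mapping = {}
    for prog, members in wiring.program_cres.items():
        for cre in members:
            mapping[cre] = prog
    return mapping


def generate_counts(
    wiring: LatentWiring,
    templates: list[KineticTemplate] | None = None,
    dispersion: float = 50.0,
    depth: float = 100.0,
    seed: int = 0,
    effect_scale: float = 2.0,
    up_fraction: float = 0.2,
    depth_sigma: float = 0.15,
    sensitivity: tuple[float, float] = (0.5, 1.5),
    vehicle: str = "DMSO",
    stimulus: str = "LPS",
) -> tuple[MultiTableSet, SyntheticTruth]:
    """Draw negative-binomial count tables for vehicle and every inhibitor.

    Vehicle counts are NB with mean ``exp(template profile) * depth`` times a
    per-sample log-normal(0, depth_sigma) depth multiplier. An inhibitor
    shifts the log-mean of every CRE belonging to a program wired to one of
    its inhibited kinases by ``-(sum of potencies) * effect_scale`` at the
    induced time points (t > 0), modulated by a per-CRE responsiveness drawn
    uniformly from ``sensitivity`` (CREs differ in how strongly their
    acetylation depends on the upstream kinase program); a minority
    ``up_fraction`` of programs is up-regulatory (the shift is applied with
    positive sign). The truth table records every nonzero effect.

    ``dispersion`` is the NB size parameter: Var = m + m^2/dispersion, so
    large dispersion approaches Poisson.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    templates = templates if templates is not None else default_templates()
    time_points = templates[0].time_points
    rng = np.random.default_rng(seed)

    cres = wiring.cres
    n_cres = len(cres)
    cluster_idx = rng.integers(0, len(templates), size=n_cres)
    cluster_of = pd.Series(
        [templates[i].cluster_id for i in cluster_idx], index=cres, name="cluster"
    )
    base_log = np.stack([templates[i].profile for i in cluster_idx])  # CRE x time
    if not np.all(np.isfinite(base_log)):
        raise ValueError("non-finite template log-means; check template parameters")

    cre_sens = pd.Series(
        rng.uniform(sensitivity[0], sensitivity[1], size=n_cres), index=cres
    )
    prog_ids = sorted(wiring.program_cres)
    n_up = int(round(up_fraction * len(prog_ids)))
    up_programs = sorted(rng.choice(prog_ids, size=n_up, replace=False)) if n_up else []
    cre_prog = _cre_program_map(wiring)
    cre_pos = {c: i for i, c in enumerate(cres)}
    induced = np.asarray(time_points) > 0  # effect applies to induced time points

    conditions = [vehicle] + list(wiring.inhibitors)
    effect = pd.DataFrame(0.0, index=cres, columns=wiring.inhibitors)
    counts: dict[str, pd.DataFrame] = {}
    depth_factors: dict[str, float] = {}

    for cond in conditions:
        log_mean = base_log.copy()
        if cond != vehicle:
            # sum potency over the inhibitor's kinases that drive each program
            prog_hit: dict[str, float] = {}
            for kinase, pot in wiring.inhibitor_targets[cond]:
                prog = wiring.programs.get(kinase)
                if prog is not None:
                    prog_hit[prog] = prog_hit.get(prog, 0.0) + pot
            for prog, pot_sum in prog_hit.items():
                base_eff = pot_sum * effect_scale
                if prog not in up_programs:
                    base_eff = -base_eff
                for cre in wiring.program_cres[prog]:
                    i = cre_pos[cre]
                    eff = base_eff * cre_sens[cre]
                    log_mean[i, induced] += eff
                    effect.loc[cre, cond] = eff
        if not np.all(np.isfinite(log_mean)):
            raise ValueError("non-finite log-means; check templates/effect parameters")
        dmul = np.exp(rng.normal(0.0, depth_sigma, size=len(time_points)))
        for j, t in enumerate(time_points):
            depth_factors[f"{cond}_{t:g}h"] = float(dmul[j])
        mean = np.exp(log_mean) * depth * dmul[None, :]
        p = dispersion / (dispersion + mean)
        tab = rng.negative_binomial(dispersion, p)
        counts[cond] = pd.DataFrame(
            tab, index=pd.Index(cres, name="cre_id"), columns=list(time_points)
        )

    cre_intervals = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": [i * 2000 for i in range(n_cres)],
            "end": [i * 2000 + 1000 for i in range(n_cres)],
            "name": cres,
        }
    )
    direction = effect.map(lambda e: "down" if e < 0 else ("up" if e > 0 else "none"))
    mts = MultiTableSet(
        stimulus=stimulus,
        conditions=conditions,
        vehicle=vehicle,
        time_points=tuple(time_points),
        counts=counts,
        cre_intervals=cre_intervals,
        depth_factors=depth_factors,
    )
    truth = SyntheticTruth(
        effect=effect,
        direction=direction,
        cluster_of=cluster_of,
        up_programs=list(up_programs),
    )
    return mts, truth


def generate_tf_peaks(
    wiring: LatentWiring,
    cre_intervals: pd.DataFrame,
    fpr: float = 0.05,
    fnr: float = 0.1,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """TF peak interval sets aligned to the latent programs.

    The TF of program ``P`` carries a peak inside each member CRE with
    probability ``1 - fnr`` and inside each non-member CRE with probability
    ``fpr``. Peaks are placed in the central half of the CRE interval so
    every peak lies within its CRE.
    """
    if not (0 <= fpr < 1 and 0 <= fnr < 1):
        raise ValueError("fpr and fnr must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    iv = cre_intervals.set_index("name")
    peaks: dict[str, pd.DataFrame] = {}
    for prog in sorted(wiring.program_cres):
        tf = f"TF_{prog}"
        members = set(wiring.program_cres[prog])
        rows = []
        for cre in iv.index:
            p_hit = (1.0 - fnr) if cre in members else fpr
            if rng.random() < p_hit:
                start, end = int(iv.at[cre, "start"]), int(iv.at[cre, "end"])
                span = end - start
                rows.append(
                    {
                        "chrom": iv.at[cre, "chrom"],
                        "start": start + span // 4,
                        "end": end - span // 4,
                        "name": f"{tf}@{cre}",
                    }
                )
        peaks[tf] = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return peaks
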