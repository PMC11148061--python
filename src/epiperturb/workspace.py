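"""I/O, configuration and pipeline orchestration.

File conventions: count tables are TSV with a ``cre_id`` column followed by
``<condition>_<time>h`` sample columns; genomic intervals are BED (0-based
half-open, strand ignored); wiring/truth/manifests are JSON. The pipeline
chains simulate -> normalize -> mfa -> score -> compare -> enrich ->
classify, caching each stage's outputs on disk and recording seeds and
output checksums in a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier as classifier_mod
from . import comparative as comparative_mod
from . import enrichment as enrichment_mod
from . import mfa as mfa_mod
from . import normalization as normalization_mod
from . import perturbation as perturbation_mod
from . import synthetic as synthetic_mod
from .synthetic import MultiTableSet

logger = logging.getLogger("epiperturb")
if not logger.handlers:
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    logger.addHandler(h)
logger.setLevel(logging.INFO)

_SAMPLE_RE = re.compile(r"^(?P<cond>.+)_(?P<time>[0-9]*\.?[0-9]+)h$")

PIPELINE_STAGES = (
    "simulate",
    "normalize",
    "mfa",
    "score",
    "compare",
    "enrich",
    "classify",
)


@dataclass
class RunConfig:
    """All knobs of a pipeline run; every seed is recorded in the manifest."""

    out_dir: str = "epiperturb_run"
    stimulus: str = "LPS"
    vehicle: str = "DMSO"
    counts_path: str | None = None  # load instead of simulating when set
    n_cres: int = 2000
    n_inhibitors: int = 12
    n_kinases: int = 8
    n_programs: int = 4
    offtarget_rate: float = 0.15
    effect_scale: float = 1.0
    dispersion: float = 10.0
    depth: float = 20.0
    seed: int = 0
    sigma_window: float = 1.0
    log2_transform: bool = True
    n_perm_mfa: int = 200
    n_perm_proximity: int = 200
    n_perm_enrich: int = 1000
    n_perm_overlap: int = 1000
    alpha: float = 0.01
    threshold: float = 1.0
    k_neighbors: int = 3
    min_var: float = 0.01
    classify_inhibitor: str | None = None  # default: first inhibitor
    tune: bool = False

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        text = Path(path).read_text()
        if path.endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def parse_sample_column(name: str) -> tuple[str, float]:
    m = _SAMPLE_RE.match(name)
    if not m:
        raise ValueError(f"cannot parse sample column {name!r} as <condition>_<time>h")
    return m.group("cond"), float(m.group("time"))


def read_counts(path: str, vehicle: str, stimulus: str = "LPS") -> MultiTableSet:
    """Read a wide counts TSV (cre_id + ``<condition>_<time>h`` columns)."""
    df = pd.read_csv(path, sep="\t")
    if "cre_id" not in df.columns:
        raise ValueError("counts TSV must have a 'cre_id' first column")
    dup = df["cre_id"][df["cre_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate CRE id(s): {sorted(set(dup))[:5]}")
    if df.isna().any().any():
        raise ValueError("ragged or missing values in counts TSV")
    df = df.set_index("cre_id")
    parsed = [parse_sample_column(c) for c in df.columns]
    conditions = list(dict.fromkeys(c for c, _ in parsed))
    times = sorted({t for _, t in parsed})
    if vehicle not in conditions:
        raise ValueError(f"vehicle {vehicle!r} not found among conditions {conditions}")
    counts = {}
    for cond in conditions:
        cols = [f"{cond}_{t:g}h" for t in times]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"condition {cond!r} missing sample column(s) {missing}")
        tab = df[cols].copy()
        tab.columns = times
        counts[cond] = tab
    n_cres = len(df)
    cre_intervals = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": [i * 2000 for i in range(n_cres)],
            "end": [i * 2000 + 1000 for i in range(n_cres)],
            "name": df.index,
        }
    )
    return MultiTableSet(
        stimulus=stimulus,
        conditions=conditions,
        vehicle=vehicle,
        time_points=tuple(times),
        counts=counts,
        cre_intervals=cre_intervals,
    )


def write_counts(mts: MultiTableSet, path: str) -> None:
    wide = mts.as_wide()
    wide.to_csv(path, sep="\t")


def read_bed(path: str) -> pd.DataFrame:
    """Read BED3+ into a sorted DataFrame (chrom, start, end, name)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {ln}: fewer than 3 BED fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"line {ln}: start >= end ({start} >= {end})")
            name = parts[3] if len(parts) > 3 else f"region_{ln}"
            rows.append({"chrom": chrom, "start": start, "end": end, "name": name})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def write_bed(intervals: pd.DataFrame, path: str) -> None:
    intervals[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_dir(out: Path, stage: str) -> Path:
    d = out / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Run (or resume) the full pipeline; returns the manifest dict.

    Each stage writes its outputs under ``<out_dir>/<stage>/`` and is
    skipped when its ``.done`` marker exists (unless ``force``); the
    manifest lists per-stage output checksums, so two runs with the same
    config produce identical manifests.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }

    def finish(stage: str, d: Path):
        (d / ".done").write_text("ok")
        files = sorted(p for p in d.iterdir() if p.name != ".done")
        manifest["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in files}
        }
        logger.info("stage %s: %d output file(s)", stage, len(files))

    def fresh(stage: str, d: Path) -> bool:
        if force or not (d / ".done").exists():
            for p in d.iterdir():
                p.unlink()
            return True
        files = sorted(p for p in d.iterdir() if p.name != ".done")
        manifest["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in files},
            "cached": True,
        }
        logger.info("stage %s: cached", stage)
        return False

    rng = np.random.default_rng(config.seed)
    stage_seeds = {s: int(rng.integers(0, 2**31 - 1)) for s in PIPELINE_STAGES}
    manifest["stage_seeds"] = stage_seeds

    # --- simulate (or load) -------------------------------------------------
    d = _stage_dir(out, "simulate")
    if fresh("simulate", d):
        if config.counts_path:
            mts = read_counts(config.counts_path, vehicle=config.vehicle,
                              stimulus=config.stimulus)
            wiring = None
            write_counts(mts, str(d / "counts.tsv"))
            write_bed(mts.cre_intervals, str(d / "cres.bed"))
        else:
            wiring = synthetic_mod.generate_wiring(
                config.n_cres,
                config.n_inhibitors,
                config.n_kinases,
                config.n_programs,
                offtarget_rate=config.offtarget_rate,
                seed=stage_seeds["simulate"],
            )
            mts, truth = synthetic_mod.generate_counts(
                wiring,
                dispersion=config.dispersion,
                depth=config.depth,
                seed=stage_seeds["simulate"],
                effect_scale=config.effect_scale,
                vehicle=config.vehicle,
                stimulus=config.stimulus,
            )
            tf_peaks = synthetic_mod.generate_tf_peaks(
                wiring, mts.cre_intervals, seed=stage_seeds["simulate"]
            )
            truth.tf_peaks = tf_peaks
            write_counts(mts, str(d / "counts.tsv"))
            write_bed(mts.cre_intervals, str(d / "cres.bed"))
            (d / "wiring.json").write_text(wiring.to_json())
            truth.effect.to_csv(d / "truth_effect.tsv", sep="\t")
            for tf, peaks in tf_peaks.items():
                write_bed(peaks, str(d / f"peaks_{tf}.bed"))
        finish("simulate", d)
    mts = read_counts(str(d / "counts.tsv"), vehicle=config.vehicle,
                      stimulus=config.stimulus)
    mts.cre_intervals = read_bed(str(d / "cres.bed"))
    wiring_path = d / "wiring.json"
    wiring = (
        synthetic_mod.LatentWiring.from_json(wiring_path.read_text())
        if wiring_path.exists()
        else None
    )
    tf_peaks = {
        p.stem.removeprefix("peaks_"): read_bed(str(p))
        for p in sorted(d.glob("peaks_*.bed"))
    }

    # --- normalize ----------------------------------------------------------
    d = _stage_dir(out, "normalize")
    if fresh("normalize", d):
        normed, fit = normalization_mod.normalize_tables(
            mts, sigma_window=config.sigma_window
        )
        write_counts(normed, str(d / "normalized.tsv"))
        fit.scale_factors.to_csv(d / "scale_factors.tsv", sep="\t")
        finish("normalize", d)
    normed = read_counts(str(d / "normalized.tsv"), vehicle=config.vehicle,
                         stimulus=config.stimulus)

    # --- mfa ----------------------------------------------------------------
    d = _stage_dir(out, "mfa")
    std = mfa_mod.standardize(normed, log2_transform=config.log2_transform)
    if fresh("mfa", d):
        res = mfa_mod.fit_with_selection(
            std,
            n_perm=config.n_perm_mfa,
            alpha=config.alpha,
            seed=stage_seeds["mfa"],
        )
        res.compromise_scores.to_csv(d / "compromise.tsv", sep="\t")
        pd.DataFrame(
            {"eigenvalue": res.eigenvalues[: len(res.perm_pvalues)],
             "perm_p": res.perm_pvalues[: len(res.eigenvalues)]}
        ).to_csv(d / "eigenvalues.tsv", sep="\t")
        (d / "selection.json").write_text(
            json.dumps({"selected_dims": res.selected_dims})
        )
        for cond, ps in res.partial_scores.items():
            ps.to_csv(d / f"partial_{cond}.tsv", sep="\t")
        finish("mfa", d)
        mfa_res = res
    else:
        mfa_res = mfa_mod.mfa_fit(std)
        sel = json.loads((d / "selection.json").read_text())
        mfa_res.selected_dims = sel["selected_dims"]

    # --- score --------------------------------------------------------------
    d = _stage_dir(out, "score")
    dist = perturbation_mod.cre_distances(mfa_res, vehicle=config.vehicle)
    scores = perturbation_mod.score_perturbations(
        dist, std, vehicle=config.vehicle, threshold=config.threshold
    )
    if fresh("score", d):
        scores.score.to_csv(d / "scores.tsv", sep="\t")
        scores.calls.to_csv(d / "calls.tsv", sep="\t")
        _, summary = perturbation_mod.call_events(
            scores.score, threshold=config.threshold
        )
        summary.to_json(d / "summary.json", indent=1)
        finish("score", d)

    # --- compare ------------------------------------------------------------
    d = _stage_dir(out, "compare")
    if fresh("compare", d):
        model = comparative_mod.proximity_fit(
            scores,
            n_perm=config.n_perm_proximity,
            alpha=config.alpha,
            seed=stage_seeds["compare"],
            k=config.k_neighbors,
        )
        edges = pd.DataFrame(model.knn_edges, columns=["source", "target", "distance"])
        edges.to_csv(d / "knn_edges.tsv", sep="\t", index=False)
        _write_graphml(model, d / "knn.graphml")
        if wiring is not None:
            obs, _, p, kw_p = comparative_mod.family_distance_test(
                model, wiring.family, seed=stage_seeds["compare"]
            )
            (d / "family_test.json").write_text(
                json.dumps({"observed": obs, "p": p, "kruskal_p": kw_p})
            )
        first = scores.score.columns[0]
        up, down = comparative_mod.angle_frequency(mfa_res, scores.calls, first)
        pd.DataFrame(
            {"bin_start": up.bin_edges[:-1], "up": up.frequency, "down": down.frequency}
        ).to_csv(d / f"angles_{first}.tsv", sep="\t", index=False)
        sets = perturbation_mod.affected_sets(scores.calls)
        rows = []
        inhibs = list(scores.score.columns)
        srng = np.random.default_rng(stage_seeds["compare"])
        for i, a in enumerate(inhibs):
            for b in inhibs[i + 1 :]:
                for direction in ("down", "up"):
                    sa, sb = sets[(a, direction)], sets[(b, direction)]
                    if not (sa | sb):
                        continue
                    st = comparative_mod.ses_jaccard(
                        sa, sb, scores.score.index,
                        n_perm=config.n_perm_overlap,
                        seed=int(srng.integers(0, 2**31 - 1)),
                        pair=(a, b, direction),
                    )
                    rows.append(
                        {"a": a, "b": b, "direction": direction,
                         "jaccard": st.jaccard, "ses": st.ses}
                    )
        pd.DataFrame(rows).to_csv(d / "overlap.tsv", sep="\t", index=False)
        finish("compare", d)

    # --- enrich -------------------------------------------------------------
    d = _stage_dir(out, "enrich")
    if fresh("enrich", d):
        if tf_peaks:
            sets = perturbation_mod.affected_sets(scores.calls)
            assoc = enrichment_mod.associate_all(
                sets,
                tf_peaks,
                mts.cre_intervals,
                n_perm=config.n_perm_enrich,
                seed=stage_seeds["enrich"],
                min_set_size=5,
            )
            assoc.to_csv(d / "associations.tsv", sep="\t", index=False)
        finish("enrich", d)

    # --- classify -----------------------------------------------------------
    d = _stage_dir(out, "classify")
    if fresh("classify", d):
        if config.classify_inhibitor:
            inhibitor = config.classify_inhibitor
        else:
            # the inhibitor with the most balanced call counts, so all three
            # classes are represented in both splits
            balance = {
                c: scores.calls[c].value_counts().reindex(
                    ["down", "none", "up"], fill_value=0
                ).min()
                for c in scores.calls.columns
            }
            inhibitor = max(sorted(balance), key=lambda c: balance[c])
        feat_tables = {"kinetics": std.tables[config.vehicle]}
        for tf, peaks in tf_peaks.items():
            ind, _ = enrichment_mod.interval_overlap(mts.cre_intervals, peaks)
            feat_tables[tf] = ind.astype(float).to_frame("bound") * 2 - 1
        fs = classifier_mod.build_feature_space(feat_tables, min_var=config.min_var)
        labels = scores.calls[inhibitor]
        ev = classifier_mod.train_eval(
            fs, labels, seed=stage_seeds["classify"], tune=config.tune
        )
        ev.metrics.to_json(d / "metrics.json", indent=1)
        attr = classifier_mod.tree_attributions(ev.model, fs.features)
        imp = classifier_mod.directional_importance(fs.features, attr)
        imp.to_csv(d / "directional_importance.tsv", sep="\t")
        finish("classify", d)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _write_graphml(model, path: Path) -> None:
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(model.labels)
    for a, b, dist in model.knn_edges:
        g.add_edge(a, b, distance=dist)
    nx.write_graphml(g, path)
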