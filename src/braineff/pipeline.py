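"""End-to-end orchestration: cohort -> preprocessing -> networks ->
efficiency profiles -> group statistics -> mediation -> classification.

A single :class:`RunConfig` (YAML-serializable, round-trip safe) drives the
run; one global seed fans out deterministically to every stochastic stage,
so re-running the same config reproduces the results bundle bit for bit.
Artifacts are plain TSV/CSV/JSON in one output directory, and downstream
stages communicate only through those artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import efficiency, mediation, network, stats
from .preprocess import PreprocessConfig, preprocess, screen_motion
from .synthetic import Cohort, CohortDesign, generate_atlas, generate_cohort, read_cohort, write_cohort


@dataclass(frozen=True)
class RunConfig:
    """Everything one analysis run depends on."""

    input_mode: str = "synthetic"  # "synthetic" | "directory"
    design: CohortDesign = field(default_factory=CohortDesign)
    node_count: int = 160
    data_dir: str | None = None
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    s_min: float = 0.10
    s_max: float = 0.40
    s_step: float = 0.01
    alpha: float = 0.05
    bonferroni_divisor: int = 3
    fdr_q: float = 0.05
    n_boot: int = 1000
    classification_modes: tuple = ("nested", "paper")
    include_subnetwork_nodal: bool = True
    persist_cohort: bool = True  # write the raw cohort (incl. time series) into the bundle
    seed: int = 0

    def __post_init__(self):
        if self.input_mode not in ("synthetic", "directory"):
            raise ValueError("input_mode must be 'synthetic' or 'directory'")
        if self.input_mode == "directory" and not self.data_dir:
            raise ValueError("directory mode needs data_dir")
        object.__setattr__(self, "classification_modes", tuple(self.classification_modes))
        # the global seed wins over any seed embedded in the design
        if self.design.seed != self.seed:
            object.__setattr__(self, "design", dataclasses.replace(self.design, seed=self.seed))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"] = self.design.to_dict()
        d["classification_modes"] = list(self.classification_modes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "design" in d and not isinstance(d["design"], CohortDesign):
            d["design"] = CohortDesign.from_dict(d["design"])
        if "preprocessing" in d and not isinstance(d["preprocessing"], PreprocessConfig):
            d["preprocessing"] = PreprocessConfig(**d["preprocessing"])
        if "classification_modes" in d:
            d["classification_modes"] = tuple(d["classification_modes"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def load_inputs(config: RunConfig) -> Cohort:
    """Generate (synthetic mode) or read (directory mode) the cohort."""
    if config.input_mode == "synthetic":
        atlas = generate_atlas(config.node_count)
        return generate_cohort(config.design, atlas)
    return read_cohort(config.data_dir)


def compute_profiles(cohort: Cohort, config: RunConfig, log=None) -> pd.DataFrame:
    """Preprocess, screen motion, build graphs and profile every subject.

    Returns the long metrics table with a ``subject_id`` column; subjects
    failing motion screening are excluded and logged.
    """
    log = log if log is not None else []
    frames = []
    cfg = config.preprocessing
    for ts in cohort.timeseries:
        if not screen_motion(ts, cfg.max_disp_mm, cfg.max_rot_deg, cfg.on_missing_motion):
            log.append(f"excluded {ts.subject_id}: failed motion screening")
            continue
        try:
            clean = preprocess(ts, cfg)
            cm = network.connectivity_from_timeseries(clean)
            graphs = network.sparsity_sweep(cm, config.s_min, config.s_max, config.s_step)
            prof = efficiency.profile_subject(graphs, cohort.atlas, config.include_subnetwork_nodal)
        except Exception as e:  # abort with stage context per contract
            raise RuntimeError(f"metrics stage failed for subject {ts.subject_id}: {e}") from e
        prof.insert(0, "subject_id", ts.subject_id)
        frames.append(prof)
    if not frames:
        raise RuntimeError("metrics stage: no subject passed screening")
    return pd.concat(frames, ignore_index=True)


def run_group_statistics(profiles: pd.DataFrame, table: pd.DataFrame, config: RunConfig) -> dict:
    out = stats.compare_efficiency_families(
        profiles, table, config.alpha, config.bonferroni_divisor, config.fdr_q
    )
    out["demographics"] = stats.demographic_comparisons(table, config.alpha)
    return out


def _mediator_feature_columns(cohort: Cohort, features: pd.DataFrame, stats_results: dict) -> list:
    """Mediator AUC columns: planted mediator nodes when ground truth is
    available, else the strongest nodal-global FDR discoveries."""
    if cohort.ground_truth is not None and cohort.ground_truth.mediator_nodes:
        cols = [f"node:{nid}:global" for nid in cohort.ground_truth.mediator_nodes]
        return [c for c in cols if c in features.columns]
    nodal = stats_results.get("nodal", pd.DataFrame())
    if len(nodal):
        cand = nodal[(nodal.metric == "global")].sort_values("q")
        cand = cand[cand.get("fdr_reject", False)] if cand.get("fdr_reject") is not None else cand
        return [f"node:{nid}:global" for nid in cand.node_id.head(3)]
    return []


def run_mediation_stage(
    cohort_table: pd.DataFrame,
    features: pd.DataFrame,
    mediator_cols: list,
    config: RunConfig,
) -> pd.DataFrame:
    """The four path-diagram templates: lesion burden -> nodal efficiency ->
    timed-test / processing-speed outcomes, adjusted for age, gender and
    education."""
    if len(mediator_cols) < 3:
        raise RuntimeError("mediation stage: fewer than 3 mediator columns available")
    df = cohort_table.set_index("subject_id").join(features[mediator_cols], how="inner").reset_index()
    for col in ("tmt_a_seconds", "stroop_a_seconds", "stroop_b_seconds"):
        inv = 1.0 / df[col]
        df[col.replace("_seconds", "_z")] = (inv - inv.mean()) / inv.std(ddof=0)
    zc = stats.composite_z(df)
    df["processing_speed"] = zc["processing_speed"].to_numpy()
    templates = mediation.default_templates(
        "log_pwmh_norm",
        mediator_cols,
        {
            "single": "tmt_a_z",
            "double": "stroop_b_z",
            "triple_1": "stroop_a_z",
            "triple_2": "processing_speed",
        },
    )
    return mediation.run_mediation_templates(
        df, templates, covariates=("age", "gender", "education"), n_boot=config.n_boot, seed=config.seed
    )


def run_classification_stage(
    features: pd.DataFrame,
    table: pd.DataFrame,
    stats_results: dict,
    config: RunConfig,
) -> dict:
    """LOOCV linear SVM in every configured selection mode."""
    reports = {}
    for mode in config.classification_modes:
        try:
            fm = clf.select_features(
                features, table, mode=mode, alpha=config.alpha, stats_results=stats_results if mode == "paper" else None
            )
            reports[mode] = clf.loocv_classify(fm, alpha=config.alpha)
        except ValueError as e:
            reports[mode] = {"error": str(e)}
    return reports


def _versions() -> dict:
    import scipy
    import sklearn
    import statsmodels

    from . import __version__

    return {
        "braineff": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full analysis and persist a reproducible bundle.

    The bundle contains the manifest (config + versions + seed), the cohort
    table, the per-subject metrics TSV, group-statistics TSVs, mediation
    TSV/JSON, classification JSON with ROC points, and a plain-text log.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list = []

    log.append(f"stage simulate/ingest: mode={config.input_mode}")
    cohort = load_inputs(config)
    if config.input_mode == "synthetic" and config.persist_cohort:
        write_cohort(cohort, out / "cohort")
    table = cohort.table.copy()
    zc = stats.composite_z(table)
    table["processing_speed"] = zc["processing_speed"].to_numpy()
    table.to_csv(out / "cohort.csv", index=False)

    log.append(f"stage metrics: sparsity grid {config.s_min}..{config.s_max} step {config.s_step}")
    profiles = compute_profiles(cohort, config, log)
    kept = profiles.subject_id.unique()
    table = table[table.subject_id.isin(kept)].reset_index(drop=True)
    profiles.to_csv(out / "metrics.tsv", sep="\t", index=False, float_format="%.10g")

    log.append(
        f"stage stats: alpha={config.alpha}, bonferroni 1/{config.bonferroni_divisor}, FDR q={config.fdr_q}"
    )
    stats_results = run_group_statistics(profiles, table, config)
    for name, tab in stats_results.items():
        tab.to_csv(out / f"stats_{name}.tsv", sep="\t", index=False, float_format="%.10g")

    features = clf.profiles_to_features(profiles)
    mediator_cols = _mediator_feature_columns(cohort, features, stats_results)
    log.append(f"stage mediation: k={config.n_boot} bootstrap samples, mediators={mediator_cols}")
    med = run_mediation_stage(table, features, mediator_cols, config)
    med.to_csv(out / "mediation.tsv", sep="\t", index=False, float_format="%.10g")
    (out / "mediation.json").write_text(med.to_json(orient="records", indent=1))

    log.append(f"stage classification: modes={list(config.classification_modes)}")
    reports = run_classification_stage(features, table, stats_results, config)
    payload = {}
    for mode, rep in reports.items():
        if isinstance(rep, dict):
            payload[mode] = rep
            log.append(f"classification[{mode}] skipped: {rep['error']}")
        else:
            payload[mode] = rep.to_json_dict()
            rep.roc_points.to_csv(out / f"roc_{mode}.tsv", sep="\t", index=False, float_format="%.10g")
            if rep.selection_leaks_labels:
                log.append(
                    f"warning: classification[{mode}] selects features on the full sample; "
                    "estimates are optimistic (label leakage)"
                )
    (out / "classification.json").write_text(json.dumps(payload, indent=1))

    manifest = {"config": config.to_dict(), "seed": config.seed, "versions": _versions()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "run.log").write_text("\n".join(log) + "\n")

    return {
        "out_dir": out,
        "cohort": table,
        "profiles": profiles,
        "stats": stats_results,
        "mediation": med,
        "classification": reports,
        "log": log,
    }


def validate_inputs(data_dir) -> pd.DataFrame:
    """Consistency report for a cohort directory (always returns, never raises).

    Checks file presence, unique atlas nodes, cohort/time-series subject
    alignment, node-id alignment and uniform T across subjects.
    """
    d = Path(data_dir)
    checks = []

    def add(name, ok, detail=""):
        checks.append({"check": name, "passed": bool(ok), "detail": detail})

    required = ["atlas.tsv", "cohort.csv", "manifest.json"]
    for f in required:
        add(f"file {f} present", (d / f).exists())
    if not all(c["passed"] for c in checks):
        return pd.DataFrame(checks)

    atlas = pd.read_csv(d / "atlas.tsv", sep="\t")
    add("atlas node ids unique", atlas.node_id.is_unique)
    cohort = pd.read_csv(d / "cohort.csv")
    add("cohort subject ids unique", cohort.subject_id.is_unique)

    ts_dir = d / "timeseries"
    lengths, missing, misaligned = {}, [], []
    for sid in cohort.subject_id:
        f = ts_dir / f"{sid}.tsv"
        if not f.exists():
            missing.append(sid)
            continue
        df = pd.read_csv(f, sep="\t", nrows=1)
        if list(df.columns) != list(atlas.node_id):
            misaligned.append(sid)
        lengths[sid] = sum(1 for _ in open(f)) - 1
    add("time-series file per cohort row", not missing, f"missing: {missing[:5]}" if missing else "")
    add("node ids aligned with atlas", not misaligned, f"misaligned: {misaligned[:5]}" if misaligned else "")
    add("uniform T across subjects", len(set(lengths.values())) <= 1, f"T values: {sorted(set(lengths.values()))}")
    extra = {p.stem for p in ts_dir.glob("*.tsv")} - set(cohort.subject_id) if ts_dir.exists() else set()
    add("no orphan time-series files", not extra, f"orphans: {sorted(extra)[:5]}" if extra else "")
    return pd.DataFrame(checks)
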