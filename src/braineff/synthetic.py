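"""Synthetic cohort generator with known planted structure.

Emulates a three-group white-matter-hyperintensity (WMH) study — healthy
controls (HC), WMH with normal cognition (WMH-NC) and WMH with cognitive
impairment no dementia (WMH-CIND) — so that every downstream stage of the
analysis has ground truth:

* ROI time series follow a community-structured Gaussian factor model,
  ``x_i(t) = sqrt(rho_g) g(t) + sqrt(rho_w_i) c_m(i)(t)
  + sqrt(1 - rho_g - rho_w_i) eps_i(t)``, giving a population correlation of
  ``rho_g + rho_w`` within a subnetwork and ``rho_g`` across subnetworks.
* WMH-CIND subjects carry a coupling deficit (``rho_w - delta``) in chosen
  subnetworks, lowering their within-subnetwork connectivity and hence the
  efficiency of the corresponding graph communities.
* WMH lesion volumes are log-normal with group-dependent medians; cognition
  is generated from an explicit mediation model X -> M -> Y (X = log10
  normalized periventricular WMH volume, M = latent nodal-efficiency
  mediator, Y = processing-speed cognition) whose true paths are recorded.
  The mediator M physically perturbs the coupling of designated "mediator
  nodes", so that measured nodal efficiency genuinely mediates the planted
  lesion-cognition association.

All randomness derives from the design seed; identical designs produce
byte-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .preprocess import RoiTimeSeries

SUBNETWORKS = ("DMN", "FPN", "CON", "SMN", "ON", "CN")
GROUPS = ("HC", "WMH-NC", "WMH-CIND")

# node counts of the 160-ROI functional atlas's six subnetworks
DEFAULT_SUBNETWORK_SIZES = {"DMN": 34, "FPN": 21, "CON": 32, "SMN": 33, "ON": 22, "CN": 18}


@dataclass(frozen=True)
class AtlasSpec:
    """A parcellation: ordered node labels, each assigned to one subnetwork."""

    node_ids: tuple
    subnetwork_of: dict
    coordinates: np.ndarray | None = None

    def __post_init__(self):
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node_ids must be unique")
        missing = [n for n in self.node_ids if n not in self.subnetwork_of]
        if missing:
            raise ValueError(f"nodes without subnetwork assignment: {missing[:5]}")
        labels = set(self.subnetwork_of.values())
        if not labels <= set(SUBNETWORKS):
            raise ValueError(f"unknown subnetwork labels: {labels - set(SUBNETWORKS)}")
        for lab in SUBNETWORKS:
            if lab not in labels:
                raise ValueError(f"subnetwork {lab} is empty")

    @property
    def node_count(self) -> int:
        return len(self.node_ids)

    def indices_of(self, label: str) -> np.ndarray:
        """Positional indices of the nodes belonging to ``label``."""
        if label not in SUBNETWORKS:
            raise ValueError(f"unknown subnetwork label: {label!r}")
        return np.array([k for k, n in enumerate(self.node_ids) if self.subnetwork_of[n] == label])

    def subnetwork_index(self) -> np.ndarray:
        """Per-node integer subnetwork code (order of SUBNETWORKS)."""
        code = {lab: k for k, lab in enumerate(SUBNETWORKS)}
        return np.array([code[self.subnetwork_of[n]] for n in self.node_ids])


def generate_atlas(node_count: int = 160, subnetwork_sizes=None) -> AtlasSpec:
    """Deterministic atlas with contiguous node blocks per subnetwork.

    ``subnetwork_sizes`` is a mapping or sequence of six sizes (order of
    ``SUBNETWORKS``) summing to ``node_count``. The default reproduces the
    six-subnetwork partition of the 160-ROI functional atlas.
    """
    if subnetwork_sizes is None:
        if node_count == 160:
            sizes = [DEFAULT_SUBNETWORK_SIZES[s] for s in SUBNETWORKS]
        elif node_count % 6 == 0:
            sizes = [node_count // 6] * 6
        else:
            raise ValueError("provide subnetwork_sizes when node_count is not 160 or a multiple of 6")
    elif isinstance(subnetwork_sizes, dict):
        sizes = [subnetwork_sizes[s] for s in SUBNETWORKS]
    else:
        sizes = list(subnetwork_sizes)
    if len(sizes) != 6:
        raise ValueError(f"expected 6 subnetwork sizes, got {len(sizes)}")
    if any(s < 1 for s in sizes):
        raise ValueError("every subnetwork must be non-empty")
    if sum(sizes) != node_count:
        raise ValueError(f"subnetwork sizes sum to {sum(sizes)}, expected {node_count}")
    node_ids, sub_of, coords = [], {}, []
    for b, (lab, sz) in enumerate(zip(SUBNETWORKS, sizes)):
        for k in range(sz):
            nid = f"{lab}_{k + 1:03d}"
            node_ids.append(nid)
            sub_of[nid] = lab
            coords.append((30.0 * b - 75.0, 4.0 * k - 2.0 * sz, 10.0 * (b % 3)))
    return AtlasSpec(tuple(node_ids), sub_of, np.asarray(coords))


def _default_mediation_params() -> dict:
    # beta_age / beta_edu are the small covariate effects on cognition
    return {
        "a": -0.5,
        "b": 0.4,
        "c_prime": -0.2,
        "noise_sd_M": 1.0,
        "noise_sd_Y": 1.0,
        "beta_age": -0.10,
        "beta_edu": 0.05,
    }


def _default_group_sizes() -> dict:
    return {"HC": 38, "WMH-NC": 36, "WMH-CIND": 38}


@dataclass(frozen=True)
class CohortDesign:
    """Full specification of one synthetic cohort.

    ``coupling_within`` (rho_w) and ``coupling_global`` (rho_g) set the
    factor-model correlation structure; WMH-CIND subjects lose
    ``deficit_delta`` of within-subnetwork coupling in
    ``deficit_subnetworks``. ``mediation_params`` are the true paths of the
    planted X -> M -> Y model. ``ar1_phi`` optionally gives all latent
    factors an AR(1) autocorrelation (unit marginal variance); it defaults
    off because the downstream analysis only consumes correlations.
    """

    group_sizes: dict = field(default_factory=_default_group_sizes)
    timepoints: int = 200
    sampling_interval_s: float = 2.0
    coupling_within: float = 0.30
    coupling_global: float = 0.10
    deficit_subnetworks: tuple = ("FPN", "CON")
    deficit_delta: float = 0.15
    n_mediator_nodes: int = 3
    mediation_params: dict = field(default_factory=_default_mediation_params)
    ar1_phi: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.timepoints < 2:
            raise ValueError("timepoints must be >= 2")
        if not 0 <= self.coupling_within < 1:
            raise ValueError("coupling_within must be in [0, 1)")
        if self.coupling_within + self.coupling_global >= 1:
            raise ValueError("coupling_within + coupling_global must be < 1")
        if not 0 <= self.deficit_delta <= self.coupling_within:
            raise ValueError("deficit_delta must be in [0, coupling_within]")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs at least 2 subjects")
        unknown = set(self.group_sizes) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups: {unknown}")
        if set(self.deficit_subnetworks) - set(SUBNETWORKS):
            raise ValueError("unknown deficit subnetwork label")
        if not 0 <= self.ar1_phi < 1:
            raise ValueError("ar1_phi must be in [0, 1)")

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())

    def subject_groups(self) -> list:
        out = []
        for g in GROUPS:
            out.extend([g] * self.group_sizes.get(g, 0))
        return out

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["deficit_subnetworks"] = list(self.deficit_subnetworks)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortDesign":
        d = dict(d)
        if "deficit_subnetworks" in d:
            d["deficit_subnetworks"] = tuple(d["deficit_subnetworks"])
        return cls(**d)


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters, reproducible from (design, seed)."""

    subject_ids: tuple
    groups: tuple
    coupling: np.ndarray  # n_subjects x n_nodes within-subnetwork coupling
    mediator_nodes: tuple
    mediator_values: np.ndarray  # latent M per subject
    paths: dict  # true a, b, c_prime
    deficit_flags: tuple  # per-subject bool

    def to_json_dict(self) -> dict:
        return {
            "subject_ids": list(self.subject_ids),
            "groups": list(self.groups),
            "coupling": self.coupling.tolist(),
            "mediator_nodes": list(self.mediator_nodes),
            "mediator_values": self.mediator_values.tolist(),
            "paths": self.paths,
            "deficit_flags": [bool(f) for f in self.deficit_flags],
        }


def _trunc_normal(rng, mean, sd, lo, hi, size):
    """Truncated normal by resampling (vectorized rejection)."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


# group-level log10(WMH mm^3) centres, ordered HC < WMH-NC < WMH-CIND to
# match the reported median lesion burdens (~280 / ~960 / ~2340 mm^3)
_LOG10_WMH_CENTRE = {"HC": 2.45, "WMH-NC": 2.95, "WMH-CIND": 3.35}
_LOG10_WMH_SD = 0.45


def generate_covariates_and_cognition(design: CohortDesign, per_subject_M: np.ndarray | None = None):
    """Demographics, lesion volumes, mediator and cognition for one cohort.

    Returns ``(cohort, info)`` where ``cohort`` is one row per subject and
    ``info`` carries the standardized predictor ``x_std``, the mediator
    ``M`` and the true paths. When ``per_subject_M`` is given it replaces
    the model-generated mediator (the X -> M path is then the caller's).
    """
    mp = design.mediation_params
    rng = np.random.default_rng([design.seed, 3])
    groups = design.subject_groups()
    n = len(groups)
    subject_ids = tuple(f"sub-{k + 1:03d}" for k in range(n))

    age = _trunc_normal(rng, 63.0, 7.0, 50.0, 80.0, n)
    education = _trunc_normal(rng, 11.0, 3.0, 0.0, 22.0, n)
    gender = rng.integers(0, 2, n)
    total_brain = _trunc_normal(rng, 1.1e6, 8e4, 8.5e5, 1.4e6, n)
    mu = np.array([_LOG10_WMH_CENTRE[g] for g in groups])
    wmh = 10.0 ** rng.normal(mu, _LOG10_WMH_SD)
    pwmh_frac = rng.beta(8.0, 2.0, n)
    pwmh = wmh * pwmh_frac
    dwmh = wmh - pwmh

    x = np.log10(pwmh / total_brain)
    x_std = (x - x.mean()) / x.std(ddof=0)
    if per_subject_M is None:
        M = mp["a"] * x_std + rng.normal(0.0, mp["noise_sd_M"], n)
    else:
        M = np.asarray(per_subject_M, dtype=float)
        if M.shape != (n,):
            raise ValueError(f"per_subject_M must have shape ({n},)")
    age_std = (age - age.mean()) / age.std(ddof=0)
    edu_std = (education - education.mean()) / education.std(ddof=0)
    y = (
        mp["c_prime"] * x_std
        + mp["b"] * M
        + mp.get("beta_age", -0.10) * age_std
        + mp.get("beta_edu", 0.05) * edu_std
        + rng.normal(0.0, mp["noise_sd_Y"], n)
    )

    # raw neuropsychological scores derived from the cognition latent; the
    # timed tests are recorded in seconds (lower cognition -> slower)
    tmt_a = np.clip(45.0 - 10.0 * y + rng.normal(0, 6.0, n), 12.0, 240.0)
    stroop_a = np.clip(17.0 - 3.0 * y + rng.normal(0, 2.5, n), 6.0, 120.0)
    stroop_b = np.clip(20.0 - 3.5 * y + rng.normal(0, 2.5, n), 7.0, 150.0)
    mmse = np.clip(np.round(28.3 + 0.6 * y + rng.normal(0, 0.8, n)), 10, 30)
    moca = np.clip(np.round(25.0 + 1.5 * y + rng.normal(0, 1.2, n)), 5, 30)

    cohort = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "group": groups,
            "age": age,
            "gender": gender,
            "education": education,
            "wmh_mm3": wmh,
            "pwmh_mm3": pwmh,
            "dwmh_mm3": dwmh,
            "total_brain_mm3": total_brain,
            "log_pwmh_norm": x,
            "cognition_y": y,
            "tmt_a_seconds": tmt_a,
            "stroop_a_seconds": stroop_a,
            "stroop_b_seconds": stroop_b,
            "mmse": mmse,
            "moca": moca,
        }
    )
    info = {
        "x_std": x_std,
        "M": M,
        "paths": {"a": mp["a"], "b": mp["b"], "c_prime": mp["c_prime"]},
        "subject_ids": subject_ids,
        "groups": tuple(groups),
    }
    return cohort, info


def _planted_couplings(design: CohortDesign, atlas: AtlasSpec, groups, M) -> tuple:
    """Per-subject per-node within-subnetwork coupling and mediator nodes."""
    n, N = len(groups), atlas.node_count
    rho_w, delta = design.coupling_within, design.deficit_delta
    fpn = atlas.indices_of("FPN")
    mediator_nodes = tuple(atlas.node_ids[k] for k in fpn[: design.n_mediator_nodes])
    med_idx = fpn[: design.n_mediator_nodes]
    deficit_idx = np.concatenate([atlas.indices_of(s) for s in design.deficit_subnetworks]) if design.deficit_subnetworks else np.array([], dtype=int)

    coupling = np.full((n, N), rho_w)
    for s, g in enumerate(groups):
        if g == "WMH-CIND" and deficit_idx.size:
            coupling[s, deficit_idx] = rho_w - delta
        # mediator nodes: coupling driven by the latent mediator, a logistic
        # map of M onto (0, rho_w); higher M -> tighter coupling -> higher
        # nodal efficiency. The group deficit still applies on top.
        base = rho_w * expit(M[s])
        if g == "WMH-CIND":
            base = max(base - delta, 0.0)
        coupling[s, med_idx] = base
    return coupling, mediator_nodes


def _ar1(rng, phi, shape):
    """Standard-normal innovations filtered to AR(1) with unit variance."""
    e = rng.standard_normal(shape)
    if phi == 0:
        return e
    out = np.empty_like(e)
    out[0] = e[0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, shape[0]):
        out[t] = phi * out[t - 1] + scale * e[t]
    return out


def _timeseries_from_coupling(design, atlas, subject_index, coupling_row, subject_id, rng=None):
    T, N = design.timepoints, atlas.node_count
    rho_g = design.coupling_global
    rho_w = np.asarray(coupling_row, dtype=float)
    if rho_w.shape != (N,):
        raise ValueError("coupling row length must equal node count")
    if (rho_w < 0).any() or (rho_g + rho_w >= 1).any():
        raise ValueError("coupling out of range: need 0 <= rho_w and rho_g + rho_w < 1")
    if rng is None:
        rng = np.random.default_rng([design.seed, 7, subject_index])
    g = _ar1(rng, design.ar1_phi, (T, 1))
    c = _ar1(rng, design.ar1_phi, (T, len(SUBNETWORKS)))
    eps = _ar1(rng, design.ar1_phi, (T, N))
    sub = atlas.subnetwork_index()
    data = (
        np.sqrt(rho_g) * g
        + np.sqrt(rho_w) * c[:, sub]
        + np.sqrt(1.0 - rho_g - rho_w) * eps
    )
    motion_rng = np.random.default_rng([design.seed, 11, subject_index])
    return RoiTimeSeries(
        subject_id=subject_id,
        data=data,
        sampling_interval_s=design.sampling_interval_s,
        node_ids=tuple(atlas.node_ids),
        motion_max_disp_mm=float(motion_rng.uniform(0.05, 1.5)),
        motion_max_rot_deg=float(motion_rng.uniform(0.05, 1.5)),
    )


def generate_timeseries(design: CohortDesign, atlas: AtlasSpec, subject_index: int) -> RoiTimeSeries:
    """Factor-model BOLD stand-in for one subject (deterministic in seed)."""
    groups = design.subject_groups()
    if not 0 <= subject_index < len(groups):
        raise ValueError(f"subject_index {subject_index} out of range")
    cohort, info = generate_covariates_and_cognition(design)
    coupling, _ = _planted_couplings(design, atlas, groups, info["M"])
    return _timeseries_from_coupling(
        design, atlas, subject_index, coupling[subject_index], cohort.subject_id[subject_index]
    )


@dataclass(frozen=True)
class Cohort:
    """One generated cohort: table, per-subject series, atlas, ground truth."""

    design: CohortDesign
    atlas: AtlasSpec
    table: pd.DataFrame
    timeseries: tuple  # of RoiTimeSeries, aligned with table rows
    ground_truth: GroundTruth


def generate_cohort(design: CohortDesign, atlas: AtlasSpec | None = None) -> Cohort:
    """Generate a complete cohort (covariates, cognition, time series)."""
    if atlas is None:
        atlas = generate_atlas(160)
    cohort, info = generate_covariates_and_cognition(design)
    groups = list(info["groups"])
    coupling, mediator_nodes = _planted_couplings(design, atlas, groups, info["M"])
    series = tuple(
        _timeseries_from_coupling(design, atlas, s, coupling[s], cohort.subject_id[s])
        for s in range(len(groups))
    )
    cohort = cohort.assign(
        motion_max_disp_mm=[ts.motion_max_disp_mm for ts in series],
        motion_max_rot_deg=[ts.motion_max_rot_deg for ts in series],
    )
    gt = GroundTruth(
        subject_ids=info["subject_ids"],
        groups=info["groups"],
        coupling=coupling,
        mediator_nodes=mediator_nodes,
        mediator_values=info["M"],
        paths=info["paths"],
        deficit_flags=tuple(g == "WMH-CIND" for g in groups),
    )
    return Cohort(design, atlas, cohort, series, gt)


def write_cohort(cohort: Cohort, outdir) -> Path:
    """Persist a cohort: atlas TSV, cohort CSV, per-subject time-series TSVs,
    ground-truth JSON and a manifest with the full design and seed."""
    out = Path(outdir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    atlas = cohort.atlas
    coords = atlas.coordinates if atlas.coordinates is not None else np.zeros((atlas.node_count, 3))
    pd.DataFrame(
        {
            "node_id": atlas.node_ids,
            "subnetwork": [atlas.subnetwork_of[n] for n in atlas.node_ids],
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
        }
    ).to_csv(out / "atlas.tsv", sep="\t", index=False)
    cohort.table.to_csv(out / "cohort.csv", index=False)
    for ts in cohort.timeseries:
        pd.DataFrame(ts.data, columns=list(ts.node_ids)).to_csv(
            out / "timeseries" / f"{ts.subject_id}.tsv", sep="\t", index=False, float_format="%.10g"
        )
    (out / "ground_truth.json").write_text(json.dumps(cohort.ground_truth.to_json_dict(), indent=1))
    manifest = {
        "design": cohort.design.to_dict(),
        "seed": cohort.design.seed,
        "n_subjects": cohort.design.n_subjects,
        "node_count": atlas.node_count,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_cohort(indir) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort`."""
    d = Path(indir)
    manifest = json.loads((d / "manifest.json").read_text())
    design = CohortDesign.from_dict(manifest["design"])
    at = pd.read_csv(d / "atlas.tsv", sep="\t")
    atlas = AtlasSpec(
        tuple(at.node_id),
        dict(zip(at.node_id, at.subnetwork)),
        at[["x", "y", "z"]].to_numpy(),
    )
    table = pd.read_csv(d / "cohort.csv")
    gt_raw = json.loads((d / "ground_truth.json").read_text())
    gt = GroundTruth(
        subject_ids=tuple(gt_raw["subject_ids"]),
        groups=tuple(gt_raw["groups"]),
        coupling=np.asarray(gt_raw["coupling"]),
        mediator_nodes=tuple(gt_raw["mediator_nodes"]),
        mediator_values=np.asarray(gt_raw["mediator_values"]),
        paths=gt_raw["paths"],
        deficit_flags=tuple(gt_raw["deficit_flags"]),
    )
    series = []
    for k, sid in enumerate(table.subject_id):
        df = pd.read_csv(d / "timeseries" / f"{sid}.tsv", sep="\t")
        disp = float(table.motion_max_disp_mm[k]) if "motion_max_disp_mm" in table else None
        rot = float(table.motion_max_rot_deg[k]) if "motion_max_rot_deg" in table else None
        series.append(
            RoiTimeSeries(
                subject_id=sid,
                data=df.to_numpy(),
                sampling_interval_s=design.sampling_interval_s,
                node_ids=tuple(df.columns),
                motion_max_disp_mm=disp,
                motion_max_rot_deg=rot,
            )
        )
    return Cohort(design, atlas, table, tuple(series), gt)
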