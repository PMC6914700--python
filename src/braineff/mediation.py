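"""Parallel-mediator path models with bias-corrected bootstrap intervals.

The model relates a predictor X (lesion burden), one or more mediators M_j
(nodal efficiency AUCs) and an outcome Y (cognition), optionally adjusting
every equation for the same covariates:

    M_j = a_j X + covs          (path a_j)
    Y   = c' X + sum_j b_j M_j + covs   (paths b_j and c')
    Y   = c  X + covs           (total effect c)

The indirect effect through M_j is a_j * b_j, the total indirect effect is
their sum, and with identical covariate sets the OLS identity
c = c' + sum_j a_j b_j holds exactly. Inference on the indirect effects
uses case-resampling bootstrap (subjects resampled with replacement,
covariates attached) with bias-corrected percentile intervals: the
correction z0 = Phi^-1(#{theta* < theta_hat}/B) shifts the percentile
endpoints to Phi(2 z0 +/- z_{alpha/2}). An effect is declared present when
its interval excludes zero. Variables are used on their analysis scale;
standardization, if wanted, is the caller's job.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm


@dataclass(frozen=True)
class MediationModel:
    """Column specification of one mediation model."""

    x: str
    mediators: tuple
    y: str
    covariates: tuple = ()
    n_boot: int = 1000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "mediators", tuple(self.mediators))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if len(self.mediators) < 1:
            raise ValueError("need at least one mediator")
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        cols = [self.x, self.y, *self.mediators, *self.covariates]
        if len(set(cols)) != len(cols):
            raise ValueError("x, y, mediators and covariates must be distinct columns")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class MediationResult:
    """Point estimates and bias-corrected bootstrap CIs for one model."""

    model: MediationModel
    a: np.ndarray
    b: np.ndarray
    c: float
    c_prime: float
    indirect: np.ndarray
    total_indirect: float
    ci_indirect: np.ndarray  # m x 2
    ci_total: tuple
    significant: np.ndarray  # per-mediator: CI excludes 0
    total_significant: bool
    n: int
    n_boot: int
    boot_indirect: np.ndarray | None = None  # B x m bootstrap draws
    boot_total: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "mediator": m,
                "a": self.a[j],
                "b": self.b[j],
                "c": self.c,
                "c_prime": self.c_prime,
                "indirect": self.indirect[j],
                "ci_low": self.ci_indirect[j, 0],
                "ci_high": self.ci_indirect[j, 1],
                "significant": bool(self.significant[j]),
            }
            for j, m in enumerate(self.model.mediators)
        ]
        rows.append(
            {
                "mediator": "(total)",
                "a": np.nan,
                "b": np.nan,
                "c": self.c,
                "c_prime": self.c_prime,
                "indirect": self.total_indirect,
                "ci_low": self.ci_total[0],
                "ci_high": self.ci_total[1],
                "significant": self.total_significant,
            }
        )
        return pd.DataFrame(rows)


def _design(data: pd.DataFrame, model: MediationModel):
    cols = [model.x, model.y, *model.mediators, *model.covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df = data[cols].dropna()
    n = len(df)
    if n <= len(cols) + 2:
        raise ValueError(f"too few complete cases (n={n}) for {len(cols)} variables")
    x = df[model.x].to_numpy(float)
    y = df[model.y].to_numpy(float)
    M = df[list(model.mediators)].to_numpy(float)
    C = df[list(model.covariates)].to_numpy(float) if model.covariates else np.empty((n, 0))
    return x, M, y, C, n


def _paths(x, M, y, C):
    """OLS path estimates; raises on rank deficiency."""
    n, m = M.shape
    ones = np.ones((n, 1))
    Xa = np.hstack([ones, x[:, None], C])  # a-paths and total effect
    Xb = np.hstack([ones, x[:, None], M, C])  # b-paths and direct effect
    for name, X in (("a/c", Xa), ("b/c'", Xb)):
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"rank-deficient design in the {name} equation")
    beta_a, *_ = np.linalg.lstsq(Xa, M, rcond=None)  # (1+1+k) x m
    beta_c, *_ = np.linalg.lstsq(Xa, y, rcond=None)
    beta_b, *_ = np.linalg.lstsq(Xb, y, rcond=None)
    a = beta_a[1]
    c = float(beta_c[1])
    c_prime = float(beta_b[1])
    b = beta_b[2 : 2 + m]
    return a, b, c, c_prime


def fit_paths(model: MediationModel, data: pd.DataFrame) -> dict:
    """Point estimates of all paths and indirect effects (no bootstrap)."""
    x, M, y, C, n = _design(data, model)
    a, b, c, c_prime = _paths(x, M, y, C)
    indirect = a * b
    return {
        "a": a,
        "b": b,
        "c": c,
        "c_prime": c_prime,
        "indirect": indirect,
        "total_indirect": float(indirect.sum()),
        "n": n,
    }


def _batched_solve(X, Y):
    """Least squares per bootstrap replicate via normal equations.

    X: (B, n, p), Y: (B, n, q) -> coefficients (B, p, q).
    """
    XtX = np.einsum("bnp,bnq->bpq", X, X)
    XtY = np.einsum("bnp,bnq->bpq", X, Y)
    return np.linalg.solve(XtX, XtY)


def _bc_interval(boot: np.ndarray, est: float, ci_level: float):
    """Bias-corrected percentile interval from bootstrap draws."""
    B = boot.size
    if np.ptp(boot) == 0:
        warnings.warn("degenerate bootstrap distribution; zero-width CI")
        return float(boot[0]), float(boot[0])
    frac = np.clip(np.mean(boot < est), 1.0 / (B + 1), B / (B + 1.0))
    z0 = norm.ppf(frac)
    za = norm.ppf((1.0 - ci_level) / 2.0)
    lo = norm.cdf(2 * z0 + za)
    hi = norm.cdf(2 * z0 - za)
    q = np.quantile(boot, [lo, hi])
    return float(q[0]), float(q[1])


def bootstrap_bc_ci(model: MediationModel, data: pd.DataFrame) -> MediationResult:
    """Case-resampling bootstrap of the indirect effects with BC intervals.

    Subjects (rows) are resampled with replacement, keeping covariates
    attached; the whole path system is refit on every replicate. Fully
    vectorized over replicates, deterministic in ``model.seed``.
    """
    x, M, y, C, n = _design(data, model)
    a, b, c, c_prime = _paths(x, M, y, C)
    indirect = a * b
    total = float(indirect.sum())
    m = M.shape[1]

    rng = np.random.default_rng([int(model.seed), 29])
    B = model.n_boot
    idx = rng.integers(0, n, size=(B, n))
    xb, Mb, yb, Cb = x[idx], M[idx], y[idx], C[idx]
    ones = np.ones((B, n, 1))
    Xa = np.concatenate([ones, xb[..., None], Cb], axis=2)
    Xb = np.concatenate([ones, xb[..., None], Mb, Cb], axis=2)
    coef_a = _batched_solve(Xa, Mb)  # (B, p, m)
    coef_b = _batched_solve(Xb, yb[..., None])  # (B, p, 1)
    boot_a = coef_a[:, 1, :]  # (B, m)
    boot_b = coef_b[:, 2 : 2 + m, 0]  # (B, m)
    boot_ind = boot_a * boot_b
    boot_total = boot_ind.sum(axis=1)

    ci = np.array([_bc_interval(boot_ind[:, j], indirect[j], model.ci_level) for j in range(m)])
    ci_total = _bc_interval(boot_total, total, model.ci_level)
    sig = (ci[:, 0] > 0) | (ci[:, 1] < 0)
    return MediationResult(
        model=model,
        a=a,
        b=b,
        c=c,
        c_prime=c_prime,
        indirect=indirect,
        total_indirect=total,
        ci_indirect=ci,
        ci_total=ci_total,
        significant=sig,
        total_significant=bool(ci_total[0] > 0 or ci_total[1] < 0),
        n=n,
        n_boot=B,
        boot_indirect=boot_ind,
        boot_total=boot_total,
    )


def run_mediation_templates(
    data: pd.DataFrame,
    templates: list,
    covariates=("age", "gender", "education"),
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run a list of named mediation templates on one table.

    Each template is a dict with keys ``name``, ``x``, ``mediators`` (list)
    and ``y``. Covariates, bootstrap size and seed are shared. Returns one
    row per (template, mediator) plus a total row per template — the
    numbers that populate a path diagram.
    """
    frames = []
    for k, t in enumerate(templates):
        model = MediationModel(
            x=t["x"],
            mediators=tuple(t["mediators"]),
            y=t["y"],
            covariates=tuple(covariates),
            n_boot=n_boot,
            seed=int(seed) + k,
        )
        res = bootstrap_bc_ci(model, data)
        frame = res.to_frame()
        frame.insert(0, "template", t.get("name", f"template_{k + 1}"))
        frame.insert(1, "x", t["x"])
        frame.insert(2, "y", t["y"])
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def default_templates(x: str, mediators, y_by_template: dict) -> list:
    """Four path-diagram templates over a shared mediator set: a single-
    mediator model, a two-mediator model and two three-mediator models.

    ``mediators`` supplies at least three mediator columns; ``y_by_template``
    maps the four template names (``single``, ``double``, ``triple_1``,
    ``triple_2``) to outcome columns.
    """
    med = list(mediators)
    if len(med) < 3:
        raise ValueError("need at least three mediator columns")
    return [
        {"name": "single", "x": x, "mediators": med[:1], "y": y_by_template["single"]},
        {"name": "double", "x": x, "mediators": med[:2], "y": y_by_template["double"]},
        {"name": "triple_1", "x": x, "mediators": med[:3], "y": y_by_template["triple_1"]},
        {"name": "triple_2", "x": x, "mediators": med[:3], "y": y_by_template["triple_2"]},
    ]
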