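"""Per-subject constrained fitting of the four families and model selection.

Fitting profiles out the linear coefficients: for fixed nonlinear
parameters (the delay ``c`` and/or exponent ``d``) every family is linear
in its remaining coefficients, so the sum of squared errors is minimized
exactly by least squares at each candidate nonlinear point.  A multistart
quasi-Newton search (L-BFGS-B, box constraints) over the nonlinear
parameters then yields the overall fit; ``grid_oracle_fit`` provides an
independent exhaustive-grid check of the same profile surface.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .core import (
    FAMILIES,
    ModelFamily,
    ParamSet,
    SubjectTrajectory,
    delayed_term,
    gaussian_profile_loglik,
    get_family,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "FitCriteria",
    "IndividualFit",
    "FamilyComparison",
    "fit_individual",
    "grid_oracle_fit",
    "compute_criteria",
    "compare_families",
    "summarize_fits",
    "rmse_difference_analysis",
    "fits_to_frame",
]

DEFAULT_PAIRS = (("P", "D"), ("P", "QD"), ("QD", "D"), ("PD", "QD"))


@dataclass
class FitConfig:
    """Controls for the constrained multistart fit.

    ``delay_lower_margin`` turns the strict bound c > min_j(x_ij) into the
    closed box c >= min_j(x_ij) + margin that the optimizer needs.
    """

    delay_lower_margin: float = 1e-3
    d_max: float = 10.0
    n_c_starts: int = 8
    n_d_starts: int = 5
    max_iterations: int = 200
    tolerance: float = 1e-9
    min_points: int = 6

    def __post_init__(self) -> None:
        if self.delay_lower_margin <= 0:
            raise ValueError("delay_lower_margin must be > 0")
        if self.d_max <= 1:
            raise ValueError("d_max must be > 1")
        if self.n_c_starts < 1 or self.n_d_starts < 1:
            raise ValueError("start grid counts must be >= 1")


@dataclass
class FitCriteria:
    """Fit quality measures for one (subject, family) fit."""

    rmse: float
    loglik: float
    aic: float
    aicc: float
    bic: float
    k: int
    n: int
    aicc_defined: bool = True
    degenerate: bool = False


@dataclass
class IndividualFit:
    subject_id: str
    family: ModelFamily
    params: ParamSet
    criteria: FitCriteria
    sse: float
    converged: bool = True
    n_starts_used: int = 0
    method: str = "multistart-lbfgsb"


@dataclass
class FamilyComparison:
    """All four family fits for one subject plus best-by flags."""

    subject_id: str
    fits: dict[str, IndividualFit]
    best_rmse: str
    best_aicc: str
    best_bic: str


def compute_criteria(sse: float, n: int, k: int) -> FitCriteria:
    """RMSE, profile log-likelihood, AIC, AICc, BIC for a Gaussian fit.

    AIC = 2k - 2 logL, BIC = k log(n) - 2 logL, and
    AICc = AIC + 2k(k+1)/(n-k-1); the AICc correction is flagged undefined
    when n <= k+1.  A zero SSE marks the whole set degenerate (infinite
    log-likelihood sentinel).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if k <= 0:
        raise ValueError("k must be positive")
    if sse < 0:
        raise ValueError("sse must be non-negative")
    rmse = math.sqrt(sse / n)
    loglik, degenerate = gaussian_profile_loglik(sse, n)
    if degenerate:
        aic = bic = -math.inf
    else:
        aic = 2.0 * k - 2.0 * loglik
        bic = k * math.log(n) - 2.0 * loglik
    aicc_defined = n - k - 1 > 0
    if aicc_defined and not degenerate:
        aicc = aic + 2.0 * k * (k + 1) / (n - k - 1)
    elif degenerate and aicc_defined:
        aicc = -math.inf
    else:
        aicc = math.nan
    return FitCriteria(
        rmse=rmse, loglik=loglik, aic=aic, aicc=aicc, bic=bic,
        k=k, n=n, aicc_defined=aicc_defined, degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# profile least squares machinery


def _design_columns(
    fam: ModelFamily, x: np.ndarray, c: Optional[float], d: Optional[float]
) -> np.ndarray:
    """Design matrix of the linear coefficients at fixed (c, d)."""
    n = len(x)
    ones = np.ones(n)
    if fam.name == "P":
        return np.column_stack([ones, np.where(x > 0, x**d, 0.0)])
    if fam.name == "D":
        return np.column_stack([ones, delayed_term(x, c)])
    if fam.name == "PD":
        return np.column_stack([ones, delayed_term(x, c, d)])
    z = delayed_term(x, c)
    return np.column_stack([ones, z, z * z])


def _profile_sse(
    fam: ModelFamily, x: np.ndarray, y: np.ndarray,
    c: Optional[float], d: Optional[float],
) -> tuple[float, np.ndarray]:
    """Exact least-squares SSE over the linear coefficients at fixed (c, d)."""
    X = _design_columns(fam, x, c, d)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        # collinear corner (e.g. d=0 makes the power column constant, or the
        # delayed term vanishes at c=max x): prefer zero slopes over the
        # minimum-norm split by penalizing the non-intercept coefficients
        penalty = np.eye(X.shape[1])
        penalty[0, 0] = 0.0
        beta = np.linalg.solve(X.T @ X + 1e-9 * penalty, X.T @ y)
    resid = y - X @ beta
    return float(resid @ resid), beta


def _nonlinear_bounds(
    fam: ModelFamily, x: np.ndarray, config: FitConfig
) -> list[tuple[float, float]]:
    bounds = []
    for name in fam.nonlinear_names:
        if name == "c":
            bounds.append((float(x[0]) + config.delay_lower_margin, float(x[-1])))
        else:
            bounds.append((0.0, config.d_max))
    return bounds


def _build_paramset(
    fam: ModelFamily, beta: np.ndarray, theta: Mapping[str, float],
    sse: float, n: int,
) -> ParamSet:
    values: dict[str, float] = dict(theta)
    for name, b in zip(fam.linear_names, beta):
        values[name] = float(b)
    values["sigma2"] = sse / n
    return ParamSet(**values)


def _start_points(
    fam: ModelFamily,
    x: np.ndarray,
    y: np.ndarray,
    bounds: Sequence[tuple[float, float]],
    config: FitConfig,
) -> list[np.ndarray]:
    """Multistart grid over the nonlinear box plus nested-model warm starts."""
    names = fam.nonlinear_names
    axes = []
    for name, (lo, hi) in zip(names, bounds):
        n_pts = config.n_c_starts if name == "c" else config.n_d_starts
        # interior points; boundary starts tend to stall the line search
        axes.append(np.linspace(lo, hi, n_pts + 2)[1:-1])
    grids = np.meshgrid(*axes, indexing="ij")
    starts = [np.array(pt) for pt in zip(*(g.ravel() for g in grids))]

    # warm starts from the nested delay-only solution: QD at b2=0 and PD at
    # d=1 both collapse to D, whose profile optimum is cheap to pre-scan
    if fam.name in ("PD", "QD"):
        d_fam = FAMILIES["D"]
        c_lo, c_hi = bounds[names.index("c")]
        scan = np.linspace(c_lo, c_hi, 64)
        sses = [_profile_sse(d_fam, x, y, c, None)[0] for c in scan]
        c_warm = float(scan[int(np.argmin(sses))])
        if fam.name == "QD":
            starts.append(np.array([c_warm]))
        else:
            starts.append(np.array([c_warm, 1.0]))
            starts.append(np.array([c_warm, 2.0]))
    if fam.name == "P":
        starts.append(np.array([1.0]))
    return starts


def fit_individual(
    traj: SubjectTrajectory,
    family: "str | ModelFamily",
    config: Optional[FitConfig] = None,
) -> IndividualFit:
    """Best-SSE constrained fit of one family to one subject.

    Box constraints: c in [min_j x_ij + margin, max_j x_ij] and
    d in [0, d_max]; the linear coefficients are unconstrained and solved
    exactly by profile least squares.  SSE ties (within ``tolerance``) are
    broken by smaller c, then smaller d.
    """
    fam = get_family(family)
    config = config or FitConfig()
    x, y, n = traj.x, traj.y, traj.n
    if n < fam.k:
        raise ValueError(
            f"insufficient observations: subject {traj.subject_id} has "
            f"{n} points but family {fam.name} has k={fam.k} coefficients"
        )

    names = fam.nonlinear_names
    bounds = _nonlinear_bounds(fam, x, config)
    starts = _start_points(fam, x, y, bounds, config)

    def objective(theta: np.ndarray) -> float:
        kw = dict(zip(names, theta))
        return _profile_sse(fam, x, y, kw.get("c"), kw.get("d"))[0]

    candidates: list[tuple[float, np.ndarray]] = []
    any_converged = False
    for start in starts:
        res = minimize(
            objective,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": config.max_iterations},
        )
        any_converged = any_converged or bool(res.success)
        candidates.append((float(res.fun), np.clip(res.x, [b[0] for b in bounds],
                                                   [b[1] for b in bounds])))
        # keep the raw start too: L-BFGS-B can step off a narrow basin
        candidates.append((objective(start), start))

    best_sse = min(sse for sse, _ in candidates)
    tied = [(sse, th) for sse, th in candidates if sse <= best_sse + config.tolerance]

    def tie_key(item: tuple[float, np.ndarray]) -> tuple[float, ...]:
        kw = dict(zip(names, item[1]))
        return (kw.get("c", 0.0), kw.get("d", 0.0))

    _, theta_best = min(tied, key=tie_key)
    kw = dict(zip(names, (float(v) for v in theta_best)))
    sse, beta = _profile_sse(fam, x, y, kw.get("c"), kw.get("d"))
    params = _build_paramset(fam, beta, kw, sse, n)
    criteria = compute_criteria(sse, n, fam.k)
    return IndividualFit(
        subject_id=traj.subject_id,
        family=fam,
        params=params,
        criteria=criteria,
        sse=sse,
        converged=any_converged,
        n_starts_used=len(starts),
    )


def grid_oracle_fit(
    traj: SubjectTrajectory,
    family: "str | ModelFamily",
    grid_resolution: int = 200,
    config: Optional[FitConfig] = None,
) -> IndividualFit:
    """Exhaustive-grid profile fit: the independent verification oracle.

    Grids the nonlinear parameter(s) at ``grid_resolution`` points per axis
    and solves the linear coefficients exactly at every grid node via
    batched ridge-stabilized normal equations.
    """
    fam = get_family(family)
    config = config or FitConfig()
    x, y, n = traj.x, traj.y, traj.n
    if n < fam.k:
        raise ValueError(
            f"insufficient observations: subject {traj.subject_id} has "
            f"{n} points but family {fam.name} has k={fam.k} coefficients"
        )

    names = fam.nonlinear_names
    bounds = _nonlinear_bounds(fam, x, config)
    axes = [np.linspace(lo, hi, grid_resolution) for lo, hi in bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    thetas = np.column_stack([m.ravel() for m in mesh])  # (G, n_nl)
    G = thetas.shape[0]

    # batched design tensor (G, n, p)
    ones = np.ones(n)
    if fam.name == "P":
        dvals = thetas[:, 0][:, None]
        cols = [np.broadcast_to(ones, (G, n)), np.where(x > 0, x[None, :] ** dvals, 0.0)]
    elif fam.name == "D":
        z = np.maximum(x[None, :] - thetas[:, 0][:, None], 0.0)
        cols = [np.broadcast_to(ones, (G, n)), z]
    elif fam.name == "PD":
        c_idx, d_idx = names.index("c"), names.index("d")
        z = np.maximum(x[None, :] - thetas[:, c_idx][:, None], 0.0)
        with np.errstate(divide="ignore"):
            zd = np.where(z > 0, np.exp(thetas[:, d_idx][:, None] * np.log(
                np.where(z > 0, z, 1.0))), 0.0)
        cols = [np.broadcast_to(ones, (G, n)), zd]
    else:  # QD
        z = np.maximum(x[None, :] - thetas[:, 0][:, None], 0.0)
        cols = [np.broadcast_to(ones, (G, n)), z, z * z]
    X = np.stack(cols, axis=2)

    XtX = np.einsum("gnp,gnq->gpq", X, X)
    Xty = np.einsum("gnp,n->gp", X, y)
    p = X.shape[2]
    # tiny ridge on the slopes only: keeps the batch solvable where the
    # delayed/power columns degenerate and prefers zero slopes there
    penalty = np.eye(p)
    penalty[0, 0] = 0.0
    XtX = XtX + 1e-9 * penalty[None, :, :]
    beta = np.linalg.solve(XtX, Xty[..., None])[..., 0]
    resid = y[None, :] - np.einsum("gnp,gp->gn", X, beta)
    sses = np.einsum("gn,gn->g", resid, resid)

    best_sse = float(np.min(sses))
    tied = np.flatnonzero(sses <= best_sse + config.tolerance)
    order = np.lexsort(tuple(thetas[tied, i] for i in reversed(range(len(names)))))
    g = int(tied[order[0]])
    kw = dict(zip(names, (float(v) for v in thetas[g])))
    # re-solve without ridge for clean coefficients
    sse, beta_g = _profile_sse(fam, x, y, kw.get("c"), kw.get("d"))
    params = _build_paramset(fam, beta_g, kw, sse, n)
    return IndividualFit(
        subject_id=traj.subject_id,
        family=fam,
        params=params,
        criteria=compute_criteria(sse, n, fam.k),
        sse=sse,
        converged=True,
        n_starts_used=G,
        method=f"grid-{grid_resolution}",
    )


def compare_families(
    traj: SubjectTrajectory,
    config: Optional[FitConfig] = None,
    families: Iterable[str] = ("P", "D", "PD", "QD"),
) -> FamilyComparison:
    """Fit all requested families and flag the best by RMSE/AICc/BIC."""
    config = config or FitConfig()
    if traj.n < config.min_points:
        raise ValueError(
            f"subject {traj.subject_id} has {traj.n} < {config.min_points} points"
        )
    fits = {name: fit_individual(traj, name, config) for name in families}

    def best_by(attr: str) -> str:
        return min(fits, key=lambda f: getattr(fits[f].criteria, attr))

    return FamilyComparison(
        subject_id=traj.subject_id,
        fits=fits,
        best_rmse=best_by("rmse"),
        best_aicc=best_by("aicc"),
        best_bic=best_by("bic"),
    )


def fits_to_frame(fits: Iterable[IndividualFit]) -> pd.DataFrame:
    """Tidy one-row-per-(subject, family) frame of parameters and criteria."""
    rows = []
    for fit in fits:
        row = {"subject_id": fit.subject_id, "family": fit.family.name}
        row.update({k: v for k, v in fit.params.as_dict().items()})
        c = fit.criteria
        row.update(
            rmse=c.rmse, loglik=c.loglik, aic=c.aic, aicc=c.aicc, bic=c.bic,
            k=c.k, n=c.n, sse=fit.sse, converged=fit.converged,
            n_starts_used=fit.n_starts_used, method=fit.method,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_fits(
    fits: Iterable[IndividualFit],
    trajectories: Optional[Iterable[SubjectTrajectory]] = None,
    group_by: Optional[str] = None,
) -> pd.DataFrame:
    """Median and quartiles of each parameter and criterion per family.

    With ``trajectories`` given, the per-subject maximal rating is
    summarized too; ``group_by`` stratifies on a covariate column (``sex``,
    ``diagnosis``, or ``age_group`` with a split at 13 years).
    """
    frame = fits_to_frame(fits)
    if frame.empty:
        raise ValueError("no fits to summarize")

    cov_map: dict[str, dict] = {}
    max_ratings: dict[str, float] = {}
    if trajectories is not None:
        for t in trajectories:
            cov_map[t.subject_id] = dict(t.covariates)
            max_ratings[t.subject_id] = t.max_rating

    if group_by is not None:
        if trajectories is None:
            raise ValueError("group_by requires trajectories with covariates")
        if group_by == "age_group":
            frame["_group"] = frame["subject_id"].map(
                lambda s: "age<13" if cov_map.get(s, {}).get("age", np.nan) < 13
                else "age>=13"
            )
        else:
            frame["_group"] = frame["subject_id"].map(
                lambda s: cov_map.get(s, {}).get(group_by)
            )

    value_cols = ["a", "b1", "b2", "c", "d", "sigma2",
                  "rmse", "aicc", "bic"]
    rows = []
    group_levels = frame["_group"].dropna().unique() if group_by else [None]
    for level in group_levels:
        sub = frame if level is None else frame[frame["_group"] == level]
        for fam_name, fam_frame in sub.groupby("family"):
            for col in value_cols:
                vals = pd.to_numeric(fam_frame[col], errors="coerce").dropna()
                vals = vals[np.isfinite(vals)]
                if len(vals) == 0:
                    continue
                rows.append({
                    "group": level, "family": fam_name, "quantity": col,
                    "median": float(vals.median()),
                    "q1": float(vals.quantile(0.25)),
                    "q3": float(vals.quantile(0.75)),
                    "n": int(len(vals)),
                })
        if max_ratings:
            ids = sub["subject_id"].unique()
            mr = pd.Series([max_ratings[s] for s in ids if s in max_ratings])
            if len(mr):
                rows.append({
                    "group": level, "family": "(all)", "quantity": "max_rating",
                    "median": float(mr.median()),
                    "q1": float(mr.quantile(0.25)),
                    "q3": float(mr.quantile(0.75)),
                    "n": int(len(mr)),
                })
    out = pd.DataFrame(rows)
    if group_by is None and "group" in out:
        out = out.drop(columns=["group"])
    return out


def rmse_difference_analysis(
    comparisons: Mapping[str, FamilyComparison],
    trajectories: Mapping[str, SubjectTrajectory],
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    delay_family: str = "QD",
    loess_span: float = 0.75,
    min_distinct_ratings: int = 3,
    min_loess_points: int = 5,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Per-subject RMSE differences against the estimated delay, smoothed.

    Subjects whose ratings take fewer than ``min_distinct_ratings``
    distinct values are excluded.  Each returned frame has columns
    ``subject_id``, ``delay``, ``delta_rmse`` and, when enough points are
    available, a loess-smoothed ``smooth`` column (degree-1 local linear
    fit at span ``loess_span``).
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    retained = [
        sid for sid in comparisons
        if sid in trajectories
        and trajectories[sid].n_distinct_ratings >= min_distinct_ratings
    ]
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for fam_a, fam_b in pairs:
        rows = []
        for sid in retained:
            comp = comparisons[sid]
            delay = comp.fits[delay_family].params.c
            rows.append({
                "subject_id": sid,
                "delay": delay,
                "delta_rmse": comp.fits[fam_a].criteria.rmse
                - comp.fits[fam_b].criteria.rmse,
            })
        frame = pd.DataFrame(rows).sort_values("delay").reset_index(drop=True)
        if len(frame) >= min_loess_points:
            sm = lowess(frame["delta_rmse"], frame["delay"],
                        frac=loess_span, return_sorted=False)
            frame["smooth"] = sm
        else:
            warnings.warn(
                f"pair {fam_a}-{fam_b}: {len(frame)} points < "
                f"{min_loess_points}; loess smoother skipped"
            )
        out[(fam_a, fam_b)] = frame
    return out
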