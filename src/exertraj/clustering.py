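"""Functional clustering of rating trajectories.

Trajectories are projected onto a common B-spline basis on [0, 1] with a
P-spline second-difference penalty (plus a vanishing ridge), so short
trajectories with fewer points than basis functions remain representable
and coefficients outside the observed x-range are extrapolated smoothly
rather than shrunk to zero.  The coefficient vectors are clustered with a
Gaussian mixture; the number of clusters is either fixed or chosen by BIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from sklearn.mixture import GaussianMixture

from .core import SubjectTrajectory

__all__ = [
    "SplineBasis",
    "ClusterModel",
    "ClusterAssignment",
    "represent_trajectories",
    "cluster_trajectories",
    "describe_clusters",
]


@dataclass(frozen=True)
class SplineBasis:
    """B-spline basis on [0, 1] with equally spaced interior knots."""

    degree: int = 3
    n_interior: int = 5

    @property
    def knots(self) -> np.ndarray:
        interior = np.linspace(0.0, 1.0, self.n_interior + 2)[1:-1]
        return np.concatenate([
            np.zeros(self.degree + 1), interior, np.ones(self.degree + 1),
        ])

    @property
    def dim(self) -> int:
        return self.n_interior + self.degree + 1

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        # clip the right endpoint into the half-open support
        x = np.clip(x, 0.0, 1.0 - 1e-12)
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()

    def evaluate(self, coefficients: np.ndarray, x: np.ndarray) -> np.ndarray:
        return self.design(x) @ np.asarray(coefficients, dtype=float)


@dataclass
class ClusterModel:
    basis: SplineBasis
    n_clusters: int
    cluster_means: np.ndarray           # (K, basis.dim) coefficient vectors
    assignment_probabilities: pd.DataFrame  # subjects x K, rows sum to 1
    covariance_type: str
    bic: float

    def mean_curves(self, grid: Optional[np.ndarray] = None) -> pd.DataFrame:
        """Cluster mean curves evaluated on a grid of work fractions."""
        if grid is None:
            grid = np.linspace(0.0, 1.0, 101)
        rows = []
        for k in range(self.n_clusters):
            vals = self.basis.evaluate(self.cluster_means[k], grid)
            for x, y in zip(grid, vals):
                rows.append({"cluster": k, "x": float(x), "mean_rating": float(y)})
        return pd.DataFrame(rows)


@dataclass
class ClusterAssignment:
    labels: dict[str, int]
    sizes: dict[int, int]

    @property
    def n_subjects(self) -> int:
        return sum(self.sizes.values())


def represent_trajectories(
    cohort: Sequence[SubjectTrajectory],
    basis: Optional[SplineBasis] = None,
    ridge: float = 1e-6,
) -> tuple[np.ndarray, list[str], SplineBasis]:
    """Project each trajectory onto the common basis.

    Returns ``(coefficients, subject_ids, basis)`` where coefficients has
    one row per subject.  The ridge penalty keeps the projection defined
    when a subject has fewer points than basis functions.
    """
    basis = basis or SplineBasis()
    # second-difference (P-spline) roughness penalty: constants and linear
    # coefficient trends are unpenalized, so flat trajectories project
    # exactly and edge coefficients extrapolate instead of collapsing
    d2 = np.diff(np.eye(basis.dim), n=2, axis=0)
    roughness = d2.T @ d2
    coefs, ids = [], []
    for traj in cohort:
        if traj.n < 2:
            raise ValueError(
                f"subject {traj.subject_id}: need at least 2 points to project"
            )
        B = basis.design(traj.x)
        A = B.T @ B + ridge * roughness + 1e-13 * np.eye(basis.dim)
        coefs.append(np.linalg.solve(A, B.T @ traj.y))
        ids.append(traj.subject_id)
    return np.vstack(coefs), ids, basis


def _fit_gmm(feats: np.ndarray, k: int, covariance_type: str,
             seed: int) -> GaussianMixture:
    # reg_covar floors per-dimension variance at (0.22 rating units)^2:
    # subjects with fewer points than basis dimensions give degenerate
    # feature densities that otherwise inflate the likelihood without bound
    return GaussianMixture(
        n_components=k,
        covariance_type=covariance_type,
        random_state=seed,
        n_init=10,
        reg_covar=0.05,
        max_iter=500,
    ).fit(feats)


def cluster_trajectories(
    coefficients: np.ndarray,
    subject_ids: Sequence[str],
    basis: SplineBasis,
    k: "int | str" = "auto",
    seed: int = 0,
    covariance_type: str = "full",
    k_range: tuple[int, int] = (1, 12),
    feature_grid: Optional[np.ndarray] = None,
) -> tuple[ClusterModel, ClusterAssignment]:
    """Gaussian-mixture clustering of trajectory shapes.

    The mixture is fit on each subject's smoothed curve evaluated at
    ``feature_grid`` (default: 8 equispaced work fractions from 1/12 to 1,
    inside every subject's observed range) — a fixed linear map of the
    basis coefficients that avoids the wildly extrapolated left-edge
    coefficients of short trajectories.  ``k="auto"`` selects the cluster
    count in ``k_range`` by BIC.  The fit is made order-invariant by
    training on a canonically (lexicographically) sorted copy of the
    feature matrix; final labels are renumbered by descending cluster
    size, and empty clusters are compacted away.
    """
    coefs = np.asarray(coefficients, dtype=float)
    n = coefs.shape[0]
    if len(subject_ids) != n:
        raise ValueError("subject_ids and coefficient rows disagree")
    if isinstance(k, int) and k > n:
        raise ValueError(f"requested {k} clusters for {n} subjects")

    if feature_grid is None:
        feature_grid = np.linspace(1.0 / 12.0, 1.0, 8)
    feats = coefs @ basis.design(np.asarray(feature_grid, dtype=float)).T
    canon = feats[np.lexsort(feats.T[::-1])]
    ks = range(k_range[0], min(k_range[1], n) + 1) if k == "auto" else [int(k)]
    best: tuple[float, GaussianMixture, str] | None = None
    for kk in ks:
        for cov in (covariance_type, "diag"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    gm = _fit_gmm(canon, kk, cov, seed)
            except Exception:
                if cov == covariance_type and covariance_type != "diag":
                    warnings.warn(
                        f"k={kk}: {covariance_type}-covariance fit failed; "
                        "falling back to diagonal"
                    )
                    continue
                raise
            bic = gm.bic(canon)
            if best is None or bic < best[0] - 1e-9:
                best = (bic, gm, cov)
            break  # only fall through to diag on failure
    assert best is not None
    bic, gm, cov_used = best

    probs = gm.predict_proba(feats)
    raw_labels = np.argmax(probs, axis=1)

    # renumber by descending size (ties: original component order), drop empties
    counts = np.bincount(raw_labels, minlength=gm.n_components)
    order = sorted(range(gm.n_components), key=lambda j: (-counts[j], j))
    occupied = [j for j in order if counts[j] > 0]
    relabel = {old: new for new, old in enumerate(occupied)}
    labels = {sid: relabel[l] for sid, l in zip(subject_ids, raw_labels)}
    # cluster mean curves: average member coefficient vectors
    means = np.vstack([coefs[raw_labels == j].mean(axis=0) for j in occupied])
    probs_df = pd.DataFrame(
        probs[:, occupied],
        index=list(subject_ids),
        columns=[f"cluster_{j}" for j in range(len(occupied))],
    )
    sizes = {relabel[j]: int(counts[j]) for j in occupied}
    model = ClusterModel(
        basis=basis,
        n_clusters=len(occupied),
        cluster_means=means,
        assignment_probabilities=probs_df,
        covariance_type=cov_used,
        bic=float(bic),
    )
    return model, ClusterAssignment(labels=labels, sizes=sizes)


def describe_clusters(
    assignment: ClusterAssignment,
    covariates: Mapping[str, Mapping[str, object]],
    age_cut: float = 13.0,
) -> pd.DataFrame:
    """Per-cluster composition: counts and percentages of male, age<cut,
    and each diagnosis.  Percentages are over subjects with the covariate
    non-missing."""
    rows = []
    diagnoses = sorted({
        str(cov.get("diagnosis")) for cov in covariates.values()
        if cov.get("diagnosis") is not None
    })
    for cluster in sorted(assignment.sizes):
        members = [sid for sid, l in assignment.labels.items() if l == cluster]
        row: dict[str, object] = {"cluster": cluster, "n": len(members)}

        sexes = [covariates.get(s, {}).get("sex") for s in members]
        known = [v for v in sexes if v is not None]
        n_male = sum(1 for v in known if v == "male")
        row["male_n"] = n_male
        row["male_pct"] = 100.0 * n_male / len(known) if known else np.nan

        ages = [covariates.get(s, {}).get("age") for s in members]
        known_age = [v for v in ages if v is not None]
        n_young = sum(1 for v in known_age if float(v) < age_cut)
        row["age_lt13_n"] = n_young
        row["age_lt13_pct"] = (
            100.0 * n_young / len(known_age) if known_age else np.nan
        )

        diags = [covariates.get(s, {}).get("diagnosis") for s in members]
        known_d = [v for v in diags if v is not None]
        for diag in diagnoses:
            n_d = sum(1 for v in known_d if v == diag)
            row[f"{diag}_n"] = n_d
            row[f"{diag}_pct"] = 100.0 * n_d / len(known_d) if known_d else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
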