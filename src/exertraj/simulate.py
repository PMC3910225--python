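"""Synthetic cohorts with known ground truth.

Each subject is drawn from a trajectory archetype (a model family plus
per-parameter distributions), rated at equally spaced work increments
ending at the individual maximum (x_j = j/n), with Gaussian rating noise,
optional truncation to the 0-10 scale, and optional snapping to the legal
Borg values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import ParamSet, SubjectTrajectory, get_family, predict_rating

__all__ = [
    "Dist",
    "Archetype",
    "CohortConfig",
    "SyntheticCohort",
    "FilterReport",
    "default_archetypes",
    "generate_cohort",
    "filter_min_points",
    "recovery_experiment",
    "BORG_VALUES",
]

# printed anchors of the category-ratio scale: 0, 0.5, then integers to 10
BORG_VALUES = np.array([0.0, 0.5] + [float(v) for v in range(1, 11)])


@dataclass(frozen=True)
class Dist:
    """Scalar distribution spec: point mass, uniform, or (truncated) normal."""

    kind: str  # "point" | "uniform" | "normal"
    args: tuple[float, ...]
    bounds: Optional[tuple[float, float]] = None

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "point":
            return float(self.args[0])
        if self.kind == "uniform":
            lo, hi = self.args
            return float(rng.uniform(lo, hi))
        if self.kind == "normal":
            mean, sd = self.args
            if self.bounds is None:
                return float(rng.normal(mean, sd))
            lo, hi = self.bounds
            for _ in range(10_000):
                v = float(rng.normal(mean, sd))
                if lo < v < hi:
                    return v
            raise RuntimeError("truncated-normal rejection sampler stalled")
        raise ValueError(f"unknown distribution kind {self.kind!r}")

    @property
    def support_min(self) -> float:
        if self.kind == "point":
            return self.args[0]
        if self.kind == "uniform":
            return self.args[0]
        return self.bounds[0] if self.bounds else -np.inf


@dataclass(frozen=True)
class Archetype:
    """A trajectory shape: family plus parameter distributions and weight."""

    name: str
    family: str
    params: dict[str, Dist]
    weight: float = 1.0

    def validate(self) -> None:
        fam = get_family(self.family)
        missing = [p for p in fam.parameter_names if p not in self.params]
        if missing:
            raise ValueError(f"archetype {self.name}: missing params {missing}")
        if "c" in self.params and self.params["c"].support_min <= 0:
            raise ValueError(
                f"archetype {self.name}: delay c may be sampled <= 0"
            )
        if "d" in self.params and self.params["d"].support_min < 0:
            raise ValueError(
                f"archetype {self.name}: exponent d may be sampled < 0"
            )


def default_archetypes(
    delay: Dist = Dist("normal", (0.40, 0.10), bounds=(0.1, 0.7)),
) -> list[Archetype]:
    """Study-like archetype suite covering the major trajectory patterns."""
    a = Dist("uniform", (0.0, 0.6))
    return [
        Archetype("steep_linear", "D",
                  {"a": a, "b1": Dist("uniform", (8.0, 12.0)), "c": delay},
                  weight=0.2),
        Archetype("shallow_linear", "D",
                  {"a": a, "b1": Dist("uniform", (2.0, 5.0)), "c": delay},
                  weight=0.2),
        Archetype("quadratic_rise", "QD",
                  {"a": a, "b1": Dist("uniform", (1.0, 4.0)),
                   "b2": Dist("uniform", (4.0, 9.0)), "c": delay},
                  weight=0.2),
        Archetype("delayed_power", "PD",
                  {"a": a, "b2": Dist("uniform", (6.0, 12.0)),
                   "c": delay, "d": Dist("uniform", (0.8, 1.8))},
                  weight=0.2),
        Archetype("plateau", "QD",
                  {"a": a, "b1": Dist("uniform", (12.0, 20.0)),
                   "b2": Dist("uniform", (-25.0, -10.0)), "c": delay},
                  weight=0.2),
    ]


@dataclass
class CohortConfig:
    n_subjects: int = 79
    points_range: tuple[int, int] = (6, 12)
    noise_sd: float = 0.25
    archetypes: list[Archetype] = field(default_factory=default_archetypes)
    round_to_borg: bool = False
    truncate: bool = True
    sex_male_freq: float = 0.58
    age_range: tuple[int, int] = (8, 18)
    diagnosis_freqs: dict[str, float] = field(default_factory=lambda: {
        "healthy": 32 / 79, "asthma": 26 / 79, "cystic_fibrosis": 21 / 79,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        if self.points_range[0] < 2:
            raise ValueError("min_points must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        total = sum(a.weight for a in self.archetypes)
        if not np.isclose(total, 1.0):
            raise ValueError(f"archetype weights sum to {total}, expected 1")
        freq_sum = sum(self.diagnosis_freqs.values())
        if not np.isclose(freq_sum, 1.0):
            raise ValueError("diagnosis frequencies must sum to 1")
        for arch in self.archetypes:
            arch.validate()


@dataclass
class SyntheticCohort:
    trajectories: list[SubjectTrajectory]
    truth: pd.DataFrame  # subject_id, archetype, family, a, b1, b2, c, d, sigma
    config: CohortConfig

    @property
    def n_subjects(self) -> int:
        return len(self.trajectories)


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    excluded: list[tuple[str, str]]  # (subject_id, reason)


def _snap_to_borg(y: np.ndarray) -> np.ndarray:
    idx = np.argmin(np.abs(y[:, None] - BORG_VALUES[None, :]), axis=1)
    return BORG_VALUES[idx]


def generate_cohort(
    config: CohortConfig, noise_seed: Optional[int] = None
) -> SyntheticCohort:
    """Draw a cohort; reproducible from ``config.seed``.

    Parameter draws and noise draws use independent sub-streams, so
    overriding ``noise_seed`` re-noises the same true curves.
    """
    ss = np.random.SeedSequence(config.seed)
    param_ss, noise_ss, cov_ss = ss.spawn(3)
    param_rng = np.random.default_rng(param_ss)
    noise_rng = np.random.default_rng(
        noise_seed if noise_seed is not None else noise_ss
    )
    cov_rng = np.random.default_rng(cov_ss)

    weights = np.array([a.weight for a in config.archetypes])
    diag_names = list(config.diagnosis_freqs)
    diag_probs = np.array([config.diagnosis_freqs[k] for k in diag_names])

    trajectories: list[SubjectTrajectory] = []
    truth_rows = []
    lo, hi = config.points_range
    for i in range(config.n_subjects):
        sid = f"S{i + 1:04d}"
        arch = config.archetypes[param_rng.choice(len(weights), p=weights)]
        values = {name: dist.sample(param_rng) for name, dist in arch.params.items()}
        if values.get("c") is not None and values["c"] <= 0:
            raise ValueError(f"archetype {arch.name} sampled delay c <= 0")
        params = ParamSet(**values)
        n_i = int(param_rng.integers(lo, hi + 1))
        x = np.arange(1, n_i + 1) / n_i
        y = np.asarray(predict_rating(arch.family, params, x), dtype=float)
        y = y + noise_rng.normal(0.0, config.noise_sd, size=n_i)
        if config.truncate:
            y = np.clip(y, 0.0, 10.0)
        if config.round_to_borg:
            y = _snap_to_borg(y)
        covariates = {
            "sex": "male" if cov_rng.uniform() < config.sex_male_freq else "female",
            "age": int(cov_rng.integers(config.age_range[0], config.age_range[1] + 1)),
            "diagnosis": diag_names[cov_rng.choice(len(diag_probs), p=diag_probs)],
        }
        # without truncation noisy ratings may stray off the 0-10 scale
        trajectories.append(SubjectTrajectory(sid, x, y, covariates,
                                              validate_range=config.truncate))
        truth_rows.append({
            "subject_id": sid, "archetype": arch.name, "family": arch.family,
            **{k: values.get(k) for k in ("a", "b1", "b2", "c", "d")},
            "sigma": config.noise_sd,
        })
    return SyntheticCohort(trajectories, pd.DataFrame(truth_rows), config)


def filter_min_points(
    cohort: "SyntheticCohort | Sequence[SubjectTrajectory]",
    min_points: int = 6,
) -> "tuple[SyntheticCohort | list[SubjectTrajectory], FilterReport]":
    """Retain subjects with at least ``min_points`` observations."""
    if min_points < 2:
        raise ValueError("min_points must be >= 2")
    if isinstance(cohort, SyntheticCohort):
        trajs = cohort.trajectories
    else:
        trajs = list(cohort)
    kept, excluded = [], []
    for t in trajs:
        if t.n >= min_points:
            kept.append(t)
        else:
            excluded.append((t.subject_id, f"{t.n} < {min_points} data points"))
    report = FilterReport(n_input=len(trajs), n_retained=len(kept),
                          excluded=excluded)
    if not kept:
        import warnings

        warnings.warn("min-points filter excluded every subject")
    if isinstance(cohort, SyntheticCohort):
        kept_ids = {t.subject_id for t in kept}
        truth = cohort.truth[cohort.truth["subject_id"].isin(kept_ids)]
        return SyntheticCohort(kept, truth.reset_index(drop=True),
                               cohort.config), report
    return kept, report


def recovery_experiment(
    config: CohortConfig,
    families: Iterable[str],
    n_replicates: int = 5,
    seed: int = 0,
    fit_config=None,
) -> pd.DataFrame:
    """Bias/RMSE of the per-subject estimators against stored truth.

    For each replicate a fresh cohort is generated; every requested family
    is fitted to the subjects whose true family matches it.  Fit failures
    are counted, not fatal.
    """
    from .fitting import FitConfig, fit_individual

    fit_config = fit_config or FitConfig()
    families = list(families)
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_replicates)]

    records = []
    n_failures = 0
    for rep, rep_seed in enumerate(rep_seeds):
        cohort = generate_cohort(replace(config, seed=rep_seed))
        truth = cohort.truth.set_index("subject_id")
        for traj in cohort.trajectories:
            true_row = truth.loc[traj.subject_id]
            if true_row["family"] not in families:
                continue
            try:
                fit = fit_individual(traj, true_row["family"], fit_config)
            except Exception:
                n_failures += 1
                continue
            fam = get_family(true_row["family"])
            for pname in fam.parameter_names:
                records.append({
                    "replicate": rep, "family": fam.name, "parameter": pname,
                    "true": float(true_row[pname]),
                    "estimated": float(getattr(fit.params, pname)),
                })
    frame = pd.DataFrame(records)
    if frame.empty:
        raise ValueError("no subjects matched the requested families")
    frame["error"] = frame["estimated"] - frame["true"]
    out = (
        frame.groupby(["family", "parameter"])
        .agg(
            bias=("error", "mean"),
            rmse=("error", lambda e: float(np.sqrt(np.mean(np.square(e))))),
            median_abs_error=("error", lambda e: float(np.median(np.abs(e)))),
            n_fits=("error", "size"),
        )
        .reset_index()
    )
    out["n_failures"] = n_failures
    return out
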