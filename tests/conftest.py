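import numpy as np
import pytest

from exertraj.core import ParamSet, SubjectTrajectory, predict_rating
from exertraj.simulate import Archetype, CohortConfig, Dist, generate_cohort

X12 = np.arange(1, 13) / 12

# reference worked-example curves: a long-delay plateau subject (QD and PD
# parameterizations) and a long-delay power-model subject
QD_EXAMPLE = ParamSet(a=0.5, b1=30.31, b2=-22.35, c=0.46)
PD_EXAMPLE = ParamSet(a=0.4, b2=16.7, c=0.40, d=0.9)
P_EXAMPLE = ParamSet(a=-0.1, b2=4.2, d=4.7)


def noiseless_trajectory(family: str, params: ParamSet,
                         x: np.ndarray = X12,
                         subject_id: str = "fixture") -> SubjectTrajectory:
    y = np.asarray(predict_rating(family, params, x), dtype=float)
    return SubjectTrajectory(subject_id, x, y, validate_range=False)


@pytest.fixture
def qd_example_traj() -> SubjectTrajectory:
    return noiseless_trajectory("QD", QD_EXAMPLE, subject_id="qd-example")


@pytest.fixture
def pd_example_traj() -> SubjectTrajectory:
    return noiseless_trajectory("PD", PD_EXAMPLE, subject_id="pd-example")


@pytest.fixture
def p_example_traj() -> SubjectTrajectory:
    return noiseless_trajectory("P", P_EXAMPLE, subject_id="p-example")


def mqd_archetype(c: float = 0.35, tau2: float = 0.3,
                  b1: float = 5.0, b2: float = 3.0) -> Archetype:
    """Common-delay quadratic truth: random intercept a_i ~ N(0.5, tau2)."""
    return Archetype("mqd", "QD", {
        "a": Dist("normal", (0.5, float(np.sqrt(tau2)))),
        "b1": Dist("point", (b1,)),
        "b2": Dist("point", (b2,)),
        "c": Dist("point", (c,)),
    })


def recovery_qd_archetype() -> Archetype:
    """Delay-recovery harness regime: quadratic-delay curves whose kink
    slope b1 spans the pooled-analysis quartiles (~3-12), so the delay is
    statistically identifiable at sigma = 0.25."""
    return Archetype("quad", "QD", {
        "a": Dist("uniform", (0.0, 0.5)),
        "b1": Dist("uniform", (4.0, 12.0)),
        "b2": Dist("uniform", (3.0, 8.0)),
        "c": Dist("normal", (0.4, 0.1), bounds=(0.15, 0.65)),
    })


def mqdv_archetype(c_mean: float = 0.4, c_sd: float = 0.15) -> Archetype:
    """Varying-delay quadratic truth."""
    return Archetype("mqdv", "QD", {
        "a": Dist("normal", (0.5, float(np.sqrt(0.3)))),
        "b1": Dist("point", (5.0,)),
        "b2": Dist("point", (3.0,)),
        "c": Dist("normal", (c_mean, c_sd), bounds=(0.13, 0.85)),
    })


@pytest.fixture
def mqd_cohort():
    config = CohortConfig(
        n_subjects=30, points_range=(8, 12), noise_sd=0.25,
        archetypes=[mqd_archetype()], truncate=False, seed=42,
    )
    return generate_cohort(config)


@pytest.fixture
def small_cohort():
    config = CohortConfig(n_subjects=12, points_range=(6, 12),
                          noise_sd=0.25, seed=3)
    return generate_cohort(config)
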