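"""Bayesian nonlinear mixed-effects models with a common or subject-varying delay.

Four variants share the structure

    y_ij = a + f(max(x_ij - c_i, 0)) + u_i + eps_ij

with f quadratic (``MQD``/``MQDV``: b1*z + b2*z^2) or a power term
(``MPD``/``MPDV``: b2*z^d), a common delay (``MQD``/``MPD``: c_i = c) or a
random one (``MQDV``/``MPDV``: c_i = c + gamma_i, gamma_i ~ N(0, nu2)),
u_i ~ N(0, tau2) random intercepts and eps_ij ~ N(0, sigma2).

Estimation is Gibbs-within-Metropolis: conjugate Gaussian block updates
for the fixed linear coefficients and the random intercepts, conjugate
inverse-gamma updates for the variances, and random-walk Metropolis for
the delay, the exponent, and each gamma_i under their box constraints.
An interweaving (recentering) step keeps the intercept/random-intercept
and delay/random-delay pairs mixing.  Convergence is assessed with the
Gelman-Rubin potential scale reduction factor and models are compared by
the complete-likelihood deviance information criterion.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import SubjectTrajectory

logger = logging.getLogger(__name__)

__all__ = [
    "VARIANTS",
    "McmcConfig",
    "MixedFitResult",
    "fit_mixed",
    "psrf",
    "compute_dic",
    "summarize_posterior",
]

VARIANTS = ("MPD", "MQD", "MPDV", "MQDV")

_LOG2PI = math.log(2.0 * math.pi)
_VAR_FLOOR = 1e-12
_VAR_CEIL = 1e12


@dataclass
class McmcConfig:
    n_chains: int = 3
    n_iterations: int = 10_000      # convergence (burn-in) run length
    n_post: int = 1_000             # post-convergence iterations
    thin: int = 10
    seed: int = 0
    proposal_sd: dict[str, float] = field(
        default_factory=lambda: {"c": 0.05, "d": 0.2, "gamma": 0.08}
    )
    beta_prior_var: float = 1e3
    ig_shape: float = 0.01
    ig_rate: float = 0.01
    d_max: float = 10.0
    psrf_threshold: float = 1.2
    tune: bool = True
    likelihood_weight: float = 1.0  # 0 switches the likelihood off (prior checks)
    monitor_random_effects: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if self.n_post % self.thin != 0:
            raise ValueError("thin must divide n_post")
        if any(v <= 0 for v in self.proposal_sd.values()):
            raise ValueError("proposal standard deviations must be positive")

    @property
    def n_retained(self) -> int:
        return self.n_chains * (self.n_post // self.thin)


@dataclass
class MixedFitResult:
    variant: str
    samples: pd.DataFrame          # chain, draw, one column per parameter
    psrf: dict[str, float]
    max_psrf: float
    converged: bool
    dic: float
    p_dic: float
    acceptance_rates: dict[str, float]
    posterior_summary: pd.DataFrame
    config: McmcConfig
    n_subjects: int

    @property
    def n_retained(self) -> int:
        return len(self.samples)


class _VariantSpec:
    def __init__(self, variant: str):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
        self.name = variant
        self.quadratic = variant in ("MQD", "MQDV")
        self.varying = variant.endswith("V")
        # fixed linear coefficients entering the design
        self.beta_names = ("a", "b1", "b2") if self.quadratic else ("a", "b2")


class _Data:
    """Flattened cohort arrays with per-subject bookkeeping."""

    def __init__(self, cohort: Sequence[SubjectTrajectory]):
        trajs = list(cohort)
        if len(trajs) < 2:
            raise ValueError("mixed models need at least 2 subjects")
        self.subject_ids = [t.subject_id for t in trajs]
        self.m = len(trajs)
        self.x = np.concatenate([t.x for t in trajs])
        self.y = np.concatenate([t.y for t in trajs])
        self.idx = np.concatenate(
            [np.full(t.n, i, dtype=np.intp) for i, t in enumerate(trajs)]
        )
        self.n_i = np.array([t.n for t in trajs], dtype=float)
        self.N = len(self.x)
        self.sub_xmin = np.array([t.x[0] for t in trajs])
        self.sub_xmax = np.array([t.x[-1] for t in trajs])
        self.box = (float(self.x.min()), float(self.x.max()))


def _safe_pow(z: np.ndarray, d: float) -> np.ndarray:
    """z**d with the delayed-term convention 0 for z <= 0, any d >= 0."""
    return np.where(z > 0.0, np.power(z, d, where=z > 0.0, out=np.zeros_like(z)), 0.0)


def _design(spec: _VariantSpec, data: _Data, c: float,
            gamma: Optional[np.ndarray], d: float) -> np.ndarray:
    ci = c + gamma[data.idx] if spec.varying else c
    z = np.maximum(data.x - ci, 0.0)
    if spec.quadratic:
        return np.column_stack([np.ones(data.N), z, z * z])
    return np.column_stack([np.ones(data.N), _safe_pow(z, d)])


def _mu(spec: _VariantSpec, data: _Data, beta: np.ndarray, c: float,
        gamma: Optional[np.ndarray], d: float) -> np.ndarray:
    return _design(spec, data, c, gamma, d) @ beta


class _ChainState:
    __slots__ = ("beta", "u", "gamma", "c", "d", "sigma2", "tau2", "nu2")

    def __init__(self, beta, u, gamma, c, d, sigma2, tau2, nu2):
        self.beta, self.u, self.gamma = beta, u, gamma
        self.c, self.d = c, d
        self.sigma2, self.tau2, self.nu2 = sigma2, tau2, nu2


def _monitor_names(spec: _VariantSpec, data: _Data) -> list[str]:
    """All stored parameters; random effects are always stored (DIC needs
    them), the ``monitor_random_effects`` flag only gates their PSRF."""
    names = list(spec.beta_names)
    if not spec.quadratic:
        names.append("d")
    names += ["c", "sigma2", "tau2"]
    if spec.varying:
        names.append("nu2")
    names += [f"u[{sid}]" for sid in data.subject_ids]
    if spec.varying:
        names += [f"gamma[{sid}]" for sid in data.subject_ids]
    return names


def _state_vector(spec: _VariantSpec, state: _ChainState) -> np.ndarray:
    parts = [state.beta]
    if not spec.quadratic:
        parts.append([state.d])
    parts.append([state.c, state.sigma2, state.tau2])
    if spec.varying:
        parts.append([state.nu2])
    parts.append(state.u)
    if spec.varying:
        parts.append(state.gamma)
    return np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in parts])


def _init_state(spec: _VariantSpec, data: _Data, cfg: McmcConfig,
                rng: np.random.Generator) -> _ChainState:
    """Overdispersed initial values for one chain."""
    p = len(spec.beta_names)
    y_var = float(np.var(data.y)) or 1.0
    beta = rng.normal(0.0, 1.0, size=p)
    beta[0] = float(np.mean(data.y)) + rng.normal(0.0, 1.0)
    c = float(rng.uniform(*data.box))
    d = float(rng.uniform(0.5, 3.0))
    gamma = np.zeros(data.m) if spec.varying else None
    if spec.varying:
        # keep c_i inside each subject's box at start
        c = float(np.clip(c, data.sub_xmin.max(), data.sub_xmax.min()))
    return _ChainState(
        beta=beta,
        u=np.zeros(data.m),
        gamma=gamma,
        c=c,
        d=d,
        sigma2=float(y_var * rng.uniform(0.3, 3.0)),
        tau2=float(y_var * rng.uniform(0.1, 1.0)),
        nu2=float(rng.uniform(0.005, 0.05)),
    )


def _draw_invgamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    g = rng.gamma(shape, 1.0 / rate)
    return float(np.clip(1.0 / max(g, 1.0 / _VAR_CEIL), _VAR_FLOOR, _VAR_CEIL))


def _iterate(
    spec: _VariantSpec,
    data: _Data,
    cfg: McmcConfig,
    state: _ChainState,
    rng: np.random.Generator,
    prop: dict[str, float],
    accept_counts: dict[str, float],
) -> None:
    """One full Gibbs-within-Metropolis sweep, updating ``state`` in place."""
    lw = cfg.likelihood_weight
    a0, b0 = cfg.ig_shape, cfg.ig_rate
    V0 = cfg.beta_prior_var

    X = _design(spec, data, state.c, state.gamma, state.d)
    p = X.shape[1]

    # --- fixed linear coefficients: conjugate Gaussian block
    r = data.y - state.u[data.idx]
    prec = lw * (X.T @ X) / state.sigma2 + np.eye(p) / V0
    rhs = lw * (X.T @ r) / state.sigma2
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, rhs)
    state.beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))

    # --- random intercepts: conjugate Gaussian, vectorized over subjects
    mu_fix = X @ state.beta
    e = data.y - mu_fix
    s_i = np.bincount(data.idx, weights=e, minlength=data.m)
    var_i = 1.0 / (lw * data.n_i / state.sigma2 + 1.0 / state.tau2)
    mean_i = var_i * lw * s_i / state.sigma2
    state.u = mean_i + np.sqrt(var_i) * rng.standard_normal(data.m)

    # --- interweaving: shift between the intercept and the random intercepts
    # (a, u) -> (a + delta, u - delta) leaves a + u_i, hence the likelihood,
    # unchanged; delta is Gibbs-sampled from the priors' conditional
    u_pre = state.u.copy()
    prec_shift = 1.0 / V0 + data.m / state.tau2
    mean_shift = (-state.beta[0] / V0 + np.sum(state.u) / state.tau2) / prec_shift
    delta = mean_shift + rng.standard_normal() / math.sqrt(prec_shift)
    state.beta[0] += delta
    state.u -= delta

    # --- variances: conjugate inverse-gamma
    # residuals are invariant under the shift: y - (mu_fix + delta) - (u - delta)
    resid = e - u_pre[data.idx]
    sse = float(resid @ resid)
    state.sigma2 = _draw_invgamma(rng, a0 + lw * data.N / 2.0,
                                  b0 + lw * sse / 2.0)
    state.tau2 = _draw_invgamma(rng, a0 + data.m / 2.0,
                                b0 + float(state.u @ state.u) / 2.0)
    if spec.varying:
        state.nu2 = _draw_invgamma(rng, a0 + data.m / 2.0,
                                   b0 + float(state.gamma @ state.gamma) / 2.0)

    # --- random delays gamma_i: vectorized single-site Metropolis
    if spec.varying:
        mu_cur = _mu(spec, data, state.beta, state.c, state.gamma, state.d)
        e_cur = data.y - mu_cur - state.u[data.idx]
        sse_i = np.bincount(data.idx, weights=e_cur * e_cur, minlength=data.m)
        gamma_prop = state.gamma + prop["gamma"] * rng.standard_normal(data.m)
        ci_prop = state.c + gamma_prop
        valid = (ci_prop >= data.sub_xmin) & (ci_prop <= data.sub_xmax)
        mu_prop = _mu(spec, data, state.beta, state.c, gamma_prop, state.d)
        e_prop = data.y - mu_prop - state.u[data.idx]
        sse_i_prop = np.bincount(data.idx, weights=e_prop * e_prop,
                                 minlength=data.m)
        log_alpha = (
            -lw * (sse_i_prop - sse_i) / (2.0 * state.sigma2)
            - (gamma_prop**2 - state.gamma**2) / (2.0 * state.nu2)
        )
        accept = valid & (np.log(rng.uniform(size=data.m)) < log_alpha)
        state.gamma = np.where(accept, gamma_prop, state.gamma)
        accept_counts["gamma"] += float(np.mean(accept))

        # interweaving: shift between the common delay and the gamma_i
        g_mean = float(np.mean(state.gamma))
        for _ in range(20):
            delta = rng.normal(g_mean, math.sqrt(state.nu2 / data.m))
            c_new = state.c + delta
            if (data.box[0] <= c_new <= data.box[1]
                    and np.all(c_new + state.gamma - delta >= data.sub_xmin)
                    and np.all(c_new + state.gamma - delta <= data.sub_xmax)):
                state.c = c_new
                state.gamma = state.gamma - delta
                break

    # --- common delay c: random-walk Metropolis, uniform prior on the box
    mu_cur = _mu(spec, data, state.beta, state.c, state.gamma, state.d)
    e_cur = data.y - mu_cur - state.u[data.idx]
    sse_cur = float(e_cur @ e_cur)
    c_prop = state.c + prop["c"] * rng.standard_normal()
    ok = data.box[0] <= c_prop <= data.box[1]
    if ok and spec.varying:
        ci = c_prop + state.gamma
        ok = bool(np.all((ci >= data.sub_xmin) & (ci <= data.sub_xmax)))
    if ok:
        mu_prop = _mu(spec, data, state.beta, c_prop, state.gamma, state.d)
        e_prop = data.y - mu_prop - state.u[data.idx]
        sse_prop = float(e_prop @ e_prop)
        if math.log(rng.uniform()) < -lw * (sse_prop - sse_cur) / (2.0 * state.sigma2):
            state.c = c_prop
            sse_cur = sse_prop
            accept_counts["c"] += 1.0

    # --- exponent d (power variants): random-walk Metropolis
    if not spec.quadratic:
        d_prop = state.d + prop["d"] * rng.standard_normal()
        if 0.0 < d_prop <= cfg.d_max:
            mu_prop = _mu(spec, data, state.beta, state.c, state.gamma, d_prop)
            e_prop = data.y - mu_prop - state.u[data.idx]
            sse_prop = float(e_prop @ e_prop)
            if math.log(rng.uniform()) < -lw * (sse_prop - sse_cur) / (
                2.0 * state.sigma2
            ):
                state.d = d_prop
                accept_counts["d"] += 1.0


def _run_chain(
    spec: _VariantSpec,
    data: _Data,
    cfg: McmcConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[np.ndarray], dict[str, float], dict[str, float]]:
    """Burn-in run with traces, then thinned post-convergence draws."""
    state = _init_state(spec, data, cfg, rng)
    prop = dict(cfg.proposal_sd)
    tune_until = cfg.n_iterations // 2 if cfg.tune else 0
    n_monitor = len(_monitor_names(spec, data))
    traces = np.empty((cfg.n_iterations, n_monitor))

    window: dict[str, float] = {"c": 0.0, "d": 0.0, "gamma": 0.0}
    for it in range(cfg.n_iterations):
        _iterate(spec, data, cfg, state, rng, prop, window)
        traces[it] = _state_vector(spec, state)
        if cfg.tune and it < tune_until and (it + 1) % 100 == 0:
            for key in ("c", "d", "gamma"):
                rate = window[key] / 100.0
                if rate > 0.5:
                    prop[key] *= 1.4
                elif rate < 0.2:
                    prop[key] *= 0.7
                window[key] = 0.0

    draws: list[np.ndarray] = []
    post_counts: dict[str, float] = {"c": 0.0, "d": 0.0, "gamma": 0.0}
    for it in range(cfg.n_post):
        _iterate(spec, data, cfg, state, rng, prop, post_counts)
        if (it + 1) % cfg.thin == 0:
            draws.append(_state_vector(spec, state))
    rates = {k: v / cfg.n_post for k, v in post_counts.items()}
    return traces, draws, rates, prop


def psrf(chains: "Sequence[np.ndarray] | np.ndarray",
         second_half: bool = True) -> float:
    """Gelman-Rubin potential scale reduction factor for one parameter.

    ``chains`` holds one trace per chain (equal lengths >= 10).  The
    statistic is computed on the second half of each chain in the standard
    between/within-variance form; identical constant chains give exactly 1
    and constant but unequal chains give the +infinity sentinel.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError("chains must be a 2-D array (n_chains, n_iterations)")
    m, n_full = arr.shape
    if m < 2:
        raise ValueError("need at least 2 chains")
    if n_full < 10:
        raise ValueError("chains must have length >= 10")
    if second_half:
        arr = arr[:, n_full // 2:]
    if np.all(arr == arr[0]):
        return 1.0  # identical chains: no between-chain disagreement
    n = arr.shape[1]
    within = float(np.mean(np.var(arr, axis=1, ddof=1)))
    chain_means = np.mean(arr, axis=1)
    if within <= 0.0:
        return math.inf  # constant but unequal chains
    b_over_n = float(np.var(chain_means, ddof=1))
    var_hat = (n - 1) / n * within + b_over_n
    return float(math.sqrt(var_hat / within))


def _complete_deviance(
    spec: _VariantSpec,
    data: _Data,
    beta: np.ndarray,
    u: np.ndarray,
    gamma: Optional[np.ndarray],
    c: float,
    d: float,
    sigma2: float,
    tau2: float,
    nu2: float,
) -> float:
    """-2 x complete-data log-likelihood, including random-effect densities."""
    mu = _mu(spec, data, beta, c, gamma, d) + u[data.idx]
    resid = data.y - mu
    ll = -0.5 * (data.N * (_LOG2PI + math.log(sigma2))
                 + float(resid @ resid) / sigma2)
    ll += -0.5 * (data.m * (_LOG2PI + math.log(tau2))
                  + float(u @ u) / tau2)
    if spec.varying:
        ll += -0.5 * (data.m * (_LOG2PI + math.log(nu2))
                      + float(gamma @ gamma) / nu2)
    return -2.0 * ll


def _unpack_draw(spec: _VariantSpec, data: _Data, row: np.ndarray) -> dict:
    p = len(spec.beta_names)
    pos = 0
    beta = row[pos:pos + p]; pos += p
    d = 1.0
    if not spec.quadratic:
        d = float(row[pos]); pos += 1
    c = float(row[pos]); pos += 1
    sigma2 = float(row[pos]); pos += 1
    tau2 = float(row[pos]); pos += 1
    nu2 = 1.0
    if spec.varying:
        nu2 = float(row[pos]); pos += 1
    u = row[pos:pos + data.m]; pos += data.m
    gamma = None
    if spec.varying:
        gamma = row[pos:pos + data.m]; pos += data.m
    return dict(beta=beta, d=d, c=c, sigma2=sigma2, tau2=tau2, nu2=nu2,
                u=u, gamma=gamma)


def compute_dic(
    draws: np.ndarray,
    data: _Data,
    spec: _VariantSpec,
) -> tuple[float, float]:
    """Complete-likelihood DIC: 2 * mean deviance - deviance at posterior means.

    Returns ``(dic, p_dic)`` where ``p_dic`` is the effective number of
    parameters (mean deviance minus plug-in deviance).
    """
    if len(draws) < 30:
        warnings.warn(f"only {len(draws)} draws: DIC estimate may be unstable")
    devs = np.array([
        _complete_deviance(spec, data, **_unpack_draw(spec, data, row))
        for row in draws
    ])
    plug = _unpack_draw(spec, data, draws.mean(axis=0))
    dev_at_mean = _complete_deviance(spec, data, **plug)
    mean_dev = float(np.mean(devs))
    p_dic = mean_dev - dev_at_mean
    return 2.0 * mean_dev - dev_at_mean, p_dic


def fit_mixed(
    cohort: Sequence[SubjectTrajectory],
    variant: str,
    config: Optional[McmcConfig] = None,
) -> MixedFitResult:
    """Fit one mixed-effects variant by multi-chain MCMC.

    Runs ``n_chains`` independent chains from dispersed starting points,
    checks PSRF on the second half of the convergence run, then retains
    ``n_post/thin`` thinned draws per chain for summaries and DIC.  A
    maximum PSRF above the threshold sets ``converged=False`` but still
    returns the result.
    """
    cfg = config or McmcConfig()
    spec = _VariantSpec(variant)
    data = _Data(cohort)
    names = _monitor_names(spec, data)
    chain_traces = []
    all_draws = []
    chain_labels = []
    rates_acc: dict[str, float] = {}
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    for chain_id, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        traces, draws, rates, _ = _run_chain(spec, data, cfg, rng)
        chain_traces.append(traces)
        all_draws.extend(draws)
        chain_labels.extend([chain_id] * len(draws))
        for k, v in rates.items():
            rates_acc[k] = rates_acc.get(k, 0.0) + v / cfg.n_chains

    stacked = np.stack(chain_traces)  # (chains, iters, params)
    psrf_names = [
        n for n in names
        if cfg.monitor_random_effects or not n.startswith(("u[", "gamma["))
    ]
    psrf_map = {
        name: psrf(stacked[:, :, names.index(name)]) for name in psrf_names
    }
    max_psrf = max(psrf_map.values())
    converged = max_psrf <= cfg.psrf_threshold
    if not converged:
        warnings.warn(
            f"{variant}: max PSRF {max_psrf:.3f} exceeds "
            f"{cfg.psrf_threshold}; chains may not have converged"
        )

    draw_matrix = np.array(all_draws)
    dic, p_dic = compute_dic(draw_matrix, data, spec)

    samples = pd.DataFrame(draw_matrix, columns=names)
    samples.insert(0, "draw", np.concatenate(
        [np.arange(cfg.n_post // cfg.thin) for _ in range(cfg.n_chains)]))
    samples.insert(0, "chain", chain_labels)

    if spec.quadratic:
        rates_acc.pop("d", None)
    if not spec.varying:
        rates_acc.pop("gamma", None)

    result = MixedFitResult(
        variant=variant,
        samples=samples,
        psrf=psrf_map,
        max_psrf=max_psrf,
        converged=converged,
        dic=dic,
        p_dic=p_dic,
        acceptance_rates=rates_acc,
        posterior_summary=pd.DataFrame(),
        config=cfg,
        n_subjects=data.m,
    )
    result.posterior_summary = summarize_posterior(result)
    return result


def summarize_posterior(result: MixedFitResult) -> pd.DataFrame:
    """Posterior mean and central 95% interval per parameter."""
    cols = [c for c in result.samples.columns if c not in ("chain", "draw")]
    if result.samples.empty:
        raise ValueError("no retained draws to summarize")
    rows = []
    for col in cols:
        v = result.samples[col].to_numpy()
        rows.append({
            "parameter": col,
            "mean": float(np.mean(v)),
            "q2.5": float(np.quantile(v, 0.025)),
            "q97.5": float(np.quantile(v, 0.975)),
        })
    return pd.DataFrame(rows)
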