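"""Likelihood construction and random-walk Metropolis sampling.

Each experimental treatment is fitted independently.  Observations are
modelled as independent draws from a normal distribution centred on the
deterministic response curve, with a single noise standard deviation per
treatment treated as an extra nuisance parameter.  Sampling is performed on
the log of every parameter (including log sigma), which enforces positivity;
priors are flat (improper) on that log scale, so the log posterior equals
the log likelihood up to a constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import MODEL_PARAM_NAMES, evaluate_model

__all__ = [
    "FitConfig",
    "PosteriorChain",
    "log_likelihood",
    "log_posterior",
    "run_mcmc",
    "run_chains",
    "check_convergence",
    "initial_log_params",
]

_LOG_2PI = np.log(2.0 * np.pi)


class ChainError(RuntimeError):
    """Raised when a chain fails outright (e.g. never accepts a proposal)."""


@dataclass
class FitConfig:
    """Sampler settings.

    The protocol-scale run is 1,000,000 draws after a 20,000-draw burn-in;
    the defaults here are desk-scale (50,000 / 2,000), with adequacy guarded
    by effective-sample-size checks rather than raw draw count.
    """

    n_samples: int = 50_000
    burn_in: int = 2_000
    n_chains: int = 2
    seed: int | None = None
    proposal_scale: float | None = None  # None => adapt during burn-in
    a_ii: float = 0.42
    target_accept: float = 0.3

    def __post_init__(self):
        if self.burn_in >= self.n_samples:
            raise ValueError("burn_in must be smaller than n_samples")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")


@dataclass
class PosteriorChain:
    """Post-burn-in MCMC draws for one treatment.

    ``draws`` holds log-scale samples, one column per model parameter plus a
    trailing ``log_sigma`` column; ``natural()`` back-transforms.
    """

    kind: str
    param_names: tuple[str, ...]  # log-scale names
    draws: np.ndarray  # (n_kept, n_params)
    acceptance_rate: float
    seed: int | None = None
    a_ii: float = 0.42
    treatment: str | None = None
    proposal_scale: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.draws.ndim != 2 or self.draws.shape[1] != len(self.param_names):
            raise ValueError("draw matrix shape does not match parameter names")
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("non-finite draws in chain")

    def __len__(self) -> int:
        return self.draws.shape[0]

    @property
    def natural_names(self) -> tuple[str, ...]:
        return tuple(n.removeprefix("log_") for n in self.param_names)

    def natural(self) -> pd.DataFrame:
        """Draws back-transformed to the natural (positive) scale."""
        return pd.DataFrame(np.exp(self.draws), columns=list(self.natural_names))

    def summary(self) -> pd.DataFrame:
        """Mean, SD and 2.5/50/97.5 percentiles per natural-scale parameter."""
        nat = self.natural()
        q = nat.quantile([0.025, 0.5, 0.975])
        out = pd.DataFrame(
            {
                "mean": nat.mean(),
                "sd": nat.std(ddof=1),
                "q2.5": q.loc[0.025],
                "median": q.loc[0.5],
                "q97.5": q.loc[0.975],
            }
        )
        out.index.name = "parameter"
        return out


def _model_matrix(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    intensity = np.asarray(data["intensity"], dtype=float)
    response = np.asarray(data["response"], dtype=float)
    if intensity.size == 0:
        raise ValueError("empty dataset")
    if not (np.all(np.isfinite(intensity)) and np.all(np.isfinite(response))):
        raise ValueError("non-finite intensity or response values")
    return intensity, response


def log_likelihood(log_params, intensity, response, kind: str, a_ii: float = 0.42) -> float:
    """Gaussian log likelihood around the deterministic curve.

    ``log_params`` stacks the log model parameters followed by log sigma.
    A failed or non-finite model evaluation yields -inf (the proposal is
    rejected) rather than raising mid-chain.
    """
    log_params = np.asarray(log_params, dtype=float)
    n_model = len(MODEL_PARAM_NAMES[kind])
    if log_params.size != n_model + 1:
        raise ValueError(
            f"expected {n_model + 1} log-parameters for kind {kind!r}, "
            f"got {log_params.size}"
        )
    if not np.all(np.isfinite(log_params)):
        return -np.inf
    intensity = np.asarray(intensity, dtype=float)
    response = np.asarray(response, dtype=float)
    theta = np.exp(log_params[:n_model])
    sigma = np.exp(log_params[n_model])
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        mu = evaluate_model(kind, intensity, theta, a_ii)
        if not np.all(np.isfinite(mu)):
            return -np.inf
        resid = response - mu
        n = resid.size
        ll = -0.5 * n * (_LOG_2PI + 2.0 * np.log(sigma)) - 0.5 * np.dot(resid, resid) / (
            sigma * sigma
        )
    return float(ll) if np.isfinite(ll) else -np.inf


def log_posterior(log_params, intensity, response, kind: str, a_ii: float = 0.42) -> float:
    """Log posterior under flat improper priors on the log-scale parameters.

    Equals the log likelihood exactly; kept as a distinct entry point so the
    prior choice is explicit and replaceable.
    """
    return log_likelihood(log_params, intensity, response, kind, a_ii)


def initial_log_params(intensity, response, kind: str, a_ii: float = 0.42) -> np.ndarray:
    """Heuristic starting point on the log scale.

    Saturation level from the largest observed response (converted through
    a_II * I for the efficiency data), half-saturation from the median
    intensity, sigma from the residual SD at that start.  Convergence checks
    make the exact choice non-critical.
    """
    intensity = np.asarray(intensity, dtype=float)
    response = np.asarray(response, dtype=float)
    if kind == "phi_ii":
        theta0 = [max(a_ii * np.max(response * intensity), 1e-6), np.median(intensity)]
    elif kind == "tef":
        theta0 = [max(np.max(response), 1e-6), np.median(intensity)]
    elif kind == "npq":
        theta0 = [max(np.max(response), 1e-6), np.median(intensity), 1.5]
    else:
        raise KeyError(f"unknown response kind: {kind!r}")
    mu0 = evaluate_model(kind, intensity, np.asarray(theta0), a_ii)
    sigma0 = float(np.std(response - mu0, ddof=0))
    sigma0 = max(sigma0, 1e-4 * max(abs(float(np.max(response))), 1.0))
    return np.log(np.asarray(theta0 + [sigma0], dtype=float))


def _metropolis(
    logpost,
    x0: np.ndarray,
    n_samples: int,
    burn_in: int,
    rng: np.random.Generator,
    scale0: float | None,
    target_accept: float,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Random-walk Metropolis with diagonal Gaussian proposals.

    The proposal scale adapts every 100 iterations during burn-in toward the
    target acceptance rate and is then frozen, so retained draws come from a
    fixed-kernel chain.  Returns (post-burn-in draws, acceptance rate over
    retained draws, final per-parameter scale).
    """
    ndim = x0.size
    scale = np.full(ndim, 0.1 if scale0 is None else scale0, dtype=float)
    adapt = scale0 is None

    cur = x0.astype(float).copy()
    cur_lp = logpost(cur)
    if not np.isfinite(cur_lp):
        raise ChainError("log posterior is -inf at the initial point")

    kept = np.empty((n_samples - burn_in, ndim))
    # pre-draw innovations in blocks to keep the Python loop lean
    z = rng.standard_normal((n_samples, ndim))
    log_u = np.log(rng.random(n_samples))

    accepted_post = 0
    window_acc = 0
    for t in range(n_samples):
        prop = cur + scale * z[t]
        prop_lp = logpost(prop)
        if prop_lp - cur_lp > log_u[t]:
            cur = prop
            cur_lp = prop_lp
            window_acc += 1
            if t >= burn_in:
                accepted_post += 1
        if adapt and t < burn_in and (t + 1) % 100 == 0:
            rate = window_acc / 100.0
            scale *= np.exp(np.clip(rate - target_accept, -0.5, 0.5))
            window_acc = 0
        elif (t + 1) % 100 == 0:
            window_acc = 0
        if t >= burn_in:
            kept[t - burn_in] = cur

    n_kept = n_samples - burn_in
    acc_rate = accepted_post / n_kept
    if accepted_post == 0:
        raise ChainError("chain never accepted a proposal after burn-in")
    if not 0.05 <= acc_rate <= 0.7:
        warnings.warn(
            f"post-burn-in acceptance rate {acc_rate:.3f} outside [0.05, 0.7]; "
            "consider tuning proposal_scale",
            RuntimeWarning,
            stacklevel=3,
        )
    return kept, acc_rate, scale


def _validate_fit_data(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    intensity, response = _model_matrix(data)
    if np.unique(intensity).size < 3:
        raise ValueError(
            "need at least 3 distinct intensities to identify the curve parameters"
        )
    return intensity, response


def run_mcmc(
    data: pd.DataFrame,
    kind: str,
    config: FitConfig | None = None,
    *,
    start: np.ndarray | None = None,
) -> PosteriorChain:
    """Fit one treatment's light-response data by Metropolis MCMC.

    ``data`` needs columns ``intensity`` and ``response`` (other columns are
    ignored); all rows are pooled as independent observations.  Deterministic
    given ``config.seed``.
    """
    config = config or FitConfig()
    intensity, response = _validate_fit_data(data)
    rng = np.random.default_rng(config.seed)
    x0 = (
        np.asarray(start, dtype=float)
        if start is not None
        else initial_log_params(intensity, response, kind, config.a_ii)
    )

    def lp(x):
        return log_posterior(x, intensity, response, kind, config.a_ii)

    kept, acc, scale = _metropolis(
        lp, x0, config.n_samples, config.burn_in, rng,
        config.proposal_scale, config.target_accept,
    )
    names = tuple(f"log_{n}" for n in MODEL_PARAM_NAMES[kind]) + ("log_sigma",)
    return PosteriorChain(
        kind=kind,
        param_names=names,
        draws=kept,
        acceptance_rate=acc,
        seed=config.seed,
        a_ii=config.a_ii,
        proposal_scale=scale,
    )


def run_chains(data: pd.DataFrame, kind: str, config: FitConfig | None = None) -> list[PosteriorChain]:
    """Run ``config.n_chains`` chains from dispersed starting points.

    Chain i uses seed ``seed + i`` and a start jittered multiplicatively
    around the heuristic initial point, so convergence can be assessed by
    comparing chains with distinct initial conditions.
    """
    config = config or FitConfig()
    intensity, response = _validate_fit_data(data)
    base = initial_log_params(intensity, response, kind, config.a_ii)
    chains = []
    for i in range(config.n_chains):
        seed_i = None if config.seed is None else config.seed + i
        jitter_rng = np.random.default_rng(None if seed_i is None else seed_i + 10_007)
        start = base if i == 0 else base + jitter_rng.normal(0.0, 0.5, base.size)
        cfg_i = FitConfig(
            n_samples=config.n_samples,
            burn_in=config.burn_in,
            n_chains=1,
            seed=seed_i,
            proposal_scale=config.proposal_scale,
            a_ii=config.a_ii,
            target_accept=config.target_accept,
        )
        chains.append(run_mcmc(data, kind, cfg_i, start=start))
    return chains


def check_convergence(chains: list[PosteriorChain], rhat_threshold: float = 1.05) -> pd.DataFrame:
    """Quantitative convergence report across >= 2 chains.

    Computes rank-normalised split potential-scale-reduction (R-hat) and
    bulk effective sample size per log-scale parameter, flagging parameters
    with R-hat above ``rhat_threshold``.  Replaces a visual trace-plot check
    with a numeric one.
    """
    import arviz as az

    if len(chains) < 2:
        raise ValueError("need at least 2 chains to assess convergence")
    lengths = {len(c) for c in chains}
    if len(lengths) != 1:
        raise ValueError("chains must have equal length")
    names = chains[0].param_names
    if any(c.param_names != names for c in chains):
        raise ValueError("chains disagree on parameter names")

    stacked = {
        name: np.stack([c.draws[:, j] for c in chains])  # (chain, draw)
        for j, name in enumerate(names)
    }
    idata = az.from_dict(posterior=stacked)
    rhat = az.rhat(idata).to_pandas()
    ess = az.ess(idata).to_pandas()
    report = pd.DataFrame({"rhat": rhat, "ess_bulk": ess})
    report["converged"] = report["rhat"] <= rhat_threshold
    report.index.name = "parameter"
    return report
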