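"""Adaptive-Metropolis posterior sampling and convergence diagnostics.

Sampling happens in the same unconstrained (log / log-ratio) space as the
least-squares fit.  The likelihood is Poisson on reconstructed counts: a
peak-normalized TAC is rescaled by its recorded count scale and rounded to
integers, and the model prediction scaled identically gives the Poisson
means.  Priors are independent weak Gaussians in the transformed space,
centred at the transformed least-squares estimate.

The proposal is a Gaussian random walk whose covariance adapts during
burn-in to the running empirical covariance of the chain, scaled by the
Haario factor 2.38^2/d with a small diagonal jitter, and is frozen when
burn-in ends.  Convergence across chains is assessed with the classical
Gelman-Rubin potential scale reduction factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .fitting import (
    PARAM_NAMES,
    VOLTAGE_INDICES,
    FitResult,
    ParameterTransform,
    predicted_signal,
)
from .io import TimeActivityCurve, normalize_tac
from .model import SolverError

__all__ = [
    "ChainSet",
    "PosteriorSummary",
    "log_likelihood",
    "log_prior",
    "run_chains",
    "adaptive_metropolis",
    "gelman_rubin",
    "posterior_summary",
    "combine_errors",
]

#: Haario adaptive-Metropolis jitter added to the proposal covariance.
PROPOSAL_JITTER = 1e-10
#: Default prior SD per transformed coordinate.  ln(5)/2, so that +/-2 prior
#: SDs reproduce the 5x / (1/5) search box of the least-squares protocol:
#: the sampler itself is unbounded, and on ridge directions the model leaves
#: unidentified, the prior stands in for the box.
DEFAULT_PRIOR_WIDTH = float(np.log(5.0) / 2.0)
#: Robbins-Monro target acceptance rate for the global proposal scale.
TARGET_ACCEPTANCE = 0.234


def log_likelihood(
    x: np.ndarray,
    tac: TimeActivityCurve,
    count_scale: float,
) -> float:
    """Poisson log-likelihood of a fit-space vector given a normalized TAC.

    Counts are reconstructed as y_i = round(count_scale * observed_i) and
    means as mu_i = count_scale * predicted_i; the result is
    sum(y log mu - mu - log y!).  Returns -inf for solver failures or for a
    zero/negative mean with a positive count.
    """
    if count_scale <= 0:
        raise ValueError("count_scale must be > 0")
    try:
        pred = predicted_signal(x, tac)
    except SolverError:
        return -np.inf
    if np.any(~np.isfinite(pred)):
        return -np.inf
    mu = count_scale * np.clip(pred, 0.0, None)
    y = np.rint(count_scale * tac.activity)
    if np.any((mu <= 0) & (y > 0)):
        return -np.inf
    pos = mu > 0
    ll = -np.sum(mu) - np.sum(gammaln(y[pos] + 1.0))
    ll += np.sum(y[pos] * np.log(mu[pos]))
    return float(ll)


def log_prior(z: np.ndarray, center: np.ndarray, width: float = DEFAULT_PRIOR_WIDTH) -> float:
    """Independent Gaussian log-density in transformed space (up to a constant)."""
    if width <= 0:
        raise ValueError("prior width must be > 0")
    d = np.asarray(z, dtype=float) - np.asarray(center, dtype=float)
    return float(-0.5 * np.sum((d / width) ** 2))


@dataclass
class ChainSet:
    """Raw multi-chain MCMC output in transformed coordinates.

    ``draws`` has shape (n_chains, n_iter, d) and includes the burn-in
    segment; ``log_post`` holds the matching log-posterior traces.  The
    transform (with its record of fixed parameters) is retained so draws can
    be mapped back to physical units.
    """

    draws: np.ndarray
    log_post: np.ndarray
    acceptance_rates: np.ndarray
    burn_in: int
    thin: int
    seeds: tuple[int, ...]
    transform: ParameterTransform | None = None
    count_scale: float | None = None

    def __post_init__(self) -> None:
        if self.draws.ndim != 3:
            raise ValueError("draws must have shape (n_chains, n_iter, d)")
        if self.draws.shape[0] < 2:
            raise ValueError("at least 2 chains are required for diagnostics")
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("draws contain non-finite values")
        if not (0 <= self.burn_in < self.draws.shape[1]):
            raise ValueError("burn-in must be shorter than the chains")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def retained(self) -> np.ndarray:
        """Post-burn-in, thinned draws, shape (n_chains, n_kept, d)."""
        return self.draws[:, self.burn_in :: self.thin, :]

    def retained_log_post(self) -> np.ndarray:
        return self.log_post[:, self.burn_in :: self.thin]


@dataclass
class PosteriorSummary:
    """Pooled posterior statistics in physical units (voltages negative, mV)."""

    mean: dict[str, float]
    median: dict[str, float]
    sd: dict[str, float]
    map: dict[str, float]
    rhat: dict[str, float]
    n_draws: int
    acceptance_rates: tuple[float, ...] = field(default_factory=tuple)


def _adaptive_chain(
    log_post,
    z0: np.ndarray,
    n_iter: int,
    burn_in: int,
    rng: np.random.Generator,
    initial_scale: float,
    initial_cov: np.ndarray | None = None,
):
    d = len(z0)
    sd_factor = 2.38**2 / d
    if initial_cov is not None:
        cov = sd_factor * (initial_cov + PROPOSAL_JITTER * np.eye(d))
    else:
        cov = (initial_scale**2 / d) * np.eye(d)
    chol = np.linalg.cholesky(cov)
    log_scale = 0.0  # Robbins-Monro global step-size factor (sensitivity)

    z = np.asarray(z0, dtype=float).copy()
    lp = log_post(z)
    if not np.isfinite(lp):
        raise ValueError("starting point has non-finite log posterior")

    draws = np.empty((n_iter, d))
    lps = np.empty(n_iter)
    # running moments for proposal adaptation
    mean = z.copy()
    m2 = np.zeros((d, d))
    count = 1
    accepted = 0
    consecutive_rejects = 0

    for it in range(n_iter):
        prop = z + np.exp(log_scale) * (chol @ rng.standard_normal(d))
        lp_prop = log_post(prop)
        acc_prob = np.exp(min(0.0, lp_prop - lp))
        if np.log(rng.uniform()) < lp_prop - lp:
            z, lp = prop, lp_prop
            accepted += 1
            consecutive_rejects = 0
        else:
            consecutive_rejects += 1
            if consecutive_rejects >= 1000:
                warnings.warn(
                    "1000 consecutive rejections; shrinking proposal step",
                    RuntimeWarning,
                    stacklevel=2,
                )
                log_scale -= np.log(2.0)
                consecutive_rejects = 0
        draws[it] = z
        lps[it] = lp

        if it < burn_in:
            # global step size: stochastic approximation toward the standard
            # random-walk target acceptance rate
            gamma = 2.0 / (it + 1) ** 0.6
            log_scale += gamma * (acc_prob - TARGET_ACCEPTANCE)
            count += 1
            delta = z - mean
            mean += delta / count
            m2 += np.outer(delta, z - mean)
            # switch to the running empirical covariance only once the chain
            # has actually moved enough to estimate it
            if count > 2 * d and accepted >= 2 * d:
                emp = m2 / (count - 1)
                cand = sd_factor * emp + sd_factor * PROPOSAL_JITTER * np.eye(d)
                try:
                    chol = np.linalg.cholesky(cand)
                except np.linalg.LinAlgError:
                    pass  # keep the previous proposal
        # proposal covariance and step size frozen after burn-in

    return draws, lps, accepted / n_iter


def run_chains(
    log_post,
    z0s,
    n_iter: int,
    burn_in: int,
    seed: int = 0,
    initial_scale: float = 0.1,
    thin: int = 1,
    transform: ParameterTransform | None = None,
    count_scale: float | None = None,
    initial_cov: np.ndarray | None = None,
) -> ChainSet:
    """Run independent adaptive-Metropolis chains on an arbitrary target.

    ``z0s`` is a sequence of per-chain starting points; chain c uses RNG
    seed ``seed + c``.  ``initial_cov``, when given, seeds the proposal
    covariance (scaled by 2.38^2/d) before adaptation takes over.  This is
    the generic engine behind :func:`adaptive_metropolis` and is directly
    usable with stub targets for validation.
    """
    z0s = [np.asarray(z, dtype=float) for z in z0s]
    if len(z0s) < 2:
        raise ValueError("at least 2 chains are required")
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    all_draws, all_lps, rates, seeds = [], [], [], []
    for c, z0 in enumerate(z0s):
        rng = np.random.default_rng(seed + c)
        draws, lps, rate = _adaptive_chain(
            log_post, z0, n_iter, burn_in, rng, initial_scale, initial_cov
        )
        all_draws.append(draws)
        all_lps.append(lps)
        rates.append(rate)
        seeds.append(seed + c)
    return ChainSet(
        draws=np.stack(all_draws),
        log_post=np.stack(all_lps),
        acceptance_rates=np.array(rates),
        burn_in=burn_in,
        thin=thin,
        seeds=tuple(seeds),
        transform=transform,
        count_scale=count_scale,
    )


def adaptive_metropolis(
    tac: TimeActivityCurve,
    init: FitResult,
    n_iter: int = 10_000,
    n_chains: int = 3,
    burn_in: int = 1_000,
    seed: int = 0,
    thin: int = 1,
    count_scale: float | None = None,
    prior_width: float = DEFAULT_PRIOR_WIDTH,
    start_spread: float = 0.05,
    initial_scale: float = 0.1,
) -> ChainSet:
    """Sample the posterior of the kinetic parameters for one TAC.

    Chains start from independent Gaussian perturbations (SD
    ``start_spread`` in transformed space) of the least-squares estimate
    ``init``, which also centres the weak Gaussian prior.  ``count_scale``
    defaults to the value recorded in the TAC metadata (the pre-
    normalization peak counts).  Defaults follow the reference protocol:
    3 chains of 10,000 iterations, burn-in 1,000, thin 1.
    """
    tac = normalize_tac(tac)
    if count_scale is None:
        count_scale = tac.metadata.get("count_scale")
        if count_scale is None:
            raise ValueError(
                "count_scale not in TAC metadata; pass it explicitly"
            )
    tr = ParameterTransform(init.fixed)
    z_hat = tr.to_unconstrained(init.x)

    # Laplace approximation of the posterior covariance seeds the proposal:
    # likelihood information = count_scale * J^T J of the Poisson-weighted
    # residuals (per unit count scale), prior precision = 1/width^2.  This
    # gives the proposal the right scale both along the well-determined
    # directions and along weakly identified ridges, where the prior takes
    # over.
    initial_cov = None
    if init.jtj_z is not None and init.jtj_z.shape == (tr.n_free, tr.n_free):
        hess = count_scale * init.jtj_z + np.eye(tr.n_free) / prior_width**2
        try:
            initial_cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            initial_cov = None

    def log_post(z):
        ll = log_likelihood(tr.to_fit_space(z), tac, count_scale)
        if not np.isfinite(ll):
            return -np.inf
        return ll + log_prior(z, z_hat, prior_width)

    rng = np.random.default_rng(seed)
    z0s = []
    for _ in range(n_chains):
        for _attempt in range(100):
            cand = z_hat + start_spread * rng.standard_normal(len(z_hat))
            if np.isfinite(log_post(cand)):
                z0s.append(cand)
                break
        else:
            raise RuntimeError("could not find a finite-posterior starting point")
    return run_chains(
        log_post,
        z0s,
        n_iter=n_iter,
        burn_in=burn_in,
        seed=seed,
        initial_scale=initial_scale,
        thin=thin,
        transform=tr,
        count_scale=count_scale,
        initial_cov=initial_cov,
    )


def gelman_rubin(chains: ChainSet | np.ndarray) -> dict[str, float] | np.ndarray:
    """Classical Gelman-Rubin potential scale reduction factor per parameter.

    R_hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B/n the variance of the chain means.  Accepts a
    :class:`ChainSet` (uses post-burn-in draws, returns a dict keyed by free
    parameter name) or a raw (n_chains, n_samples, d) array.
    """
    squeeze = False
    if isinstance(chains, ChainSet):
        arr = chains.retained()
        names = chains.transform.free_names if chains.transform else None
    else:
        arr = np.asarray(chains, dtype=float)
        names = None
    if arr.ndim == 2:
        arr = arr[:, :, None]
        squeeze = True
    m, n, d = arr.shape
    if m < 2 or n < 10:
        raise ValueError("need >= 2 chains of length >= 10")
    chain_means = arr.mean(axis=1)  # (m, d)
    w = arr.var(axis=1, ddof=1).mean(axis=0)  # (d,)
    b_over_n = chain_means.var(axis=0, ddof=1)  # (d,)
    rhat = np.empty(d)
    for j in range(d):
        if w[j] <= 0:
            warnings.warn(
                "zero within-chain variance (degenerate chain); R-hat set to 1",
                RuntimeWarning,
                stacklevel=2,
            )
            rhat[j] = 1.0
        else:
            var_plus = (n - 1) / n * w[j] + b_over_n[j]
            rhat[j] = np.sqrt(var_plus / w[j])
    if names is not None:
        return {name: float(rhat[j]) for j, name in enumerate(names)}
    return float(rhat[0]) if squeeze else rhat


def posterior_summary(chains: ChainSet) -> PosteriorSummary:
    """Pool post-burn-in draws and summarize in physical units.

    Each retained draw is mapped back through the transform; voltages are
    reported as negative mV.  MAP is the retained draw with the highest
    log-posterior.  Fixed parameters appear at their pinned values with zero
    spread.
    """
    tr = chains.transform
    if tr is None:
        raise ValueError("ChainSet lacks a parameter transform")
    kept = chains.retained().reshape(-1, chains.draws.shape[2])
    lps = chains.retained_log_post().reshape(-1)

    x_all = np.empty((kept.shape[0], len(PARAM_NAMES)))
    for i, z in enumerate(kept):
        x_all[i] = tr.to_fit_space(z)
    # physical units: voltages to negative mV
    phys = x_all.copy()
    for vi in VOLTAGE_INDICES:
        phys[:, vi] = -1000.0 * phys[:, vi]

    x_map = phys[int(np.argmax(lps))]
    rhat_free = gelman_rubin(chains)
    rhat = {name: rhat_free.get(name, 1.0) for name in PARAM_NAMES}
    return PosteriorSummary(
        mean={n: float(phys[:, i].mean()) for i, n in enumerate(PARAM_NAMES)},
        median={n: float(np.median(phys[:, i])) for i, n in enumerate(PARAM_NAMES)},
        sd={n: float(phys[:, i].std(ddof=1)) for i, n in enumerate(PARAM_NAMES)},
        map={n: float(x_map[i]) for i, n in enumerate(PARAM_NAMES)},
        rhat=rhat,
        n_draws=int(kept.shape[0]),
        acceptance_rates=tuple(float(r) for r in chains.acceptance_rates),
    )


def combine_errors(s_fit: float, s_expt: float) -> float:
    """Combine fitting and experimental SDs in quadrature."""
    if s_fit < 0 or s_expt < 0:
        raise ValueError("standard deviations must be >= 0")
    return float(np.hypot(s_fit, s_expt))
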