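"""Poisson-weighted non-linear least squares for the 12-parameter model.

The fit vector is, in order,

    (kf, k1, Em, k2, dPsi_m, t0, alpha, beta, A0, Vp, Vc, B)

with the two membrane potentials carried as *positive magnitudes in volts*
so every coordinate is strictly positive in fitting space (the public API
reports them back as negative mV).  Positivity is enforced by a per-
coordinate log transform; the volume-fraction pair (Vp, Vc) goes through an
additive log-ratio transform instead, which keeps Vp, Vc > 0 and
Vp + Vc < 1 by construction.  Box bounds (default init/5 .. init*5) are
applied in the transformed space; because the log-ratio coordinates are not
separable in (Vp, Vc) the volume box is enforced approximately there, with
upper corners nudged inside the simplex.

Residuals are weighted for Poisson counting noise, (obs - pred)/sqrt(pred),
with a small floor on the denominator; an ODE-solver failure inside the loss
is converted to large finite penalty residuals so the optimizer can retreat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .io import TimeActivityCurve, normalize_tac
from .model import (
    InputFunctionParams,
    KineticParameters,
    SolverError,
    model_signal,
)

__all__ = [
    "PARAM_NAMES",
    "ParameterTransform",
    "FitResult",
    "default_initial_vector",
    "bounds_from_initial",
    "transform",
    "untransform",
    "vector_to_params",
    "params_to_vector",
    "predicted_signal",
    "weighted_residuals",
    "fit_nls",
]

#: Fit-vector parameter order.
PARAM_NAMES = (
    "kf", "k1", "Em", "k2", "dPsi_m", "t0",
    "alpha", "beta", "A0", "Vp", "Vc", "B",
)
_IDX = {name: i for i, name in enumerate(PARAM_NAMES)}
#: Indices of the voltage magnitudes (volts in fit space, mV outside).
VOLTAGE_INDICES = (_IDX["Em"], _IDX["dPsi_m"])
#: Indices of the volume-fraction pair.
VOLUME_INDICES = (_IDX["Vp"], _IDX["Vc"])

#: Floor on the Poisson weight denominator, as a fraction of peak activity.
WEIGHT_FLOOR_FRAC = 1e-6
#: Magnitude of the per-point penalty residual on solver failure.
PENALTY_RESIDUAL = 1e6


def default_initial_vector() -> np.ndarray:
    """Standard starting vector for the 12-parameter fit.

    Voltages appear as positive magnitudes in volts (0.05 V for Em,
    0.1 V for dPsi_m).
    """
    return np.array(
        [0.5, 0.1, 0.05, 0.01, 0.1, 1.0, 12.0, 4.0, 1.0, 0.3, 0.3, 0.05]
    )


def bounds_from_initial(x: np.ndarray, factor: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Box bounds (x/factor, x*factor) around a strictly positive vector."""
    x = np.asarray(x, dtype=float)
    if factor <= 1:
        raise ValueError("bound factor must be > 1")
    if np.any(x <= 0):
        raise ValueError("initial vector must be strictly positive")
    return x / factor, x * factor


def vector_to_params(x: np.ndarray) -> KineticParameters:
    """Fit-space vector (positive volts) -> physical parameters (negative mV)."""
    x = np.asarray(x, dtype=float)
    return KineticParameters(
        kf=x[0],
        k1=x[1],
        em_mv=-1000.0 * x[2],
        k2=x[3],
        dpsi_mv=-1000.0 * x[4],
        input=InputFunctionParams(a0=x[8], alpha=x[6], beta=x[7], t0=x[5]),
        vp=x[9],
        vc=x[10],
        b=x[11],
    )


def params_to_vector(p: KineticParameters) -> np.ndarray:
    """Inverse of :func:`vector_to_params` (voltages to positive volts)."""
    return np.array(
        [
            p.kf, p.k1, -p.em_mv / 1000.0, p.k2, -p.dpsi_mv / 1000.0,
            p.input.t0, p.input.alpha, p.input.beta, p.input.a0,
            p.vp, p.vc, p.b,
        ]
    )


class ParameterTransform:
    """Bijection between (free) fit-space coordinates and unconstrained space.

    Log transform per coordinate; the volume pair is mapped through the
    additive log-ratio u_i = log(v_i / m) with m the remaining fraction, so
    any real (u_Vp, u_Vc) maps back inside the simplex.  Parameters named in
    ``fixed`` are pinned at the given fit-space values and excluded from the
    transformed vector (a parameter fixed at 0, e.g. the baseline B in the
    simulation study, has no log image and must be handled this way).
    """

    def __init__(self, fixed: dict[str, float] | None = None):
        self.fixed = dict(fixed or {})
        for name in self.fixed:
            if name not in _IDX:
                raise ValueError(f"unknown parameter {name!r}")
        self.free_names = tuple(n for n in PARAM_NAMES if n not in self.fixed)
        self.free_idx = np.array([_IDX[n] for n in self.free_names])
        self._vol_free = [n for n in ("Vp", "Vc") if n not in self.fixed]
        # total volume available to the free members of the pair
        self._vol_budget = 1.0 - sum(
            self.fixed.get(n, 0.0) for n in ("Vp", "Vc") if n in self.fixed
        )
        if self._vol_budget <= 0:
            raise ValueError("fixed volume fractions leave no budget")

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def full_vector(self, x_free: np.ndarray) -> np.ndarray:
        """Insert fixed values into a free fit-space vector."""
        x = np.empty(len(PARAM_NAMES))
        x[self.free_idx] = x_free
        for name, val in self.fixed.items():
            x[_IDX[name]] = val
        return x

    def free_vector(self, x_full: np.ndarray) -> np.ndarray:
        return np.asarray(x_full, dtype=float)[self.free_idx]

    def to_unconstrained(self, x_full: np.ndarray) -> np.ndarray:
        """Fit-space (full 12-vector) -> unconstrained free vector."""
        x_full = np.asarray(x_full, dtype=float)
        vp, vc = x_full[list(VOLUME_INDICES)]
        if vp + vc >= 1.0:
            raise ValueError("volume fractions must satisfy Vp + Vc < 1")
        z = []
        for name, i in zip(PARAM_NAMES, range(len(PARAM_NAMES))):
            if name in self.fixed:
                continue
            xi = x_full[i]
            if name in ("Vp", "Vc"):
                m = self._vol_budget - sum(
                    x_full[_IDX[v]] for v in self._vol_free
                )
                if xi <= 0 or m <= 0:
                    raise ValueError(
                        "volume fractions must be strictly inside the simplex"
                    )
                z.append(np.log(xi / m))
            else:
                if xi <= 0:
                    raise ValueError(f"parameter {name} must be > 0 in fit space")
                z.append(np.log(xi))
        return np.array(z)

    def to_fit_space(self, z: np.ndarray) -> np.ndarray:
        """Unconstrained free vector -> full fit-space 12-vector."""
        z = np.asarray(z, dtype=float)
        x = np.empty(len(PARAM_NAMES))
        for name, val in self.fixed.items():
            x[_IDX[name]] = val
        vol_z = {}
        for zi, name in zip(z, self.free_names):
            if name in ("Vp", "Vc"):
                vol_z[name] = zi
            else:
                x[_IDX[name]] = np.exp(zi)
        if vol_z:
            expz = {n: np.exp(v) for n, v in vol_z.items()}
            denom = 1.0 + sum(expz.values())
            for n, ez in expz.items():
                x[_IDX[n]] = self._vol_budget * ez / denom
        return x

    def jacobian(self, z: np.ndarray) -> np.ndarray:
        """d(full fit-space vector)/d(z), shape (12, n_free)."""
        z = np.asarray(z, dtype=float)
        x = self.to_fit_space(z)
        jac = np.zeros((len(PARAM_NAMES), self.n_free))
        vol_cols = {n: j for j, n in enumerate(self.free_names) if n in ("Vp", "Vc")}
        for j, name in enumerate(self.free_names):
            i = _IDX[name]
            if name not in ("Vp", "Vc"):
                jac[i, j] = x[i]
        # softmax-style derivatives for the volume pair
        for ni, ji in vol_cols.items():
            vi = x[_IDX[ni]]
            for nj, jj in vol_cols.items():
                vj = x[_IDX[nj]]
                delta = 1.0 if ni == nj else 0.0
                jac[_IDX[ni], jj] = vi * (delta - vj / self._vol_budget)
        return jac

    def bounds(
        self, lower: np.ndarray, upper: np.ndarray, nudge: float = 1e-9
    ) -> tuple[np.ndarray, np.ndarray]:
        """Map fit-space box bounds into the unconstrained space.

        Upper volume corners outside the simplex are rescaled to just inside
        it before transforming.
        """
        lower = np.asarray(lower, dtype=float).copy()
        upper = np.asarray(upper, dtype=float).copy()
        vol = list(VOLUME_INDICES)
        lo_sum = lower[vol].sum()
        if lo_sum >= 1.0:
            raise ValueError("lower volume bounds lie outside the simplex")
        up_sum = upper[vol].sum()
        if up_sum >= 1.0:
            upper[vol] *= (1.0 - nudge) / up_sum
        return self.to_unconstrained(lower), self.to_unconstrained(upper)


_DEFAULT_TRANSFORM = ParameterTransform()


def transform(x: np.ndarray) -> np.ndarray:
    """Map a full fit-space vector to unconstrained coordinates (no fixing)."""
    return _DEFAULT_TRANSFORM.to_unconstrained(x)


def untransform(z: np.ndarray) -> np.ndarray:
    """Inverse of :func:`transform`."""
    return _DEFAULT_TRANSFORM.to_fit_space(z)


def predicted_signal(x: np.ndarray, tac: TimeActivityCurve, **solve_kw) -> np.ndarray:
    """Model prediction for a fit-space vector on a TAC's sampling grid.

    Frame-mode TACs are evaluated at frame midpoints.
    """
    params = vector_to_params(x)
    return model_signal(params, times=tac.eval_times, **solve_kw)


def weighted_residuals(
    x: np.ndarray,
    tac: TimeActivityCurve,
    floor_frac: float = WEIGHT_FLOOR_FRAC,
    **solve_kw,
) -> np.ndarray:
    """Poisson-weighted residuals (observed - predicted)/sqrt(predicted).

    The denominator uses the model prediction (not the data) to avoid
    division by zero-count observations, floored at ``floor_frac`` of the
    observed peak.  On solver failure returns uniform penalty residuals of
    magnitude :data:`PENALTY_RESIDUAL`.
    """
    if len(tac) == 0:
        raise ValueError("TAC is empty")
    try:
        pred = predicted_signal(x, tac, **solve_kw)
    except SolverError:
        return np.full(len(tac), PENALTY_RESIDUAL)
    if np.any(~np.isfinite(pred)):
        return np.full(len(tac), PENALTY_RESIDUAL)
    floor = floor_frac * float(tac.activity.max())
    denom = np.sqrt(np.maximum(pred, floor))
    return (tac.activity - pred) / denom


@dataclass
class FitResult:
    """Outcome of :func:`fit_nls`.

    ``x`` is the fit-space estimate (positive voltage magnitudes in volts);
    ``params`` gives the same estimate in physical units, voltages as
    negative mV.  ``covariance``/``correlation``/``cv`` are Jacobian-derived
    (Gauss-Newton) over the full 12-vector in fit-space units, with fixed
    parameters carrying zero variance.
    """

    x: np.ndarray
    params: dict[str, float]
    residuals: np.ndarray
    cost: float
    covariance: np.ndarray
    correlation: np.ndarray
    cv: dict[str, float]
    converged: bool
    degenerate: bool
    fixed: dict[str, float] = field(default_factory=dict)
    message: str = ""
    #: J^T J of the weighted residuals w.r.t. the transformed coordinates,
    #: i.e. the (unit-count-scale) Gauss-Newton information at the estimate.
    jtj_z: np.ndarray | None = None
    #: names of the free (non-fixed) parameters, in transformed-vector order
    free_names: tuple[str, ...] = ()

    @property
    def kinetic_parameters(self) -> KineticParameters:
        return vector_to_params(self.x)


def _physical_params_dict(x: np.ndarray) -> dict[str, float]:
    out = {}
    for i, name in enumerate(PARAM_NAMES):
        if i in VOLTAGE_INDICES:
            out[name] = -1000.0 * float(x[i])  # mV, polarized negative
        else:
            out[name] = float(x[i])
    return out


def fit_nls(
    tac: TimeActivityCurve,
    init: np.ndarray | None = None,
    bound_factor: float = 5.0,
    fixed: dict[str, float] | None = None,
    floor_frac: float = WEIGHT_FLOOR_FRAC,
    **ls_kw,
) -> FitResult:
    """Fit the compartmental model to a peak-normalized TAC.

    Minimizes the sum of squared Poisson-weighted residuals in transformed
    space, within box bounds ``init/bound_factor .. init*bound_factor``.
    The TAC is normalized to unit peak first if it is not already (the
    amplitude parameters A0 and B absorb the scale).  ``fixed`` pins named
    parameters at fit-space values (e.g. ``{"B": 0.0}``).

    The covariance is s^2 (J^T J)^{-1} from the final Jacobian, propagated
    from transformed to fit-space coordinates; a rank-deficient Jacobian
    flags the result as degenerate instead of raising.
    """
    tac = normalize_tac(tac)
    tr = ParameterTransform(fixed)
    x0 = default_initial_vector() if init is None else np.asarray(init, dtype=float)
    if len(x0) != len(PARAM_NAMES):
        raise ValueError(f"initial vector must have {len(PARAM_NAMES)} entries")
    lower, upper = bounds_from_initial(x0, bound_factor)
    # pinned coordinates keep their fixed value regardless of the box
    x0 = tr.full_vector(tr.free_vector(x0))
    z0 = tr.to_unconstrained(x0)
    zlo, zup = tr.bounds(lower, upper)
    zlo_f = zlo  # bounds() returns free-space vectors already
    zup_f = zup
    # guard: keep the start strictly inside the transformed box
    eps = 1e-9 * np.maximum(1.0, np.abs(z0))
    z0 = np.clip(z0, zlo_f + eps, zup_f - eps)

    def objective(z):
        return weighted_residuals(tr.to_fit_space(z), tac, floor_frac=floor_frac)

    # Minimal-norm (regularized LSMR) trust-region steps: the model has a
    # rank-deficient Jacobian (kf/k1/A0/volume-fraction trade-offs), and
    # minimal-norm steps leave unidentifiable parameter combinations at
    # their initial values instead of letting them wander along the ridge.
    ls_defaults = dict(
        method="trf",
        jac="3-point",
        diff_step=1e-6,
        x_scale=1.0,
        tr_solver="lsmr",
        tr_options=dict(regularize=True),
    )
    ls_defaults.update(ls_kw)
    res = least_squares(objective, z0, bounds=(zlo_f, zup_f), **ls_defaults)

    x_hat = tr.to_fit_space(res.x)
    n, p = len(tac), tr.n_free
    dof = max(n - p, 1)
    ssr = 2.0 * res.cost
    s2 = ssr / dof
    jtj = res.jac.T @ res.jac
    degenerate = False
    try:
        cond = np.linalg.cond(jtj)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        degenerate = True
    try:
        cov_z = s2 * np.linalg.pinv(jtj)
    except np.linalg.LinAlgError:
        degenerate = True
        cov_z = np.full((p, p), np.nan)
    cov_z = 0.5 * (cov_z + cov_z.T)  # pinv of an ill-conditioned matrix
    g = tr.jacobian(res.x)  # (12, p)
    cov_x = g @ cov_z @ g.T
    cov_x = 0.5 * (cov_x + cov_x.T)

    sd = np.sqrt(np.clip(np.diag(cov_x), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov_x / np.outer(sd, sd)
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv_arr = np.where(np.abs(x_hat) > 0, sd / np.abs(x_hat), np.inf)
    cv = {name: float(cv_arr[i]) for i, name in enumerate(PARAM_NAMES)}
    for name in tr.fixed:
        cv[name] = 0.0

    if degenerate:
        warnings.warn(
            "Jacobian is rank-deficient; parameter uncertainties are unreliable",
            RuntimeWarning,
            stacklevel=2,
        )

    return FitResult(
        x=x_hat,
        params=_physical_params_dict(x_hat),
        residuals=res.fun,
        cost=float(res.cost),
        covariance=cov_x,
        correlation=corr,
        cv=cv,
        converged=bool(res.status > 0),
        degenerate=degenerate,
        fixed=dict(tr.fixed),
        message=str(res.message),
        jtj_z=jtj,
        free_names=tr.free_names,
    )
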