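"""Variational parameter estimation for the release models.

Fitting follows the ADVI recipe: each free parameter is transformed from
its bounded support to the real line by a smooth bijection, the
variational posterior is a Gaussian in that unconstrained space, and the
evidence lower bound

    ELBO = E_q[ log p(y | theta) + log p(theta) + log |J(z)| ] + H[q]

is maximized by stochastic gradient ascent with the reparameterization
trick (z = mu + L * eps). Priors are independent Gaussians on the
constrained scale, truncated by the declared bounds; the likelihood is
i.i.d. Gaussian per FSCV sample with standard deviation v = 0.05 uM.

Two variational families are available: the fully factorized
``"meanfield"`` default, and ``"fullrank"`` with a dense Cholesky factor.
Release and uptake magnitudes are strongly correlated under the
posterior (more release plus faster uptake produces nearly the same
transient), and a factorized Gaussian then understates the marginal
uncertainty; the full-rank family restores calibrated per-parameter
standard deviations at negligible cost for the handful of free
parameters these models have.

No automatic-differentiation backend is used: gradients of the log-joint
with respect to the (few, <= 13) unconstrained coordinates are taken by
central finite differences around each Monte Carlo draw. The forward
solvers are fast enough that this keeps a full fit in the seconds range
for the simple model. Results record ``gradient_method`` accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants
from .trace import Trace

__all__ = [
    "ParamPrior",
    "PriorSpec",
    "FitResult",
    "log_likelihood",
    "r_squared",
    "advi_optimize",
    "fit_advi",
    "FREE_PARAMETER_NAMES",
]

#: Canonical order of the model's potentially-free parameters.
FREE_PARAMETER_NAMES = (
    "da_p", "v_m",
    "p1", "p2", "p3",
    "tau1", "tau2", "tau3",
    "k_s", "k_e",
    "k1_ads", "k2_ads", "k3_ads",
)

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ParamPrior:
    """Gaussian prior (constrained scale) plus hard support bounds."""

    mean: float
    sd: float
    lower: float
    upper: float | None = None  # None = half-open support [lower, inf)

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("prior sd must be positive")
        if self.upper is not None and not (self.lower < self.upper):
            raise ValueError("need lower < upper")
        lo, hi = self.lower, np.inf if self.upper is None else self.upper
        if not (lo < self.mean < hi):
            raise ValueError(
                f"prior mean {self.mean} must lie strictly inside ({lo}, {hi})"
            )


@dataclass
class PriorSpec:
    """Free-parameter priors and fixed-parameter assignments for a fit.

    ``free`` maps parameter names (subset of FREE_PARAMETER_NAMES) to
    ParamPrior; ``fixed`` maps the remaining names to point values. K_m is
    always fixed (default 0.2 uM, the literature-consensus value).
    """

    free: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    km: float = constants.KM_DEFAULT

    def __post_init__(self) -> None:
        for name in self.free:
            if name not in FREE_PARAMETER_NAMES:
                raise KeyError(f"unknown free parameter {name!r}")
        for name in self.fixed:
            if name not in FREE_PARAMETER_NAMES:
                raise KeyError(f"unknown fixed parameter {name!r}")
        missing = [
            n for n in FREE_PARAMETER_NAMES
            if n not in self.free and n not in self.fixed
        ]
        if missing:
            raise ValueError(f"parameters neither free nor fixed: {missing}")
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")

    @property
    def free_names(self) -> tuple:
        return tuple(n for n in FREE_PARAMETER_NAMES if n in self.free)

    def assemble(self, free_values: np.ndarray) -> dict:
        """Merge fixed values and an ordered free-value vector into one dict."""
        theta = dict(self.fixed)
        for name, value in zip(self.free_names, free_values):
            theta[name] = float(value)
        theta["km"] = self.km
        return theta

    @classmethod
    def from_preset(
        cls,
        preset,
        model: str = "sur",
        free=("da_p", "v_m"),
        sd_frac: float = 0.5,
        electrode=None,
        center: dict | None = None,
    ) -> "PriorSpec":
        """Priors centered on a published preset, with package-chosen widths.

        ``center`` overrides individual prior means (e.g. to start a
        recovery experiment away from the generating truth).
        """
        from .electrode import ElectrodeParams

        el = electrode or ElectrodeParams()
        values = {
            "da_p": preset.da_p[model],
            "v_m": preset.v_m,
            "p1": preset.plasticity.p[0],
            "p2": preset.plasticity.p[1],
            "p3": preset.plasticity.p[2],
            "tau1": preset.plasticity.tau[0],
            "tau2": preset.plasticity.tau[1],
            "tau3": preset.plasticity.tau[2],
            "k_s": el.k_s,
            "k_e": el.k_e,
            "k1_ads": el.k1_ads,
            "k2_ads": el.k2_ads,
            "k3_ads": el.k3_ads,
        }
        bounds = _default_bounds(values)
        center = center or {}
        free_specs = {}
        fixed = {}
        for name, value in values.items():
            if name in free:
                mean = float(center.get(name, value))
                lo, hi = bounds[name]
                sd = max(sd_frac * abs(mean), _SD_FLOORS[_param_kind(name)])
                free_specs[name] = ParamPrior(mean=mean, sd=sd, lower=lo, upper=hi)
            else:
                fixed[name] = float(value)
        return cls(free=free_specs, fixed=fixed, km=preset.km)


_SD_FLOORS = {"rate": 0.05, "p": 0.001, "tau": 1.0, "release": 0.02}


def _param_kind(name: str) -> str:
    if name.startswith("p"):
        return "p"
    if name.startswith("tau"):
        return "tau"
    if name in ("da_p", "v_m"):
        return "release"
    return "rate"


def _default_bounds(values: dict) -> dict:
    """Package-default support bounds per parameter (documented choices)."""
    b = {}
    for name in ("da_p", "v_m"):
        v = values[name]
        b[name] = (0.0, max(4.0 * v, 1.0))
    b["p1"] = (0.0, 0.05)
    # depressing components are nominally negative; a small positive margin
    # keeps the knockout value p3 = 0 strictly inside the support
    b["p2"] = (-0.05, 0.005)
    b["p3"] = (-0.05, 0.005)
    b["tau1"] = (0.5, 100.0)
    b["tau2"] = (0.5, 200.0)
    b["tau3"] = (100.0, 3600.0)
    for name in ("k_s", "k_e"):
        b[name] = (0.05, 50.0)
    for name in ("k1_ads", "k2_ads", "k3_ads"):
        b[name] = (0.0, 2.0)
    return b


# ---------------------------------------------------------------------------
# likelihood / goodness of fit

def _values(trace) -> np.ndarray:
    return trace.values if isinstance(trace, Trace) else np.asarray(trace, dtype=float)


def _check_aligned(observed, predicted):
    yo = _values(observed)
    yp = _values(predicted)
    if yo.size == 0:
        raise ValueError("empty trace")
    if yo.shape != yp.shape:
        raise ValueError("observed and predicted traces are not on the same grid")
    if isinstance(observed, Trace) and isinstance(predicted, Trace):
        if not np.allclose(observed.times, predicted.times):
            raise ValueError("observed and predicted time grids differ")
    return yo, yp


def log_likelihood(observed, predicted, v: float = constants.LIKELIHOOD_SD) -> float:
    """Gaussian log-likelihood of the observed trace given the model trace.

    Each observed sample C_t is N(C_hat_t, v) with the model value as the
    mean; v defaults to 0.05 uM.
    """
    if v <= 0:
        raise ValueError("likelihood sd v must be positive")
    yo, yp = _check_aligned(observed, predicted)
    z = (yo - yp) / v
    return float(-0.5 * np.sum(z**2) - yo.size * (np.log(v) + 0.5 * _LOG_2PI))


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot of a fitted trace."""
    yo, yp = _check_aligned(observed, predicted)
    if yo.size < 2:
        raise ValueError("need at least two samples")
    ss_tot = float(np.sum((yo - yo.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed trace has zero variance")
    ss_res = float(np.sum((yo - yp) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# bijections between bounded supports and the real line

def _sigmoid(z):
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))


class _Bijection:
    """theta = T(z): R -> (lower, upper) with log-Jacobian log|dT/dz|."""

    def __init__(self, lower: float, upper: float | None):
        self.lower = lower
        self.upper = upper

    def forward(self, z):
        if self.upper is None:
            return self.lower + np.exp(z)
        return self.lower + (self.upper - self.lower) * _sigmoid(z)

    def inverse(self, theta):
        if self.upper is None:
            return np.log(max(theta - self.lower, 1e-12))
        width = self.upper - self.lower
        u = np.clip((theta - self.lower) / width, 1e-9, 1.0 - 1e-9)
        return float(np.log(u) - np.log1p(-u))

    def log_jacobian(self, z):
        if self.upper is None:
            return z
        s = _sigmoid(z)
        return np.log(self.upper - self.lower) + np.log(s) + np.log1p(-s)


# ---------------------------------------------------------------------------
# the optimizer

@dataclass
class FitResult:
    """Posterior summaries and diagnostics from a variational fit.

    ``params``/``sd`` are per-free-parameter posterior means and standard
    deviations on the constrained (physical) scale, estimated from the
    fitted variational distribution. ``elbo_trace`` is the per-iteration
    stochastic ELBO estimate.
    """

    params: pd.Series
    sd: pd.Series
    bounds: dict
    fixed: dict
    elbo_trace: np.ndarray
    predicted: Trace
    rsquared: float
    seed: int
    n_iter: int
    converged: bool
    message: str
    gradient_method: str = "finite_difference"
    family: str = "meanfield"
    model: str = "sur"

    def summary(self) -> str:
        lines = [
            f"ADVI fit ({self.model.upper()} model, {self.family} family)",
            f"  iterations: {self.n_iter}   converged: {self.converged}",
            f"  final ELBO: {self.elbo_trace[-1]:.2f}   R^2: {self.rsquared:.4f}",
            "",
            f"{'parameter':>10} {'post. mean':>12} {'post. sd':>10} {'lower':>9} {'upper':>9}",
        ]
        for name in self.params.index:
            lo, hi = self.bounds[name]
            hi_s = f"{hi:9.4g}" if hi is not None else "      inf"
            lines.append(
                f"{name:>10} {self.params[name]:12.5g} {self.sd[name]:10.4g} "
                f"{lo:9.4g} {hi_s}"
            )
        if self.fixed:
            lines.append("")
            lines.append("  fixed: " + ", ".join(
                f"{k}={v:.4g}" for k, v in sorted(self.fixed.items())
            ))
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.params.index:
            lo, hi = self.bounds[name]
            rows.append(
                {"parameter": name, "mean": self.params[name], "sd": self.sd[name],
                 "lower": lo, "upper": hi}
            )
        return pd.DataFrame(rows)


def advi_optimize(
    observed_values: np.ndarray,
    predict_fn,
    priors: PriorSpec,
    seed: int = 0,
    max_iter: int = 800,
    learning_rate: float = 0.05,
    mc_samples: int = 2,
    v: float = constants.LIKELIHOOD_SD,
    family: str = "meanfield",
    fd_step: float = 1e-4,
    init_log_sd: float = -2.3,
    convergence_window: int = 80,
    convergence_tol: float = 1e-3,
    posterior_draws: int = 512,
):
    """Core ADVI loop over a generic forward model.

    ``predict_fn(theta: dict) -> np.ndarray`` must return the model trace
    on the observed grid. ``family`` selects the variational Gaussian:
    ``"meanfield"`` (diagonal) or ``"fullrank"`` (dense Cholesky factor).
    Convergence is declared when consecutive window-averaged ELBO values
    agree to ``convergence_tol`` relative (the window average tames the
    stochastic-gradient noise in the per-iteration ELBO estimate).
    Returns (posterior mean/sd Series on the constrained scale, elbo
    trace, n_iter, converged flag, message).
    """
    if family not in ("meanfield", "fullrank"):
        raise ValueError(f"unknown variational family {family!r}")
    names = priors.free_names
    k = len(names)
    if k == 0:
        raise ValueError("no free parameters to fit")
    bijections = [
        _Bijection(priors.free[n].lower, priors.free[n].upper) for n in names
    ]
    prior_mean = np.array([priors.free[n].mean for n in names])
    prior_sd = np.array([priors.free[n].sd for n in names])

    def logjoint_unconstrained(z: np.ndarray) -> float:
        theta = np.array([b.forward(zi) for b, zi in zip(bijections, z)])
        logjac = float(sum(b.log_jacobian(zi) for b, zi in zip(bijections, z)))
        lp = float(np.sum(
            -0.5 * ((theta - prior_mean) / prior_sd) ** 2
            - np.log(prior_sd) - 0.5 * _LOG_2PI
        ))
        pred = predict_fn(priors.assemble(theta))
        ll = log_likelihood(observed_values, pred, v=v)
        return ll + lp + logjac

    def grad_logjoint(z: np.ndarray) -> tuple[float, np.ndarray]:
        f0 = logjoint_unconstrained(z)
        g = np.empty(k)
        for j in range(k):
            dz = np.zeros(k)
            dz[j] = fd_step
            g[j] = (
                logjoint_unconstrained(z + dz) - logjoint_unconstrained(z - dz)
            ) / (2.0 * fd_step)
        return f0, g

    rng = np.random.default_rng(seed)
    mu = np.array([b.inverse(m) for b, m in zip(bijections, prior_mean)])
    # Scale/cov parameters: omega = log diagonal of L; lower strict
    # triangle of L is parametrized directly (full-rank only).
    omega = np.full(k, init_log_sd)
    tril_idx = np.tril_indices(k, -1)
    n_tril = tril_idx[0].size if family == "fullrank" else 0
    ltri = np.zeros(n_tril)

    def chol() -> np.ndarray:
        L = np.diag(np.exp(omega))
        if n_tril:
            L[tril_idx] = ltri
        return L

    # Adam state over the concatenated (mu, omega, ltri) vector
    n_var = 2 * k + n_tril
    adam_m = np.zeros(n_var)
    adam_v = np.zeros(n_var)
    b1, b2, eps = 0.9, 0.999, 1e-8

    elbo_trace = np.empty(max_iter)
    entropy_const = 0.5 * k * (1.0 + _LOG_2PI)
    converged = False
    n_done = max_iter
    for it in range(max_iter):
        L = chol()
        g_mu = np.zeros(k)
        g_om = np.zeros(k)
        g_lt = np.zeros(n_tril)
        elbo_mc = 0.0
        for _ in range(mc_samples):
            epsilon = rng.standard_normal(k)
            z = mu + L @ epsilon
            f0, g_z = grad_logjoint(z)
            g_mu += g_z
            # dz/dL_ij = eps_j on row i; diagonal is exp(omega)
            g_om += g_z * np.exp(omega) * epsilon
            if n_tril:
                outer = np.outer(g_z, epsilon)
                g_lt += outer[tril_idx]
            elbo_mc += f0
        g_mu /= mc_samples
        g_om = g_om / mc_samples + 1.0  # + d(entropy)/d(omega); entropy = sum(omega) + const
        if n_tril:
            g_lt /= mc_samples
        elbo_trace[it] = elbo_mc / mc_samples + entropy_const + float(np.sum(omega))

        grad = np.concatenate([g_mu, g_om, g_lt])
        t = it + 1
        adam_m = b1 * adam_m + (1 - b1) * grad
        adam_v = b2 * adam_v + (1 - b2) * grad**2
        step = learning_rate * (adam_m / (1 - b1**t)) / (
            np.sqrt(adam_v / (1 - b2**t)) + eps
        )
        mu += step[:k]
        omega += step[k : 2 * k]
        if n_tril:
            ltri += step[2 * k :]

        if it >= 2 * convergence_window:
            recent = elbo_trace[it - convergence_window + 1 : it + 1].mean()
            prev = elbo_trace[
                it - 2 * convergence_window + 1 : it - convergence_window + 1
            ].mean()
            scale = max(abs(prev), 1.0)
            if abs(recent - prev) / scale < convergence_tol:
                converged = True
                n_done = it + 1
                break
    elbo_trace = elbo_trace[:n_done]
    message = (
        "ELBO plateau reached"
        if converged
        else f"no ELBO plateau within {max_iter} iterations; treat estimates with caution"
    )
    if not converged:
        warnings.warn(message, RuntimeWarning, stacklevel=2)

    # Posterior summaries on the constrained scale, by sampling q.
    L = chol()
    zs = mu[None, :] + rng.standard_normal((posterior_draws, k)) @ L.T
    thetas = np.column_stack(
        [bijections[j].forward(zs[:, j]) for j in range(k)]
    )
    post_mean = pd.Series(thetas.mean(axis=0), index=list(names))
    post_sd = pd.Series(thetas.std(axis=0, ddof=1), index=list(names))
    return post_mean, post_sd, elbo_trace, n_done, converged, message


def fit_advi(
    observed: Trace,
    model: str,
    protocol,
    priors: PriorSpec,
    seed: int = 0,
    max_iter: int = 800,
    **kwargs,
) -> FitResult:
    """Fit a release-model variant to an observed trace (convenience wrapper).

    Builds a :class:`fscvmodels.model.ReleaseModel` and calls its ``fit``;
    see that class for the full set of options.
    """
    from .model import ReleaseModel

    m = ReleaseModel(observed, protocol, variant=model, priors=priors, **kwargs)
    res = m.fit(seed=seed, max_iter=max_iter)
    return res.fit_result
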