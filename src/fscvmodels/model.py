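"""Model/Results objects tying the forward simulators to the ADVI fitter.

``ReleaseModel`` is constructed from an observed FSCV trace, a
stimulation protocol and a prior specification, in the style of a
statsmodels model; ``.fit()`` runs variational inference and returns a
``ReleaseModelResults`` carrying posterior means, uncertainties, the ELBO
trajectory, goodness of fit and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import constants
from .electrode import ElectrodeParams, measure_trace
from .inference import FitResult, PriorSpec, advi_optimize, r_squared
from .plasticity import PlasticityParams
from .presets import get_preset
from .release import (
    GeometryParams,
    ReleaseUptakeParams,
    simulate_stdr,
    simulate_stur,
    simulate_sur,
)
from .stimulus import BurstProtocol
from .trace import Trace

__all__ = ["ReleaseModel", "ReleaseModelResults"]

VARIANTS = ("sur", "stur", "stdr")


def _theta_to_objects(theta: dict):
    """Split a flat parameter dict into the solver parameter objects."""
    release = ReleaseUptakeParams(
        da_p=theta["da_p"], v_m=theta["v_m"], km=theta.get("km", constants.KM_DEFAULT)
    )
    plasticity = PlasticityParams(
        p=(theta["p1"], theta["p2"], theta["p3"]),
        tau=(theta["tau1"], theta["tau2"], theta["tau3"]),
    )
    electrode = ElectrodeParams(
        k_s=theta["k_s"], k_e=theta["k_e"],
        k1_ads=theta["k1_ads"], k2_ads=theta["k2_ads"], k3_ads=theta["k3_ads"],
    )
    return release, plasticity, electrode


class ReleaseModel:
    """A release-model variant bound to an observed trace and priors.

    Parameters
    ----------
    endog : Trace
        The observed FSCV trace (uniform grid, usually 10 Hz).
    protocol : BurstProtocol
        The stimulation protocol that evoked the trace.
    variant : {"sur", "stur", "stdr"}
    priors : PriorSpec
        Free-parameter priors and fixed-parameter values. Defaults to a
        two-parameter (da_p, v_m) fit around the WT sweep-1 preset.
    geometry : GeometryParams, optional
        Required settings for the spatial variants; ignored by "sur".
    solver_dt : float
        Fine-grid step of the forward solvers (s).
    bypass_electrode : bool
        If True the model predicts [DA]_S directly (artifact-free view).
    initial_H : triple
        Plasticity component values at the start of the trace.
    """

    def __init__(
        self,
        endog: Trace,
        protocol: BurstProtocol,
        variant: str = "sur",
        priors: PriorSpec | None = None,
        geometry: GeometryParams | None = None,
        solver_dt: float = constants.SOLVER_DT,
        bypass_electrode: bool = False,
        initial_H=(1.0, 1.0, 1.0),
        likelihood_sd: float = constants.LIKELIHOOD_SD,
    ):
        if variant not in VARIANTS:
            raise ValueError(f"unknown model variant {variant!r}")
        if not isinstance(endog, Trace):
            raise TypeError("endog must be a Trace")
        self.endog = endog
        self.protocol = protocol
        self.variant = variant
        if priors is None:
            priors = PriorSpec.from_preset(get_preset("WT-sweep1-S"), model=variant)
        self.priors = priors
        self.geometry = geometry or GeometryParams()
        self.solver_dt = float(solver_dt)
        self.bypass_electrode = bool(bypass_electrode)
        self.initial_H = tuple(initial_H)
        self.likelihood_sd = float(likelihood_sd)

        # fine solver grid aligned with the observed samples
        t0, t1 = endog.times[0], endog.times[-1]
        n_fine = int(round((t1 - t0) / self.solver_dt))
        if abs(t0 + n_fine * self.solver_dt - t1) > 1e-9:
            raise ValueError("solver_dt must divide the observed trace span")
        stride = endog.dt / self.solver_dt
        if abs(stride - round(stride)) > 1e-6:
            raise ValueError("solver_dt must divide the FSCV sampling interval")
        self._tfine = t0 + self.solver_dt * np.arange(n_fine + 1)

    @classmethod
    def from_preset(
        cls,
        endog: Trace,
        preset_name: str,
        variant: str = "sur",
        free=("da_p", "v_m"),
        protocol: BurstProtocol | None = None,
        **kwargs,
    ) -> "ReleaseModel":
        """Build a model whose priors center on a published preset row."""
        preset = get_preset(preset_name)
        priors = PriorSpec.from_preset(preset, model=variant, free=free)
        return cls(
            endog,
            protocol if protocol is not None else preset.protocol(),
            variant=variant,
            priors=priors,
            **kwargs,
        )

    # -- forward path -----------------------------------------------------

    def striatal_signal(self, theta: dict):
        """[DA]_S on the fine grid for one parameter set (field for PDEs)."""
        release, plasticity, _ = _theta_to_objects(theta)
        if self.variant == "sur":
            da_s = simulate_sur(
                self.protocol, plasticity, release, self._tfine, self.initial_H
            )
            return None, da_s
        sim = simulate_stur if self.variant == "stur" else simulate_stdr
        field, da_s = sim(
            self.protocol, plasticity, release, self.geometry, self._tfine,
            self.initial_H,
        )
        return field, da_s

    def predict_values(self, theta: dict) -> np.ndarray:
        """Model trace on the observed grid for one parameter set."""
        _, da_s = self.striatal_signal(theta)
        _, _, electrode = _theta_to_objects(theta)
        tr = measure_trace(
            da_s, self._tfine, electrode, fs=self.endog.fs,
            bypass=self.bypass_electrode,
        )
        return tr.values

    def simulate(self, theta: dict | None = None, meta: dict | None = None) -> Trace:
        """Forward-run the model (defaults: prior means + fixed values)."""
        theta = theta or self.default_theta()
        values = self.predict_values(theta)
        return Trace(times=self.endog.times.copy(), values=values, meta=dict(meta or {}))

    def default_theta(self) -> dict:
        free_means = np.array([self.priors.free[n].mean for n in self.priors.free_names])
        return self.priors.assemble(free_means)

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        seed: int = 0,
        max_iter: int = 800,
        learning_rate: float = 0.05,
        mc_samples: int = 2,
        family: str = "meanfield",
        **kwargs,
    ) -> "ReleaseModelResults":
        """Run ADVI (mean-field by default) and return a results object."""
        post_mean, post_sd, elbo, n_iter, converged, message = advi_optimize(
            self.endog.values,
            self.predict_values,
            self.priors,
            seed=seed,
            max_iter=max_iter,
            learning_rate=learning_rate,
            mc_samples=mc_samples,
            v=self.likelihood_sd,
            family=family,
            **kwargs,
        )
        theta_hat = self.priors.assemble(post_mean.to_numpy())
        predicted = Trace(
            times=self.endog.times.copy(),
            values=self.predict_values(theta_hat),
            meta={"model": self.variant, "role": "posterior-mean prediction"},
        )
        bounds = {
            n: (self.priors.free[n].lower, self.priors.free[n].upper)
            for n in self.priors.free_names
        }
        fixed = dict(self.priors.fixed)
        fixed["km"] = self.priors.km
        try:
            rsq = r_squared(self.endog, predicted)
        except ValueError:  # e.g. an identically-zero observed trace
            rsq = float("nan")
        fit_result = FitResult(
            params=post_mean,
            sd=post_sd,
            bounds=bounds,
            fixed=fixed,
            elbo_trace=elbo,
            predicted=predicted,
            rsquared=rsq,
            seed=seed,
            n_iter=n_iter,
            converged=converged,
            message=message,
            family=family,
            model=self.variant,
        )
        return ReleaseModelResults(self, fit_result)


class ReleaseModelResults:
    """Results wrapper: posterior estimates, diagnostics and plots."""

    def __init__(self, model: ReleaseModel, fit_result: FitResult):
        self.model = model
        self.fit_result = fit_result

    @property
    def params(self) -> pd.Series:
        """Posterior means of the free parameters (constrained scale)."""
        return self.fit_result.params

    @property
    def bse(self) -> pd.Series:
        """Posterior standard deviations (the ADVI uncertainty estimate)."""
        return self.fit_result.sd

    @property
    def rsquared(self) -> float:
        return self.fit_result.rsquared

    @property
    def elbo_trace(self) -> np.ndarray:
        return self.fit_result.elbo_trace

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    def predict(self) -> Trace:
        """Model trace at the posterior mean, on the observed grid."""
        return self.fit_result.predicted

    def theta(self) -> dict:
        """Full parameter dict (posterior means merged with fixed values)."""
        return self.model.priors.assemble(self.params.to_numpy())

    def summary(self) -> str:
        return self.fit_result.summary()

    def to_frame(self) -> pd.DataFrame:
        return self.fit_result.to_frame()

    def plot(self, ax=None):
        """Observed vs fitted trace (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        obs = self.model.endog
        pred = self.predict()
        ax.plot(obs.times, obs.values, ".", ms=3, label="observed", color="tab:orange")
        ax.plot(pred.times, pred.values, "-", label="fit", color="tab:blue")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("[DA] (uM)")
        ax.legend()
        return ax

    def __repr__(self) -> str:
        return (
            f"<ReleaseModelResults {self.model.variant} R2={self.rsquared:.3f} "
            f"converged={self.converged}>"
        )
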