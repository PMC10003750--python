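"""Carbon-fiber electrode response and electrochemical adsorption.

The striatal concentration [DA]_S is not observed directly: dopamine
transfers toward the electrode at rate k_S, leaves at rate k_E, and
transiently adsorbs to the carbon surface. Adsorbed dopamine Gamma_DA
returns to the electrode pool at the fixed rate k_Gamma = 1/s, which is
what makes the signal baseline creep upward across rapid successive
bursts:

    d[DA]_E/dt = k_S [DA]_S - k_E [DA]_E + k_Gamma Gamma_DA
    dGamma_DA/dt = k1 [DA]_E - k2 [DA]_E Gamma_DA - k3 Gamma_DA

The measured FSCV trace is [DA]_E decimated to the 10 Hz scan grid
(instantaneous scans every 100 ms, not bin averages). A bypass flag
returns [DA]_S itself, i.e. the signal with the recording artifacts
removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants
from ._kernels import electrode_forward
from .trace import Trace

__all__ = ["ElectrodeParams", "ElectrodeState", "step_electrode", "solve_electrode", "measure_trace"]


@dataclass(frozen=True)
class ElectrodeParams:
    """Transfer and adsorption rates of the carbon-fiber electrode.

    The transfer rates default to k_s = k_e = 6/s (unit steady-state gain,
    ~0.17 s response time); adsorption defaults give a visible but modest
    baseline creep. k_gamma is fixed at 1/s unless explicitly overridden.
    """

    k_s: float = 6.0  # striatum -> electrode (1/s)
    k_e: float = 6.0  # electrode -> away (1/s)
    k_gamma: float = constants.K_GAMMA  # adsorbed -> electrode (1/s)
    k1_ads: float = 0.12  # adsorption (1/s)
    k2_ads: float = 0.10  # concentration-dependent desorption (1/(uM*s))
    k3_ads: float = 0.05  # desorption (1/s)

    def __post_init__(self) -> None:
        for name in ("k_s", "k_e", "k_gamma", "k1_ads", "k2_ads", "k3_ads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def without_adsorption(self) -> "ElectrodeParams":
        """Copy with the adsorption pathway switched off."""
        return ElectrodeParams(
            k_s=self.k_s, k_e=self.k_e, k_gamma=self.k_gamma,
            k1_ads=0.0, k2_ads=0.0, k3_ads=0.0,
        )


@dataclass(frozen=True)
class ElectrodeState:
    """Instantaneous electrode pool [DA]_E and adsorbed pool Gamma_DA (uM)."""

    da_e: float = 0.0
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.da_e < 0 or self.gamma < 0:
            raise ValueError("electrode state concentrations must be non-negative")


def step_electrode(
    da_s: float, state: ElectrodeState, params: ElectrodeParams, dt: float
) -> ElectrodeState:
    """Advance the electrode system one RK4 step under constant [DA]_S."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if da_s < 0:
        raise ValueError("da_s must be non-negative")
    da_e, gamma = electrode_forward(
        np.array([da_s, da_s]), dt,
        params.k_s, params.k_e, params.k_gamma,
        params.k1_ads, params.k2_ads, params.k3_ads,
        state.da_e, state.gamma,
    )
    return ElectrodeState(da_e=float(da_e[-1]), gamma=float(gamma[-1]))


def solve_electrode(
    da_s: np.ndarray,
    dt: float,
    params: ElectrodeParams,
    state0: ElectrodeState | None = None,
):
    """Integrate the electrode ODEs along a fine-grid [DA]_S series.

    Returns ([DA]_E, Gamma_DA) arrays on the same grid.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    da_s = np.asarray(da_s, dtype=float)
    if np.any(da_s < 0):
        raise ValueError("da_s must be non-negative")
    s0 = state0 or ElectrodeState()
    return electrode_forward(
        da_s, dt,
        params.k_s, params.k_e, params.k_gamma,
        params.k1_ads, params.k2_ads, params.k3_ads,
        s0.da_e, s0.gamma,
    )


def measure_trace(
    da_s: np.ndarray,
    tgrid: np.ndarray,
    params: ElectrodeParams,
    fs: float = constants.FSCV_SAMPLING_RATE,
    bypass: bool = False,
    state0: ElectrodeState | None = None,
    meta: dict | None = None,
) -> Trace:
    """Forward the striatal signal through the electrode and sample at fs.

    Decimates by picking the solver sample nearest each scan instant (the
    scan rate must divide the solver rate). With ``bypass=True`` the
    electrode and adsorption dynamics are skipped and [DA]_S itself is
    sampled — the artifact-free view of the model.
    """
    tgrid = np.asarray(tgrid, dtype=float)
    dt = float(tgrid[1] - tgrid[0])
    stride = (1.0 / fs) / dt
    if fs > 1.0 / dt + 1e-9:
        raise ValueError(f"requested fs = {fs} Hz exceeds solver rate {1.0 / dt:.6g} Hz")
    if abs(stride - round(stride)) > 1e-6:
        raise ValueError("the FSCV rate must divide the solver rate evenly")
    stride = int(round(stride))
    if bypass:
        signal = np.asarray(da_s, dtype=float)
    else:
        signal, _ = solve_electrode(da_s, dt, params, state0)
    return Trace(
        times=tgrid[::stride].copy(),
        values=signal[::stride].copy(),
        meta=dict(meta or {}),
    )
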