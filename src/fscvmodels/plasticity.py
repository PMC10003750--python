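"""Short-term facilitation/depression kinetics of evoked dopamine release.

Release per pulse is scaled by A(t), the product of N = 3 kinetic
components H_j(t) (short-term facilitation, short-term depression,
long-term depression). During stimulation each component grows or decays
exponentially at rate f*p_j (positive p_j -> facilitation, negative ->
depression); between bursts each relaxes toward its equilibrium value 1
with time constant tau_j:

    dH_j/dt = f * p_j * H_j * S(t) + (1 - S(t)) * (1 - H_j) / tau_j

The equation is scalar and piecewise linear in every interval where S is
constant, so trajectories are propagated with the exact per-interval
closed form rather than a generic ODE stepper; a fixed-step RK4 stepper
is kept behind the same interface for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimulus import BurstProtocol

__all__ = [
    "COMPONENT_NAMES",
    "PlasticityComponent",
    "PlasticityParams",
    "step_component",
    "kinetic_product",
    "simulate_kinetics",
]

#: Fixed component ordering: index 0 facilitates, 1 and 2 depress.
COMPONENT_NAMES = ("facilitation", "short_depression", "long_depression")


@dataclass(frozen=True)
class PlasticityComponent:
    """One kinetic component: plasticity factor p, time constant tau, value H."""

    p: float
    tau: float
    H: float = 1.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("time constant tau must be positive")
        if self.H <= 0:
            raise ValueError("kinetic component H must stay positive")


@dataclass(frozen=True)
class PlasticityParams:
    """The three (p_j, tau_j) pairs in fixed order.

    Order is (facilitation, short-term depression, long-term depression);
    signs are not enforced because knockout presets zero some factors.
    """

    p: tuple[float, float, float]
    tau: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.p) != 3 or len(self.tau) != 3:
            raise ValueError("exactly three kinetic components are required")
        object.__setattr__(self, "p", tuple(float(x) for x in self.p))
        object.__setattr__(self, "tau", tuple(float(x) for x in self.tau))
        if any(t <= 0 for t in self.tau):
            raise ValueError("all time constants must be positive")

    def components(self, H=(1.0, 1.0, 1.0)) -> list[PlasticityComponent]:
        return [
            PlasticityComponent(p=p, tau=tau, H=h)
            for p, tau, h in zip(self.p, self.tau, H)
        ]


def step_component(
    c: PlasticityComponent, S: int, f: float, dt: float
) -> PlasticityComponent:
    """Advance one component by dt under constant stimulus state S in {0, 1}.

    Uses the exact solution of the component ODE on the interval:
    H -> H*exp(f*p*dt) while stimulated, H -> 1 + (H-1)*exp(-dt/tau) while
    relaxing.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if S:
        H = c.H * float(np.exp(f * c.p * dt))
    else:
        H = 1.0 + (c.H - 1.0) * float(np.exp(-dt / c.tau))
    return PlasticityComponent(p=c.p, tau=c.tau, H=H)


def kinetic_product(components) -> float:
    """Net release kinetic A = H_1 * H_2 * H_3."""
    H = [c.H if isinstance(c, PlasticityComponent) else float(c) for c in components]
    if len(H) != 3:
        raise ValueError("exactly three kinetic components are required")
    return float(np.prod(H))


def _segments(protocol: BurstProtocol, t_end: float) -> list[tuple[float, float, int]]:
    """Partition [0, t_end] into maximal constant-S segments (start, stop, S)."""
    edges = [0.0]
    for a, b in protocol.intervals():
        edges.extend((max(a, 0.0), min(b, t_end)))
    edges.append(t_end)
    edges = sorted(set(e for e in edges if 0.0 <= e <= t_end))
    segs = []
    for a, b in zip(edges, edges[1:]):
        if b > a:
            s = int(protocol.indicator(0.5 * (a + b)))
            segs.append((a, b, s))
    return segs


def simulate_kinetics(
    protocol: BurstProtocol,
    params: PlasticityParams,
    tgrid: np.ndarray,
    initial_H=(1.0, 1.0, 1.0),
    method: str = "analytic",
):
    """Evaluate the three H_j(t) and their product A(t) on a time grid.

    Parameters
    ----------
    protocol : BurstProtocol
    params : PlasticityParams
    tgrid : array
        Non-negative, strictly increasing sample times (s). For the
        analytic method the grid may be arbitrarily coarse; the RK4
        cross-check method requires dt well below min(tau_j, 1/(f*|p_j|)).
    initial_H : triple of float
        Component values at t = tgrid[0]. Defaults to equilibrium (1,1,1);
        a long-depression component carried over from an earlier protocol
        in the same experimental timeline can be passed here.
    method : {"analytic", "rk4"}

    Returns
    -------
    A : array (n,)
    H : array (3, n)
    """
    tgrid = np.asarray(tgrid, dtype=float)
    if tgrid.ndim != 1 or tgrid.size < 1:
        raise ValueError("tgrid must be a 1-D array")
    if np.any(np.diff(tgrid) <= 0):
        raise ValueError("tgrid must be strictly increasing")
    if tgrid[0] < 0:
        raise ValueError("tgrid must be non-negative")
    initial_H = np.asarray(initial_H, dtype=float)
    if initial_H.shape != (3,) or np.any(initial_H <= 0):
        raise ValueError("initial_H must be three positive values")

    if method == "analytic":
        return _simulate_analytic(protocol, params, tgrid, initial_H)
    if method == "rk4":
        return _simulate_rk4(protocol, params, tgrid, initial_H)
    raise ValueError(f"unknown method {method!r}")


def _simulate_analytic(protocol, params, tgrid, initial_H):
    f = protocol.frequency
    p = np.asarray(params.p)
    tau = np.asarray(params.tau)
    n = tgrid.size
    H = np.empty((3, n))
    # Propagate exactly across constant-S segments, evaluating the closed
    # form at every grid point inside each segment.
    segs = _segments(protocol, float(tgrid[-1]) + 1e-12)
    h = initial_H.copy()
    t_seg_start = tgrid[0]
    # Segments before tgrid[0] must first advance the initial state.
    for a, b, s in segs:
        if b <= t_seg_start:
            continue
        a_eff = max(a, t_seg_start)
        inside = (tgrid >= a_eff) & (tgrid <= b)
        dt_pts = tgrid[inside] - a_eff
        if s:
            vals = h[:, None] * np.exp(f * p[:, None] * dt_pts[None, :])
        else:
            vals = 1.0 + (h[:, None] - 1.0) * np.exp(-dt_pts[None, :] / tau[:, None])
        H[:, inside] = vals
        # advance state to segment end
        dt_full = b - a_eff
        if s:
            h = h * np.exp(f * p * dt_full)
        else:
            h = 1.0 + (h - 1.0) * np.exp(-dt_full / tau)
    A = H.prod(axis=0)
    return A, H


def _simulate_rk4(protocol, params, tgrid, initial_H):
    f = protocol.frequency
    p = np.asarray(params.p)
    tau = np.asarray(params.tau)
    dt = float(np.min(np.diff(tgrid)))
    limit = min(tau.min(), *(1.0 / (f * abs(pj)) if pj != 0 else np.inf for pj in p))
    if dt > 0.2 * limit:
        raise ValueError(
            f"tgrid step {dt} s too coarse for RK4 accuracy (need < {0.2 * limit:.3g} s)"
        )
    # Sample S at step midpoints so steps straddling a burst edge get the
    # state of the interval they mostly cover (grids should align to edges).
    S = protocol.indicator(0.5 * (tgrid[:-1] + tgrid[1:]))

    def rhs(h, s):
        return f * p * h * s + (1.0 - s) * (1.0 - h) / tau

    n = tgrid.size
    H = np.empty((3, n))
    H[:, 0] = initial_H
    h = initial_H.copy()
    for i in range(n - 1):
        step = tgrid[i + 1] - tgrid[i]
        s = S[i]
        k1 = rhs(h, s)
        k2 = rhs(h + 0.5 * step * k1, s)
        k3 = rhs(h + 0.5 * step * k2, s)
        k4 = rhs(h + step * k3, s)
        h = h + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        H[:, i + 1] = h
    A = H.prod(axis=0)
    return A, H
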