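"""Stimulation protocols and the burst indicator function S(t).

A burst train is described by its onset times, the pulse count per burst
and the intra-burst frequency. Within the models a burst is treated as a
continuous "on" period of duration NP/f rather than NP individual pulses;
the indicator S(t) is 1 inside a burst window and 0 elsewhere, with closed
(inclusive) interval edges so boundary membership is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import constants

__all__ = [
    "BurstProtocol",
    "stimulus_indicator",
    "make_single_burst",
    "make_repeated_burst",
]


@dataclass(frozen=True)
class BurstProtocol:
    """A train of electrical bursts delivered to the midbrain stimulating electrode.

    Parameters
    ----------
    onsets : tuple of float
        Burst start times t_i in seconds, strictly increasing and
        non-overlapping (t_{i+1} >= t_i + NP/f).
    np_pulses : int
        Number of pulses NP per burst.
    frequency : float
        Intra-burst pulse frequency f in Hz.
    current : float
        Stimulus current I in mA.
    onset_shift : float
        Constant added to every onset when evaluating S(t). The
        spatiotemporal models place burst onsets slightly earlier than the
        simple model to compensate for the diffusion lag through the dead
        space; a small negative shift implements that. Default 0.
    """

    onsets: tuple[float, ...]
    np_pulses: int = constants.PULSES_PER_BURST
    frequency: float = constants.BURST_FREQUENCY
    current: float = constants.STIM_CURRENT
    onset_shift: float = 0.0

    def __post_init__(self) -> None:
        if len(self.onsets) == 0:
            raise ValueError("protocol needs at least one burst onset")
        onsets = tuple(float(t) for t in self.onsets)
        object.__setattr__(self, "onsets", onsets)
        if any(t < 0 for t in onsets):
            raise ValueError("burst onsets must be non-negative")
        if self.np_pulses <= 0:
            raise ValueError("np_pulses must be a positive integer")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive (Hz)")
        if self.current <= 0:
            raise ValueError("current must be positive (mA)")
        dur = self.burst_duration
        for a, b in zip(onsets, onsets[1:]):
            if b < a + dur:
                raise ValueError(
                    f"bursts overlap: onset {b} s < previous offset {a + dur} s"
                )

    @property
    def burst_duration(self) -> float:
        """Duration NP/f of one burst in seconds."""
        return self.np_pulses / self.frequency

    @property
    def n_bursts(self) -> int:
        return len(self.onsets)

    @property
    def total_on_time(self) -> float:
        """Total stimulation time: n_bursts * NP/f seconds."""
        return self.n_bursts * self.burst_duration

    @property
    def end_time(self) -> float:
        """Offset of the last burst (ignoring onset_shift)."""
        return self.onsets[-1] + self.burst_duration

    def intervals(self) -> list[tuple[float, float]]:
        """Closed [start, stop] windows where S(t) = 1, with onset_shift applied."""
        dur = self.burst_duration
        return [(t + self.onset_shift, t + self.onset_shift + dur) for t in self.onsets]

    def indicator(self, t) -> np.ndarray:
        """Evaluate S(t) elementwise; returns 0/1 with inclusive edges."""
        t = np.asarray(t, dtype=float)
        if not np.all(np.isfinite(t)):
            raise ValueError("t must be finite")
        out = np.zeros(t.shape, dtype=float)
        for a, b in self.intervals():
            out = np.where((t >= a) & (t <= b), 1.0, out)
        return out if out.shape else float(out)

    def with_shift(self, onset_shift: float) -> "BurstProtocol":
        return replace(self, onset_shift=onset_shift)

    def to_dict(self) -> dict:
        return {
            "onsets": list(self.onsets),
            "np_pulses": self.np_pulses,
            "frequency": self.frequency,
            "current": self.current,
            "onset_shift": self.onset_shift,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BurstProtocol":
        return cls(
            onsets=tuple(d["onsets"]),
            np_pulses=int(d.get("np_pulses", constants.PULSES_PER_BURST)),
            frequency=float(d.get("frequency", constants.BURST_FREQUENCY)),
            current=float(d.get("current", constants.STIM_CURRENT)),
            onset_shift=float(d.get("onset_shift", 0.0)),
        )


def stimulus_indicator(protocol: BurstProtocol, t) -> np.ndarray:
    """Burst indicator S(t): 1 iff t lies within some burst window [t_i, t_i + NP/f]."""
    return protocol.indicator(t)


def make_single_burst(
    t0: float = 5.0, current: float = constants.STIM_CURRENT
) -> BurstProtocol:
    """Single Burst protocol: one train of 30 pulses at 50 Hz starting at t0."""
    if t0 < 0:
        raise ValueError("t0 must be non-negative")
    return BurstProtocol(onsets=(t0,), current=current)


def make_repeated_burst(
    t0: float = 5.0,
    current: float = constants.STIM_CURRENT,
    interstimulus: float = 5.0,
    spacing_convention: str = "offset_to_onset",
) -> BurstProtocol:
    """Repeated Burst protocol: six Single Bursts separated by a 5 s interstimulus period.

    The interstimulus period is read by default as the stimulus-free gap
    between the *offset* of one burst and the *onset* of the next, so
    consecutive onsets are NP/f + 5 = 5.6 s apart. Pass
    ``spacing_convention="onset_to_onset"`` for 5 s onset spacing instead.
    """
    if t0 < 0:
        raise ValueError("t0 must be non-negative")
    dur = constants.PULSES_PER_BURST / constants.BURST_FREQUENCY
    if spacing_convention == "offset_to_onset":
        step = dur + interstimulus
    elif spacing_convention == "onset_to_onset":
        step = interstimulus
    else:
        raise ValueError(f"unknown spacing convention {spacing_convention!r}")
    onsets = tuple(t0 + k * step for k in range(6))
    return BurstProtocol(onsets=onsets, current=current)
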