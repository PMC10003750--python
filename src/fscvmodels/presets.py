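"""Best-fit parameter presets for WT and synuclein-knockout mice.

The registry holds the published best-fit kinetic and release parameters
for each genotype (wildtype, alpha-synuclein knockout, synuclein triple
knockout), experimental sweep (1 or 6) and burst protocol (Single "S" or
Repeated "R"), for all three model variants. K_m is fixed at 0.2 uM
throughout. Preset names are single tokens like ``WT-sweep1-S``.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import constants
from .plasticity import PlasticityParams
from .stimulus import BurstProtocol, make_repeated_burst, make_single_burst

__all__ = ["Preset", "get_preset", "list_presets", "PRESETS"]

MODEL_VARIANTS = ("sur", "stur", "stdr")


@dataclass(frozen=True)
class Preset:
    """One genotype/sweep/burst parameter set.

    ``da_p`` maps model variant -> DA_P (uM/mA for sur/stur, uM*um/mA for
    stdr); ``v_m`` is the maximal DAT uptake velocity (uM/s), shared
    across variants within a row.
    """

    name: str
    genotype: str
    sweep: int
    burst: str  # "S" single or "R" repeated
    plasticity: PlasticityParams
    da_p: dict
    v_m: float
    km: float = constants.KM_DEFAULT

    def release_params(self, model: str = "sur"):
        from .release import ReleaseUptakeParams

        if model not in MODEL_VARIANTS:
            raise KeyError(f"unknown model variant {model!r}")
        return ReleaseUptakeParams(da_p=self.da_p[model], v_m=self.v_m, km=self.km)

    def protocol(self, t0: float = 5.0) -> BurstProtocol:
        if self.burst == "S":
            return make_single_burst(t0)
        return make_repeated_burst(t0)


# (p1, tau1, p2, tau2, p3, tau3) per genotype/sweep; tau in s.
_KINETICS = {
    ("WT", 1): (0.0105, 7.50, -0.003, 15.0, -0.0011, 900.0),
    ("WT", 6): (0.0105, 7.50, -0.003, 12.5, -0.0011, 900.0),
    ("aSynKO", 1): (0.0050, 7.25, -0.003, 37.5, 0.0, 900.0),
    ("aSynKO", 6): (0.0040, 7.25, -0.003, 45.0, 0.0, 900.0),
    ("SynTKO", 1): (0.0040, 7.25, -0.003, 37.5, 0.0, 900.0),
    ("SynTKO", 6): (0.0040, 7.25, -0.004, 37.5, 0.0, 900.0),
}

# (sur DA_P, stur DA_P, stdr DA_P, V_m) per genotype/sweep/burst.
_RELEASE = {
    ("WT", 1, "S"): (0.420, 0.422, 2.43, 4.8),
    ("WT", 1, "R"): (0.395, 0.400, 2.30, 4.8),
    ("WT", 6, "S"): (0.305, 0.310, 1.79, 3.2),
    ("WT", 6, "R"): (0.280, 0.290, 1.70, 3.2),
    ("aSynKO", 1, "S"): (0.460, 0.460, 2.65, 4.8),
    ("aSynKO", 1, "R"): (0.450, 0.443, 2.55, 4.8),
    ("aSynKO", 6, "S"): (0.320, 0.315, 1.80, 3.2),
    ("aSynKO", 6, "R"): (0.295, 0.295, 1.70, 3.2),
    ("SynTKO", 1, "S"): (0.460, 0.460, 2.63, 4.8),
    ("SynTKO", 1, "R"): (0.450, 0.450, 2.55, 4.8),
    ("SynTKO", 6, "S"): (0.506, 0.505, 2.77, 5.6),
    ("SynTKO", 6, "R"): (0.467, 0.467, 2.65, 5.6),
}


def _build() -> dict:
    registry = {}
    for (genotype, sweep, burst), (sur, stur, stdr, v_m) in _RELEASE.items():
        p1, t1, p2, t2, p3, t3 = _KINETICS[(genotype, sweep)]
        name = f"{genotype}-sweep{sweep}-{burst}"
        registry[name.lower()] = Preset(
            name=name,
            genotype=genotype,
            sweep=sweep,
            burst=burst,
            plasticity=PlasticityParams(p=(p1, p2, p3), tau=(t1, t2, t3)),
            da_p={"sur": sur, "stur": stur, "stdr": stdr},
            v_m=v_m,
        )
    return registry


PRESETS = _build()


def get_preset(name: str) -> Preset:
    """Look up a preset by its case-insensitive token, e.g. ``WT-sweep1-S``."""
    key = name.lower()
    if key not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(p.name for p in PRESETS.values()))}"
        )
    return PRESETS[key]


def list_presets() -> list[str]:
    return sorted(p.name for p in PRESETS.values())
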