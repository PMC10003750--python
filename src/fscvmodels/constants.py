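"""Physical constants and fixed experimental settings.

Every fixed quantity used across the package lives here so that nothing is
inlined at call sites. Units are fixed package-wide: micrometres (um),
seconds (s), micromolar (uM), milliamps (mA).
"""

#: Diffusion coefficient of dopamine in striatal tissue, tortuosity-corrected (um^2/s).
DIFFUSION_COEFF = 240.0

#: Michaelis constant of DAT uptake under normal conditions in mice (uM).
KM_DEFAULT = 0.2

#: Radius of the damaged-tissue ("dead space") annulus around the electrode (um).
DEAD_SPACE_RADIUS = 3.0

#: Radius of the modelled striatal cylinder (um); diameter 100 um.
CYLINDER_RADIUS = 50.0

#: Default spacing between adjacent discrete release sites (um).
SITE_SPACING = 6.0

#: Stimulus current used in the recordings the models target (mA).
STIM_CURRENT = 0.4

#: Pulses per burst in the Single Burst protocol.
PULSES_PER_BURST = 30

#: Intra-burst pulse frequency (Hz).
BURST_FREQUENCY = 50.0

#: FSCV sampling rate (Hz): one concentration sample every 100 ms.
FSCV_SAMPLING_RATE = 10.0

#: Observation-noise standard deviation of the Gaussian likelihood (uM).
LIKELIHOOD_SD = 0.05

#: Rate of adsorbed dopamine returning to the electrode pool (1/s); fixed at 1.
K_GAMMA = 1.0

#: Number of plasticity kinetic components (facilitation, short- and long-term depression).
N_KINETIC_COMPONENTS = 3

#: Default fine-grid time step for the ODE/PDE solvers (s).
SOLVER_DT = 1e-3

#: Default radial grid spacing for the spatiotemporal models (um).
SOLVER_DR = 0.5
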