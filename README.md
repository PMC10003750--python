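# fscvmodels

Kinetic models of evoked striatal dopamine release measured by in vivo
fast-scan cyclic voltammetry (FSCV), with Bayesian (variational)
parameter fitting.

FSCV reports the dopamine concentration at a carbon-fiber electrode
every 100 ms. When midbrain dopamine neurons are driven with electrical
bursts, the evoked transients encode presynaptic plasticity (how release
facilitates and depresses across and between bursts), dopamine
transporter (DAT) reuptake, diffusion through the damaged "dead space"
around the electrode, and electrochemical adsorption to the electrode
itself. This package implements three forward models of that chain and
an inference engine to estimate their biologically interpretable
parameters from recorded traces, for neuroscientists quantifying release
kinetics under genetic or pharmacological manipulations.

## Models

Release per pulse is `DA_P · I`, scaled by the plasticity kinetic
`A(t) = Π_j H_j(t)` with

    dH_j/dt = f p_j H_j S(t) + (1 − S(t)) (1 − H_j)/τ_j ,

where `S(t)` indicates the stimulation bursts (`NP` pulses at `f` Hz),
`p_j > 0` facilitates and `p_j < 0` depresses, and the three components
represent short-term facilitation, short-term depression and long-term
depression. Uptake follows Michaelis–Menten kinetics `V_m C/(C + K_m)`
with `K_m = 0.2 μM` fixed.

* **SUR** — Simple Uniform Release: well-mixed ODE,
  `d[DA]_S/dt = DA_P·I·f·S·A − V_m[DA]_S/([DA]_S + K_m)`.
* **STUR** — Spatiotemporal Uniform Release: the same reaction embedded
  in a radial reaction–diffusion equation on a 100 μm tissue cylinder
  (`D = 240 μm²/s`), with a dead-space annulus (default 3 μm) that has
  neither release nor uptake; the electrode reads `[DA](R = R_L, t)`.
* **STDR** — Spatiotemporal Discrete Release: as STUR, with release
  entering at discrete radii (concentric shell sources, default 6 μm
  spacing).

The striatal signal then passes through the electrode model

    d[DA]_E/dt = k_S[DA]_S − k_E[DA]_E + k_Γ Γ ,
    dΓ/dt = k1[DA]_E − k2[DA]_E Γ − k3 Γ ,

whose adsorbed pool Γ produces the baseline creep seen across rapid
repeated bursts, and is sampled at 10 Hz.

Fitting is by ADVI: bounded parameters are mapped to the real line,
a Gaussian variational posterior (mean-field or full-rank) is optimized
by stochastic gradient ascent on the ELBO, and each parameter is
reported as a posterior mean ± SD honoring its biological bounds. The
Gaussian likelihood uses `v = 0.05 μM` per sample. See
`docs/methods.md` for numerical details.

## Worked example

Generate a noisy synthetic wildtype Single-Burst trace, then re-fit the
release and uptake parameters:

```python
import fscvmodels as fm

trace = fm.generate_trace(model="sur", preset="WT-sweep1-S",
                          noise_sd=0.05, seed=42)
model = fm.ReleaseModel.from_preset(trace, "WT-sweep1-S",
                                    free=("da_p", "v_m"))
result = model.fit(seed=1, max_iter=600, family="fullrank")
print(result.summary())
```

```
ADVI fit (SUR model, fullrank family)
  iterations: 367   converged: True
  final ELBO: 231.22   R^2: 0.9932

 parameter   post. mean   post. sd     lower     upper
      da_p      0.41893    0.01071         0      1.68
       v_m        4.708     0.1658         0      19.2

  fixed: k1_ads=0.12, k2_ads=0.1, k3_ads=0.05, k_e=6, k_s=6, km=0.2, p1=0.0105, p2=-0.003, p3=-0.0011, tau1=7.5, tau2=15, tau3=900
```

The trace was generated at `DA_P = 0.420 μM/mA` and `V_m = 4.8 μM/s`;
the fit recovers both within ~2%, with the posterior SDs quantifying the
uncertainty left by the measurement noise, and explains 99% of the
variance of the noisy trace. `result.predict()` returns the fitted
trace, `result.plot()` overlays it on the data, and
`fm.run_recovery(...)` repeats this over many replicates and reports
error and coverage statistics per parameter.

The twelve published parameter rows (wildtype, α-synuclein knockout and
synuclein triple-knockout mice; sweeps 1 and 6; Single and Repeated
Burst) are available as presets: `fm.list_presets()`.

## Command line

```sh
fscvmodels presets list
fscvmodels simulate run.yaml --out trace.txt       # forward simulation
fscvmodels simulate run.yaml --out s.txt --artifact-free   # [DA]_S itself
fscvmodels fit run.yaml trace.txt --out summary.tsv
fscvmodels recover run.yaml --out report.tsv       # parameter recovery
```

`run.yaml` is a schema-validated configuration (model variant, protocol,
priors, geometry, solver settings, seed); unknown keys are rejected.

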