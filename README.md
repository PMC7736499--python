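# papsim

Perisynaptic astroglia and glutamate spillover: a stochastic 3D simulator of
the synaptic micro-environment plus the quantification toolbox used to study
LTP-driven withdrawal of perisynaptic astroglial processes (PAPs).

## The problem

Hippocampal excitatory synapses are wrapped by nanoscopic astroglial
processes whose GLT-1 glutamate transporters confine released glutamate to
the cleft. If LTP induction makes these processes withdraw, glutamate
travels further and activates high-affinity extrasynaptic NMDA receptors —
including receptors of neighbouring, silent synapses. `papsim` provides,
for researchers modelling or measuring this phenomenon:

* **`papsim.simcore`** — a Monte Carlo simulator: 3000 glutamate molecules
  released at the cleft centre of a calibrated 3D environment (truncated
  250-nm hemispheres, 300 x 20 nm apposition zone, 200 nm cleft, 20-30 nm
  intercellular gaps, extracellular fraction alpha ~ 0.15), Brownian
  diffusion at D = 0.4 um^2/ms, stochastic capture by transporters on a
  perisynaptic astroglial collar, and activation of extrasynaptic NMDAR
  clusters at 200-250 nm, under four astroglial-coverage scenarios
  (baseline; withdrawal conserving transporter number; withdrawal losing
  half the transporters; lateral re-arrangement), compared within shared
  32-run ensembles.
* **`papsim.optical`** — astroglial volume-fraction readout
  VF = (F_roi - F_bg)/(F_soma - F_bg) and its exponential decay fit
  VF(t) = VF_ss + (1 - VF_ss) e^(-t/tau); FRAP recovery rates; point-source
  extracellular diffusivity from Gaussian variance growth w = D_eff t;
  glutamate-sensor dF/F0 profiles and FWHM = 2 sqrt(2 ln 2) sigma;
  ratiometric FRET responses.
* **`papsim.nanoscale`** — 3D localization nearest-neighbour distance
  densities (GLT1-bassoon), the 20-nm STED contact rule, line-profile FWHM
  widths, and astroglial volume fractions in 100-nm concentric shells
  around postsynaptic densities.
* **`papsim.crosstalk`** — MK801 two-pathway cross-talk statistics and the
  spillover arithmetic: per-discharge activation probability from
  (1-p)^n = 1-f, density-scaled nearest-neighbour distance d0 p^(-1/3),
  extracellular-space increase, paired-pulse ratio, 1/CV^2, MK801 decay
  constants.
* **`papsim.synth`** — seeded generators for every input the analyses
  consume, with ground truth stored beside the data.

See `docs/methods.md` for models, assumptions, parameter defaults and
limitations.

## Worked example

```python
from papsim import simcore

model = simcore.build_geometry()          # calibrated default environment
print(f"alpha = {model.ecs_fraction:.3f}")

sim = simcore.SimConfig(n_runs=8, rng_seed=1)
comparison = simcore.compare_scenarios(model, sim)
print(comparison.table[["scenario", "open_integral_mean",
                        "capture_fraction_mean"]].to_string(index=False))
```

prints (8-run demonstration ensemble; the full comparison uses 32):

```
alpha = 0.152
scenario  open_integral_mean  capture_fraction_mean
baseline            2.382888               0.219833
       i            3.445561               0.219417
      ii            3.758112               0.146750
     iii            3.385551               0.216042
```

`alpha` is the extracellular volume fraction of the constructed
environment. Each row is one astroglial-coverage scenario run in its own
sector of the same stochastic ensemble: `open_integral_mean` is the
time-integrated open count of that sector's extrasynaptic NMDAR cluster
(channel-ms per run, mean over runs) — the remote-activation readout — and
`capture_fraction_mean` is the fraction of released glutamate taken up in
that sector. All three perturbed patterns clearly exceed baseline; the
contrasts *among* them are smaller than 8-run noise (here scenario ii
happens to land on top). At the full 32 runs, withdrawal with conserved
transporter number (scenario i) shows the highest remote activation, and
halving the transporter number (ii) takes up the least glutamate — see the
scenario-ordering test in `tests/test_acceptance.py`.

Analysis example — recover a VF decay from synthetic data:

```python
from papsim.synth import gen_vf_trace
from papsim.optical import fit_vf_decay

trace, truth = gen_vf_trace(vf_ss=0.77, tau=14.0, noise_sd=0.02, seed=7)
fit = fit_vf_decay(trace)
print(f"VF_ss = {fit.vf_ss:.2f} +- {fit.vf_ss_stderr:.2f}, "
      f"tau = {fit.tau:.1f} +- {fit.tau_stderr:.1f} min")
# VF_ss = 0.75 +- 0.02, tau = 14.6 +- 2.1 min
```

A command-line interface mirrors the library
(`papsim simulate | compare-scenarios | analyze-vf | analyze-diffusivity |
analyze-frap | analyze-linescan | nnd | shells | crosstalk |
spillover-arithmetic | generate`), each command taking a YAML `--config`,
`--set key=value` overrides and `--seed`, and writing a run record beside
its output.

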