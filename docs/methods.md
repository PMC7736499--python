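# Methods

This note documents the models and procedures implemented in `papsim`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generators do and do not emulate.

## The scientific setting

High-affinity glial glutamate transporters (GLT-1/EAAT1-2) expressed on
perisynaptic astroglial processes (PAPs) confine the action of synaptically
released glutamate largely to the cleft. If LTP induction makes PAPs
withdraw from potentiated synapses, released glutamate should travel
further, activating high-affinity extrasynaptic NMDA receptors — including
those of neighbouring, non-active synapses ("spillover cross-talk"). The
package implements (a) a stochastic 3D model of this competition between
diffusion, transporter capture and extrasynaptic NMDAR activation under four
astroglial-coverage patterns, and (b) the quantification procedures used to
measure PAP withdrawal and its functional consequences in imaging and
electrophysiology data: astroglial volume-fraction (VF) readout and decay
fitting, FRAP, point-source diffusivity, glutamate-sensor profile widths,
single-molecule nearest-neighbour statistics, concentric-shell coverage
profiles, and MK801 two-pathway cross-talk statistics.

## The simulator (`papsim.simcore`)

### Geometry

The synapse is modelled as two truncated 250-nm spheres (presynaptic bouton,
postsynaptic spine head) whose flat faces form a 300 nm wide, 20 nm high
apposition zone containing a 200 nm wide cleft. The synapse is embedded in a
periodic cubic lattice of obstacles (neighbouring neurites) separated by
20-30 nm extracellular gaps (default 25 nm). The cube side is set
analytically from the gap width so the bulk extracellular space (ECS)
fraction is alpha = 0.15; with the default dimensions the voxel-integrated
alpha of the full environment is 0.152 at 5 nm pitch, and the integrator is
cross-checked against a uniform-random-point volume estimator. Because the
voxel grid is generally incommensurate with the lattice period, the
axis-aligned cubes are integrated with exact per-axis partial-volume
weights; the smooth sphere surfaces use centre sampling.

The obstacle packing is *calibrated*: changing the gap width re-derives the
cube side so that bulk alpha stays at 0.15. The packing actually used is
recorded in the model (`GeometryModel.packing_record`).

Perisynaptic astroglia are represented by a reactive "collar": a 25-nm-thick
shell centred 30 nm outside the apposition edge (radius 180 nm), spanning
the free gap between the two cell surfaces. Transporter sites are scattered
through this shell; a membrane-folding factor (default 6) converts the
nominal collar ring area into the much larger convoluted PAP membrane area,
bringing total transporter numbers (~2500 at 7,500 um^-2) to the scale
implied by millimolar-range effective transporter concentrations near
hippocampal synapses. The collar carries no solid volume (it is a capture
region, not a wall), so it does not perturb alpha.

Extrasynaptic NMDAR clusters sit on the postsynaptic sphere surface at
200-250 nm from the synaptic centroid — the half nearest-neighbour synapse
distance — one cluster of 24 receptors per sector, all sectors carrying the
same cluster template (rotated copies) so per-sector readouts differ only
through the coverage scenario and the stochastic run.

The extrasynaptic space is divided into four azimuthal sectors separated by
infinitely thin reflective partitions (starting 10 nm outside the apposition
edge). The four coverage scenarios occupy the four sectors of a single run;
the partitions enforce the sector non-interaction that this shared-run
design assumes. A diagnostic reports the fraction of binding events whose
molecule first left the synapse through a different sector.

### Coverage scenarios

* **baseline** — transporters at reference density over the collar patch
  (60 degrees of azimuth per 90-degree sector, full z-extent).
* **i** — withdrawal conserving transporter number: occupied area halved
  (the presynaptic-side half of the collar is retained, opening the corridor
  toward the postsynaptic extrasynaptic NMDAR cluster), local density
  doubled.
* **ii** — withdrawal with transporter loss: same geometry as (i) at
  unchanged density, so half the transporters.
* **iii** — lateral re-arrangement: area and number conserved, patch shifted
  azimuthally to one flank of the NMDAR cluster.

### Dynamics

3000 glutamate molecules are released at the cleft centre and take Brownian
steps with per-axis variance 2 D dt, D = 0.4 um^2/ms (free-medium value;
tortuosity emerges from the explicit obstacles). The time step is the
largest satisfying sqrt(6 D dt) <= gap/4 (~16 ns at 25 nm gaps), so narrow
gaps are resolved. Per-step displacements are drawn from a zero-mean uniform
with exactly the required variance; over the >= 10^3 steps of any observable
interval the propagator is Gaussian by the central limit theorem, and the
ensemble MSD satisfies the Einstein relation exactly in expectation (checked
against 6 D t within 3 SE in the tests). Solid surfaces reflect by step
rejection.

The outer boundary of the ~1.9 um domain absorbs by default: a molecule
that wanders that far is booked as "escaped", representing dilution into
and eventual uptake by the distal neuropil, whose astroglial transporters
are ubiquitous. A reflective (mirror) option represents instead a periodic
tissue with no distal sink; the choice matters for long-time comparisons
(see below). Mass conservation is exact under either boundary: free +
transporter-bound + receptor-bound + (taken-up + escaped) = 3000 at every
output bin, with escaped identically zero in the reflective mode.

Binding uses the standard particle-based reaction-radius approach: a
molecule within the reaction radius of a free site binds with a
per-encounter probability. A helper derives per-step binding probabilities
from bimolecular on-rates (well-mixed-within-radius construction) for users
who prefer rate-based parametrisation; the shipped defaults specify the
encounter probability directly.

### Kinetic schemes and their defaults

Rates live in configuration objects (`KineticScheme`), never in code. The
defaults are effective desk-scale values chosen once, within physiological
reasoning, to place the model in the regime of interest —
transporters that initially buffer rather than instantly remove glutamate:

* Transporter (3-state: free -> bound -> translocated, with stochastic
  re-release): reaction radius 4 nm, encounter probability 0.9, k_unbind =
  10 /ms, k_transport = 2.5 /ms. Uptake efficiency per capture is therefore
  0.2 — captured glutamate is re-released four times out of five, the
  stochastic-unbinding buffering that is central to the spillover
  mechanism. The 4-nm radius
  keeps single-pass capture sensitive to local site density (mean site
  spacing ~8 nm at baseline), so doubling the density genuinely tightens
  the astroglial seal; with a large radius a site is always within reach
  and scenarios i and ii would be artificially indistinguishable.
* NMDAR (C0 <-> C1 <-> C2 <-> O, two glutamate bindings): reaction radius
  10 nm, encounter probability 0.5, k_off = 0.06 /ms (slow, GluN2B-like),
  k_open = 0.1 /ms, k_close = 0.2 /ms. Bound glutamate cannot unbind while
  the channel is open.

These choices are deliberately on the fast-cycling side of the literature
spread for a millisecond-scale observation window; slower unbinding rates
(~0.1-0.5 /ms) leave most captured glutamate unresolved within any window
short enough to simulate at 16-ns steps, hiding the buffering dynamics the
model exists to exhibit. The window (default total_time = 2 ms) covers the
rise and most of the extrasynaptic activation transient at these rates.

### Readouts

Per run and sector: NMDAR open-channel count per time bin (peak and time
integral), cumulative transporter uptake, free molecules beyond a 200-nm
probe radius (dwell-time readout), and the cross-sector binding diagnostic.
Ensembles (default 32 runs, per-run streams spawned deterministically from
one root seed) are summarised as mean +/- sd; `compare_scenarios` returns
one table row per scenario.

## Analysis procedures

* **VF readout** — VF = (F_roi - F_bg) / (F_soma - F_bg); scale-invariant,
  exactly 1 at the soma. Decay after LTP induction is fitted as
  VF(t) = VF_ss + (1 - VF_ss) exp(-t/tau) by least squares with parameter
  standard errors; a non-decaying trace (drop below twice the noise-derived
  threshold) is flagged unidentifiable rather than silently fitted.
* **Point-source diffusivity** — each post-puff line profile is fitted with
  a Gaussian exp(-(x - xc)^2 / (4 w)); since the kernel variance spreads as
  w = D_eff t (sigma^2 = 2 w), D_eff is the slope of w(t), by default
  regressed through the origin (free-intercept option available, since the
  original regression convention is not stated). Per-line fits use
  moment-based width initialisation and are individually rejected on
  failure; more than 50% rejections aborts.
* **FRAP** — recovery rate = initial slope of the baseline-normalised
  recovery over its first 20% (exponential-fit alternative behind a
  switch); reported absolutely and as percent of a reference recording.
  The estimator is deliberately simple: the underlying recordings report
  *relative* changes in diffusion coupling, not absolute diffusivities.
* **iGluSnFR profiles** — dF/F0(x) from disjoint pre/post line windows;
  Gaussian fit with the centre fixed at the uncaging spot by default
  (free-centre option for QC); FWHM = 2 sqrt(2 ln 2) sigma, exact on exact
  Gaussians.
* **Ratiometric sensor** — dR(t) = donor/acceptor minus baseline mean, with
  zero-acceptor masking; a one-site saturation fit recovers the
  half-saturation constant from titrations.
* **Nearest-neighbour statistics** — 3D Euclidean NND via a k-d tree;
  binned probability density normalised to integrate to 1, per-bin SEM over
  preparation-level groups (NaN for a single group). Synapse grouping, when
  needed, clusters the synaptic-marker channels with DBSCAN and assigns
  GLT1 points to the nearest clustered marker (the original grouping rule
  is unstated; parameters are exposed).
* **STED proximity and width** — contact iff edge distance <= max(20 nm,
  one pixel) at the 19.53-nm pixel size; spine width is the FWHM of a short
  line profile by direct half-maximum crossing with linear interpolation
  (not a Gaussian fit), erroring on edge-peaked (truncated) profiles.
* **Shell profiles** — astroglial VF in 100-nm concentric spherical shells,
  0-0.5 um, around a PSD centroid: occupied-voxel volume over in-grid shell
  volume, with out-of-grid shells flagged as truncated. Surface area uses
  exposed-face counting with a 2/3 correction (face counting overestimates
  smooth surfaces by ~3/2 for isotropic orientations); exactness is not
  claimed. Only spherical shells are implemented (curvilinear PSD-following
  shells give qualitatively identical results in practice).
* **Cross-talk statistics** — cross-talk percent = 100 (1 -
  mean(resumed)/mean(NMDAR baseline)) on the silent pathway; per-discharge
  probability solves (1 - p)^n = 1 - f (the compound independent-discharge
  model — only the compound model yields ~0.4% per discharge from
  f = 40%, n = 120; simple division f/n does not); density-scaled nearest-neighbour distance
  d0 p^(-1/3); ECS increase = dVF x VF_astro / ECS; paired-pulse ratio,
  1/CV^2 = mean^2/variance (binomial-model prediction N p/(1-p)), and the
  MK801 trial-decay constant from an exponential fit over trial number
  (non-decaying series flagged unidentifiable). Amplitudes are rectified to
  magnitudes at load time; no baseline detrending by default.

## Synthetic data (`papsim.synth`)

Each generator is deterministic given (parameters, seed) and serialises its
ground truth alongside the data. Defaults reproduce the experimental
operating points of LTP-induced PAP withdrawal: VF decay to 0.77 with tau = 14 min under 2% noise; point-source
scans at D in the 0.1-1.0 um^2/ms range with the bolus kept inside the
scanned line and a constant detector offset so additive noise is not
rectified at zero; uncaging scan pairs with a +9% spatial-width change;
three-channel localization clouds with GLT1 on a noisy spherical shell
(150 nm control / 200 nm potentiated) around bassoon clusters; sphere and
ellipsoid voxel masks; and two-pathway EPSC series under a binomial release
model (N = 20 sites, p = 0.35, q = 10 pA) with use-dependent MK801 block
and an injectable silent-pathway cross-talk reduction.

Noise models are additive Gaussian for imaging, multiplicative Gaussian for
EPSC amplitudes, optional Poisson shot noise for line scans. The generators
emulate the statistical structure the estimators assume — they do not
emulate point-spread functions, drift, photobleaching, detector nonlinearity
or motion artefacts, so passing recovery tests demonstrates estimator
correctness under the stated noise models, not robustness to real-world
instrument pathologies.

## What the scenario comparison shows

At the defaults above, the shared-run ensemble comparison reproduces the
expected qualitative behaviour: all three perturbed coverage patterns raise
remote NMDAR activation above baseline, and withdrawal with conserved
transporter number (scenario i) raises it the most — the retained,
density-doubled patch seals the off-corridor routes and recycles captured
glutamate (80% re-release) into the single opened corridor toward the
receptor cluster, while scenario ii's leakier patch lets molecules disperse
and escape and scenario iii only exposes one flank. These are ensemble-mean
statements at 32 runs; single runs overlap substantially.

A counter-intuitive consequence of the same mechanism deserves emphasis:
removing all transporters does *not* maximise remote activation in this
model. The zero-transporter control loses the seal-and-recycle effect —
glutamate that would have been captured, held and re-released beside the
corridor instead disperses into the surrounding neuropil and is lost to the
distal sink — so its ensemble-mean activation falls slightly below
scenario i (while still exceeding the other patterns). Buffering by
transporter unbinding can therefore locally out-weigh the uptake they
perform. Under the reflective boundary, where nothing is ever lost
distally, the ranking inverts: survival dominates, the no-uptake control is
maximal, and the transporter-conserving scenario loses its edge. The
boundary condition thus selects which of the two competing channels —
steering/buffering versus survival — controls the comparison; the shipped
default (absorbing) is the regime in which the coverage-scenario ordering
matches the experimentally supported mechanism.

## Numerical choices and limitations

* Reflection by step rejection introduces an O(step) boundary layer bias,
  negligible at 6-nm steps against 20-nm gaps.
* Receptor-encounter checks scan the (small) cluster lists directly;
  transporter encounters use a uniform hash grid in CSR form, nearest free
  site within the reaction radius.
* Simulation sizes were chosen for a desk-scale package: 3000 molecules,
  32 runs, 2-ms window, 24 receptors per sector, ~2000 transporter
  sites. The scenario contrasts are genuine but modest relative to
  run-to-run variance; ensemble means at 32 runs resolve the ordering, and
  the tests pin the random streams for reproducibility.
* The obstacle lattice is a regular idealisation of the neuropil; real
  tissue tortuosity is irregular. Only alpha is calibrated.
* The two-glutamate NMDAR scheme omits desensitised states; open
  probability is therefore an effective, not a biophysically complete,
  quantity.
* Voxel ECS integration is exact for the lattice term and centre-sampled
  for spheres; at 5 nm pitch the total error is ~1e-4 against Monte Carlo
  sampling.
* The sector partitions are a modelling device for running four scenarios
  in one stochastic environment; they have no biological counterpart.
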