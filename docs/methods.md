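# Methods

## Model system

`dendrinh` models two dentate gyrus cell classes as branched passive/active
cable trees: fast-spiking parvalbumin-expressing interneurons (PVIs) and
granule cells (GCs). The scientific question the protocols address is how
the somato-dendritic distributions of the GABA_A reversal potential
(E_GABA) and of the GABAergic peak conductance (G_GABA) decide whether
*on-path* inhibition (between an excitatory dendritic input and the soma)
or *off-path* inhibition (distal to the input) dominates the cell's
input-output transformation.

Each compartment obeys

    C_m dV/dt = -g_L (V - E_L) - g_Na m^3 h (V - E_Na) - g_K n^4 (V - E_K)
                - g_h q (V - E_h) - sum_syn g_syn(t) (V - E_syn)
                + axial coupling + I_inj,

integrated with backward Euler; the branched linear system is solved
exactly once per step by parent-ordered Gaussian elimination on the tree
(parent index < child index), giving one O(N) sweep per time step.
Gating variables use an exponential-Euler update evaluated at the
previous-step voltage; synaptic double exponentials and the
Ornstein-Uhlenbeck background conductances use exact per-step analytic
updates, so no waveform aliasing occurs at the default dt.

### Passive parameters

* PVI: R_a 170 Ohm cm, C_m 0.9 uF/cm^2, R_m rising from 10 kOhm cm^2 at
  the soma to 100 kOhm cm^2 at the distal tips as
  R_m(d) = R_dist − (R_dist − R_soma) exp(−tau d / d_max) with the
  dimensionless constant tau = 5 over normalized path distance. The
  functional form is configurable (`RmSpec`); only the endpoint values and
  tau are constrained.
* GC: R_a 210 Ohm cm; C_m 1.0 uF/cm^2 at soma and primary dendrites,
  1.6 uF/cm^2 elsewhere (spine compensation); R_m 80 kOhm cm^2 at soma and
  perisomatic dendrites and 50 kOhm cm^2 beyond. "Perisomatic" is
  implemented as path distance < 20 um (configurable; the boundary is not
  otherwise constrained).
* Leak reversals (PVI −82 mV, GC −70 mV) were set so that, together with
  Ih, the somatic resting potentials land where the printed holding-current
  windows put them: the PVI rests a few mV below −65 mV (positive holding
  current), the GC a few mV above −70 mV (negative holding current).

### Gradients

E_GABA is linear between a proximal anchor at 50 um and a distal anchor at
250 um — PVI: −57.9 → −69.1 mV; GC: −78.2 → −74.4 mV — linearly
extrapolated from the proximal anchor to the soma and clamped at the distal
value beyond 250 um. The anchor distances correspond to the inner- and
outer-molecular-layer stimulation bands (25–75 and 200–250 um). G_GABA is
uniform by default (PVI 14 nS, GC 10 nS per synapse) or linear between
anchors (the fitted PVI gradient runs 14 → 54 nS).

### Active channels

The paper-level densities are: PVI g_Na 25/25/1 mS/cm^2 (soma/axon/
dendrite; 55/85/0 in the spiking preset), g_K 20 mS/cm^2 uniform, g_Ih
1 pS/um^2 (= 0.1 mS/cm^2); the GC uses a reduced spiking set (Na +
delayed rectifier + Ih) standing in for the full eleven-conductance granule
cell model, whose calcium and after-hyperpolarization machinery is out of
scope here.

Kinetics are not constrained by the source data, so the package ships
editable tables (`dendrinh.model.KINETICS`) built on the standard
fast-spiking interneuron Na/K(DR) rate functions (temperature factor
phi = 5) with three adjustable knobs per table: rigid voltage shifts for
the m-gate, h-gate, and n-gate, and a speed factor on m activation. Two
regimes are exposed:

* Subthreshold presets (used for the voltage-clamp and inhibitory-effect
  protocols) keep unshifted rates: the low-Na, high-K dendrites then
  integrate near-linearly, which is the documented integration mode of both
  cell types.
* Spiking presets use m shift −4 mV, h shift +10 mV, unshifted K and an
  m-speed factor of 3. This is the region of kinetics space in which, on
  the synthetic morphologies, (i) the cells hold stably at −65 / −70 mV,
  (ii) a single-site dendritic excitatory conductance can trigger somatic
  spikes, and (iii) no depolarized plateau (window-current bistability)
  exists. The resulting spike-onset voltages (dV/dt > 20 V/s criterion)
  are ≈ −52.6 mV (PVI) and ≈ −48.6 mV (GC) — more hyperpolarized than the
  ≈ −42 / −46 mV measured on the original reconstructed morphologies,
  a known consequence of the stronger dendritic attenuation of the
  synthetic trees (see Limitations).

Ih is a first-order Boltzmann gate (V_1/2 −110 mV, slope 10 mV, tau 50 ms,
E_h −30 mV). The half-activation voltage was placed hyperpolarized enough
that the sag conductance does not dominate the 1-s input-resistance pulse;
with steeper Ih the diameter calibration (below) compensates by shrinking
dendrites several-fold, which destroys the attenuation phenotypes.

### Synapses, clamps, noise

Synaptic conductances are peak-normalized double exponentials
(g(t) = g_max N (e^(−t/τ_d) − e^(−t/τ_r))): excitation τ 0.1/8 ms at
0 mV, GABA_A τ 0.1/20 ms (variants 2 and 4 ms decay supported). The
voltage-clamp electrode is an ideal source in series with R_s (10 MOhm in
the mapping protocols); an "ideal" clamp uses R_s = 100 Ohm. Background
activity is the point-conductance model at the soma: OU excitatory and
inhibitory conductances with means 0.25 and 5 nS reversing at 0 and
−70 mV; the paper states only means and reversals, so sd = mean/3 and
correlation times 2.7 / 10.5 ms follow the standard point-conductance
parameterization; negative samples are floored at zero.

## Synthetic morphologies

The generator grows soma-rooted trees of apical dendrites (PVI: 8
primaries branching once at ~150 um; GC: 5 primaries branching at ~40 and
~150 um), with jittered branch lengths, linear-or-power-law radius taper,
and a short axon (60 / 30 um, 1 um diameter) to carry the axonal Na
density. Geometry defaults were fixed once so that the **calibrated**
trees reproduce four anchors simultaneously: somatic input resistance
(101.5 / 308.7 MOhm), the perisomatic conductance-mapping relation (a
local 14 nS PVI synapse at 50 um reads ≈ 6.5 nS at the soma; measured
value 6.7 nS), the PVI uniform-G attenuation endpoint (g_norm(250) ≈ 0.33
vs 0.36 for the reconstructed morphologies) and the GC endpoint (≈ 0.16 vs
0.15). Calibration itself is a secant loop that rescales all dendritic
radii uniformly until the passive somatic R_in (nonlinear steady state with
Ih at chord conductance, measured as the secant over a −10 mV clamp step —
the infinite-duration limit of the pulse protocol) is within 2% of target;
it errors out after 50 iterations reporting the achieved value.

What the synthetic trees do **not** emulate: real reconstruction artifacts
(varicosities, z-shrinkage), spines (beyond the GC C_m scaling), total
dendritic lengths of real cells (real PV basket cells carry 2–4× more
membrane), and the exact transfer impedances of the deposited
morphologies. Tests that pass on these trees therefore validate the
machinery and the direction/size-class of the effects, not
morphology-specific numbers.

## Protocols

* **Conductance mapping** (passive variant, Na/K removed, Ih retained —
  the same convention as the simulated voltage-clamp experiments; a flag
  drops Ih): GABA synapses at 50–250 um in 50 um steps, somatic clamp
  through 10 MOhm, holding potentials −90…−50 mV in 5 mV steps, peak
  currents baseline-subtracted over a 50 ms window, slope of the I–V line
  = apparent G_GABA, normalized to the 50 um site.
* **IE mapping**: excitation at 150 um (PVI 5 nS, GC 3 nS), single GABA
  site stepped along the same dendrite, GABA onset 4 ms before excitation,
  holding −65 / −70 mV via somatic current. IE = 1 − PSP/EPSP on
  baseline-subtracted positive peaks; search windows 100 ms (PVI) and
  200 ms (GC) after onset, matching the kinetics ranges.
* **IE surface**: IE over an (E_GABA, G_GABA) grid at the 50 um (on-path)
  or 250 um (off-path) site.
* **Discharge**: spiking presets plus somatic background noise; seven GABA
  synapses on distinct apical branches in the 50–100 um (on-path) or
  200–250 um (off-path) band, activated sequentially at 2 ms intervals
  starting 20 ms before the excitation; per-synapse conductances PVI 14
  (on) / 54 nS (off), GC 7.5 nS. The seven branches are drawn (seeded)
  from dendrites *other than* the one carrying the excitation, mirroring
  the distributed placement of the uncaging sites; same-branch placement
  would locally shunt the excitatory input and erase the on/off asymmetry.
  Spikes are counted by the dV/dt > 20 V/s criterion in a 50 ms window
  after excitation onset (inhibited trials fire at longer latency, so a
  20 ms window undercounts them); both spikes/trial and the fraction of
  trials with ≥ 1 spike are reported, with 40 trials by default.
* **IPSP propagation**: one distal (250 um) GABA input at the off-path
  per-synapse conductance; IPSP peak recorded at every compartment along
  the path to the soma, absolute and normalized to the induction site.

All protocols are pure functions of (model, parameters, seed); rerunning
with the same inputs reproduces results tables bit-for-bit.

## Estimators and inverse procedures

E_GABA is the x-axis intercept of a third-order polynomial fit to the
amplitude–voltage relation; when the cubic has several real roots in the
data range the one nearest the empirical zero crossing is taken (the
multi-root rule is not otherwise specified). The IE–EPSP-amplitude
relation is fit per cell with a single exponential extrapolated over
1–25 mV; discharge curves with a logistic; slope conductance by ordinary
least squares (pA/mV = nS).

`calibrate_local_ggaba` inverts the mapping protocol at the 50 um site
(secant iteration on the near-proportional local→somatic conductance
relation, 1% tolerance). `fit_ggaba_gradient` grid-searches the distal
endpoint of a linear G_GABA gradient anchored at (50 um, 14 nS), scoring
each candidate by the sum of squared differences between model and target
*normalized* profiles over the distances the target actually contains
(no interpolation of unmeasured points; absolute-conductance weighting is
available), then refines by golden section around the best grid point.

## Synthetic recordings

`gen_iv_dataset` produces amplitude–voltage data with known reversal,
optional cubic distortion and Gaussian noise. `gen_sweep_set` builds
EPSP/IPSP/PSP sweep triplets whose per-sweep rise times and half-durations
are sampled from the in vitro statistics and inverted numerically (smooth
root-finding on the continuous waveform, 1% tolerance) into
double-exponential time constants; the PSP is a linear sum or, under the
driving-force option, the response of a leaky compartment in which the
inhibitory conductance acts through the instantaneous (V − E_GABA) — the
pure-shunt case (E_GABA at baseline) yields a flat IPSP trace with a
nonzero true IE. Noise is white Gaussian; the noiseless truth (amplitudes,
IE) is recorded per sweep before noise is added, so every downstream
statistic can be scored without re-simulation.

## Numerical choices

Default dt 25 us (10 us for spiking runs); default spatial resolution
5 um maximum compartment length (finer than 0.1 length constants
everywhere for these parameters; a lambda-based rule is available).
Halving dt changes recorded peaks by < 0.5% (tested). Holding currents are
found by secant iteration on the settled somatic voltage (tolerance
0.1 mV). Spike onsets are linearly interpolated at the dV/dt threshold
crossing and grouped with a 2 ms refractory rule. Peak currents subtract a
50 ms pre-onset baseline mean. Degenerate inputs (all-zero discharge data,
single-sign I–V data, unrealizable kinetics) raise flagged errors rather
than returning numbers.

Problem sizes used by the shipped test-suite and acceptance script —
synthetic trees of ~900–1200 compartments, 9-point holding grids,
12–16 trials per discharge point, 100 synthetic I–V datasets — were chosen
as the smallest sizes at which the estimator variance is clearly below the
tolerances being checked.

## Known limitations

* The synthetic GC attenuates single-site excitation more strongly than
  the reconstructed cells, so its somatic EPSP saturates only a few mV
  above spike threshold. Off-path inhibition therefore suppresses GC
  discharge more than in the original data (where it was mild); the
  qualitative asymmetry survives in overcome-ability — GC off-path
  silencing yields to strong drive (p(spike) ≈ 0.6–0.7 at 58 nS) while GC
  on-path and PVI off-path silencing never do.
* Spike-onset voltages sit ~6–10 mV hyperpolarized of the values measured
  on the deposited morphologies, for the same reason.
* The gradient-swap controls (PVI given a GC-like uniform E_GABA, GC given
  the PVI gradient) can show GABAergic boosting of discharge when the
  depolarizing proximal E_GABA approaches the lowered spike threshold;
  they are reported qualitatively and not part of the validated claims.
* Fitting the PVI gradient against the in vitro-style attenuation target
  (endpoint 0.61) pushes the distal estimate to large values (≥ 46 nS)
  but the synthetic forward map saturates below 0.61, so that estimate is
  an upper-region value, not an interior optimum; the quantitative
  recovery guarantee (±10%) holds for self-generated targets.
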