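# Methods

## Scope and model overview

`socsim` simulates the brainstem circuit that encodes interaural time
differences (ITDs): per-ear inner-hair-cell (IHC) synaptic release drives
spiral ganglion neuron (SGN) spike trains, which converge onto spherical and
globular bushy cells (SBC, GBC) of the ipsilateral cochlear nucleus; medial
superior olive (MSO) cells on each side then receive binaural SBC excitation
and binaural GBC-driven inhibition and act as coincidence detectors.  The
difference between left and right MSO population rates over ITD (ΔR) is the
circuit's azimuth code.  Two peripheral neuropathies associated with hidden
hearing loss are modeled: *myelinopathy* (heterogeneity of the length L_u of
the SGN's initial unmyelinated segment, 10–20 µm) and *synaptopathy* (loss
of IHC–SGN synapses, either selectively high-threshold or random).

## Cell models

SBC and GBC share a single-compartment conductance-based model of the
Rothman–Manis type II flavor (fast Na with α/β kinetics, high- and
low-threshold K⁺, H-current, leak to E_rest), differing only in excitatory
in-degree (4 vs 40) and unitary synaptic strength (13 vs 4.76 nS,
instantaneous-rise exponential decay, τ = 0.2 ms).  The MSO cell carries
Na, low-threshold K⁺ (w⁴z), H-current and leak on a 70 pF membrane;
excitation is an alpha conductance (A = 54.37 nS, τ = 0.17 ms, axonal
delays 1.5/1.6 ms ipsi/contra) and inhibition a rise–decay double
exponential (A = 5.5 nS, τ 0.14/1.6 ms, delays 1.5/1.0 ms, E_in = −70 mV).
MNTB/LNTB relays are not modeled; the inhibitory delays absorb relay time.

Two conventions are fixed as part of this package's model definition:

* the bushy current balance includes the H-current term and the synaptic
  current alongside Na, KHT, KLT and leak (so that g_h, E_h and the r gate
  participate in the dynamics), and
* inhibition enters as a non-negative conductance times (V − E_in), the
  sign that makes a current with a −70 mV reversal hyperpolarizing above
  rest.

Circulating transcriptions of this MSO kinetics family differ in the
Na-inactivation time constant.  We use
τ_h = 19.23/(7·e^{(V+60)/11} + 10·e^{−(V+60)/25}) + 0.12 ms, which follows
the same compositional pattern as the KLT activation τ_w.  This choice
matters for one result: the single-cell resonance minimum sits at 250 Hz
under this form and near 340 Hz under the faster alternative
(19.2/(37e^{…}+10e^{…})+0.12); the resonance such cells are known for
(~300 Hz) lies between the two.  We kept the pattern-consistent form
rather than tuning between them.

## Synthetic periphery

The upstream ear (middle ear → basilar membrane → IHC receptor potential →
vesicle pools) is not reimplemented.  Release events at each intact synapse
are an inhomogeneous Poisson process
λ(t) = r_class(L)·m(φ(t)) + r_spont with a per-class sigmoidal rate–level
function r(L) = r_max/(1+exp(−(L−θ)/k)) and a phase density
m ∝ max(sin φ, 0)^e normalized to unit cycle average.  Each release fires
the SGN with probability p(L_u) = clip(0.95 − 0.08·(L_u−10), 0, 1) at the
release time plus latency 0.5 + 0.08·(L_u−10) ms plus Gaussian jitter of
SD 0.05 + 0.04·(L_u−10) ms, pruned by a 0.7 ms absolute refractory period.

**Calibration.** The free constants were fixed against four facts the
circuit must reproduce at 200 Hz / 50 dB: SGN population vector strength
≈ 0.82, SBC ≈ 0.93, a ≈ 10% SGN rate loss when all HT synapses are removed,
and ≈ 1/3 loss when the same synapse count is removed at random.  Defaults:
θ_LT/θ_MT/θ_HT = 15/30/75.5 dB, k = 6 dB, r_max = 6000 s⁻¹,
r_spont = 30 s⁻¹, e = 8.  The large r_max puts low/medium-threshold
synapses in a *burst regime*: each fiber fires a short refractory-spaced
volley every cycle whose first spike is locked to ~0.14 ms.  This regime is
forced by the fixed postsynaptic side — a 4-input SBC with 13 nS unitary
conductance and a ≈ 38 nS threshold only fires when most of its inputs
arrive within a fraction of a millisecond — while the population vector
strength stays near 0.82 because the later burst spikes and the
uniform-phase spontaneous component spread the phase histogram.  θ_HT was
bisected so that the HT class carries 10.0% of the SGN *spike* rate at the
operating point (refractory compression makes the release-rate share an
unreliable proxy).

**What the periphery does not emulate.**  No adaptation or vesicle
depletion; a single spontaneous-rate class; rate–level functions saturate
within ~15 dB of threshold (real auditory-nerve dynamic range is wider), so
sound-level effects above ~50 dB are carried almost entirely by HT
recruitment; and at the saturated operating point myelinopathy leaves the
SGN *rate* nearly unchanged (the conduction-failure probability is absorbed
by surplus releases) while still strongly desynchronizing spikes — the
degradation of downstream rate and synchrony with myelinopathy is
reproduced, but its SGN-level rate component is muted relative to a full
compartmental axon model.  Tests of transduction monotonicity therefore
probe below saturation.

## Circuit and protocols

300 cells per population per side by default (SGN: 100 per threshold
class); each SBC pools 4 ipsilateral SGNs, each GBC 40; each MSO cell
receives 6 SBC inputs per side and 3 GBC inputs per side, drawn without
replacement.  The same index wiring is used on both sides, making the
circuit structurally mirror-symmetric; ITD > 0 delays the right-ear phase.
A standard experiment runs 5 independent 100 ms stimuli (trials) with fixed
wiring and fixed neuropathy draw; rates and phases are measured on
[5, 100] ms to skip onset.  Relative rate and relative VS always use the
same experiment's 0% condition with matched seeds as denominator.  Phase
references: monaural populations against their own ear, MSO against the
contralateral ear (its dominant excitation).

## Numerics

Fixed-step RK4 at dt = 0.005 ms.  Gate kinetics are evaluated through
dense lookup tables (0.025 mV grid, linear interpolation) built from the
exact closed forms; the closed forms themselves are exported and tested
against independent transcriptions to 1e-12.  All gate time constants are
floored at 0.004 ms — the MSO Na-activation τ falls to ~1 µs at spike peak
and would destabilize any explicit method at usable steps; the floor is
dt-independent so dt-refinement compares the same dynamics (halving dt
moves spike times by < 0.001 ms in the convergence tests, against a 0.02 ms
requirement).  Synaptic conductances are linear filters propagated exactly
between steps; presynaptic arrivals snap to the nearest grid point
(≤ 2.5 µs).  Spikes are upward crossings of −20 mV with linear
interpolation and a 1 ms detection refractory; gates are clamped to [0,1].
Integration failure (non-finite state) raises an error naming the blow-up
time and cell identity.

## Resonance probe

A single MSO cell with inhibition set identically to zero receives the
alpha conductance restarted at every multiple of 1/f (presynaptic time
t − mod(t, 1/f)); spike probability is output spikes divided by input
count, and the threshold conductance at each frequency is the smallest
drive reaching probability 0.5.  The probe's conductance grid extends to
400 nS because a lone periodic input must substitute for ~4 coincident
network EPSGs (threshold ≈ 144 nS at the best frequency); the probe
duration (200 ms) has no visible effect on the threshold curve between 50
and 400 ms.

## Problem sizes

The shipped test suite and the acceptance script scale population sizes
and trial counts to what the statistics require: single-cell checks run at
full resolution; circuit-level statistics use 30–100 cells per population
for property tests and orderings, and the full 300-cell, 5-trial protocol
for the control-circuit phase-locking and synaptopathy measurements.  The
ITD-sweep frequency scan uses 100 cells, a ±1 ms grid at 0.25 ms steps and
3 trials.  Scaling down population size adds Monte-Carlo noise but does not
change any per-cell statistic, because bushy/MSO inputs are always drawn
from the full 300-fiber SGN pool per side.

## Known limitations

* Absolute SBC/GBC/MSO rates are not calibrated against in vivo data; only
  the relative measures the analyses use are.
* The resonance minimum (250 Hz here) is sensitive to the τ_h ambiguity
  described above.
* Myelinopathy's SGN rate effect is muted at the default operating point
  (see the periphery section); its desynchronizing effect, which drives the
  downstream degradation, is intact.
* ΔR at frequencies ≥ 800 Hz is near zero because the MSO model stops
  firing to cycle-locked volleys faster than its integration window; the
  high-frequency/high-level interactions seen in richer ear models are out
  of reach of this reduced periphery.
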