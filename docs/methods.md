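# Methods

This note documents the model, its calibration, the numerical choices, and
what the synthetic test conditions do and do not establish.

## Network architecture

Three two-dimensional grids share a physical extent of 0.15 × 1.5 mm
(y × x): 10×90 = 900 mossy fibers (MF), 30×270 = 8100 granule cells (GC)
and 5×45 = 225 Golgi cells (GoC), 9,225 units in total. The GC:GoC ratio
of 36:1 is a deliberate reduction of the ~400:1 anatomical ratio that keeps
millimeter-scale simulations tractable while preserving the feedback loop.
Each cell sits at its lattice-cell center displaced uniformly by up to ±20%
of the local grid spacing per axis (`jitter_fraction`, scaled by the
`spatial_randomness` knob) and clamped to the extent. All
distance-dependent quantities are computed from the jittered positions, so
positional randomization effectively randomizes synaptic and gap-junction
strengths.

### Connectivity rules

The convergence targets are MF→GC 4, MF→GoC 100, PF→GoC 4000, GoC→GC 8.
Per-cell convergence is drawn as `round(Normal(mean, 0.05·mean))`, floored
at 1, because realized synapse counts in the reference bookkeeping scatter
around the products of the means (e.g. ~32.5k MF→GC contacts vs 8100×4 =
32,400). The selection rules are:

* **MF→GC** and **GoC→GC**: k nearest presynaptic cells (glomerulus-like
  locality). These reproduce the published population-mean delays —
  0.026 ms (MF→GC) and 0.0758 ms (GoC→GC) — to within a few percent with
  no free parameters beyond the grid geometry.
* **MF→GoC**: sampling without replacement with probability ∝
  exp(−β·d). β is not derivable from published text; it was calibrated
  once to β = 0.0075 µm⁻¹ so the realized mean delay matches the published
  0.312 ms (β = 0.01 gives 0.26 ms, too local). The realized conductance
  spread (±0.50 nS) then also matches the published ±0.506 nS.
* **PF→GoC**: each GoC samples uniformly among GCs whose parallel fiber
  (running along x in both directions, default reach 2.5 mm) passes its x
  position. The fiber path length is |Δx| plus an ascending-segment
  constant (default 0 µm). With the 1.5-mm extent the resulting mean delay
  is ~1.0 ms versus the published 1.308 ms; the ordering of the three
  projection delays, which is what the dynamics depend on, is preserved.
  Divergences are treated as derived quantities (convergence × n_post /
  n_pre), since the published convergence and divergence for GoC→GC are
  mutually inconsistent by ~18%.

### Synaptic conductances

Peak conductances decay with distance as `g_base·exp(−0.01 µm⁻¹·d)`,
except PF→GoC, which is constant along the fiber. Rather than adopting
unmapped per-contact literature values, `g_base` is solved per network
instance so that the realized population means equal the published
realized means (MF→GC AMPAR 2.28 nS, NMDAR 0.198 nS, MF→GoC 0.706 nS,
GoC→GC 0.968 nS, PF→GoC 2.588 nS). The population SDs then emerge from
the distance spread alone and land on the published SDs without further
tuning — a useful consistency check of the geometry rules.

### Gap junctions

GoC pairs within 2 grid spacings (~67 µm) are coupled. Each coupling is
`Gj = min(2.5 nS · exp(−0.03 µm⁻¹·d) · u, 1.25 nS)` with `u ~
Uniform(0.4, 1.6)` (the ±60% physiological variability). The cap encodes
the upper end of the experimentally reported short-range coupling
(0.25–1.25 nS); with the default geometry, nearest-neighbor couplings fall
inside that range and Gj decreases with pair distance (Spearman ρ ≈ −0.7).
Coupling currents are ohmic, `I_into_i = Gj (V_j − V_i)`, applied
bidirectionally with exact antisymmetry.

## Neuron models

Both cell types are exponential integrate-and-fire (EIF) neurons with a
conductance-based afterhyperpolarization (AHP):

C dV/dt = g_L(E_L−V) + g_K(E_K−V) + g_Na·Δ_T·exp((V−V_T)/Δ_T)
          + g_AHP(E_AHP−V) + I_syn + I_gap + I_ext

The exponential term stands in for the sodium spike-initiation current;
setting g_Na = 0 ("sodium suppression") removes spiking *and* disables the
spike detector while leaving the passive membrane intact. On threshold
crossing (0 mV) the trace is pinned at +10 mV for one step, reset, and
g_AHP is incremented — giving the membrane an explicit fast peak and slow
undershoot, both of which matter for what a gap junction transmits.

**GoC** (soma, default single compartment): C = 80 pF; total static
conductance 6.29 nS from the 159-MΩ somatic input resistance, split
between a depolarizing leak (E = −44.5 mV) and a background K conductance
(E = −80 mV) so that the sodium-suppressed cell rests at −60 mV. With
V_T = −57 mV, Δ_T = 3 mV and g_Na = 13 nS there is no stable subthreshold
fixed point, so the cell pacemakes. The pacemaker rate at 0 pA is a
calibration target chosen at 8 Hz — the published single-cell F/I figure
shows spontaneous firing without printing the number, and 2–10 Hz covers
spontaneous Golgi firing in vitro; g_Na and the AHP (1.5 nS per spike,
τ = 60 ms, E = −80 mV) were set once to meet it. The published F/I anchor
points are used only as monotonicity constraints. An optional
4-compartment variant (soma + 3 passive dendrites, 55%/15% conductance
split, 3 nS axial coupling) exists for the soma-versus-dendrite coupling
comparison; network simulations use the single compartment, since coupling
location makes little difference.

**GC** (single sphere, 11.8 µm for bookkeeping): input resistance
1.62 GΩ, rest −70 mV, V_T = −52.8 mV, Δ_T = 1 mV, reset −75 mV,
refractory 2 ms. The EIF rheobase g(V_T−E_L−Δ_T) equals 10 pA by
construction, and the model fires ~165 Hz at 50 pA (target 150 Hz ± 15%).
C = 10 pF was calibrated jointly against the synaptic coincidence
requirement: one mossy-fiber input at the network-mean conductances
(2.28 nS AMPAR + 0.198 nS NMDAR) peaks ~5 mV below threshold, two
simultaneous inputs spike.

**Randomization.** The published ±20% randomization of "leak current,
membrane area and initial membrane potential" maps onto the reduced models
as: leak conductances × Uniform(1±0.2), capacitance × Uniform(1±0.2)
(independent draws), and initial V × Uniform(1±0.2) at simulation start.
The `cell_randomness` knob scales all three fractions together; together
with `spatial_randomness` it implements the randomness-level axis of the
robustness-tuning experiments.

**NMDAR voltage dependence.** The receptor description specifies only time
constants and reversal, so the NMDAR conductance is linear by default; a
standard Mg²⁺-block factor is available behind `nmda_mg_block` but is off
in every documented condition.

## Synapse kinetics and event delivery

Each receptor conductance is a difference of exponentials normalized to
its peak. The engine integrates two state variables per (receptor,
neuron) with exact per-step exponential decay; a synaptic event adds
`g_peak·N` to both at `spike_time + delay`. This recursion agrees with the
closed form to better than 0.1% (tested), and summation is purely linear
(no saturation). Delays are quantized to the integration step with a
one-step minimum (max rounding error dt/2 = 12.5 µs, far below every
population-mean delay).

## Integration

Fixed-step explicit (forward Euler) update with dt = 0.025 ms, chosen so
that dt × (static conductance + gap-junction load)/C stays well below the
stability boundary (checked at startup against the maximum per-cell load).
Gap-junction currents use previous-step voltages (explicit coupling).
Halving dt changes single-cell spike counts by ≤1 spike/s and full-scale
layer rates by <3%. Simulations are bit-reproducible given (network,
stimulus, config): the only randomness at run time is the seeded
initial-potential draw. Spike times are recorded at the detection step;
per-cell spike sequences are strictly increasing because of the refractory
period.

## Stimulation

Each MF draws a rate from Normal(mean, SD) — the published (mean, SD)
pairs from 1 ± 0.71 to 100 ± 8.72 Hz, with a 16-entry variant for the
6-mm network — truncated at 0 (a small upward bias on realized means at
the lowest rates), then fires as a homogeneous Poisson process during
[1000, 2000) ms after 1 s of silence. Poisson is the natural reading of
"random" drive with no stated regularity structure. Rates are redrawn per
(trial, seed). Resonance scans inject A·sin(2πft), A = 0.1 nA, into every
GoC soma over background 7 ± 2.86 Hz MF noise. The sparse-drive variant
restricts MF→GoC inputs to a seeded random fiber subset (default 50%
active) while leaving the GC drive intact.

## Analysis pipeline

Only the centered cells of each layer are analyzed (60% of rows, ~91% of
columns — exactly 6×82, 18×246 and 3×41 at full scale), which removes the
reduced-in-degree border cells. Mean firing rates average spike counts over
*firing* neurons across the stimulation second; this published convention
inflates the sparse GC layer's value relative to an all-neuron mean (and
is the convention under which rates are invariant to the coupling toggle —
the all-neuron GC mean shifts with recruitment). PSTHs use 1-ms bins.

Spectra are time-averaged Morlet scalograms (`pywt` complex Morlet,
bandwidth 1.5, center frequency 1.0) of the mean-subtracted PSTH on a
log-spaced 1–120 Hz grid; this normalization is flat for white noise above
~4 Hz and recovers synthetic sinusoid peaks to ±0.5 Hz. "Normalized power"
scales a spectrum by its maximum per condition.

Cycle extraction low-pass-filters the PSTH with a 5th-order Butterworth.
The stated 500-Hz cutoff sits exactly at the Nyquist frequency of the
1-kHz sampling, so the filter is implemented with its normalized cutoff
clipped just below 1 and applied forward-backward (zero phase), keeping
cycle peak times unbiased. Cycles are local maxima above a noise floor of
pre-onset mean + 3 SD, separated by ≥8 ms, with prominence ≥5% of the
post-onset peak-to-peak range (the prominence test rejects the integer
quantization ripple that a near-Nyquist filter passes). First-cycle
latency is the first peak after stimulus onset minus the onset; "no cycle"
returns NaN, never 0.

The robustness effect pairs runs that share the network instance and
stimulus realization and differ only in the gap-junction flag:
Δamplitude = mean over index-paired cycles of (amplitude with − without),
in spikes/bin, and Δlatency = latency(without) − latency(with).

## Test-scale conditions and problem sizes

The `mini` preset (5×30 MF, 15×90 GC, 3×15 GoC over 75 × 500 µm, broad
convergences scaled to the shrunken pools: MF→GoC 17, PF→GoC 667)
preserves densities and per-cell drive, and is the package's chosen scale
for trend-style checks; full-scale (default) runs back the quantities that
need population averaging. Specifically, in the tests: structural counts,
delay and conductance statistics, the rate/frequency invariance under the
coupling toggle, the latency advance and the oscillation band are
evaluated at full scale; the amplitude-gain trends across (MF rate, PF
weight) and the randomness inverted-U use 3-trial means at mini scale,
where the absolute cycle-amplitude differences resolve the trend reliably.
At full scale with single trials the absolute amplitude difference
saturates at high MF rates in this reduced model (cycle amplitudes grow
with rate), so the declining trend is a reduced-scale statement here.

## What passing tests show — and what they do not

The synthetic conditions establish the mechanism: electrically coupled,
heterogeneous pacemakers synchronize; that synchrony strengthens and
advances feedback-driven population oscillations without changing their
frequency or the layers' mean rates; and the effect needs intermediate
biological variability (too little → already synchronized, too much →
coupling cannot synchronize). They do not reproduce the original power
surfaces number-for-number: the neurons here are reduced EIF models, not
the multi-channel conductance models, so absolute powers, exact band edges
(the full-scale feedback peak sits at ~32 Hz, at the top of the 15–30 Hz
band), and GoC rates at extreme drive differ quantitatively. The MF drive
is steady-state (unmodulated), so transient or bursty input regimes are
out of scope, as are 3D geometry and anatomically detailed glomeruli.

## Known limitations

* The rate/frequency invariance under the coupling toggle holds in the
  feedback configuration; in the purely feedforward configuration (no
  parallel fibers) the coupled network recruits more granule cells, and
  GC rates are not invariant — consistent with the coupling's strong
  effect there.
* The GC mean rate *decreases* with feedback weight in this model (more
  inhibition), so rate monotonicity in feedback weight is asserted for the
  GoC layer only.
* The elongated 6-mm preset runs at reduced density (same cell counts,
  stretched extent); full-density elongation is configurable but not a
  default condition.
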