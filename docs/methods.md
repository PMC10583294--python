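# Methods

## Model and assumptions

`flipcorr` models hyperpolarization dynamics with a single-compartment
rate equation, `dP/dt = (A − P)·kW − kR·P`: one polarization pool, one
source proportional to the unoccupied capacity `A − P`, one first-order
relaxation channel. The model assumes the sample is describable as a
single compartment (homogeneous radical distribution, fast spin
diffusion); multi-compartment samples violate this and corrected
parameters for them are unreliable. The thermal nuclear polarization is
neglected against the hyperpolarized signal (valid for enhancements
≫ 1), so relaxation drives P toward 0 rather than toward P_eq, and a
readout pulse — a coherent process — acts on the hyperpolarization
exactly like an extra incoherent relaxation channel, which is what
makes the analytical correction possible.

Parameters and units:

| parameter | meaning | default | units |
|---|---|---|---|
| `A` | polarization capacity | 1 (pure simulation), thermal electron polarization ≈ 0.89 for DNP workflows | fraction |
| `kW`, `kR` | injection / relaxation rate | from observables via `kW = P0/(A·τ)`, `kR = (1 − P0/A)/τ` | 1/time |
| `θ` | readout flip angle | — | degrees at every public boundary |
| `TR` | repetition time | — | same unit as τ |
| `noise σ` | additive Gaussian sd on the measured (transverse) signal | 0 | signal units |

Time units are an opaque label (`a.u.` or `s`), carried through and
never converted: different samples live on second-to-hour timescales
and nothing in the mathematics depends on the unit.

Thermal polarization uses the spin-1/2 closed form
`P_eq = tanh(h·f/(2·k_B·T))`, with the electron frequency derived from
the 1H frequency via the gyromagnetic ratio 658.21. At the field of a
299 MHz 1H system and 3.3 K this gives 0.89 for the electron, the value
used as capacity `A` in DNP workflows.

## Pulsed-readout simulation

Pulses occur at `t = TR, 2·TR, …` (first-pulse time configurable); the
recorded sample is the polarization immediately **before** each pulse,
after which the state is multiplied by cos θ. This pre-pulse convention
is what reproduces the package's apparent-parameter table (e.g.
P0′ = 0.091 at 25°/TR 2); post-pulse sampling does not, which was
confirmed against the fixed-point oracle before building on it.

Because free evolution between pulses is an affine map, the pre-pulse
samples follow the geometric recurrence `P_{n+1} = P* + (P_n − P*)·ρ`
with `ρ = cos θ·e^(−TR/τ)`; the simulator propagates this closed form,
so it is exact to rounding and has no step-size parameter. An explicit
Euler time-slicer (`slice_integrate`) is kept solely as an independent
cross-check; it converges first-order to the analytic engine and warns
if its step exceeds TR/10. Consequence of the closed form: noiseless
pre-pulse samples lie *exactly* on `P0′(1 − e^(−t/τ′))`, which is what
justifies the mono-exponential fit ansatz for pulsed data.

Noise is additive, homoscedastic and Gaussian on the measured
(transverse, sin θ·P) signal — the convention under which the reference
noise level 3.2×10⁻⁴ yields a steady-state SNR of ≈ 40 for a 2.5° pulse
on the canonical build-up. A polarization-scale series therefore
carries noise σ/sin θ; for θ = 0 (no transverse signal) σ is applied in
polarization units. All generators are numpy `default_rng` seeded
explicitly; study replicates derive child seeds via
`SeedSequence(master, spawn_key=(cell, replicate))`, so every study is
bit-for-bit reproducible and individual cells can be recomputed alone.

What the generator does *not* emulate: off-resonance and finite pulse
duration, T2*/FID structure, spectrometer dead time, receiver drift,
multi-exponential behaviour of multi-compartment samples. Passing tests
therefore demonstrate correctness of the correction arithmetic and its
noise robustness under ideal single-compartment sampling, not immunity
to those instrumental effects.

## Fitting

Build-ups are fitted with `P0·(1 − e^(−t/τ))`, decays with
`P0·e^(−t/τ)`, optionally plus a constant offset (recommended for
experimental records whose first point carries a start-up delay; it
stabilizes the fit at the cost of wider intervals). Fits operate on
polarization-scale signals (measured/sin θ) so amplitudes are
comparable across flip angles. Initialization is deterministic: the
amplitude from the last (build-up) or first (decay) decile mean, τ from
a log-linear regression on the appropriately folded signal. Parameters
live in a generous but finite box (|amplitude| ≤ 100× data scale,
τ ∈ [10⁻⁶, 10⁶]× record span) so degenerate low-SNR fits return a
flagged estimate instead of running off to infinity; non-convergence is
flagged, never silent. 95 % intervals are linearized (covariance ×
t-quantile). SNR is reported as the fitted steady-state amplitude over
the noise sd (metadata if known, residual-based otherwise), i.e. the
steady-state *measured* SNR of the uncorrected record.

## Corrections: numerical choices

* `cc_correct_time` is the exact algebraic inverse of the apparent-rate
  relation; its denominator `1/τ′ + ln(cos θ)/TR` is non-positive when
  RF depletion outpaces the apparent rate (aggressively pulsed decays
  whose τ′ is overestimated by noise or flip-angle miscalibration). The
  strict API raises `NonPhysicalCorrectionError`; the pipeline instead
  returns a flagged result carrying the divergent/negative raw value,
  matching how such corrections surface in practice.
* The CC amplitude rescaling `P0′·τ/τ′` is approximate by construction:
  its noiseless recovery error grows from ≈ 0.4 % at 7°/TR 2 to ≈ 1.2 %
  at 12.5° and ≈ 5 % at 25°, always upward. The iterative method's
  residual is smaller there (≈ −1.5 % at 25°), so it is the pipeline
  default.
* The iterative recursion needs the total rate `kW + kR` (just `kR` for
  decays, where the source term is absent). The default is a **single
  pass** with the rate taken from the CC-corrected time constant — on
  noiseless data that rate is exact. An optional outer loop re-derives
  the rate from the refit of the corrected series (≤ 20 iterations,
  relative tolerance 10⁻⁶). Empirically the loop converges but drifts a
  few percent *below* the truth at large flip angles: the recursion's
  first-order-in-((kW+kR)·TR) residual feeds back through the refit.
  The single pass is therefore both the default and the more accurate
  choice; the loop is retained for sensitivity analysis.
* Non-uniform sample spacing is rejected for the per-point correction
  (the recursion is derived for fixed TR), negative corrected values
  under noise are retained (clipping would bias the refit), and the
  first point is kept uncorrected — no pulse precedes it.
* `cos_power_correct` refuses build-ups: its factor diverges while a
  build-up signal saturates, so the "correction" grows without bound.

## Studies and problem sizes

`reproduce_table1` simulates the five standard schemes noiselessly over
300 time units and tabulates fitted (τ′, P0′). `monte_carlo_accuracy`
runs seeded replicates per (θ, TR, P0, σ) cell; the package default is
200 replicates, a desk-scale choice whose cell means are stable to well
under 1 % (a flag raises it to 5000 for full parity with large
published sweeps). `min_snr_map` sweeps P0 over 0.01–0.1 (10 linear
steps) and σ over 3.2×10⁻⁵–3.2×10⁻³ (10 log steps) at TR = 2 with 100
replicates per cell, averages the corrected parameters per cell, and
reports per flip angle the smallest measured steady-state SNR above
which every cell deviates < 10 % from truth; cells whose correction
diverged count as failing, a never-passing grid reports "not attained"
rather than raising. The shipped default covers flip angles 2.5°, 7°
and 25°, spanning the gentle-to-aggressive readout range at tractable
cost. Cell SNR labels use the replicate *median* of measured SNRs so a
single diverged fit cannot inflate a cell's label.

Under these conditions the corrections stay accurate (averaged over
replicates) down to measured SNRs of about 2 for small flip angles,
while 25° requires roughly an order of magnitude more — its apparent
build-up is so short that few informative points remain. The bounded
fits contribute to the small-angle robustness: replicate averages are
not corrupted by unbounded outlier estimates.

## Known limitations

Single compartment only; fixed TR and fixed flip angle per record; no
vendor raw-format readers (input is an integrated-signal time series);
enhancements are corrected scale-free, so absolute polarizations are
only as good as the thermal reference they are anchored to; the CC
amplitude correction should not be trusted above ~25° and decay
corrections degrade earlier than build-up ones, since a strongly pulsed
decay leaves few points above the noise.
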