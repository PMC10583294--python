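"""Correct a noisy pulsed build-up back to its RF-free parameters.

A 25 deg / TR 2 readout of the canonical build-up (P0=0.3, tau=50) is
simulated with noise giving a steady-state SNR of about 40, then
corrected with the analytical (CC) and the per-point iterative method.
"""

import math

from flipcorr import (
    PulseScheme,
    apparent_params,
    correct_experiment,
    estimate_snr,
    fit_buildup,
    params_from_observables,
    simulate_buildup,
)

base = params_from_observables(P0=0.3, tau=50.0, A=1.0)
theta, TR = 25.0, 2.0
app = apparent_params(base, theta, TR)
sigma = math.sin(math.radians(theta)) * app.P0 / 40.0  # SNR ~ 40

ts = simulate_buildup(base, PulseScheme(theta=theta, TR=TR), noise_sigma=sigma, seed=7)
uncorr = fit_buildup(ts)
snr = estimate_snr(ts, uncorr)

print(f"truth:       P0 = 0.300, tau = 50.0")
print(f"uncorrected: P0 = {uncorr.P0_hat:.3f}, tau = {uncorr.tau_hat:.1f}  (SNR = {snr:.0f})")
for method in ("cc", "iterative"):
    res = correct_experiment(ts, method=method)
    print(f"{method:>11}: P0 = {res.P0:.3f}, tau = {res.tau:.1f}")

print()
print("The raw fit underestimates both parameters by a factor ~3; both")
print("corrections recover them to within a few percent at this SNR.")
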