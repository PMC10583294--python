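"""Compare all three corrections on a pulsed polarization decay.

A decay with tau_decay = 173 s is read out with 7 deg pulses every
second; the pulse train makes the decay look more than twice as fast.
All three methods (analytical CC, per-point iterative, and the
decay-only 1/cos^(n-1) point rescaling) recover the true constant.
"""

from flipcorr import (
    PulseScheme,
    correct_experiment,
    fit_decay,
    simulate_decay,
)

kR = 1.0 / 173.0
ts = simulate_decay(kR, PulseScheme(theta=7.0, TR=1.0, n_pulses=300), P_init=0.3)

print(f"true decay constant: 173.0 s")
print(f"uncorrected fit:     {fit_decay(ts).tau_hat:6.1f} s")
for method in ("cc", "iterative", "cospower"):
    res = correct_experiment(ts, method=method)
    print(f"{method:>19}: {res.tau:6.1f} s")

print()
print("On noiseless decays the 1/cos^(n-1) rescaling is exact; under noise")
print("its divergent factor amplifies late-time points and the fit-based")
print("methods (CC, iterative) are preferred.")
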