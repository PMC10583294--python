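"""Thermal polarization and enhancement bookkeeping for a DNP system.

At the field of a 299 MHz 1H spectrometer and 3.3 K, the electron is
almost fully polarized (this sets the polarization capacity A of the
rate-equation model), while protons are polarized only ~0.2 %; a DNP
enhancement multiplies the latter.
"""

from flipcorr import (
    electron_frequency,
    enhancement_to_polarization,
    thermal_polarization,
)

f_1h = 299e6
T = 3.3
P_e = thermal_polarization(electron_frequency(f_1h), T)
P_h = thermal_polarization(f_1h, T)

print(f"electron thermal polarization at 7 T, {T} K: {P_e:.3f}  (capacity A)")
print(f"1H thermal polarization:                     {P_h:.2e}")
eps = 133.0
print(f"enhancement {eps:.0f} -> absolute 1H polarization:  "
      f"{enhancement_to_polarization(eps, P_h):.3f}")

print()
print("An enhancement of 133 over the 0.22 % thermal level corresponds to")
print("about 29 % absolute proton polarization -- a third of the ceiling")
print("set by the 89 % electron polarization.")
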