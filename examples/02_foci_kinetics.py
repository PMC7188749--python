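"""Foci response to a pulse versus a decaying radiotracer exposure.

The gammaH2AX foci curve is the convolution of the dose-rate history with
a two-compartment impulse response (formation 0.10/min, loss 0.006/min,
peak ~30 min).  An X-ray-like pulse and an [18F]-decay profile of equal
total dose illustrate why the radiotracer response is delayed, flattened
and lower.
"""

import numpy as np

from petdsb import DsbKineticsParams, foci_curve, peak_time, steady_state_check

params = DsbKineticsParams()
print(f"impulse response peak time: {peak_time(params):.2f} min")

t = np.arange(0.0, 240.0 + 1e-9, 0.25)
dose, lam = 2.5, np.log(2.0) / 109.77
width = 2.0
pulse = lambda tt: np.where(tt < width, dose / width * (1 - np.cos(2 * np.pi * tt / width)), 0.0)
norm = -np.expm1(-lam * t[-1])
decay = lambda tt: dose * lam * np.exp(-lam * tt) / norm

f_pulse = foci_curve(pulse, params, t)
f_decay = foci_curve(decay, params, t)
print(f"pulse profile:  max {f_pulse.max():.3f} at {t[np.argmax(f_pulse)]:.1f} min")
print(f"decay profile:  max {f_decay.max():.3f} at {t[np.argmax(f_decay)]:.1f} min")
print("equal total dose, but the prolonged exposure yields a lower, later maximum")

ok, dev = steady_state_check(decay, params, (120.0, 240.0), t)
print(f"\nrate-tracking equilibrium in [120, 240] min: {ok} "
      f"(max relative deviation {dev:.3f})")
late = (t >= 120.0) & (t <= 240.0)
spread = (f_decay[late].max() - f_decay[late].min()) / f_decay.max()
print(f"foci-level variation over the window: {100 * spread:.1f} % of the maximum")
print("the loss constant (0.006/min) is comparable to the decay constant")
print("(0.0063/min), so the response never strictly tracks the dose rate --")
print("but the curve sits on its broad maximum and drifts only slowly, which")
print("is what keeps damage rates at different incubation times comparable")
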