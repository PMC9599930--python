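"""Decompose a two-tone signal into variational modes.

Builds 4 s of a 5 Hz + 40 Hz mixture sampled at 256 Hz, decomposes it into
K=2 band-limited modes and prints each mode's center frequency and its
correlation with the pure tone it should isolate.  The center frequencies
should land on 5 and 40 Hz and the correlations near 1, showing that VMD
separates rhythms without any filter design.
"""

import numpy as np

from vmdforest import VMDConfig, decompose
from vmdforest.vmd import center_frequency_scan

fs = 256.0
t = np.arange(int(4 * fs)) / fs
x = np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 40 * t)

result = decompose(x, fs, VMDConfig(K=2, alpha=2000.0, tau=0.1))
for k, (mode, f_hz) in enumerate(zip(result.modes, result.center_freqs_hz), start=1):
    tone = np.sin(2 * np.pi * round(f_hz) * t)
    r = abs(np.corrcoef(mode, tone)[0, 1])
    print(f"VMF{k}: center frequency {f_hz:6.2f} Hz, |r| vs pure tone = {r:.3f}")

residual = np.linalg.norm(x - result.modes.sum(axis=0)) / np.linalg.norm(x)
print(f"relative reconstruction residual: {residual:.3f}")

# over-decomposition diagnostic: with too many modes the solver-order
# center frequencies stop increasing monotonically
print("\ncenter-frequency scan (solver order):")
for row in center_frequency_scan(x, fs, K_range=[1, 2, 3]):
    freqs = ", ".join(f"{f:.1f}" for f in row.center_freqs_hz)
    flag = "monotone" if row.monotone else "NON-MONOTONE (over-decomposed)"
    print(f"  K={row.K}: [{freqs}] -> {flag}")
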