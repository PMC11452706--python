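"""Closing kinetics from a SEC elution time series.

Chromatograms recorded at increasing incubation times with a closing-state
trapping nucleotide are deconvolved into open and closed Gaussian peaks
(shared shapes across the series); the closed-peak area fraction follows
first-order kinetics whose rate constant the exponential fit recovers.
"""

import numpy as np

import fretcycle as fc
from fretcycle.kinetics import fit_bigaussian_series, fit_closing

k_true = 1.03  # min^-1, fast closer at moderate salt
times = np.array([0, 0.2, 0.5, 1, 1.5, 2, 3, 5, 8]) / k_true
series = fc.generate_chromatogram_series(times, k=k_true, f_inf=0.95,
                                         noise_sd=0.01, seed=42)

decs = fit_bigaussian_series(series)
print("time (min)  closed fraction")
for d in decs:
    print(f"  {d.time_min:7.2f}   {d.closed_fraction:.3f}")

rate = fit_closing([d.time_min for d in decs], [d.closed_fraction for d in decs])
print(f"\nfitted k_closing = {rate.k:.3f} +/- {rate.k_stderr:.3f} min^-1 "
      f"(true {k_true}), plateau f_inf = {rate.f_asym:.3f}")
print()
print("The closed peak elutes later (compact state, smaller hydrodynamic")
print("radius); its area fraction rises exponentially to the plateau, and the")
print("rate constant comes back within a few percent at 1% profile noise.")
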