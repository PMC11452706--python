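"""Resolve millisecond interconversion rates by dynamic PDA.

Fixed 0.5/1/2 ms time bins are cut from simulated bursts of a two-state
system (E = 0.2 / 0.9, both rates 0.5 ms^-1).  The shot-noise-limited
proximity-ratio histograms are fitted jointly with the dynamic PDA model;
the bridge between the two quasi-static peaks carries the rate information.
"""

import numpy as np

import fretcycle as fc

truth = fc.TwoStateKineticModel(E1=0.2, E2=0.9, k12=0.5, k21=0.5)
ident = fc.CorrectionSet.identity()
cfg = fc.PdaConfig(bin_durations=(0.5, 1.0, 2.0))

rng = np.random.default_rng(3)
binned = {}
for T in cfg.bin_durations:
    counts = rng.poisson(60 * T, 20_000)
    counts = counts[(counts >= 20) & (counts <= 120)]
    binned[T] = fc.simulate_pda_bins(truth, ident, counts, T, len(counts), rng=rng)

init = fc.TwoStateKineticModel(E1=0.15, E2=0.8, k12=1.0, k21=0.3)
res = fc.fit_pda(binned, init, cfg, corrections=ident)

print(f"true model     : E1=0.20 E2=0.90 k12=0.50 k21=0.50 (ms^-1)")
print(f"fitted model   : E1={res.model.E1:.3f} E2={res.model.E2:.3f} "
      f"k12={res.model.k12:.3f} k21={res.model.k21:.3f}")
print(f"amplitudes     : static1={res.amplitudes[0]:.3f} "
      f"static2={res.amplitudes[1]:.3f} dynamic={res.amplitudes[2]:.3f}")
print(f"reduced chi^2  : {res.redchi:.2f}")
print()
print("The dynamic component should carry essentially all the amplitude and")
print("the rates should come back within a few percent: sub-millisecond")
print("hopping widens the histograms beyond shot noise in a rate-specific way.")
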