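"""Simulate a burst measurement and recover corrected FRET efficiencies.

A dual-labelled dimer hops between a low-FRET open state (E = 0.2) and a
high-FRET closed state (E = 0.9) at 0.5 ms^-1 in each direction while
diffusing through the confocal spot.  The stream is distorted by crosstalk,
direct excitation, unequal detection and background; analysing it with the
matching correction factors must return the species-weighted efficiency.
"""

import fretcycle as fc

corrections = fc.CorrectionSet(alpha=0.05, beta=0.15, gamma=0.8,
                               background_rates=(0.3, 0.2, 0.5))
model = fc.TwoStateKineticModel(E1=0.2, E2=0.9, k12=0.5, k21=0.5)
cfg = fc.SimBurstConfig(n_bursts=1000, truth_corrections=corrections,
                        donor_only_fraction=0.1, seed=7)

stream = fc.simulate_photon_stream(model, cfg)
spans = fc.find_bursts(stream, window_T=0.5, min_in_window=15, min_total=60)
table = fc.analyze_bursts(stream, spans, corrections)
hists = fc.build_histograms(table)

selected = table["S"].between(0.3, 0.7) & table["E"].notna()
print(f"photons simulated      : {len(stream)}")
print(f"bursts found           : {len(table)}")
print(f"dual-labelled selected : {hists['retained']} (stoichiometry 0.3-0.7)")
print(f"mean corrected E       : {table.loc[selected, 'E'].mean():.3f}")
print(f"mean donor lifetime    : {table.loc[selected, 'tauDA_ns'].mean():.2f} ns")
print()
print("The mean corrected E sits between the two state efficiencies at the")
print("equilibrium weight (~0.55 here); the donor lifetime is shortened from")
print("the donor-only 3.8 ns by transfer, as the E-vs-lifetime diagnostics expect.")
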