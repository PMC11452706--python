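# fretcycle

Quantitative analysis of the conformational cycle of the Hsp90 chaperone
dimer — and of any two-state opening/closing system observed the same way —
combining four measurement modalities in one tested Python library:

* **Single-molecule FRET burst analysis.** Freely diffusing dual-labelled
  dimers produce photon bursts; after background subtraction the corrected
  transfer efficiency of a burst is

  E = (F_GR − α·F_RR − β·F_GG) / (F_GR − α·F_RR − β·F_GG + γ·F_GG)

  with α the direct-excitation, β the crosstalk and γ the detection-ratio
  correction, alongside the PIE stoichiometry S and the donor lifetime
  τ_D(A). Static species fall on the line E = 1 − τ_D(A)/τ_D(0); species
  hopping between two states of lifetimes τ₁, τ₂ within a burst follow the
  dynamic FRET line E = 1 − τ₁τ₂ / (τ_D(0)·(τ₁+τ₂−τ)), which lies above the
  static line and diagnoses sub-millisecond dynamics.
* **Dynamic photon distribution analysis (PDA).** Photons are counted in
  fixed time bins; the acceptor count at total count N is binomial with a
  success probability mixed over the analytic distribution of the time
  fraction spent in each state (computed by uniformisation of the two-state
  Markov chain, with exact no-transition endpoint masses p·e^(−kT)).
  Fitting the predicted proximity-ratio histograms — jointly over several
  bin durations — recovers the state efficiencies E₁, E₂ and the
  millisecond interconversion rates k₁₂, k₂₁.
* **Accessible-volume (AV) dye modelling.** The sterically allowed cloud of
  dye positions around a label site is computed by a geodesic flood fill on
  a cubic grid (linker length 21 Å, width 4.5 Å, three-radii dye model,
  e.g. 5.5/4.5/1.5 Å for the donor and 7.15/4.5/1.5 Å for the acceptor),
  yielding structure-based predictions ⟨R_DA⟩, R_mp, ⟨E⟩ and R⟨E⟩ for a
  donor/acceptor pair with E = 1/(1+(R/R₀)⁶), R₀ = 59 Å.
* **Open/closed population kinetics.** SEC elution profiles are deconvolved
  into open and closed Gaussian peaks (shapes shared across a time series);
  the closed-peak area fraction follows f(t) = f_inf(1−e^(−kt)) during
  closing and f(t) = f_eq + (f₀−f_eq)e^(−kt) during reopening, giving
  k_closing / k_opening in min⁻¹. The same rate layer serves
  crosslinking-gel dimer/monomer fraction series.

A first-class synthetic-data generator (`fretcycle.simulate`) produces
photon streams with known hidden state paths and forward-applied
distortions, chromatogram series with known kinetics, gel tables and toy
atomic geometries, so that every stage is testable against ground truth
without instrument data.

## Worked example

`examples/sec_closing_kinetics.py` builds a SEC time series at the yeast
closing rate and recovers it:

```
time (min)  closed fraction
     0.00   0.001
     0.19   0.172
     0.49   0.373
     0.97   0.603
     1.46   0.739
     1.94   0.821
     2.91   0.903
     4.85   0.944
     7.77   0.954

fitted k_closing = 1.028 +/- 0.004 min^-1 (true 1.03), plateau f_inf = 0.952
```

The closed fraction rises exponentially to its plateau and the fitted rate
matches the generating 1.03 min⁻¹ within its standard error.
`examples/pda_dynamics.py` does the same for millisecond dynamics:

```
true model     : E1=0.20 E2=0.90 k12=0.50 k21=0.50 (ms^-1)
fitted model   : E1=0.201 E2=0.900 k12=0.513 k21=0.494
amplitudes     : static1=0.025 static2=0.000 dynamic=0.975
reduced chi^2  : 1.07
```

The other examples cover burst analysis under full corrections
(`burst_analysis.py`) and AV validation plus pair statistics
(`accessible_volume.py`). A thin CLI (`fretcycle simulate|bursts|pda|av|
kinetics|run`) wraps the same functions for shell use.

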