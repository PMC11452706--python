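# Methods

This note records the models implemented in `fretcycle`, the assumptions
behind them, the defaults that matter and the choices made where the design
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Photon-stream model and the correction inverse

Bursts are modelled as Poisson photon emission at a constant rate while the
molecule traverses the confocal volume; burst durations are exponential
(mean 3 ms by default) and inter-burst gaps exponential with ten times that
mean, which makes bursts trivially separable without simulating diffusion
through a Gaussian excitation profile. Within a dual-labelled burst the
hidden conformational state follows a continuous-time Markov chain started
from its stationary law (two states by default; an n-state generator with a
full rate matrix is available).

The forward distortions are constructed so that the accurate-FRET formula
is their exact inverse in expectation:

* crosstalk re-assigns a detected donor photon to the red channel with
  probability c = β/(1+β), so the leaked signal is exactly β·F_GG;
* the FRET-sensitised acceptor pathway is detected with relative
  efficiency γ/(1+β), making γ·F_GG the correctly scaled donor signal;
* direct excitation adds an independent Poisson stream into GR with rate
  α times the acceptor-excitation rate, i.e. exactly α·F_RR;
* background is homogeneous Poisson per channel over the full acquisition.

Defaults (α = 0.05, β = 0.15, γ = 0.8, background 0.3/0.2/0.5 photons/ms,
60 photons/ms burst rate, donor-only lifetime τ_D(0) = 3.8 ns, acceptor
lifetime 3.5 ns, 50 ns excitation period) are typical for a green/red
MFD-PIE setup with Atto-class dyes; the instrument the data emulate is not
parameterised in more detail than the analysis needs. Microtimes are
single-exponential truncated to the excitation period; there is no IRF
convolution, triplet blinking or multi-molecule coincidence — consequently
a passing test validates the estimators' statistics, not their robustness
to those instrument effects.

Burst search is the all-photon sliding window (≥ 15 photons within
±0.25 ms, bursts ≥ 60 photons), conventional MFD values, all exposed as
parameters. Correction factors are inputs, not estimated from donor-only /
acceptor-only subpopulations: with synthetic truth the inputs are exact,
and the estimation procedure itself is out of scope. Donor lifetimes per
burst are maximum-likelihood estimates of a truncated exponential (solved
by bisection from the sample mean); with ≥ 20 photons and τ ≪ period this
reduces to the sample mean. Corrected E is deliberately not clipped to
[0, 1] — photon-starved bursts keep their shot-noise wings and are flagged
instead.

## Dynamic PDA

For a bin of duration T containing N donor-excitation photons the acceptor
count is Binomial(N, ε̄(f₁)), where f₁ is the fraction of T spent in state 1
and ε̄ interpolates the two states' apparent (distorted) efficiencies.
Because photon arrivals are uniform given N, this binomial mixing is exact
for the generator's physics, which is what makes the bin-level Monte-Carlo
oracle a genuine cross-check rather than a re-implementation.

The distribution of f₁ for a stationary two-state chain is computed by
uniformisation: with Λ = k₁₂+k₂₁, the number of virtual jumps is
Poisson(ΛT); given n jumps the n+1 interval lengths are Dirichlet(1,…,1)
and — a special property of the two-state chain uniformised at Λ — the
interval states are i.i.d. Bernoulli(p₁). Hence f₁ | (n, a) ~ Beta(a, n+1−a)
with a ~ Binomial(n+1, p₁), and the endpoint masses sum exactly to the
no-transition probabilities p₁e^(−k₁₂T), p₂e^(−k₂₁T). The series cost grows
as (ΛT)²; above ΛT = 40 a moment-matched Beta surrogate (exact mean p₁ and
variance 2p₁p₂(ΛT−1+e^(−ΛT))/(ΛT)²) replaces it, where the endpoint masses
are already e^(−ΛT)-negligible. The variance step across the threshold is
below one percent.

Fitting minimises χ² (σ² = max(observed, 1) per histogram bin) over
(E₁, E₂, k₁₂, k₂₁) and three mixture amplitudes — quasi-static state 1,
quasi-static state 2 and the dynamically interconverting component.
A single bin duration leaves the static amplitudes partially degenerate
with the dynamic component's endpoint masses; fitting several durations
jointly (0.5/1/2 ms in the examples and recovery checks) breaks this, since
endpoint masses move with T while a static population does not. Defaults:
1 ms bins, counts 20–120 per bin, 41 proximity-ratio bins, 101 occupancy
grid points. The PDA histogram model omits direct acceptor excitation and
background (assumed negligible or pre-compensated at the configured count
range); the burst-level analysis carries the full correction set. Standard
errors come from the local curvature at the optimum; fits are deterministic
given data and initial values.

## Accessible volumes

A grid point belongs to the AV iff a path from the attachment atom of
geodesic length ≤ L (21 Å) reaches it with every path cell clearing all
atoms by half the linker width (2.25 Å), and the endpoint clears all atoms
by the dye radius. The attachment residue's own atoms are excluded from
clash tests, and cells within linker_width/2 plus the attachment atom's
van der Waals radius of the attachment point are always traversable: the
first linker segment necessarily threads the clash zone of the atoms bonded
to the label site, and without this stem exemption buried-by-collar sites
would be unreachable on coarse grids.

Geodesics use a chamfer propagation with all coprime integer offsets up to
three cells, each step allowed only if the straight segment's intermediate
cells are free (so thin walls cannot be jumped); the metric error of this
neighbourhood is below one percent of L on average, confirmed by the
sphere-volume check (< 5 % deficit at 0.5 Å spacing, dominated by the
chamfer overshoot near the boundary). AV3 averages the three single-radius
AVs sharing one geodesic field, weighting grid points by the number of AVs
containing them. Pair statistics (⟨R_DA⟩, R_mp, ⟨E⟩, R⟨E⟩) are weighted
Monte-Carlo over point pairs, deterministic per seed, with the exhaustive
decimated double sum as the test oracle. Defaults follow the
Atto532/Atto643 labelling (radii 5.5/4.5/1.5 and 7.15/4.5/1.5 Å, spacing
0.9 Å); the attachment atom defaults to SG for cysteines, CB otherwise,
since label sites are cysteines but structures may carry the wild-type
residue. Van der Waals radii come from a fixed internal per-element table.

## SEC and gel kinetics

"Bi-Gaussian" is implemented as a sum of two Gaussians, one per
conformational state, because the decomposition's purpose is a closed-state
area fraction; component areas are analytic (amplitude·σ·√2π). For a time
series the centers and widths are shared across all time points (the
conformers do not change shape during incubation) with per-time amplitudes;
this global fit is initialised deterministically from the modes of the
first and last profiles — the most extreme mixtures — falling back to the
two largest smoothed local maxima of the pooled profile. Each center is
bounded to its own side of the initial gap so a one-component profile
cannot be fitted by two coincident Gaussians; an optional shared-σ
constraint stabilises strongly overlapping peaks. The closed state elutes
later by default (compact state, smaller hydrodynamic radius); the
assignment is a switch, not a hard-coded rule.

Closing kinetics are first-order growth to a plateau, f(t) = f_inf
(1 − e^(−kt)) with f(0) = 0; opening is f(t) = f_eq + (f₀ − f_eq)e^(−kt)
with f_eq free (nucleotide exchange that leaves part of the dimers closed)
or pinned to zero. First-order laws are the only model consistent with a
single quoted rate constant per condition. Gel lanes give the crosslinked
fraction dimer/(dimer+monomer), optionally monomer-weighted by a
staining-mass ratio, and feed the same closing fit; the gel generator
supports a nonzero fraction at t = 0 for species whose closed state is
populated already at mixing.

Synthetic chromatogram series default to 1 % additive noise (of the series
maximum), peak centers 10.4/11.0 mL with σ = 0.25 mL, plateau 0.95, and a
time grid of 0, 0.2, 0.5, 1, 1.5, 2, 3, 5, 8 in units of 1/k — the sampling
a kineticist would choose for a rate expected on that timescale. These are
the conditions under which the rate-recovery checks run.

## Problem sizes and numerics

Recovery checks use sizes at which the estimators' statistical error is
comfortably below the tolerances being demonstrated: 10–20 thousand PDA
bins per bin duration (20 seeded replicates for the median-error property),
several hundred bursts per efficiency point, nine chromatogram time points
with three-figure signal-to-noise, AV grids of ≤ 90³ cells. Histogram χ²
uses observed-count weights; rate and peak fits use Levenberg–Marquardt
via lmfit with deterministic initialisation throughout (half-change time
for rates, profile modes for peaks). Degenerate inputs are flagged, not
guessed at: flat fraction series (unidentifiable rate), near-degenerate
PDA states (|E₁−E₂| < 0.05), photon-starved bursts, buried label sites.

## Known limitations

The generator omits diffusion-profile brightness variation, acceptor
photophysics (blinking/bleaching), IRF convolution and multi-molecule
events, so corrections and PDA are validated under ideal photon statistics
only. PDA fitting is strictly two-state (the simulator is n-state capable);
Gaussian within-state distance broadening is not modelled. Correction
factors are not estimated from data. The AV model has no dye-surface
sticking term, and the linker-dynamics modification of the static FRET line
at high efficiency is not applied. Structure-based AV predictions for the
closed Hsp90 dimers require the user to supply the PDB files; the engine is
validated against analytic geometries in their absence.
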