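"""Static and dynamic photon distribution analysis (PDA).

PDA predicts the full shot-noise-limited histogram of per-bin proximity
ratios: photons are counted in fixed-duration time bins, and for a bin with
N donor-excitation photons the acceptor-channel count is binomial with a
success probability set by the apparent (corrected) FRET efficiency.  For a
molecule hopping between two states within the bin, the success probability
is the occupancy-weighted mixture of the two state efficiencies, mixed over
the analytic distribution of the fraction of bin time spent in state 1.
Fitting the predicted histograms to the measured ones recovers the state
efficiencies and the millisecond interconversion rates.

The occupancy distribution is computed by uniformisation of the two-state
chain: with total rate Lambda = k12 + k21 the number of uniformised jumps
in a bin of length T is Poisson(Lambda*T); conditional on n jumps the n+1
inter-jump intervals are jointly Dirichlet(1,...,1), the interval states
are independently state 1 with probability p1 = k21/Lambda, and therefore
the state-1 time fraction is Beta(a, n+1-a) with a ~ Binomial(n+1, p1).
The endpoint masses come out exactly as the no-transition probabilities
p1*exp(-k12*T) and p2*exp(-k21*T).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Minimizer, Parameters
from scipy import stats
from scipy.special import betainc, gammaln, xlogy

from .models import CorrectionSet, TwoStateKineticModel
from .photons import GR, PhotonStream

__all__ = [
    "PdaConfig",
    "PdaResult",
    "OccupancyDensity",
    "apparent_efficiency",
    "occupancy_density",
    "expected_histogram",
    "bin_photon_stream",
    "fit_pda",
]


@dataclass(frozen=True)
class PdaConfig:
    """Binning and discretisation choices for PDA.

    ``bin_durations`` lists the fixed bin lengths (ms) analysed jointly —
    fitting several bin times simultaneously is what makes the two
    interconversion rates identifiable separately from the quasi-static
    amplitudes.  ``count_range`` keeps only bins whose donor-excitation
    photon count falls inside it; ``n_bins_E`` is the number of proximity-
    ratio histogram bins on [0, 1]; ``occupancy_grid`` the number of grid
    points for the state-1 time fraction.
    """

    bin_durations: tuple[float, ...] = (1.0,)
    count_range: tuple[int, int] = (20, 120)
    n_bins_E: int = 41
    occupancy_grid: int = 101
    min_usable_bins: int = 1000

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.bin_durations):
            raise ValueError("bin durations must be positive")
        if self.occupancy_grid < 51:
            raise ValueError("occupancy_grid must be >= 51")
        if self.count_range[0] < 1 or self.count_range[1] < self.count_range[0]:
            raise ValueError("invalid count_range")


def apparent_efficiency(E: float | np.ndarray, corr: CorrectionSet) -> float | np.ndarray:
    """Probability that a detected donor-excitation photon lands in GR.

    Forward image of the true efficiency under crosstalk (beta) and the
    detection ratio (gamma): eps = (E*gamma + (1-E)*beta) /
    (E*gamma + (1-E)*(1+beta)).  Direct acceptor excitation and background
    are not part of the PDA model (assumed negligible or pre-compensated at
    the configured count range).  Identity corrections give eps = E.
    """
    E = np.asarray(E, dtype=float)
    num = E * corr.gamma + (1.0 - E) * corr.beta
    den = E * corr.gamma + (1.0 - E) * (1.0 + corr.beta)
    out = num / den
    return float(out) if out.ndim == 0 else out


@dataclass
class OccupancyDensity:
    """Discrete distribution of the state-1 time fraction over a bin."""

    f_grid: np.ndarray  # grid points in [0, 1], endpoints included
    weights: np.ndarray  # cell masses, sum to 1; endpoint cells hold the point masses
    mass_at_0: float
    mass_at_1: float


def occupancy_density(
    model: TwoStateKineticModel, T: float, grid: int = 101
) -> OccupancyDensity:
    """Distribution of f1 = (time in state 1)/T for a stationary two-state CTMC.

    Exact endpoint point-masses p1*exp(-k12*T), p2*exp(-k21*T); the
    continuous part is the uniformisation mixture of Beta laws described in
    the module docstring, integrated over grid cells with the regularised
    incomplete beta function.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    f = np.linspace(0.0, 1.0, grid)
    w = np.zeros(grid)
    lam = model.k12 + model.k21
    m1 = model.p1 * math.exp(-model.k12 * T)
    m0 = model.p2 * math.exp(-model.k21 * T)
    if lam == 0.0:
        w[0], w[-1] = m0, m1
        return OccupancyDensity(f, w, m0, m1)

    p1 = model.k21 / lam
    lt = lam * T
    # cell edges: midpoints between grid points, with [0] and [1] closed
    edges = np.concatenate([[0.0], (f[:-1] + f[1:]) / 2.0, [1.0]])

    if lt > 40.0:
        # fast-exchange regime: the no-transition masses are negligible and
        # the occupancy is asymptotically Beta-shaped; match the exact mean
        # and variance of the time-average occupancy,
        # Var = 2 p1 p2 (lt - 1 + e^-lt) / lt^2
        var = 2.0 * p1 * (1.0 - p1) * (lt - 1.0 + math.exp(-lt)) / lt**2
        var = min(var, p1 * (1.0 - p1) * 0.999)
        if var <= 0:
            w[np.argmin(np.abs(f - p1))] = 1.0
            return OccupancyDensity(f, w, m0, m1)
        nu = p1 * (1.0 - p1) / var - 1.0
        a_par, b_par = p1 * nu, (1.0 - p1) * nu
        cdf = betainc(a_par, b_par, edges)
        w = np.diff(cdf)
        w[0] += m0
        w[-1] += m1
        w /= w.sum()
        return OccupancyDensity(f, w, m0, m1)

    n_max = int(stats.poisson.ppf(1.0 - 1e-12, lt)) + 1
    pois = stats.poisson.pmf(np.arange(n_max + 1), lt)
    for n in range(1, n_max + 1):
        a = np.arange(1, n + 1)  # interior interval counts (a=0, n+1 are endpoints)
        binom_w = stats.binom.pmf(a, n + 1, p1)
        if not binom_w.any():
            continue
        # Beta(a, n+1-a) CDF at the cell edges, rows = a values
        cdf = betainc(a[:, None], (n + 1 - a)[:, None], edges[None, :])
        w += pois[n] * binom_w @ np.diff(cdf, axis=1)
    w[0] += m0
    w[-1] += m1
    # endpoint contributions of the Binomial (a=0 or n+1) are exactly the
    # no-transition masses already added, so the total is 1 up to the
    # truncation of the Poisson series
    return OccupancyDensity(f, w, m0, m1)


def expected_histogram(
    model: TwoStateKineticModel | float,
    corrections: CorrectionSet,
    count_distribution: np.ndarray | dict[int, float],
    cfg: PdaConfig,
    bin_duration: float | None = None,
) -> np.ndarray:
    """Probability vector over proximity-ratio bins for one bin duration.

    ``model`` may be a static efficiency (float) — pure shot noise — or a
    two-state kinetic model, in which case the binomial success probability
    is mixed over the occupancy distribution.  ``count_distribution`` is
    either an array of observed per-bin counts (its empirical distribution
    is used) or a mapping count -> probability.
    """
    if isinstance(count_distribution, dict):
        counts = np.array(sorted(count_distribution), dtype=int)
        count_w = np.array([count_distribution[c] for c in counts], dtype=float)
    else:
        arr = np.asarray(count_distribution, dtype=int)
        if arr.size == 0:
            raise ValueError("empty photon-count distribution")
        counts, freq = np.unique(arr, return_counts=True)
        count_w = freq / freq.sum()
    count_w = count_w / count_w.sum()

    if isinstance(model, TwoStateKineticModel):
        T = bin_duration if bin_duration is not None else cfg.bin_durations[0]
        occ = occupancy_density(model, T, cfg.occupancy_grid)
        eps_grid = occ.f_grid * apparent_efficiency(model.E1, corrections) + (
            1.0 - occ.f_grid
        ) * apparent_efficiency(model.E2, corrections)
        occ_w = occ.weights
    else:
        eps_grid = np.array([apparent_efficiency(float(model), corrections)])
        occ_w = np.array([1.0])

    edges = np.linspace(0.0, 1.0, cfg.n_bins_E + 1)
    hist = np.zeros(cfg.n_bins_E)
    for n, wn in zip(counts, count_w):
        pmf = _binomial_mixture_pmf(int(n), eps_grid, occ_w)
        ratio = np.arange(n + 1) / n
        idx = np.minimum(np.searchsorted(edges, ratio, side="right") - 1, cfg.n_bins_E - 1)
        np.add.at(hist, idx, wn * pmf)
    return hist


def _binomial_mixture_pmf(n: int, eps: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Binomial(n, eps) pmf mixed over ``weights``, one vectorised evaluation."""
    k = np.arange(n + 1)[:, None]
    eps = np.clip(eps[None, :], 0.0, 1.0)
    log_pmf = (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + xlogy(k, eps)
        + xlogy(n - k, 1.0 - eps)
    )
    return np.exp(log_pmf) @ weights


def bin_photon_stream(
    stream: PhotonStream,
    spans: np.ndarray,
    cfg: PdaConfig,
    bin_duration: float | None = None,
) -> pd.DataFrame:
    """Cut bursts into consecutive fixed-duration windows and count photons.

    Only donor-excitation photons (GG and GR) are counted.  Windows start
    at the first photon of each burst; the trailing partial window is kept
    (the count-range filter removes under-filled bins).  Returns columns
    ``n_total``, ``n_gr`` for bins inside ``cfg.count_range``.
    """
    if len(stream) == 0:
        raise ValueError("empty photon stream")
    T = bin_duration if bin_duration is not None else cfg.bin_durations[0]
    t_ms = stream.times_s * 1e3
    lo, hi = cfg.count_range
    n_tot, n_gr = [], []
    for start, stop in np.asarray(spans, dtype=np.intp):
        t = t_ms[start:stop]
        ch = stream.channel[start:stop]
        dexc = ch != 2  # GG or GR
        t = t[dexc]
        ch = ch[dexc]
        if t.size == 0:
            continue
        idx = np.floor((t - t[0]) / T).astype(np.intp)
        for b in range(idx.max() + 1):
            sel = idx == b
            n = int(sel.sum())
            if lo <= n <= hi:
                n_tot.append(n)
                n_gr.append(int(np.count_nonzero(ch[sel] == GR)))
    return pd.DataFrame({"n_total": n_tot, "n_gr": n_gr})


@dataclass
class PdaResult:
    """Outcome of a dynamic-PDA histogram fit."""

    model: TwoStateKineticModel
    amplitudes: tuple[float, float, float]  # static 1, static 2, dynamic
    redchi: float
    stderr: dict[str, float]
    success: bool
    message: str = ""
    warnings: tuple[str, ...] = ()
    observed: dict = field(default_factory=dict, repr=False)
    predicted: dict = field(default_factory=dict, repr=False)


def _model_histogram(
    params_or_values,
    corrections: CorrectionSet,
    counts_by_T: dict[float, np.ndarray],
    cfg: PdaConfig,
) -> dict[float, np.ndarray]:
    v = params_or_values
    e1, e2, k12, k21 = v["E1"], v["E2"], v["k12"], v["k21"]
    w1, w2 = v["w1"], v["w2"]
    norm = w1 + w2 + 1.0
    a1, a2, ad = w1 / norm, w2 / norm, 1.0 / norm
    dyn = TwoStateKineticModel(E1=e1, E2=e2, k12=k12, k21=k21)
    out = {}
    for T, counts in counts_by_T.items():
        h = (
            a1 * expected_histogram(e1, corrections, counts, cfg)
            + a2 * expected_histogram(e2, corrections, counts, cfg)
            + ad * expected_histogram(dyn, corrections, counts, cfg, bin_duration=T)
        )
        out[T] = h
    return out


def fit_pda(
    binned: pd.DataFrame | dict[float, pd.DataFrame],
    initial: TwoStateKineticModel,
    cfg: PdaConfig,
    corrections: CorrectionSet | None = None,
    initial_amplitudes: tuple[float, float, float] = (0.05, 0.05, 0.90),
    vary_amplitudes: bool = True,
) -> PdaResult:
    """Chi-square fit of PDA histograms over (E1, E2, k12, k21, amplitudes).

    ``binned`` is the table from :func:`bin_photon_stream`, or a mapping
    bin-duration -> table when several bin times are fitted jointly.  The
    predicted histogram is a three-component mixture: quasi-static state 1,
    quasi-static state 2 and a dynamically interconverting component whose
    shape carries the rate information.  Chi-square uses sigma^2 =
    max(observed, 1) per histogram bin; parameter standard errors come from
    the local curvature at the optimum.  Deterministic given data and
    initial values.
    """
    corrections = corrections or CorrectionSet.identity()
    if isinstance(binned, pd.DataFrame):
        binned = {cfg.bin_durations[0]: binned}
    counts_by_T = {}
    obs_by_T = {}
    n_bins_total = 0
    edges = np.linspace(0.0, 1.0, cfg.n_bins_E + 1)
    for T, table in binned.items():
        n = table["n_total"].to_numpy(int)
        if n.size == 0:
            raise ValueError("no usable bins for bin duration %.3g ms" % T)
        ratio = table["n_gr"].to_numpy(float) / n
        idx = np.minimum(np.searchsorted(edges, ratio, side="right") - 1, cfg.n_bins_E - 1)
        hist = np.bincount(idx, minlength=cfg.n_bins_E).astype(float)
        counts_by_T[T] = n
        obs_by_T[T] = hist
        n_bins_total += n.size
    warns = []
    if n_bins_total < cfg.min_usable_bins:
        warns.append(f"only {n_bins_total} usable bins (< {cfg.min_usable_bins})")
    if abs(initial.E1 - initial.E2) < 0.05:
        warns.append("near-degenerate initial states: |E1-E2| < 0.05")

    params = Parameters()
    params.add("E1", value=initial.E1, min=0.0, max=1.0)
    params.add("E2", value=initial.E2, min=0.0, max=1.0)
    params.add("k12", value=max(initial.k12, 1e-4), min=1e-6, max=1e3)
    params.add("k21", value=max(initial.k21, 1e-4), min=1e-6, max=1e3)
    a1, a2, ad = initial_amplitudes
    ad = max(ad, 1e-6)
    params.add("w1", value=a1 / ad, min=0.0, max=1e6, vary=vary_amplitudes)
    params.add("w2", value=a2 / ad, min=0.0, max=1e6, vary=vary_amplitudes)

    static_cache: dict = {}

    def cached_static(e: float, T: float) -> np.ndarray:
        key = (round(e, 12), T)
        if key not in static_cache:
            static_cache[key] = expected_histogram(e, corrections, counts_by_T[T], cfg)
        return static_cache[key]

    def residual(p):
        v = {k: p[k].value for k in p}
        norm = v["w1"] + v["w2"] + 1.0
        dyn = TwoStateKineticModel(E1=v["E1"], E2=v["E2"], k12=v["k12"], k21=v["k21"])
        res = []
        for T in counts_by_T:
            h = (
                v["w1"] / norm * cached_static(v["E1"], T)
                + v["w2"] / norm * cached_static(v["E2"], T)
                + 1.0 / norm
                * expected_histogram(dyn, corrections, counts_by_T[T], cfg, bin_duration=T)
            )
            o = obs_by_T[T]
            res.append((o - h * o.sum()) / np.sqrt(np.maximum(o, 1.0)))
        return np.concatenate(res)

    mini = Minimizer(residual, params)
    out = mini.minimize(method="leastsq")
    v = {k: out.params[k].value for k in out.params}
    norm = v["w1"] + v["w2"] + 1.0
    amplitudes = (v["w1"] / norm, v["w2"] / norm, 1.0 / norm)
    fitted = TwoStateKineticModel(E1=v["E1"], E2=v["E2"], k12=v["k12"], k21=v["k21"])
    stderr = {
        k: (out.params[k].stderr if out.params[k].stderr is not None else math.nan)
        for k in out.params
    }
    if not out.success:
        warns.append(f"fit did not converge: {out.message}")
    pred = _model_histogram(v, corrections, counts_by_T, cfg)
    return PdaResult(
        model=fitted,
        amplitudes=amplitudes,
        redchi=float(out.redchi),
        stderr=stderr,
        success=bool(out.success),
        message=str(out.message),
        warnings=tuple(warns),
        observed={T: obs_by_T[T] for T in obs_by_T},
        predicted={T: pred[T] * obs_by_T[T].sum() for T in pred},
    )
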