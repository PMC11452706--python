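"""Burst search and per-burst accurate-FRET quantities.

The corrected transfer efficiency of a burst is

    E = (F_GR - alpha*F_RR - beta*F_GG) / (F_GR - alpha*F_RR - beta*F_GG + gamma*F_GG)

with F_X the background-subtracted signal in channel X, alpha the direct-
excitation, beta the crosstalk and gamma the detection-ratio correction.
The PIE stoichiometry S uses the same corrected donor-excitation signal
over the total including the acceptor-excitation signal F_RR.  Diagnostics
against millisecond dynamics come from efficiency-versus-donor-lifetime
plots: a static species falls on the line E = 1 - tau/tauD0, while a
species hopping between two states of lifetimes tau1, tau2 follows the
curved dynamic line E = 1 - tau1*tau2 / (tauD0*(tau1+tau2-tau)), which lies
above (to the right of) the static line between the two state endpoints.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .models import CorrectionSet, FretConstants
from .photons import GG, GR, RR, PhotonStream

__all__ = [
    "BurstFlag",
    "BurstMetrics",
    "find_bursts",
    "correct_and_score",
    "analyze_bursts",
    "estimate_donor_lifetime",
    "static_fret_line",
    "dynamic_fret_line",
    "efficiency_to_distance",
    "distance_to_efficiency",
    "build_histograms",
]


class BurstFlag(enum.IntFlag):
    OK = 0
    UNDEFINED_E = 1  # zero denominator in the corrected-E formula
    E_OUT_OF_RANGE = 2  # photon-starved burst with E outside [0, 1]
    NO_LIFETIME = 4  # too few donor photons for a lifetime estimate


@dataclass
class BurstMetrics:
    """Corrected per-burst quantities (a single burst)."""

    F_GG: float
    F_GR: float
    F_RR: float
    E: float
    S: float
    tauDA: float = math.nan
    n_photons: int = 0
    duration: float = 0.0  # ms
    flags: BurstFlag = BurstFlag.OK


def find_bursts(
    stream: PhotonStream,
    window_T: float = 0.5,
    min_in_window: int = 15,
    min_total: int = 60,
) -> np.ndarray:
    """All-photon sliding-window burst search.

    A photon qualifies when at least ``min_in_window`` photons (itself
    included, any channel) fall within ±``window_T``/2 ms around it.
    Maximal runs of consecutive qualifying photons with at least
    ``min_total`` photons are returned as an ``(n, 2)`` array of
    ``[start, stop)`` photon indices, ordered and non-overlapping.
    """
    if window_T <= 0:
        raise ValueError("window_T must be positive")
    if min_in_window < 1 or min_total < 1:
        raise ValueError("thresholds must be >= 1")
    if len(stream) == 0:
        return np.empty((0, 2), dtype=np.intp)
    t = stream.times_s * 1e3  # ms
    half = window_T / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    good = (hi - lo) >= min_in_window
    # maximal runs of consecutive qualifying photons
    edges = np.diff(good.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if good[0]:
        starts = np.concatenate([[0], starts])
    if good[-1]:
        stops = np.concatenate([stops, [len(good)]])
    spans = np.column_stack([starts, stops])
    return spans[(spans[:, 1] - spans[:, 0]) >= min_total]


def correct_and_score(
    n_gg: float,
    n_gr: float,
    n_rr: float,
    duration: float,
    corr: CorrectionSet,
) -> BurstMetrics:
    """Background-subtract raw channel counts and compute corrected E and S.

    E may legitimately fall outside [0, 1] for photon-starved bursts; it is
    returned as computed with ``E_OUT_OF_RANGE`` set rather than clipped,
    so histograms keep their shot-noise wings.  A vanishing denominator
    flags the burst ``UNDEFINED_E``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    bg_gg, bg_gr, bg_rr = corr.background_rates
    f_gg = n_gg - bg_gg * duration
    f_gr = n_gr - bg_gr * duration
    f_rr = n_rr - bg_rr * duration
    num = f_gr - corr.alpha * f_rr - corr.beta * f_gg
    den_e = num + corr.gamma * f_gg
    den_s = den_e + f_rr
    flags = BurstFlag.OK
    if den_e == 0.0:
        e = math.nan
        flags |= BurstFlag.UNDEFINED_E
    else:
        e = num / den_e
        if not 0.0 <= e <= 1.0:
            flags |= BurstFlag.E_OUT_OF_RANGE
    s = math.nan if den_s == 0.0 else den_e / den_s
    n_raw = int(round(n_gg + n_gr + n_rr))
    return BurstMetrics(
        F_GG=f_gg, F_GR=f_gr, F_RR=f_rr, E=e, S=s,
        n_photons=n_raw, duration=duration, flags=flags,
    )


def estimate_donor_lifetime(
    microtimes_ns: np.ndarray,
    excitation_period: float,
    min_photons: int = 20,
) -> float:
    """Maximum-likelihood lifetime of a truncated single-exponential decay.

    For decay times observed modulo the excitation period T the MLE of tau
    solves mean(x) = tau - T/(exp(T/tau)-1); when T >> tau this reduces to
    the sample mean.  Returns NaN when fewer than ``min_photons`` photons
    are available or the sample mean reaches the uniform limit T/2.
    """
    x = np.asarray(microtimes_ns, dtype=float)
    if x.size < min_photons:
        return math.nan
    m = float(x.mean())
    T = float(excitation_period)
    if m <= 0 or m >= T / 2.0:
        return math.nan

    def gap(tau):
        r = T / tau
        return tau - T / math.expm1(r) - m if r < 700 else tau - m

    return brentq(gap, 1e-6, 1e7, xtol=1e-12, rtol=1e-12)


def analyze_bursts(
    stream: PhotonStream,
    spans: np.ndarray,
    corr: CorrectionSet,
    min_lifetime_photons: int = 20,
) -> pd.DataFrame:
    """Per-burst table: counts, corrected E, S, donor lifetime, duration, flags."""
    rows = []
    t_ms = stream.times_s * 1e3
    for start, stop in np.asarray(spans, dtype=np.intp):
        ch = stream.channel[start:stop]
        n_gg = int(np.count_nonzero(ch == GG))
        n_gr = int(np.count_nonzero(ch == GR))
        n_rr = int(np.count_nonzero(ch == RR))
        dur = max(t_ms[stop - 1] - t_ms[start], 1e-6)
        bm = correct_and_score(n_gg, n_gr, n_rr, dur, corr)
        mt = stream.microtime_ns[start:stop][ch == GG]
        tau = estimate_donor_lifetime(mt, stream.excitation_period_ns, min_lifetime_photons)
        flags = bm.flags | (BurstFlag.NO_LIFETIME if math.isnan(tau) else BurstFlag.OK)
        rows.append(
            {
                "start": int(start), "stop": int(stop),
                "t_start_ms": t_ms[start], "duration_ms": dur,
                "n_photons": n_gg + n_gr + n_rr,
                "n_GG": n_gg, "n_GR": n_gr, "n_RR": n_rr,
                "F_GG": bm.F_GG, "F_GR": bm.F_GR, "F_RR": bm.F_RR,
                "E": bm.E, "S": bm.S, "tauDA_ns": tau, "flags": int(flags),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# FRET lines and distance conversion
# --------------------------------------------------------------------------


def static_fret_line(tau_grid: np.ndarray, constants: FretConstants) -> np.ndarray:
    """Static-species relation E(tau) = 1 - tau/tauD0 (not clipped)."""
    return 1.0 - np.asarray(tau_grid, dtype=float) / constants.tauD0


def dynamic_fret_line(
    tau1: float, tau2: float, constants: FretConstants, tau_grid: np.ndarray
) -> np.ndarray:
    """Dynamic FRET line for two-state hopping within a burst.

    E(tau) = 1 - tau1*tau2 / (tauD0 * (tau1 + tau2 - tau)) with tau the
    photon-weighted mean donor lifetime.  It passes exactly through the
    static endpoints (tau_i, 1 - tau_i/tauD0); tau must stay below
    tau1 + tau2 (pole).
    """
    if not (0 < tau1 < constants.tauD0 and 0 < tau2 < constants.tauD0):
        raise ValueError("state lifetimes must lie in (0, tauD0)")
    tau = np.asarray(tau_grid, dtype=float)
    if np.any(tau >= tau1 + tau2):
        raise ValueError("tau must stay below tau1 + tau2")
    return 1.0 - tau1 * tau2 / (constants.tauD0 * (tau1 + tau2 - tau))


def distance_to_efficiency(R: np.ndarray | float, R0: float = 59.0) -> np.ndarray | float:
    """Förster relation E = 1 / (1 + (R/R0)^6)."""
    R = np.asarray(R, dtype=float)
    out = 1.0 / (1.0 + (R / R0) ** 6)
    return float(out) if out.ndim == 0 else out


def efficiency_to_distance(E: np.ndarray | float, R0: float = 59.0) -> np.ndarray | float:
    """Inverse Förster relation R = R0 * ((1-E)/E)^(1/6).

    E = 0 maps to +inf and E = 1 to 0 (signalled boundary values).
    """
    E = np.asarray(E, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(E <= 0.0, np.inf, R0 * ((1.0 - E) / np.maximum(E, 1e-300)) ** (1.0 / 6.0))
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# histograms
# --------------------------------------------------------------------------


def build_histograms(
    bursts: pd.DataFrame,
    e_bins: int | np.ndarray = 51,
    s_bins: int | np.ndarray = 51,
    tau_bins: int | np.ndarray = 51,
    s_window: tuple[float, float] = (0.3, 0.7),
    tau_max: float | None = None,
) -> dict:
    """1-D E histogram and 2-D E-vs-S / E-vs-tauDA histograms.

    The stoichiometry window (default 0.3–0.7) removes donor-only and
    acceptor-only molecules before the FRET histograms are built; the
    E-vs-S histogram itself is unfiltered.  Counts in the filtered
    histograms sum to the number of retained bursts.
    """
    if bursts.empty:
        import warnings

        warnings.warn("empty burst table: returning empty histograms")
        return {"E_hist": (np.zeros(0), np.zeros(1)), "ES": None, "Etau": None, "retained": 0}
    if np.isscalar(e_bins):
        finite_e = bursts["E"].dropna()
        e_lo = min(-0.2, float(finite_e.min()) - 1e-9) if len(finite_e) else -0.2
        e_hi = max(1.2, float(finite_e.max()) + 1e-9) if len(finite_e) else 1.2
        e_edges = np.linspace(e_lo, e_hi, e_bins + 1)
    else:
        e_edges = np.asarray(e_bins)
    s_edges = np.linspace(0.0, 1.0, s_bins + 1) if np.isscalar(s_bins) else np.asarray(s_bins)
    if tau_max is None:
        tau_max = np.nanmax(bursts["tauDA_ns"]) if bursts["tauDA_ns"].notna().any() else 1.0
    t_edges = (
        np.linspace(0.0, tau_max, tau_bins + 1) if np.isscalar(tau_bins) else np.asarray(tau_bins)
    )

    ok = bursts["E"].notna() & bursts["S"].notna()
    es_counts, _, _ = np.histogram2d(
        bursts.loc[ok, "E"], bursts.loc[ok, "S"], bins=(e_edges, s_edges)
    )
    keep = ok & bursts["S"].between(*s_window)
    e_counts, _ = np.histogram(bursts.loc[keep, "E"], bins=e_edges)
    has_tau = keep & bursts["tauDA_ns"].notna()
    etau_counts, _, _ = np.histogram2d(
        bursts.loc[has_tau, "E"], bursts.loc[has_tau, "tauDA_ns"], bins=(e_edges, t_edges)
    )
    return {
        "E_hist": (e_counts, e_edges),
        "ES": (es_counts, e_edges, s_edges),
        "Etau": (etau_counts, e_edges, t_edges),
        "retained": int(keep.sum()),
    }
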