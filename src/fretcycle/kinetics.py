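"""Open/closed population kinetics from SEC profiles and crosslink gels.

A size-exclusion elution profile of a dimer that interconverts slowly
between an open and a compact closed conformation is modelled as the sum of
two Gaussians, one per state; the closed-state area fraction

    f = A_closed / (A_closed + A_open),   A = amplitude * sigma * sqrt(2*pi)

is followed over incubation time and fitted with first-order laws:

    closing:  f(t) = f_inf * (1 - exp(-k t))
    opening:  f(t) = f_eq + (f0 - f_eq) * exp(-k t)

yielding the closing/opening rate constants (min⁻¹).  The compact closed
state has the smaller hydrodynamic radius and elutes later by default; the
assignment is switchable.  The same rate layer serves crosslinking-gel
dimer/monomer fraction series.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lmfit import Minimizer, Parameters
from scipy.ndimage import gaussian_filter1d
from scipy.signal import argrelmax

from .simulate import Chromatogram, closing_law, opening_law

__all__ = [
    "BiGaussianDecomposition",
    "RateFit",
    "fit_bigaussian",
    "fit_bigaussian_series",
    "fit_closing",
    "fit_opening",
    "gel_band_fractions",
    "load_chromatogram_series",
]

_SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass
class BiGaussianDecomposition:
    """Two-Gaussian deconvolution of one elution profile."""

    open_center: float
    open_sigma: float
    open_amplitude: float
    closed_center: float
    closed_sigma: float
    closed_amplitude: float
    closed_fraction: float
    residual_norm: float
    time_min: float = 0.0
    success: bool = True
    flags: tuple[str, ...] = ()

    @property
    def open_area(self) -> float:
        return self.open_amplitude * self.open_sigma * _SQRT2PI

    @property
    def closed_area(self) -> float:
        return self.closed_amplitude * self.closed_sigma * _SQRT2PI


@dataclass
class RateFit:
    """First-order rate constant from a closed-fraction time series."""

    k: float  # min^-1
    k_stderr: float
    f0: float
    f_asym: float  # f_inf for closing, f_eq for opening
    model: Literal["closing", "opening"]
    residuals: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    flags: tuple[str, ...] = ()


def _two_gauss(x, c1, s1, a1, c2, s2, a2):
    return a1 * np.exp(-0.5 * ((x - c1) / s1) ** 2) + a2 * np.exp(
        -0.5 * ((x - c2) / s2) ** 2
    )


def _initial_centers(chrom: Chromatogram) -> tuple[float, float, float]:
    """Deterministic init: the two largest local maxima of the smoothed signal."""
    v, y = chrom.volume_mL, chrom.signal
    dx = float(np.median(np.diff(v)))
    smooth = gaussian_filter1d(y, sigma=max(1.0, 0.02 / dx))
    (peaks,) = argrelmax(smooth, order=3)
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(smooth))])
    order = np.argsort(smooth[peaks])[::-1]
    peaks = peaks[order[:2]]
    half_max = smooth.max() / 2.0
    width = max(dx * np.count_nonzero(smooth > half_max) / 2.355, 2 * dx)
    if peaks.size == 2:
        c_lo, c_hi = sorted(v[peaks])
    else:
        c = v[peaks[0]]
        c_lo, c_hi = c - width, c + width
    return c_lo, c_hi, width


def fit_bigaussian(
    chrom: Chromatogram,
    init_centers: tuple[float, float] | None = None,
    closed_elutes: Literal["later", "earlier"] = "later",
    share_sigma: bool = False,
) -> BiGaussianDecomposition:
    """Nonlinear least-squares fit of a two-Gaussian sum to one profile.

    Component areas are analytic (amplitude * sigma * sqrt(2*pi)); the
    closed fraction is the closed-component share of the total area.  The
    ``closed_elutes`` switch decides which peak is the closed state
    (default ``later``: compact species elute at higher volume).
    ``share_sigma`` ties the two peak widths — both conformers experience
    the same column dispersion — which stabilises strongly overlapping
    peaks.
    """
    v, y = chrom.volume_mL, chrom.signal
    if len(v) < 20:
        raise ValueError("need at least 20 data points")
    if init_centers is not None:
        c_lo, c_hi = sorted(init_centers)
        width = max((c_hi - c_lo) / 4.0, 2 * float(np.median(np.diff(v))))
    else:
        c_lo, c_hi, width = _initial_centers(chrom)
    amp0 = max(y.max(), 1e-12) * 0.7

    params = Parameters()
    span = v[-1] - v[0]
    # each center stays on its own side of the gap midpoint so that a
    # single-component profile cannot be fitted by two coincident Gaussians
    gap = max(c_hi - c_lo, 4 * float(np.median(np.diff(v))))
    params.add("c1", value=c_lo, min=c_lo - gap / 2, max=c_lo + gap / 2)
    params.add("c2", value=c_hi, min=c_hi - gap / 2, max=c_hi + gap / 2)
    params.add("s1", value=width, min=1e-6, max=span)
    if share_sigma:
        params.add("s2", expr="s1")
    else:
        params.add("s2", value=width, min=1e-6, max=span)
    params.add("a1", value=amp0, min=0.0)
    params.add("a2", value=amp0, min=0.0)

    def residual(p):
        return _two_gauss(v, p["c1"], p["s1"], p["a1"], p["c2"], p["s2"], p["a2"]) - y

    out = Minimizer(residual, params).minimize(method="leastsq")
    p = {k: out.params[k].value for k in out.params}
    flags: list[str] = []
    if not out.success:
        flags.append("non-convergence")
    # order components by center
    comp = sorted(
        [(p["c1"], p["s1"], p["a1"]), (p["c2"], p["s2"], p["a2"])], key=lambda t: t[0]
    )
    (c_early, s_early, a_early), (c_late, s_late, a_late) = comp
    if closed_elutes == "later":
        op, cl = (c_early, s_early, a_early), (c_late, s_late, a_late)
    else:
        op, cl = (c_late, s_late, a_late), (c_early, s_early, a_early)
    area_open = op[2] * op[1] * _SQRT2PI
    area_closed = cl[2] * cl[1] * _SQRT2PI
    total = area_open + area_closed
    if total <= 0:
        flags.append("zero-total-area")
        frac = math.nan
    else:
        frac = area_closed / total
        if min(area_open, area_closed) / total < 1e-6:
            flags.append("single-component")
    return BiGaussianDecomposition(
        open_center=op[0], open_sigma=op[1], open_amplitude=op[2],
        closed_center=cl[0], closed_sigma=cl[1], closed_amplitude=cl[2],
        closed_fraction=frac,
        residual_norm=float(np.linalg.norm(out.residual)),
        time_min=chrom.time_min,
        success=bool(out.success),
        flags=tuple(flags),
    )


def fit_bigaussian_series(
    series: Sequence[Chromatogram],
    init_centers: tuple[float, float] | None = None,
    closed_elutes: Literal["later", "earlier"] = "later",
) -> list[BiGaussianDecomposition]:
    """Global two-Gaussian fit of a time series with shared peak shapes.

    Peak centers and widths are tied across all time points, only the two
    amplitudes vary per chromatogram — the compact and open conformers do
    not change shape during incubation, which stabilises the decomposition
    when one population is nearly absent (earliest/latest time points).
    """
    if len(series) < 3:
        raise ValueError("need at least 3 time points for a global fit")
    # the first and last profiles of a kinetic series are the most extreme
    # open/closed mixtures, so their modes are robust center initialisers;
    # fall back to the pooled profile when they coincide (flat series)
    pooled = Chromatogram(
        series[0].volume_mL,
        np.mean([c.signal for c in series], axis=0),
        time_min=0.0,
    )
    dx = float(np.median(np.diff(pooled.volume_mL)))
    if init_centers is not None:
        c_lo, c_hi = sorted(init_centers)
        width = max((c_hi - c_lo) / 4.0, 2 * dx)
    else:
        smooth_first = gaussian_filter1d(series[0].signal, sigma=max(1.0, 0.02 / dx))
        smooth_last = gaussian_filter1d(series[-1].signal, sigma=max(1.0, 0.02 / dx))
        c_a = series[0].volume_mL[int(np.argmax(smooth_first))]
        c_b = series[-1].volume_mL[int(np.argmax(smooth_last))]
        half = smooth_first.max() / 2.0
        width = max(dx * np.count_nonzero(smooth_first > half) / 2.355, 2 * dx)
        if abs(c_a - c_b) > 2 * dx:
            c_lo, c_hi = sorted((c_a, c_b))
        else:
            c_lo, c_hi, width = _initial_centers(pooled)

    params = Parameters()
    v0 = series[0].volume_mL
    span = v0[-1] - v0[0]
    gap = max(c_hi - c_lo, 4 * dx)
    params.add("c1", value=c_lo, min=c_lo - gap / 2, max=c_lo + gap / 2)
    params.add("c2", value=c_hi, min=c_hi - gap / 2, max=c_hi + gap / 2)
    params.add("s1", value=width, min=1e-6, max=span)
    params.add("s2", value=width, min=1e-6, max=span)
    amp0 = max(pooled.signal.max(), 1e-12) * 0.7
    for i in range(len(series)):
        params.add(f"a1_{i}", value=amp0, min=0.0)
        params.add(f"a2_{i}", value=amp0, min=0.0)

    def residual(p):
        res = []
        for i, chrom in enumerate(series):
            res.append(
                _two_gauss(
                    chrom.volume_mL,
                    p["c1"], p["s1"], p[f"a1_{i}"],
                    p["c2"], p["s2"], p[f"a2_{i}"],
                )
                - chrom.signal
            )
        return np.concatenate(res)

    out = Minimizer(residual, params).minimize(method="leastsq")
    p = {k: out.params[k].value for k in out.params}
    decomps = []
    for i, chrom in enumerate(series):
        comp = sorted(
            [
                (p["c1"], p["s1"], p[f"a1_{i}"]),
                (p["c2"], p["s2"], p[f"a2_{i}"]),
            ],
            key=lambda t: t[0],
        )
        (c_early, s_early, a_early), (c_late, s_late, a_late) = comp
        if closed_elutes == "later":
            op, cl = (c_early, s_early, a_early), (c_late, s_late, a_late)
        else:
            op, cl = (c_late, s_late, a_late), (c_early, s_early, a_early)
        area_open = op[2] * op[1] * _SQRT2PI
        area_closed = cl[2] * cl[1] * _SQRT2PI
        total = area_open + area_closed
        decomps.append(
            BiGaussianDecomposition(
                open_center=op[0], open_sigma=op[1], open_amplitude=op[2],
                closed_center=cl[0], closed_sigma=cl[1], closed_amplitude=cl[2],
                closed_fraction=area_closed / total if total > 0 else math.nan,
                residual_norm=float(np.linalg.norm(out.residual)),
                time_min=chrom.time_min,
                success=bool(out.success),
                flags=() if out.success else ("non-convergence",),
            )
        )
    return decomps


def _rate_fit(times, fractions, model, fix_feq=None) -> RateFit:
    times = np.asarray(times, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if times.size < 4:
        raise ValueError("need at least 4 time points")
    flags: list[str] = []
    spread = f.max() - f.min()
    if spread < 0.05:
        flags.append("unidentifiable: fraction spread < 0.05")
    trend = np.polyfit(times, f, 1)[0]
    if model == "closing" and trend < 0 and spread >= 0.05:
        flags.append("model-mismatch: fractions decrease under a closing model")
    if model == "opening" and trend > 0 and spread >= 0.05:
        flags.append("model-mismatch: fractions increase under an opening model")

    # half-change time gives the deterministic rate init
    target = (f[0] + f[-1]) / 2.0
    crossing = np.argmin(np.abs(f - target))
    t_half = times[crossing] if times[crossing] > 0 else (times[times > 0].min() if (times > 0).any() else 1.0)
    k0 = math.log(2.0) / t_half

    params = Parameters()
    params.add("k", value=max(k0, 1e-6), min=0.0, max=1e4)
    if model == "closing":
        params.add("f_inf", value=np.clip(f.max(), 1e-3, 1.0), min=0.0, max=1.0)

        def law(p):
            return closing_law(times, p["k"], p["f_inf"])

    else:
        params.add("f0", value=np.clip(f[0], 0.0, 1.0), min=0.0, max=1.0)
        if fix_feq is not None:
            params.add("f_eq", value=float(fix_feq), vary=False)
        else:
            params.add("f_eq", value=np.clip(f.min(), 0.0, 1.0), min=0.0, max=1.0)

        def law(p):
            return opening_law(times, p["k"], p["f0"], p["f_eq"])

    out = Minimizer(lambda p: law(p) - f, params).minimize(method="leastsq")
    k = out.params["k"].value
    k_se = out.params["k"].stderr if out.params["k"].stderr is not None else math.nan
    if "unidentifiable: fraction spread < 0.05" in flags or (
        not math.isnan(k_se) and k > 0 and k_se / k > 1.0
    ):
        if "unidentifiable: fraction spread < 0.05" not in flags:
            flags.append("poorly-determined rate: stderr exceeds estimate")
    if model == "closing":
        return RateFit(
            k=k, k_stderr=k_se, f0=0.0, f_asym=out.params["f_inf"].value,
            model="closing", residuals=np.asarray(out.residual), flags=tuple(flags),
        )
    return RateFit(
        k=k, k_stderr=k_se, f0=out.params["f0"].value, f_asym=out.params["f_eq"].value,
        model="opening", residuals=np.asarray(out.residual), flags=tuple(flags),
    )


def fit_closing(times: Sequence[float], fractions: Sequence[float]) -> RateFit:
    """Fit f(t) = f_inf (1 - e^{-kt}) to a closed-fraction series (t in min)."""
    return _rate_fit(times, fractions, "closing")


def fit_opening(
    times: Sequence[float],
    fractions: Sequence[float],
    fix_feq: float | None = None,
) -> RateFit:
    """Fit f(t) = f_eq + (f0 - f_eq) e^{-kt}; ``fix_feq`` pins the plateau.

    A free f_eq accommodates nucleotide exchange that reaches an
    equilibrium leaving part of the dimers closed (ADP); ``fix_feq=0``
    describes complete reopening (inhibitor displacement).
    """
    return _rate_fit(times, fractions, "opening", fix_feq=fix_feq)


def gel_band_fractions(
    table: pd.DataFrame,
    dimer_col: str = "dimer_intensity",
    monomer_col: str = "monomer_intensity",
    time_col: str = "time_min",
    mw_ratio: float | None = None,
) -> pd.DataFrame:
    """Crosslinked-dimer fraction per gel lane: dimer / (dimer + monomer).

    ``mw_ratio`` (dimer/monomer staining-mass ratio) optionally weights the
    monomer band; all-zero lanes are dropped with a warning.  Returns a
    ``(time_min, fraction)`` table ready for :func:`fit_closing`.
    """
    d = table[dimer_col].to_numpy(float)
    m = table[monomer_col].to_numpy(float)
    if np.any(d < 0) or np.any(m < 0):
        raise ValueError("band intensities must be nonnegative")
    if mw_ratio is not None:
        m = m * mw_ratio
    total = d + m
    keep = total > 0
    if not keep.all():
        warnings.warn(f"dropping {np.count_nonzero(~keep)} all-zero lane(s)")
    return pd.DataFrame(
        {
            "time_min": table[time_col].to_numpy(float)[keep],
            "fraction": d[keep] / total[keep],
        }
    )


def load_chromatogram_series(manifest: str | Path) -> list[Chromatogram]:
    """Load a chromatogram series from a manifest CSV (file, time_min[, condition])."""
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    out = []
    for _, row in df.iterrows():
        out.append(
            Chromatogram.from_csv(
                manifest.parent / row["file"],
                time_min=float(row["time_min"]),
                condition=str(row.get("condition", "")),
            )
        )
    return out
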