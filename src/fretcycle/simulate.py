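"""Synthetic data with known ground truth for every pipeline stage.

Three families of inputs are emulated:

* **Photon streams** — freely diffusing dual-labelled dimers produce bursts
  of donor/acceptor photons while the molecule interconverts between FRET
  states as a continuous-time Markov chain.  The forward model applies the
  same distortions that accurate-FRET analysis corrects: donor crosstalk
  into the red channel, direct acceptor excitation, unequal detection
  efficiencies and per-channel background.  The exact (alpha, beta, gamma)
  that invert the distortions are recorded, so the corrected efficiency is
  a true inverse of the generator in expectation.
* **SEC chromatogram series** — two-Gaussian elution profiles whose
  closed-peak area fraction evolves by first-order closing or opening
  kinetics, plus additive Gaussian noise.
* **Toy atomic geometries** — lone attachment atom, planar wall and
  spherical cavity, used to validate the accessible-volume engine against
  analytic results.

Burst durations are exponential with the configured mean and inter-burst
gaps exponential with ten times that mean, so that bursts are separable by
any reasonable burst search.  No diffusion-profile, triplet or IRF model is
included; acceptor microtimes are single-exponential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import (
    CorrectionSet,
    MultiStateKineticModel,
    TwoStateKineticModel,
    two_state_as_multi,
)
from .photons import GG, GR, RR, PhotonStream

__all__ = [
    "SimBurstConfig",
    "simulate_photon_stream",
    "simulate_pda_bins",
    "Chromatogram",
    "closing_law",
    "opening_law",
    "generate_chromatogram_series",
    "write_chromatogram_series",
    "generate_gel_table",
    "generate_toy_structure",
]


# --------------------------------------------------------------------------
# photon streams
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SimBurstConfig:
    """Study conditions for a synthetic burst measurement.

    Rates are per millisecond.  ``photon_rate`` is the donor-excitation
    photon generation rate during a burst (before detection losses);
    ``photon_rate_rr`` the acceptor-excitation rate (defaults to
    ``photon_rate``).  ``truth_corrections`` holds the alpha/beta/gamma and
    background that the generator applies in the forward direction and that
    the analysis must use to invert.
    """

    n_bursts: int = 2000
    burst_duration_mean: float = 3.0  # ms
    photon_rate: float = 60.0  # photons/ms during a burst
    photon_rate_rr: float | None = None
    truth_corrections: CorrectionSet = field(
        default_factory=lambda: CorrectionSet(
            alpha=0.05, beta=0.15, gamma=0.8, background_rates=(0.3, 0.2, 0.5)
        )
    )
    donor_only_fraction: float = 0.0
    acceptor_only_fraction: float = 0.0
    tauD0: float = 3.8  # ns
    acceptor_lifetime: float = 3.5  # ns
    excitation_period: float = 50.0  # ns
    resolution: float = 1e-9  # s per macrotime tick
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photon_rate <= 0 or self.excitation_period <= 0:
            raise ValueError("photon_rate and excitation_period must be positive")
        if self.burst_duration_mean <= 0 or self.n_bursts <= 0:
            raise ValueError("burst_duration_mean and n_bursts must be positive")
        if self.donor_only_fraction < 0 or self.acceptor_only_fraction < 0:
            raise ValueError("species fractions must be nonnegative")
        if self.donor_only_fraction + self.acceptor_only_fraction > 1:
            raise ValueError("donor_only_fraction + acceptor_only_fraction must be <= 1")
        if self.photon_rate_rr is not None and self.photon_rate_rr < 0:
            raise ValueError("photon_rate_rr must be nonnegative")

    @property
    def rr_rate(self) -> float:
        return self.photon_rate if self.photon_rate_rr is None else self.photon_rate_rr


def _detection_probs(corr: CorrectionSet) -> tuple[float, float, float]:
    """Forward detection model consistent with the correction factors.

    A donor-pathway photon is detected and assigned to GR (crosstalk) with
    conditional probability ``c = beta/(1+beta)`` and to GG otherwise; an
    acceptor-pathway (FRET) photon is detected with relative efficiency
    ``gamma/(1+beta)``.  If that exceeds one, both pathways are scaled down
    so the larger detection probability is one.  Returns
    ``(p_detect_donor, p_detect_acceptor, c)``.
    """
    c = corr.beta / (1.0 + corr.beta)
    g_a = corr.gamma / (1.0 + corr.beta)
    scale = max(1.0, g_a)
    return 1.0 / scale, g_a / scale, c


def _sample_truncated_exp(rng: np.random.Generator, tau: np.ndarray, upper: float) -> np.ndarray:
    """Exponential(tau) samples conditioned on being below ``upper`` (ns)."""
    tau = np.asarray(tau, dtype=float)
    u = rng.random(tau.shape)
    cdf_upper = -np.expm1(-upper / tau)
    return -tau * np.log1p(-u * cdf_upper)


def _simulate_ctmc_path(
    rng: np.random.Generator,
    Q: np.ndarray,
    pi0: np.ndarray,
    duration: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One CTMC realisation: segment boundaries and the state per segment.

    Returns (edges, states) with ``edges`` of length ``len(states)+1``,
    ``edges[0]==0`` and ``edges[-1]==duration``.
    """
    n = Q.shape[0]
    exit_rates = -np.diag(Q)
    state = int(rng.choice(n, p=pi0))
    t = 0.0
    edges = [0.0]
    states = []
    while True:
        rate = exit_rates[state]
        dwell = math.inf if rate <= 0 else rng.exponential(1.0 / rate)
        if t + dwell >= duration:
            states.append(state)
            edges.append(duration)
            return np.asarray(edges), np.asarray(states, dtype=np.intp)
        t += dwell
        edges.append(t)
        states.append(state)
        probs = Q[state].copy()
        probs[state] = 0.0
        probs = probs / probs.sum()
        state = int(rng.choice(n, p=probs))


def simulate_photon_stream(
    model: TwoStateKineticModel | MultiStateKineticModel,
    cfg: SimBurstConfig,
) -> PhotonStream:
    """Generate a time-ordered photon stream of diffusing labelled dimers.

    The returned stream carries a ``truth`` table with one row per burst:
    start/stop time (s), species (``DA``/``D``/``A``), time fraction spent
    in each state, the intensity-weighted mean efficiency and the photon
    count, so downstream estimators can be checked against ground truth.
    """
    if isinstance(model, TwoStateKineticModel):
        multi = two_state_as_multi(model)
    else:
        multi = model
    Q = multi.Q
    pi0 = (
        np.array([model.p1, model.p2])
        if isinstance(model, TwoStateKineticModel)
        else multi.stationary
    )
    effs = np.asarray(multi.efficiencies)
    taus = multi.lifetimes
    corr = cfg.truth_corrections
    p_det_d, p_det_a, cross = _detection_probs(corr)
    rng = np.random.default_rng(cfg.seed)
    period = cfg.excitation_period

    durations = rng.exponential(cfg.burst_duration_mean, cfg.n_bursts)  # ms
    gaps = rng.exponential(10.0 * cfg.burst_duration_mean, cfg.n_bursts)  # ms
    starts = np.cumsum(gaps) + np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    u_species = rng.random(cfg.n_bursts)
    # 0 = dual labelled, 1 = donor only, 2 = acceptor only
    species = np.zeros(cfg.n_bursts, dtype=np.intp)
    species[u_species < cfg.donor_only_fraction] = 1
    species[
        (u_species >= cfg.donor_only_fraction)
        & (u_species < cfg.donor_only_fraction + cfg.acceptor_only_fraction)
    ] = 2

    all_t: list[np.ndarray] = []
    all_ch: list[np.ndarray] = []
    all_mt: list[np.ndarray] = []
    truth_rows = []

    for b in range(cfg.n_bursts):
        dur = durations[b]
        t0 = starts[b]
        sp = species[b]
        times: list[np.ndarray] = []
        chans: list[np.ndarray] = []
        micro: list[np.ndarray] = []

        if sp == 0:
            edges, path = _simulate_ctmc_path(rng, Q, pi0, dur)
            occupancy = np.zeros(multi.n_states)
            seg_len = np.diff(edges)
            np.add.at(occupancy, path, seg_len)
            occupancy /= dur
        else:
            edges = np.array([0.0, dur])
            path = np.array([0], dtype=np.intp)
            occupancy = np.full(multi.n_states, np.nan)

        # donor-excitation photons (absent for acceptor-only molecules)
        if sp in (0, 1):
            n_d = rng.poisson(cfg.photon_rate * dur)
            t_d = np.sort(rng.random(n_d)) * dur
            if sp == 0:
                seg = np.searchsorted(edges, t_d, side="right") - 1
                seg = np.clip(seg, 0, len(path) - 1)
                e_phot = effs[path[seg]]
                tau_phot = taus[path[seg]]
            else:
                e_phot = np.zeros(n_d)
                tau_phot = np.full(n_d, cfg.tauD0)
            transferred = rng.random(n_d) < e_phot
            det_a = transferred & (rng.random(n_d) < p_det_a)
            keep_d = ~transferred & (rng.random(n_d) < p_det_d)
            to_gr = keep_d & (rng.random(n_d) < cross)
            to_gg = keep_d & ~to_gr
            # acceptor-pathway photons decay with the acceptor lifetime
            for mask, ch, tau_arr in (
                (to_gg, GG, tau_phot),
                (to_gr, GR, tau_phot),
                (det_a, GR, np.full(n_d, cfg.acceptor_lifetime)),
            ):
                if mask.any():
                    times.append(t_d[mask])
                    chans.append(np.full(mask.sum(), ch, dtype=np.uint8))
                    micro.append(_sample_truncated_exp(rng, tau_arr[mask], period))

        # acceptor-excitation photons and direct excitation during the
        # donor window (both require an acceptor dye)
        if sp in (0, 2):
            n_rr = rng.poisson(cfg.rr_rate * dur)
            if n_rr:
                times.append(rng.random(n_rr) * dur)
                chans.append(np.full(n_rr, RR, dtype=np.uint8))
                micro.append(
                    _sample_truncated_exp(
                        rng, np.full(n_rr, cfg.acceptor_lifetime), period
                    )
                )
            n_dir = rng.poisson(corr.alpha * cfg.rr_rate * dur)
            if n_dir:
                times.append(rng.random(n_dir) * dur)
                chans.append(np.full(n_dir, GR, dtype=np.uint8))
                micro.append(
                    _sample_truncated_exp(
                        rng, np.full(n_dir, cfg.acceptor_lifetime), period
                    )
                )

        if times:
            t_burst = np.concatenate(times)
            ch_burst = np.concatenate(chans)
            mt_burst = np.concatenate(micro)
        else:
            t_burst = np.empty(0)
            ch_burst = np.empty(0, dtype=np.uint8)
            mt_burst = np.empty(0)
        order = np.argsort(t_burst, kind="stable")
        all_t.append(t0 + t_burst[order])
        all_ch.append(ch_burst[order])
        all_mt.append(mt_burst[order])

        row = {
            "burst": b,
            "t_start_ms": t0,
            "t_stop_ms": t0 + dur,
            "duration_ms": dur,
            "species": ("DA", "D", "A")[sp],
            "n_photons": len(t_burst),
        }
        for s in range(multi.n_states):
            row[f"occupancy_{s + 1}"] = occupancy[s]
        row["mean_E"] = float(np.dot(occupancy, effs)) if sp == 0 else (0.0 if sp == 1 else np.nan)
        truth_rows.append(row)

    total_ms = starts[-1] + durations[-1] + 10.0 * cfg.burst_duration_mean

    # background: homogeneous Poisson per channel over the whole acquisition
    for ch, rate in zip((GG, GR, RR), corr.background_rates):
        n_bg = rng.poisson(rate * total_ms)
        if n_bg:
            all_t.append(rng.random(n_bg) * total_ms)
            all_ch.append(np.full(n_bg, ch, dtype=np.uint8))
            all_mt.append(rng.random(n_bg) * period)

    t = np.concatenate(all_t)
    ch = np.concatenate(all_ch)
    mt = np.concatenate(all_mt)
    order = np.argsort(t, kind="stable")
    ticks = np.round(t[order] * 1e-3 / cfg.resolution).astype(np.int64)
    # rounding to ticks must not break ordering
    ticks = np.maximum.accumulate(ticks)

    return PhotonStream(
        timestamps=ticks,
        channel=ch[order],
        microtime_ns=mt[order],
        resolution=cfg.resolution,
        excitation_period_ns=period,
        duration_s=total_ms * 1e-3,
        truth=pd.DataFrame(truth_rows),
    )


def simulate_pda_bins(
    model: TwoStateKineticModel,
    corrections: CorrectionSet,
    counts: np.ndarray | int,
    bin_duration: float,
    n_bins: int,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Direct Monte-Carlo of fixed-duration PDA bins (oracle-grade).

    Each bin draws its photon count from ``counts`` (an integer for a fixed
    count, or an array resampled with replacement), realises the state
    occupancy by explicit jump-by-jump CTMC simulation over the bin and
    splits photons binomially between GR and GG with the corrected apparent
    efficiency.  Returns columns ``n_total`` and ``n_gr``.
    """
    from .pda import apparent_efficiency  # local import to avoid a cycle

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if np.isscalar(counts):
        n_tot = np.full(n_bins, int(counts))
    else:
        counts = np.asarray(counts, dtype=int)
        n_tot = rng.choice(counts, size=n_bins, replace=True)

    # vectorised jump-chain simulation of the two-state CTMC
    state = rng.random(n_bins) < model.p1  # True = state 1
    remaining = np.full(n_bins, bin_duration)
    time_in_1 = np.zeros(n_bins)
    active = np.ones(n_bins, dtype=bool)
    rates = np.array([model.k21, model.k12])  # exit rate per (state2, state1)
    while active.any():
        idx = np.flatnonzero(active)
        r = rates[state[idx].astype(int)]
        dwell = np.where(
            r > 0, rng.exponential(1.0, idx.size) / np.where(r > 0, r, 1.0), np.inf
        )
        done = dwell >= remaining[idx]  # dwell outlasts the bin
        stay = np.minimum(dwell, remaining[idx])
        time_in_1[idx] += np.where(state[idx], stay, 0.0)
        remaining[idx] -= stay
        active[idx[done]] = False
        flip = idx[~done]
        state[flip] = ~state[flip]
    f1 = time_in_1 / bin_duration

    eps = f1 * apparent_efficiency(model.E1, corrections) + (1.0 - f1) * apparent_efficiency(
        model.E2, corrections
    )
    n_gr = rng.binomial(n_tot, eps)
    return pd.DataFrame({"n_total": n_tot, "n_gr": n_gr})


# --------------------------------------------------------------------------
# chromatograms and gels
# --------------------------------------------------------------------------


@dataclass
class Chromatogram:
    """A SEC elution profile at one incubation time point."""

    volume_mL: np.ndarray
    signal: np.ndarray
    time_min: float = 0.0
    condition: str = ""

    def __post_init__(self) -> None:
        self.volume_mL = np.asarray(self.volume_mL, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.volume_mL.ndim != 1 or self.volume_mL.shape != self.signal.shape:
            raise ValueError("volume and signal must be matching 1-D arrays")
        if np.any(np.diff(self.volume_mL) <= 0):
            raise ValueError("elution volume must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"volume_mL": self.volume_mL, "signal": self.signal}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(
        cls, path: str | Path, time_min: float = 0.0, condition: str = ""
    ) -> "Chromatogram":
        df = pd.read_csv(path)
        return cls(df["volume_mL"].to_numpy(), df["signal"].to_numpy(), time_min, condition)


def closing_law(t: np.ndarray | float, k: float, f_inf: float) -> np.ndarray | float:
    """Closed fraction during first-order closing: f(t) = f_inf (1 - e^{-kt})."""
    return f_inf * -np.expm1(-k * np.asarray(t, dtype=float))


def opening_law(
    t: np.ndarray | float, k: float, f0: float, f_eq: float
) -> np.ndarray | float:
    """Closed fraction during first-order opening: f(t) = f_eq + (f0-f_eq) e^{-kt}."""
    return f_eq + (f0 - f_eq) * np.exp(-k * np.asarray(t, dtype=float))


def generate_chromatogram_series(
    times: Sequence[float],
    k: float,
    f_inf: float | None = None,
    f0: float | None = None,
    f_eq: float | None = None,
    open_center: float = 10.4,
    closed_center: float = 11.0,
    open_sigma: float = 0.25,
    closed_sigma: float = 0.25,
    total_area: float = 1.0,
    volume_grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    condition: str = "",
    seed: int = 0,
) -> list[Chromatogram]:
    """Two-Gaussian SEC profiles whose closed fraction follows first-order law.

    Closing mode (``f_inf`` given): f(t) = f_inf (1 - e^{-kt}).  Opening
    mode (``f0``/``f_eq`` given): f(t) = f_eq + (f0-f_eq) e^{-kt}.  The
    closed peak elutes at ``closed_center`` (later than the open peak by
    default: a compact state has the smaller hydrodynamic radius).  Noise
    is additive Gaussian with sd ``noise_sd`` times the maximum noise-free
    signal of the series.
    """
    if open_center == closed_center:
        raise ValueError("open and closed peak centers must differ")
    if (f_inf is None) == (f0 is None):
        raise ValueError("give exactly one of f_inf (closing) or f0/f_eq (opening)")
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    if volume_grid is None:
        lo = min(open_center, closed_center) - 8.0 * max(open_sigma, closed_sigma)
        hi = max(open_center, closed_center) + 8.0 * max(open_sigma, closed_sigma)
        volume_grid = np.arange(lo, hi, 0.01)
    rng = np.random.default_rng(seed)

    if f_inf is not None:
        fracs = closing_law(times, k, f_inf)
    else:
        if f_eq is None:
            f_eq = 0.0
        fracs = opening_law(times, k, f0, f_eq)

    def gauss(x, c, s):
        return np.exp(-0.5 * ((x - c) / s) ** 2) / (s * math.sqrt(2.0 * math.pi))

    clean = [
        total_area
        * (
            f * gauss(volume_grid, closed_center, closed_sigma)
            + (1.0 - f) * gauss(volume_grid, open_center, open_sigma)
        )
        for f in np.atleast_1d(fracs)
    ]
    peak = max(sig.max() for sig in clean)
    out = []
    for t, sig in zip(np.atleast_1d(times), clean):
        noisy = sig + rng.normal(0.0, noise_sd * peak, sig.shape) if noise_sd > 0 else sig
        out.append(Chromatogram(volume_grid, noisy, time_min=float(t), condition=condition))
    return out


def write_chromatogram_series(
    series: Iterable[Chromatogram], outdir: str | Path, prefix: str = "chrom"
) -> Path:
    """Write one CSV per time point plus a ``manifest.csv``; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, chrom in enumerate(series):
        name = f"{prefix}_{i:03d}.csv"
        chrom.to_csv(outdir / name)
        rows.append({"file": name, "time_min": chrom.time_min, "condition": chrom.condition})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def generate_gel_table(
    times: Sequence[float],
    k: float,
    f_inf: float,
    f0: float = 0.0,
    total_intensity: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic crosslinking-gel densitometry: dimer/monomer band intensities.

    The crosslinked-dimer fraction follows f(t) = f0 + (f_inf-f0)(1-e^{-kt});
    a nonzero ``f0`` emulates species whose closed state is populated
    already at mixing time.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    frac = f0 + (f_inf - f0) * -np.expm1(-k * times)
    dimer = total_intensity * frac
    monomer = total_intensity * (1.0 - frac)
    if noise_sd > 0:
        dimer = np.clip(dimer + rng.normal(0, noise_sd * total_intensity, dimer.shape), 0, None)
        monomer = np.clip(
            monomer + rng.normal(0, noise_sd * total_intensity, monomer.shape), 0, None
        )
    return pd.DataFrame(
        {
            "lane": np.arange(len(times)),
            "time_min": times,
            "dimer_intensity": dimer,
            "monomer_intensity": monomer,
        }
    )


# --------------------------------------------------------------------------
# toy structures
# --------------------------------------------------------------------------


def generate_toy_structure(kind: str, **kw):
    """Toy geometries with a designated attachment atom for AV validation.

    ``lone-attachment-atom``
        a single atom at the origin.
    ``planar-wall``
        a square lattice of pseudo-atoms in the plane ``z = z0`` (optionally
        several layers stacked downward) with the attachment atom at the
        origin; parameters ``extent`` (Å), ``spacing`` (Å), ``radius`` (Å),
        ``layers``.
    ``spherical-cavity``
        pseudo-atoms tiling a sphere of radius ``radius`` around the
        attachment atom at the origin; parameter ``point_spacing`` controls
        the tiling density.
    """
    from .av import Structure  # deferred: av imports nothing from simulate

    if kind == "lone-attachment-atom":
        radius = kw.pop("radius", 1.7)
        if kw:
            raise ValueError(f"unknown parameters {sorted(kw)}")
        return Structure(
            coords=np.zeros((1, 3)),
            radii=np.array([radius]),
            element=np.array(["C"]),
            chain_id=np.array(["A"]),
            res_id=np.array([1]),
            atom_name=np.array(["CA"]),
            source="toy:lone-attachment-atom",
            attachment_index=0,
        )

    if kind == "planar-wall":
        z0 = kw.pop("z", 0.0)
        extent = kw.pop("extent", 60.0)
        spacing = kw.pop("spacing", 1.5)
        radius = kw.pop("radius", 1.5)
        layers = kw.pop("layers", 1)
        if kw:
            raise ValueError(f"unknown parameters {sorted(kw)}")
        ax = np.arange(-extent / 2, extent / 2 + spacing / 2, spacing)
        xx, yy = np.meshgrid(ax, ax, indexing="ij")
        coords = []
        for layer in range(layers):
            zz = np.full(xx.size, z0 - layer * spacing)
            coords.append(np.column_stack([xx.ravel(), yy.ravel(), zz]))
        coords = np.concatenate(coords)
        # attachment = the wall atom closest to the origin, in its own residue
        attach = int(np.argmin(np.linalg.norm(coords - [0.0, 0.0, z0], axis=1)))
        res = np.ones(len(coords), dtype=int)
        res[attach] = 2
        return Structure(
            coords=coords,
            radii=np.full(len(coords), radius),
            element=np.full(len(coords), "C"),
            chain_id=np.full(len(coords), "A"),
            res_id=res,
            atom_name=np.array(
                ["CA" if i == attach else "CW" for i in range(len(coords))]
            ),
            source="toy:planar-wall",
            attachment_index=attach,
        )

    if kind == "spherical-cavity":
        radius = kw.pop("radius", 15.0)
        point_spacing = kw.pop("point_spacing", 1.0)
        atom_radius = kw.pop("atom_radius", 1.5)
        if kw:
            raise ValueError(f"unknown parameters {sorted(kw)}")
        n = max(12, int(4.0 * math.pi * radius**2 / point_spacing**2))
        i = np.arange(n)
        phi = math.pi * (3.0 - math.sqrt(5.0)) * i  # Fibonacci sphere
        z = 1.0 - 2.0 * (i + 0.5) / n
        r_xy = np.sqrt(1.0 - z**2)
        shell = radius * np.column_stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z])
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        res = np.concatenate([[2], np.ones(n, dtype=int)])
        return Structure(
            coords=coords,
            radii=np.concatenate([[1.0], np.full(n, atom_radius)]),
            element=np.full(n + 1, "C"),
            chain_id=np.full(n + 1, "A"),
            res_id=res,
            atom_name=np.array(["CA"] + ["CW"] * n),
            source="toy:spherical-cavity",
            attachment_index=0,
        )

    raise ValueError(f"unknown toy structure kind: {kind!r}")
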