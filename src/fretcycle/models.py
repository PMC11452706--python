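"""Shared value types for the smFRET / kinetics pipeline.

These small frozen dataclasses carry the physical parameters that every
stage of the analysis agrees on: the two-state interconversion model of a
FRET-labelled dimer, the intensity correction factors of accurate-FRET
analysis, and the dye-pair photophysical constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TwoStateKineticModel",
    "MultiStateKineticModel",
    "CorrectionSet",
    "FretConstants",
]


@dataclass(frozen=True)
class FretConstants:
    """Dye-pair constants: Förster radius and donor-only lifetime.

    R0 is the distance (Å) at which transfer efficiency is 0.5 (59 Å for
    the Atto532/Atto643 pair used throughout); tauD0 is the fluorescence
    lifetime (ns) of the donor in the absence of an acceptor.
    """

    R0: float = 59.0
    tauD0: float = 3.8

    def __post_init__(self) -> None:
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")
        if self.tauD0 <= 0:
            raise ValueError("tauD0 must be positive")


@dataclass(frozen=True)
class CorrectionSet:
    """Intensity corrections of accurate FRET analysis.

    alpha scales the acceptor-excitation signal F_RR to remove direct
    acceptor excitation from F_GR; beta scales F_GG to remove donor
    crosstalk from F_GR; gamma is the acceptor/donor detection-efficiency
    times quantum-yield ratio.  ``background_rates`` are per-channel
    (GG, GR, RR) background count rates in photons/ms, subtracted from the
    raw burst counts before the corrected efficiency is formed.
    """

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 1.0
    background_rates: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if any(b < 0 for b in self.background_rates):
            raise ValueError("background rates must be nonnegative")

    @classmethod
    def identity(cls) -> "CorrectionSet":
        return cls()

    def without_background(self) -> "CorrectionSet":
        return replace(self, background_rates=(0.0, 0.0, 0.0))


@dataclass(frozen=True)
class TwoStateKineticModel:
    """Two FRET states interconverting as a continuous-time Markov chain.

    E1, E2 are the transfer efficiencies of the two conformations; k12 and
    k21 the 1→2 and 2→1 rate constants in ms⁻¹.  Donor lifetimes of the
    states follow from the donor-only lifetime: tau_i = tauD0 * (1 - E_i).

    Equilibrium occupancies are p1 = k21/(k12+k21) and p2 = 1 - p1; for a
    frozen chain (both rates zero) ``p1`` falls back to ``p1_static``.
    """

    E1: float
    E2: float
    k12: float = 0.0
    k21: float = 0.0
    tauD0: float = 3.8
    p1_static: float = 1.0

    def __post_init__(self) -> None:
        for name in ("E1", "E2"):
            e = getattr(self, name)
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.k12 < 0 or self.k21 < 0:
            raise ValueError("rates must be nonnegative")
        if self.tauD0 <= 0:
            raise ValueError("tauD0 must be positive")
        if not 0.0 <= self.p1_static <= 1.0:
            raise ValueError("p1_static must lie in [0, 1]")

    @property
    def p1(self) -> float:
        k = self.k12 + self.k21
        if k == 0.0:
            return self.p1_static
        return self.k21 / k

    @property
    def p2(self) -> float:
        return 1.0 - self.p1

    @property
    def tau1(self) -> float:
        """Donor lifetime (ns) of state 1."""
        return self.tauD0 * (1.0 - self.E1)

    @property
    def tau2(self) -> float:
        """Donor lifetime (ns) of state 2."""
        return self.tauD0 * (1.0 - self.E2)

    @property
    def mean_E(self) -> float:
        return self.p1 * self.E1 + self.p2 * self.E2


@dataclass(frozen=True)
class MultiStateKineticModel:
    """CTMC over n FRET states with a full rate matrix.

    ``rate_matrix[i, j]`` (i != j) is the i→j rate in ms⁻¹; the diagonal is
    ignored.  Used by the photon-stream generator to emulate ensembles with
    more than two conformations; histogram fitting stays two-state.
    """

    efficiencies: tuple[float, ...]
    rate_matrix: tuple[tuple[float, ...], ...]
    tauD0: float = 3.8

    def __post_init__(self) -> None:
        n = len(self.efficiencies)
        q = np.asarray(self.rate_matrix, dtype=float)
        if q.shape != (n, n):
            raise ValueError("rate_matrix must be square, one row per state")
        off = q[~np.eye(n, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be nonnegative")
        if any(not 0.0 <= e <= 1.0 for e in self.efficiencies):
            raise ValueError("efficiencies must lie in [0, 1]")

    @property
    def n_states(self) -> int:
        return len(self.efficiencies)

    @property
    def Q(self) -> np.ndarray:
        """Generator matrix (ms⁻¹) with the proper negative diagonal."""
        q = np.asarray(self.rate_matrix, dtype=float).copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    @property
    def stationary(self) -> np.ndarray:
        """Stationary distribution of the chain (uniform over closed classes)."""
        q = self.Q
        n = self.n_states
        a = np.vstack([q.T, np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()

    @property
    def lifetimes(self) -> np.ndarray:
        return self.tauD0 * (1.0 - np.asarray(self.efficiencies))


def two_state_as_multi(model: TwoStateKineticModel) -> MultiStateKineticModel:
    return MultiStateKineticModel(
        efficiencies=(model.E1, model.E2),
        rate_matrix=((0.0, model.k12), (model.k21, 0.0)),
        tauD0=model.tauD0,
    )
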