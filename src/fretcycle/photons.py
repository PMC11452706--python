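"""Time-tagged photon streams and their on-disk formats.

A :class:`PhotonStream` is the raw observable of a diffusion-based smFRET
measurement with pulsed interleaved excitation: for every detected photon a
macrotime (laser-clock ticks since the start of the acquisition), a
microtime (ns after the excitation pulse) and a channel tag.  Channels
follow the usual MFD-PIE convention:

* ``GG`` — green detector, donor-excitation window (donor photons),
* ``GR`` — red detector, donor-excitation window (FRET-sensitised acceptor
  photons plus crosstalk and direct excitation),
* ``RR`` — red detector, acceptor-excitation window.

Streams round-trip through a minimal Photon-HDF5-style layout
(``/photon_data/timestamps|detectors|nanotimes``) and through a plain CSV
with columns ``macrotime,microtime_ns,channel``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

__all__ = ["CHANNELS", "GG", "GR", "RR", "PhotonStream"]

GG, GR, RR = 0, 1, 2
CHANNELS = {"GG": GG, "GR": GR, "RR": RR}
_CHANNEL_NAMES = {v: k for k, v in CHANNELS.items()}


@dataclass
class PhotonStream:
    """Time-ordered photons with channel tags.

    Parameters
    ----------
    timestamps : int64 array, macrotime in clock ticks.
    channel : uint8 array, one of GG/GR/RR.
    microtime_ns : float array, time after excitation pulse (ns).
    resolution : macrotime tick length in seconds.
    excitation_period_ns : PIE excitation period (ns); all microtimes lie in
        ``[0, excitation_period_ns)``.
    duration_s : acquisition length in seconds.
    truth : optional per-burst ground-truth table attached by the
        synthetic-data generator (never written to disk by default).
    """

    timestamps: np.ndarray
    channel: np.ndarray
    microtime_ns: np.ndarray
    resolution: float = 1e-9
    excitation_period_ns: float = 50.0
    duration_s: float = 0.0
    truth: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.channel = np.asarray(self.channel, dtype=np.uint8)
        self.microtime_ns = np.asarray(self.microtime_ns, dtype=np.float64)
        n = len(self.timestamps)
        if len(self.channel) != n or len(self.microtime_ns) != n:
            raise ValueError("timestamps, channel and microtime_ns must have equal length")
        if n and np.any(np.diff(self.timestamps) < 0):
            raise ValueError("macrotimes must be nondecreasing")
        if not np.all(np.isin(self.channel, (GG, GR, RR))):
            raise ValueError("invalid channel tag")
        if n and (self.microtime_ns.min() < 0 or self.microtime_ns.max() >= self.excitation_period_ns):
            raise ValueError("microtimes must lie in [0, excitation_period)")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def times_s(self) -> np.ndarray:
        """Macrotimes in seconds."""
        return self.timestamps * self.resolution

    def channel_mask(self, name: str) -> np.ndarray:
        return self.channel == CHANNELS[name]

    # ------------------------------------------------------------------ CSV

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "macrotime": self.timestamps,
                "microtime_ns": self.microtime_ns,
                "channel": [_CHANNEL_NAMES[c] for c in self.channel],
            }
        )
        with open(path, "w") as fh:
            fh.write(
                f"# resolution_s={float(self.resolution):.17g} "
                f"excitation_period_ns={float(self.excitation_period_ns):.17g} "
                f"duration_s={float(self.duration_s):.17g}\n"
            )
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PhotonStream":
        meta = {"resolution_s": 1e-9, "excitation_period_ns": 50.0, "duration_s": 0.0}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for token in first[1:].split():
                    key, _, val = token.partition("=")
                    if key in meta:
                        meta[key] = float(val)
                df = pd.read_csv(fh)
            else:
                df = pd.read_csv(path)
        return cls(
            timestamps=df["macrotime"].to_numpy(np.int64),
            channel=np.array([CHANNELS[c] for c in df["channel"]], dtype=np.uint8),
            microtime_ns=df["microtime_ns"].to_numpy(float),
            resolution=meta["resolution_s"],
            excitation_period_ns=meta["excitation_period_ns"],
            duration_s=meta["duration_s"],
        )

    # ----------------------------------------------------------- Photon-HDF5

    def to_hdf5(self, path: str | Path) -> None:
        """Write a minimal Photon-HDF5-style file."""
        with h5py.File(path, "w") as f:
            pd_grp = f.create_group("photon_data")
            pd_grp.create_dataset("timestamps", data=self.timestamps)
            pd_grp.create_dataset("detectors", data=self.channel)
            pd_grp.create_dataset("nanotimes", data=self.microtime_ns)
            spec = pd_grp.create_group("timestamps_specs")
            spec.create_dataset("timestamps_unit", data=self.resolution)
            setup = f.create_group("setup")
            setup.create_dataset("excitation_period_ns", data=self.excitation_period_ns)
            setup.create_dataset("acquisition_duration", data=self.duration_s)
            f.attrs["format"] = "Photon-HDF5-like"

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "PhotonStream":
        with h5py.File(path, "r") as f:
            return cls(
                timestamps=f["photon_data/timestamps"][()],
                channel=f["photon_data/detectors"][()],
                microtime_ns=f["photon_data/nanotimes"][()],
                resolution=float(f["photon_data/timestamps_specs/timestamps_unit"][()]),
                excitation_period_ns=float(f["setup/excitation_period_ns"][()]),
                duration_s=float(f["setup/acquisition_duration"][()]),
            )

    @classmethod
    def load(cls, path: str | Path) -> "PhotonStream":
        """Load from ``.h5``/``.hdf5`` or ``.csv`` by extension."""
        path = Path(path)
        if path.suffix.lower() in (".h5", ".hdf5"):
            return cls.from_hdf5(path)
        return cls.from_csv(path)
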