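"""Configuration-driven pipeline runs and machine-readable reports.

A run configuration is a plain mapping (usually loaded from YAML) with one
section per stage plus global ``seed``/``out``/``log_level`` keys.  Stage
defaults equal the library defaults; unknown keys fail validation before
any stage executes.  ``run_pipeline`` executes the requested stages in
order (simulate → bursts → pda → kinetics → av, whichever are present) and
writes per-stage outputs plus a JSON summary with every fitted parameter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .models import CorrectionSet, TwoStateKineticModel
from .photons import PhotonStream
from .burst import analyze_bursts, find_bursts
from .kinetics import (
    fit_bigaussian_series,
    fit_closing,
    fit_opening,
    load_chromatogram_series,
)
from .pda import PdaConfig, bin_photon_stream, fit_pda
from .simulate import SimBurstConfig, simulate_photon_stream

logger = logging.getLogger("fretcycle")

__all__ = ["ConfigError", "load_config", "save_config", "validate_config", "run_pipeline", "write_report"]

_GLOBAL_KEYS = {"seed", "out", "log_level"}
_STAGE_KEYS = {
    "simulate": {
        "model": {"E1", "E2", "k12", "k21", "tauD0"},
        "config": {f.name for f in dataclasses.fields(SimBurstConfig)},
        "corrections": {"alpha", "beta", "gamma", "background_rates"},
        "output": None,
    },
    "bursts": {
        "photons": None,
        "window_T": None,
        "min_in_window": None,
        "min_total": None,
        "s_window": None,
        "corrections": {"alpha", "beta", "gamma", "background_rates"},
        "output": None,
    },
    "pda": {
        "photons": None,
        "bursts": None,
        "init": {"E1", "E2", "k12", "k21"},
        "bin_durations": None,
        "count_range": None,
        "n_bins_E": None,
        "corrections": {"alpha", "beta", "gamma", "background_rates"},
        "output": None,
    },
    "kinetics": {
        "manifest": None,
        "mode": None,
        "fix_feq": None,
        "closed_elutes": None,
        "output": None,
    },
    "av": {
        "pdb": None,
        "site": None,
        "site2": None,
        "donor_radii": None,
        "acceptor_radii": None,
        "linker_length": None,
        "linker_width": None,
        "grid_spacing": None,
        "r0": None,
        "n_samples": None,
        "output": None,
    },
}


class ConfigError(ValueError):
    pass


def validate_config(config: Mapping[str, Any]) -> None:
    """Reject unknown keys anywhere in the configuration tree."""
    for key, value in config.items():
        if key in _GLOBAL_KEYS:
            continue
        if key not in _STAGE_KEYS:
            raise ConfigError(f"unknown configuration section {key!r}")
        allowed = _STAGE_KEYS[key]
        if not isinstance(value, Mapping):
            raise ConfigError(f"section {key!r} must be a mapping")
        for sub, subval in value.items():
            if sub not in allowed:
                raise ConfigError(f"unknown key {key}.{sub}")
            inner = allowed[sub]
            if inner is not None and isinstance(subval, Mapping):
                extra = set(subval) - inner
                if extra:
                    raise ConfigError(f"unknown key(s) {key}.{sub}.{sorted(extra)}")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    validate_config(config)
    return config


def save_config(config: Mapping[str, Any], path: str | Path) -> None:
    validate_config(config)
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)


def _corrections_from(section: Mapping[str, Any] | None) -> CorrectionSet:
    if not section:
        return CorrectionSet.identity()
    kw = dict(section)
    if "background_rates" in kw:
        kw["background_rates"] = tuple(kw["background_rates"])
    return CorrectionSet(**kw)


def run_pipeline(config: Mapping[str, Any], outdir: str | Path | None = None) -> dict:
    """Execute the configured stages and write outputs plus a summary JSON."""
    validate_config(config)
    outdir = Path(outdir if outdir is not None else config.get("out", "fretcycle_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    logging.basicConfig(level=getattr(logging, str(config.get("log_level", "INFO")).upper(), logging.INFO))
    summary: dict[str, Any] = {"version": __version__, "seed": seed}
    stream: PhotonStream | None = None
    bursts_df: pd.DataFrame | None = None
    spans = None

    if "simulate" in config:
        sec = config["simulate"]
        model = TwoStateKineticModel(**sec.get("model", {"E1": 0.2, "E2": 0.9}))
        cfg_kw = dict(sec.get("config", {}))
        if "truth_corrections" not in cfg_kw and "corrections" in sec:
            cfg_kw["truth_corrections"] = _corrections_from(sec["corrections"])
        cfg_kw.setdefault("seed", seed)
        sim_cfg = SimBurstConfig(**cfg_kw)
        stream = simulate_photon_stream(model, sim_cfg)
        out_file = outdir / sec.get("output", "photons.h5")
        stream.to_hdf5(out_file)
        stream.truth.to_csv(outdir / "burst_truth.csv", index=False)
        summary["simulate"] = {
            "photons": len(stream),
            "bursts": int(len(stream.truth)),
            "output": str(out_file),
        }
        logger.info("simulated %d photons in %d bursts", len(stream), len(stream.truth))

    if "bursts" in config:
        sec = config["bursts"]
        if stream is None:
            stream = PhotonStream.load(sec["photons"])
        corr = _corrections_from(sec.get("corrections"))
        spans = find_bursts(
            stream,
            window_T=float(sec.get("window_T", 0.5)),
            min_in_window=int(sec.get("min_in_window", 15)),
            min_total=int(sec.get("min_total", 60)),
        )
        bursts_df = analyze_bursts(stream, spans, corr)
        out_file = outdir / sec.get("output", "bursts.csv")
        bursts_df.to_csv(out_file, index=False)
        s_lo, s_hi = sec.get("s_window", (0.3, 0.7))
        sel = bursts_df["S"].between(s_lo, s_hi) & bursts_df["E"].notna()
        summary["bursts"] = {
            "n_bursts": int(len(bursts_df)),
            "n_selected": int(sel.sum()),
            "mean_E_selected": float(bursts_df.loc[sel, "E"].mean()) if sel.any() else None,
            "output": str(out_file),
        }

    if "pda" in config:
        sec = config["pda"]
        if stream is None:
            stream = PhotonStream.load(sec["photons"])
        if spans is None:
            spans = find_bursts(stream)
        cfg_kw = {}
        if "bin_durations" in sec:
            cfg_kw["bin_durations"] = tuple(sec["bin_durations"])
        if "count_range" in sec:
            cfg_kw["count_range"] = tuple(sec["count_range"])
        if "n_bins_E" in sec:
            cfg_kw["n_bins_E"] = int(sec["n_bins_E"])
        pda_cfg = PdaConfig(**cfg_kw)
        corr = _corrections_from(sec.get("corrections"))
        init = TwoStateKineticModel(
            **{"E1": 0.1, "E2": 0.8, "k12": 0.5, "k21": 0.5, **sec.get("init", {})}
        )
        binned = {
            T: bin_photon_stream(stream, spans, pda_cfg, bin_duration=T)
            for T in pda_cfg.bin_durations
        }
        result = fit_pda(binned, init, pda_cfg, corrections=corr)
        payload = {
            "E1": result.model.E1,
            "E2": result.model.E2,
            "k12": result.model.k12,
            "k21": result.model.k21,
            "amplitudes": list(result.amplitudes),
            "redchi": result.redchi,
            "stderr": result.stderr,
            "success": result.success,
            "warnings": list(result.warnings),
        }
        out_file = outdir / sec.get("output", "pda.json")
        out_file.write_text(json.dumps(payload, indent=2, sort_keys=True))
        summary["pda"] = payload

    if "kinetics" in config:
        sec = config["kinetics"]
        series = load_chromatogram_series(sec["manifest"])
        closed_elutes = sec.get("closed_elutes", "later")
        decomps = fit_bigaussian_series(series, closed_elutes=closed_elutes)
        times = [d.time_min for d in decomps]
        fracs = [d.closed_fraction for d in decomps]
        mode = sec.get("mode", "closing")
        if mode == "closing":
            rate = fit_closing(times, fracs)
        else:
            rate = fit_opening(times, fracs, fix_feq=sec.get("fix_feq"))
        payload = {
            "k": rate.k,
            "se": rate.k_stderr,
            "f0": rate.f0,
            ("f_inf" if mode == "closing" else "f_eq"): rate.f_asym,
            "model": rate.model,
            "flags": list(rate.flags),
            "fractions": [
                {"time_min": t, "closed_fraction": f} for t, f in zip(times, fracs)
            ],
        }
        out_file = outdir / sec.get("output", "kinetics.json")
        out_file.write_text(json.dumps(payload, indent=2, sort_keys=True))
        summary["kinetics"] = payload

    if "av" in config:
        from .av import AVParams, av_pair_stats, compute_av3, read_structure

        sec = config["av"]
        structure = read_structure(sec["pdb"])
        common = dict(
            linker_length=float(sec.get("linker_length", 21.0)),
            linker_width=float(sec.get("linker_width", 4.5)),
            grid_spacing=float(sec.get("grid_spacing", 0.9)),
        )
        donor = compute_av3(
            structure,
            AVParams(
                dye_radii=tuple(sec.get("donor_radii", (5.5, 4.5, 1.5))),
                attachment=sec["site"],
                **common,
            ),
        )
        acceptor = compute_av3(
            structure,
            AVParams(
                dye_radii=tuple(sec.get("acceptor_radii", (7.15, 4.5, 1.5))),
                attachment=sec["site2"],
                **common,
            ),
        )
        stats = av_pair_stats(
            donor,
            acceptor,
            R0=float(sec.get("r0", 59.0)),
            n_samples=int(sec.get("n_samples", 200_000)),
            seed=seed,
        )
        out_file = outdir / sec.get("output", "av.json")
        out_file.write_text(json.dumps(stats, indent=2, sort_keys=True))
        summary["av"] = stats

    write_report(summary, outdir / "summary.json")
    return summary


def write_report(summary: Mapping[str, Any], path: str | Path) -> None:
    """Serialise a stage summary: deterministic key order, full float precision."""

    def default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"cannot serialise {type(obj).__name__}")

    Path(path).write_text(json.dumps(dict(summary), indent=2, sort_keys=True, default=default))
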