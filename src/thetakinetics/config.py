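"""YAML experiment configuration: timer, analyte, mode, fit and simulation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .abundance import ResponseFactors
from .calibration import TimerSystem
from .fitting import AnalyteSystem, FitOptions
from .kinetics import RateConstants
from .simulate import SimulationConfig

__all__ = ["ExperimentConfig", "load_config", "preset", "PRESETS", "config_hash"]

#: benchmark regime: GFP binding Nb15 timed by the NbAS epitope timer
GFP_NB15_PRESET = {
    "timer": {"epitope_total_M": 1.0e-6, "nb_total_M": 2.0e-6, "kon": 3.6e5, "koff": 9.4e-6},
    "analyte": {"protein_total_M": 0.8e-6, "ligand_total_M": 2.0e-6, "reversible": True},
    "mode": "nonfusion",
    "response_factors": {},
    "fit": {"model": "both", "outlier_threshold": 3.0, "equilibrated_eps": 0.01},
    "simulation": {
        "truth": {"kon": 1.3e5, "koff": 1.3e-2},
        "n_bursts": 5,
        "spectra_per_burst": 15,
        "alpha": [0.4, 0.6],
        "time_bounds_s": [0.1, 40.0],
        "noise_sigma": 0.02,
        "seed": 1,
    },
}

PRESETS = {"gfp-nb15": GFP_NB15_PRESET}


@dataclass
class ExperimentConfig:
    timer: TimerSystem
    analyte: AnalyteSystem
    mode: str
    response_factors: ResponseFactors
    fit_model: str
    fit_options: FitOptions
    outlier_threshold: float
    simulation: SimulationConfig | None
    raw: dict


def _f(x) -> float:
    """Coerce YAML scalars (which may parse as strings like '3.6e5') to float."""
    return float(x)


def _build(raw: dict) -> ExperimentConfig:
    t = raw["timer"]
    timer = TimerSystem(
        epitope_total=_f(t["epitope_total_M"]),
        nb_total=_f(t["nb_total_M"]),
        rates=RateConstants(kon=_f(t["kon"]), koff=_f(t["koff"])),
    )
    a = raw["analyte"]
    analyte = AnalyteSystem(
        protein_total=_f(a["protein_total_M"]),
        ligand_total=_f(a["ligand_total_M"]),
        reversible=bool(a.get("reversible", True)),
    )
    mode = raw.get("mode", "nonfusion")
    rf = ResponseFactors({k: _f(v) for k, v in (raw.get("response_factors") or {}).items()})
    fit_raw = raw.get("fit") or {}
    fit_options = FitOptions(
        equilibrated_eps=_f(fit_raw.get("equilibrated_eps", 0.01)),
        min_spectra_per_burst=int(fit_raw.get("min_spectra_per_burst", 3)),
    )
    sim = None
    if raw.get("simulation"):
        s = raw["simulation"]
        alpha = s.get("alpha", [0.4, 0.6])
        if isinstance(alpha, list) and len(alpha) == 2:
            alpha = (float(alpha[0]), float(alpha[1]))
        elif isinstance(alpha, list):
            alpha = [float(v) for v in alpha]
        else:
            alpha = float(alpha)
        bounds = s.get("time_bounds_s", [0.1, 40.0])
        sim = SimulationConfig(
            truth=RateConstants(kon=_f(s["truth"]["kon"]), koff=_f(s["truth"]["koff"])),
            timer=timer,
            protein_total=analyte.protein_total,
            ligand_total=analyte.ligand_total,
            n_bursts=int(s.get("n_bursts", 5)),
            spectra_per_burst=int(s.get("spectra_per_burst", 15)),
            alpha=alpha,
            time_bounds=(float(bounds[0]), float(bounds[1])),
            time_distribution=s.get("time_distribution", "log-uniform"),
            noise_sigma=_f(s.get("noise_sigma", 0.02)),
            seed=int(s.get("seed", 0)),
            mode=mode,
        )
    return ExperimentConfig(
        timer=timer,
        analyte=analyte,
        mode=mode,
        response_factors=rf,
        fit_model=str(fit_raw.get("model", "both")),
        fit_options=fit_options,
        outlier_threshold=_f(fit_raw.get("outlier_threshold", 3.0)),
        simulation=sim,
        raw=raw,
    )


def load_config(path) -> ExperimentConfig:
    """Load an experiment configuration from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return _build(raw)


def preset(name: str) -> ExperimentConfig:
    """Built-in configuration presets (``gfp-nb15``)."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return _build(PRESETS[name])


def config_hash(raw: dict) -> str:
    """Stable short hash of a configuration for run logs."""
    blob = json.dumps(raw, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
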