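"""Per-spectrum species-abundance tables, mole fractions, response factors.

The canonical input is a deconvoluted species table: tab-delimited text
with header ``emitter_id  burst_id  scan_index  species  abundance``
and one row per (spectrum, species). Deconvolution (e.g. UniDec) is
upstream and out of scope; intensities are taken as proportional to
concentration within a protein margin.

Two species vocabularies are supported:

* nonfusion — timer and analyte are separate proteins:
  ``timer_apo, timer_bound, analyte_apo, analyte_bound``
* fusion — the timer epitope is genetically fused to the analyte, so a
  single protein carries up to two binders and the four species
  ``apo, bound_timer, bound_analyte, bound_both`` form a 2x2
  contingency whose margins are the timer and analyte occupancies
  (``bound_both`` counts toward both).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "NONFUSION_SPECIES",
    "FUSION_SPECIES",
    "SpectrumRecord",
    "ResponseFactors",
    "read_species_table",
    "read_wide_table",
    "write_species_table",
    "mole_fractions",
    "estimate_response_factors",
    "fraction_to_concentration",
]

logger = logging.getLogger(__name__)

NONFUSION_SPECIES = ("timer_apo", "timer_bound", "analyte_apo", "analyte_bound")
FUSION_SPECIES = ("apo", "bound_timer", "bound_analyte", "bound_both")

#: margin -> (apo species, bound species) per mode
_MARGINS = {
    "nonfusion": {
        "timer": (("timer_apo",), ("timer_bound",)),
        "analyte": (("analyte_apo",), ("analyte_bound",)),
    },
    "fusion": {
        "timer": (("apo", "bound_analyte"), ("bound_timer", "bound_both")),
        "analyte": (("apo", "bound_timer"), ("bound_analyte", "bound_both")),
    },
}

_COLUMNS = ["emitter_id", "burst_id", "scan_index", "species", "abundance"]


@dataclass(frozen=True)
class SpectrumRecord:
    """One spectrum's deconvoluted species abundances."""

    emitter_id: str
    burst_id: str
    scan_index: int
    abundances: Mapping[str, float]

    def __post_init__(self) -> None:
        for sp, a in self.abundances.items():
            if a < 0:
                raise ValueError(f"negative abundance {a!r} for species {sp!r}")
        if sum(self.abundances.values()) <= 0:
            raise ValueError("spectrum has no positive abundance")

    @property
    def mode(self) -> str:
        """Infer fusion/nonfusion from the species labels present."""
        labels = set(self.abundances)
        if labels <= set(FUSION_SPECIES):
            return "fusion"
        if labels <= set(NONFUSION_SPECIES):
            return "nonfusion"
        raise ValueError(f"mixed or unknown species labels: {sorted(labels)}")


@dataclass(frozen=True)
class ResponseFactors:
    """Multiplicative per-species MS response corrections (default 1.0).

    Corrected mole amount = r * raw intensity, with r estimated so that
    corrected fractions reproduce known solution compositions. r = 1 for
    every species is the identity correction.
    """

    factors: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, r in self.factors.items():
            if r <= 0:
                raise ValueError(f"response factor for {sp!r} must be > 0, got {r!r}")

    def get(self, species: str) -> float:
        return self.factors.get(species, 1.0)


def read_species_table(path, mode: str | None = None) -> list[SpectrumRecord]:
    """Read a canonical species-abundance file into SpectrumRecords.

    Records are grouped by (emitter, burst) and ordered by scan_index.
    Unknown species labels, negative intensities, missing columns and
    duplicate (emitter, burst, scan, species) keys are rejected.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"emitter_id": str, "burst_id": str},
        float_precision="round_trip",
    )
    return _records_from_frame(df, str(path), mode)


def _records_from_frame(
    df: pd.DataFrame, path: str, mode: str | None
) -> list[SpectrumRecord]:
    if df.empty:
        logger.warning("species table %s is empty", path)
        return []
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if mode is None:
        labels = set(df["species"])
        if labels <= set(FUSION_SPECIES):
            mode = "fusion"
        elif labels <= set(NONFUSION_SPECIES):
            mode = "nonfusion"
        else:
            bad = labels - set(FUSION_SPECIES) - set(NONFUSION_SPECIES)
            raise ValueError(f"{path}: unknown species labels {sorted(bad)}")
    allowed = set(FUSION_SPECIES if mode == "fusion" else NONFUSION_SPECIES)
    bad = set(df["species"]) - allowed
    if bad:
        raise ValueError(f"{path}: species {sorted(bad)} not in {mode} vocabulary")
    if (df["abundance"] < 0).any():
        raise ValueError(f"{path}: negative abundances")
    keys = ["emitter_id", "burst_id", "scan_index", "species"]
    if df.duplicated(keys).any():
        dup = df[df.duplicated(keys)].iloc[0]
        raise ValueError(
            f"{path}: duplicate entry for "
            f"({dup.emitter_id}, {dup.burst_id}, {dup.scan_index}, {dup.species})"
        )
    records: list[SpectrumRecord] = []
    for (emitter, burst, scan), grp in df.groupby(
        ["emitter_id", "burst_id", "scan_index"], sort=True
    ):
        records.append(
            SpectrumRecord(
                emitter_id=str(emitter),
                burst_id=str(burst),
                scan_index=int(scan),
                abundances=dict(zip(grp["species"], grp["abundance"].astype(float))),
            )
        )
    records.sort(key=lambda r: (r.emitter_id, r.burst_id, r.scan_index))
    return records


def read_wide_table(
    path,
    species_columns: Mapping[str, str] | None = None,
    mode: str | None = None,
) -> list[SpectrumRecord]:
    """Adapter for the wide per-spectrum layout deconvolution tools export.

    One row per spectrum: ``emitter_id``, ``burst_id``, ``scan_index``
    plus one intensity column per species. ``species_columns`` maps
    column names to canonical species labels (identity by default, for
    files already using the canonical vocabulary). The canonical long
    format of :func:`read_species_table` remains authoritative; this
    merely reshapes.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"emitter_id": str, "burst_id": str},
        float_precision="round_trip",
    )
    key_cols = ["emitter_id", "burst_id", "scan_index"]
    missing = [c for c in key_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    rename = dict(species_columns or {})
    value_cols = [c for c in df.columns if c not in key_cols]
    long = df.melt(
        id_vars=key_cols, value_vars=value_cols, var_name="species", value_name="abundance"
    )
    long["species"] = long["species"].map(lambda c: rename.get(c, c))
    allowed = set(FUSION_SPECIES) | set(NONFUSION_SPECIES)
    bad = set(long["species"]) - allowed
    if bad:
        raise ValueError(f"{path}: unmapped species columns {sorted(bad)}")
    return _records_from_frame(long, str(path), mode)


def write_species_table(records: Iterable[SpectrumRecord], path) -> None:
    """Write records to the canonical tab-delimited layout.

    Deterministic row order and ``%.17g`` float formatting make
    write -> read -> write byte-identical.
    """
    rows = []
    for rec in sorted(records, key=lambda r: (r.emitter_id, r.burst_id, r.scan_index)):
        for sp in sorted(rec.abundances):
            rows.append((rec.emitter_id, rec.burst_id, rec.scan_index, sp, rec.abundances[sp]))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for emitter, burst, scan, sp, a in rows:
            fh.write(f"{emitter}\t{burst}\t{scan}\t{sp}\t{a:.17g}\n")


def mole_fractions(
    record: SpectrumRecord,
    margin: str,
    rf: ResponseFactors | None = None,
    mode: str | None = None,
) -> float:
    """Bound mole fraction of the requested margin (``timer`` or ``analyte``).

    f = corrected bound intensity / (corrected apo + bound intensity),
    where corrected = response factor x raw. In fusion mode the ternary
    ``bound_both`` species contributes to the bound side of both margins.
    """
    if margin not in ("timer", "analyte"):
        raise ValueError(f"margin must be 'timer' or 'analyte', got {margin!r}")
    rf = rf or ResponseFactors()
    mode = mode or record.mode
    apo_sp, bound_sp = _MARGINS[mode][margin]
    apo = sum(rf.get(sp) * record.abundances.get(sp, 0.0) for sp in apo_sp)
    bound = sum(rf.get(sp) * record.abundances.get(sp, 0.0) for sp in bound_sp)
    total = apo + bound
    if total <= 0:
        raise ValueError(
            f"uninformative spectrum: zero corrected intensity on the {margin} margin"
        )
    return bound / total


def estimate_response_factors(
    mixtures: Sequence[tuple[float, float]],
    bound_species: str = "bound",
) -> ResponseFactors:
    """Fit a single bound-species response factor from known mixtures.

    ``mixtures`` are (known solution bound fraction, observed MS bound
    fraction) pairs from a titration of purified apo against purified
    complex. Fits r > 0 minimizing squared error of the model

        observed = r * known / (r * known + (1 - known)).

    Requires at least two mixtures with distinct known fractions.
    """
    known = np.asarray([m[0] for m in mixtures], dtype=float)
    obs = np.asarray([m[1] for m in mixtures], dtype=float)
    if known.size < 2 or np.unique(known).size < 2:
        raise ValueError(
            "response factor is unidentifiable: need >= 2 mixtures with distinct "
            "known fractions"
        )
    if np.any((known < 0) | (known > 1) | (obs < 0) | (obs > 1)):
        raise ValueError("fractions must lie in [0, 1]")

    def sse(log_r: float) -> float:
        r = np.exp(log_r)
        pred = r * known / (r * known + (1.0 - known))
        return float(np.sum((obs - pred) ** 2))

    res = minimize_scalar(sse, bounds=(-10.0, 10.0), method="bounded",
                          options={"xatol": 1e-12})
    r_hat = float(np.exp(res.x))
    return ResponseFactors({bound_species: r_hat})


def fraction_to_concentration(f: float, total: float, alpha: float) -> float:
    """Convert a bound fraction to a bound concentration in molar.

    For a protein-channel species diluted by mixing factor alpha, the
    post-mixing total is alpha * total, so bound = f * alpha * total.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {f!r}")
    if total <= 0:
        raise ValueError(f"total must be > 0, got {total!r}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
    return f * alpha * total
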