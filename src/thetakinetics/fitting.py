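"""Global kinetic fitting across bursts with per-burst mixing factors.

Each burst (ESI voltage cycle) of spectra carries a latent mixing time
per spectrum and one mixing factor alpha describing how unevenly the two
emitter channels contributed to the mixed droplet. The fit estimates the
analyte rate constants (kon, koff — or kon alone for irreversible
binders) jointly with either a single shared alpha or one alpha per
burst, by least squares on analyte bound fractions:

    minimize  sum_i ( f_obs,i - f_model( t_i(alpha_b) ; kon, koff, alpha_b ) )^2

where t_i is re-derived from the spectrum's timer bound fraction through
the alpha-dependent calibration curve on every objective evaluation —
changing alpha changes the calibration curve and therefore every
assigned mixing time, not just the model concentrations.

Model comparison between the shared-alpha and per-burst-alpha fits uses
the classical extra-sum-of-squares F-test for nested least-squares
models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .abundance import ResponseFactors, SpectrumRecord, mole_fractions
from .calibration import (
    DEFAULT_EQUILIBRATED_EPS,
    TimerSystem,
    build_curve,
)
from .kinetics import BindingSystem, RateConstants, closed_form_complex, time_to_complex

__all__ = [
    "AnalyteSystem",
    "KineticDataset",
    "FitOptions",
    "FitResult",
    "ReplicateSummary",
    "fit_global",
    "fit_irreversible",
    "f_test",
    "flag_outlier_bursts",
    "summarize_replicates",
]

logger = logging.getLogger(__name__)

# parameter bounds (log10 for the rate constants)
_LOG10_KON_BOUNDS = (2.0, 10.0)
_LOG10_KOFF_BOUNDS = (-6.0, 3.0)
_ALPHA_BOUNDS = (0.05, 0.95)

# deterministic multi-start grid
_KON_STARTS = (1e4, 1e5, 1e6)
_KOFF_STARTS = (1e-3, 1e-1)


@dataclass(frozen=True)
class AnalyteSystem:
    """Analyte channel totals; the rate constants are what the fit estimates."""

    protein_total: float
    ligand_total: float
    reversible: bool = True

    def __post_init__(self) -> None:
        if self.protein_total <= 0:
            raise ValueError("protein_total must be > 0")
        if self.ligand_total < 0:
            raise ValueError("ligand_total must be >= 0")


@dataclass
class KineticDataset:
    """Spectra grouped into bursts plus the timer and analyte systems."""

    records: Sequence[SpectrumRecord]
    timer: TimerSystem
    analyte: AnalyteSystem
    mode: str = "nonfusion"
    response_factors: ResponseFactors = field(default_factory=ResponseFactors)

    def __post_init__(self) -> None:
        if self.mode not in ("fusion", "nonfusion"):
            raise ValueError(f"mode must be fusion|nonfusion, got {self.mode!r}")
        if not self.records:
            raise ValueError("dataset has no spectra")

    @property
    def burst_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.burst_id, None)
        return list(seen)


@dataclass(frozen=True)
class FitOptions:
    """Knobs of the global fit.

    ``equilibrated_eps`` — timer fractions within this relative distance
    of the calibration plateau are dropped as time-unresolvable.
    ``reference_alpha`` — the alpha at which the drop decision is made,
    once, before optimization (keeping the objective a fixed-length
    residual vector).
    ``min_spectra_per_burst`` — usable-spectra floor per burst.
    ``fixed_alpha`` — hold every mixing factor at this known value
    instead of estimating it (e.g. an independently characterized
    emitter); the alpha entries then leave the parameter count.
    """

    equilibrated_eps: float = DEFAULT_EQUILIBRATED_EPS
    reference_alpha: float = 0.5
    min_spectra_per_burst: int = 3
    fixed_alpha: float | None = None
    xtol: float = 1e-10
    ftol: float = 1e-10


@dataclass
class FitResult:
    """Converged global fit: rate constants, alphas, residuals, diagnostics."""

    rates: RateConstants
    alphas: dict[str, float]
    rss: float
    n_points: int
    n_params: int
    model: str
    stderr: dict[str, float]
    table: pd.DataFrame
    dropped: list[tuple[str, str, int]]
    success: bool
    message: str

    @property
    def kd(self) -> float:
        return self.rates.kd


@dataclass
class ReplicateSummary:
    """Mean +/- sample SD of kon, koff, K_D across emitter replicates.

    K_D is computed per replicate as that replicate's koff/kon and then
    averaged — never as mean(koff)/mean(kon).
    """

    n_replicates: int
    kon_mean: float
    kon_sd: float
    koff_mean: float
    koff_sd: float
    kd_mean: float
    kd_sd: float
    sd_defined: bool
    per_replicate: dict[str, FitResult]


def _prepare(dataset: KineticDataset, options: FitOptions):
    """Extract per-spectrum fractions, drop equilibrated spectra once.

    Returns (burst_ids, burst_slices, f_timer, f_analyte, meta, dropped).
    The drop decision uses the reference-alpha calibration curve so the
    least-squares objective keeps a fixed dimension while alpha moves.
    """
    ref_curve = build_curve(dataset.timer, options.reference_alpha)
    keep_ft: list[float] = []
    keep_fa: list[float] = []
    meta: list[tuple[str, str, int]] = []
    burst_of: list[str] = []
    dropped: list[tuple[str, str, int]] = []
    for rec in dataset.records:
        ft = mole_fractions(rec, "timer", dataset.response_factors, dataset.mode)
        fa = mole_fractions(rec, "analyte", dataset.response_factors, dataset.mode)
        if ft >= ref_curve.plateau_fraction * (1.0 - options.equilibrated_eps):
            dropped.append((rec.emitter_id, rec.burst_id, rec.scan_index))
            continue
        keep_ft.append(ft)
        keep_fa.append(fa)
        meta.append((rec.emitter_id, rec.burst_id, rec.scan_index))
        burst_of.append(rec.burst_id)
    if dropped:
        logger.info("dropped %d equilibrated spectra (timer at plateau)", len(dropped))
    burst_ids: list[str] = []
    for b in burst_of:
        if b not in burst_ids:
            burst_ids.append(b)
    usable_per_burst = {b: burst_of.count(b) for b in burst_ids}
    low = [b for b, n in usable_per_burst.items() if n < options.min_spectra_per_burst]
    if low:
        logger.warning(
            "bursts below the %d usable-spectra floor: %s",
            options.min_spectra_per_burst,
            low,
        )
    idx = {b: np.array([i for i, bb in enumerate(burst_of) if bb == b]) for b in burst_ids}
    return (
        burst_ids,
        idx,
        np.asarray(keep_ft, dtype=float),
        np.asarray(keep_fa, dtype=float),
        meta,
        dropped,
    )


def _fit(
    dataset: KineticDataset,
    model: str,
    options: FitOptions,
    irreversible: bool,
) -> FitResult:
    if model not in ("shared_alpha", "per_burst_alpha"):
        raise ValueError(f"model must be shared_alpha|per_burst_alpha, got {model!r}")
    if irreversible and dataset.analyte.ligand_total <= 0:
        raise ValueError("kon is unidentifiable with zero ligand")
    burst_ids, idx, f_timer, f_analyte, meta, dropped = _prepare(dataset, options)
    n = f_timer.size
    if options.fixed_alpha is not None:
        n_alpha = 0
    else:
        n_alpha = 1 if model == "shared_alpha" else len(burst_ids)
    n_kin = 1 if irreversible else 2
    n_params = n_kin + n_alpha
    if n <= n_params:
        raise ValueError(
            f"underdetermined fit: {n} usable spectra for {n_params} parameters"
        )

    timer, analyte = dataset.timer, dataset.analyte
    pa_tot, la_tot = analyte.protein_total, analyte.ligand_total

    def unpack(x):
        kon = 10.0 ** x[0]
        koff = 0.0 if irreversible else 10.0 ** x[1]
        alphas = x[n_kin:]
        return kon, koff, alphas

    def alpha_of(alphas, j):
        if options.fixed_alpha is not None:
            return options.fixed_alpha
        return alphas[0] if model == "shared_alpha" else alphas[j]

    def residuals(x):
        kon, koff, alphas = unpack(x)
        rates = RateConstants(kon=kon, koff=koff)
        res = np.empty(n)
        for j, b in enumerate(burst_ids):
            a = alpha_of(alphas, j)
            curve = build_curve(timer, a)
            sel = idx[b]
            # clamp just under the trial-alpha plateau; spectra were
            # pre-screened against the reference curve
            cmax = curve.plateau_fraction * (1.0 - 1e-9)
            ft = np.minimum(f_timer[sel], cmax)
            t = time_to_complex(curve.system, ft * curve.system.p_total)
            p0a = a * pa_tot
            l0a = (1.0 - a) * la_tot
            sys_a = BindingSystem(p_total=p0a, l_total=l0a, rates=rates)
            f_model = closed_form_complex(sys_a, t) / p0a
            res[sel] = f_analyte[sel] - f_model
        return res

    lower = [_LOG10_KON_BOUNDS[0]] + ([] if irreversible else [_LOG10_KOFF_BOUNDS[0]])
    upper = [_LOG10_KON_BOUNDS[1]] + ([] if irreversible else [_LOG10_KOFF_BOUNDS[1]])
    lower += [_ALPHA_BOUNDS[0]] * n_alpha
    upper += [_ALPHA_BOUNDS[1]] * n_alpha

    starts = []
    for kon0 in _KON_STARTS:
        if irreversible:
            starts.append([np.log10(kon0)] + [0.5] * n_alpha)
        else:
            for koff0 in _KOFF_STARTS:
                starts.append([np.log10(kon0), np.log10(koff0)] + [0.5] * n_alpha)

    best = None
    for x0 in starts:
        sol = least_squares(
            residuals,
            x0,
            bounds=(lower, upper),
            method="trf",
            xtol=options.xtol,
            ftol=options.ftol,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None

    kon, koff, alphas = unpack(best.x)
    rss = float(2.0 * best.cost)
    res_vec = best.fun

    # covariance from the Jacobian at the optimum (delta method for the
    # log-parameterized rate constants); headline uncertainties come from
    # replicate SD, this is the per-fit estimate
    stderr: dict[str, float] = {}
    dof = n - n_params
    if dof > 0:
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.pinv(jtj) * (rss / dof)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
            ln10 = np.log(10.0)
            stderr["kon"] = float(kon * ln10 * se[0])
            if not irreversible:
                stderr["koff"] = float(koff * ln10 * se[1])
            if options.fixed_alpha is None:
                for j, b in enumerate(burst_ids):
                    k = 0 if model == "shared_alpha" else j
                    stderr[f"alpha[{b}]"] = float(se[n_kin + k])
        except np.linalg.LinAlgError:  # pragma: no cover
            logger.warning("singular Jacobian; uncertainties unavailable")

    alpha_map = {b: float(alpha_of(alphas, j)) for j, b in enumerate(burst_ids)}
    rates = RateConstants(kon=kon, koff=koff)

    rows = []
    for j, b in enumerate(burst_ids):
        a = alpha_map[b]
        curve = build_curve(timer, a)
        sel = idx[b]
        cmax = curve.plateau_fraction * (1.0 - 1e-9)
        ft = np.minimum(f_timer[sel], cmax)
        t = time_to_complex(curve.system, ft * curve.system.p_total)
        for k, i in enumerate(sel):
            emitter, burst, scan = meta[i]
            rows.append(
                {
                    "emitter_id": emitter,
                    "burst_id": burst,
                    "scan_index": scan,
                    "time_s": float(t[k]),
                    "f_analyte_obs": float(f_analyte[i]),
                    "f_analyte_model": float(f_analyte[i] - res_vec[i]),
                    "residual": float(res_vec[i]),
                }
            )
    table = pd.DataFrame(rows)

    model_name = ("irreversible_" if irreversible else "") + model
    if not best.success:
        logger.warning("fit did not report convergence: %s", best.message)
    return FitResult(
        rates=rates,
        alphas=alpha_map,
        rss=rss,
        n_points=n,
        n_params=n_params,
        model=model_name,
        stderr=stderr,
        table=table,
        dropped=dropped,
        success=bool(best.success),
        message=str(best.message),
    )


def fit_global(
    dataset: KineticDataset,
    model: str = "per_burst_alpha",
    options: FitOptions | None = None,
) -> FitResult:
    """Fit kon and koff globally across bursts (reversible analyte).

    ``model`` selects a single shared mixing factor (``shared_alpha``)
    or one per burst (``per_burst_alpha``). Deterministic: a fixed grid
    of six starting points (kon in {1e4, 1e5, 1e6} x koff in
    {1e-3, 1e-1}, alpha = 0.5) is tried and the lowest-RSS solution
    kept.
    """
    return _fit(dataset, model, options or FitOptions(), irreversible=False)


def fit_irreversible(
    dataset: KineticDataset,
    model: str = "per_burst_alpha",
    options: FitOptions | None = None,
) -> FitResult:
    """Fit kon with koff fixed at zero (covalent / unmeasurably slow off-rate).

    Native MS cannot separate a reversible encounter complex from its
    covalent product (same mass), so only the rate-limiting irreversible
    step is modeled.
    """
    if dataset.analyte.reversible:
        logger.warning("analyte flagged reversible; fitting irreversible model anyway")
    return _fit(dataset, model, options or FitOptions(), irreversible=True)


def f_test(reduced: FitResult, full: FitResult) -> tuple[float, float]:
    """Extra-sum-of-squares F-test between nested least-squares fits.

    F = ((RSS_r - RSS_f) / (p_f - p_r)) / (RSS_f / (n - p_f)), with the
    p-value from F(p_f - p_r, n - p_f). F is clamped at 0 when the full
    model fails to reduce the RSS (p-value 1).
    """
    if reduced.n_points != full.n_points:
        raise ValueError("models were not fitted to the same spectra")
    dp = full.n_params - reduced.n_params
    if dp <= 0:
        raise ValueError("full model must have more parameters than reduced")
    dfd = full.n_points - full.n_params
    if dfd <= 0:
        raise ValueError("no residual degrees of freedom for the full model")
    num = max(reduced.rss - full.rss, 0.0) / dp
    den = full.rss / dfd
    f_stat = num / den if den > 0 else (0.0 if num == 0.0 else np.inf)
    p_value = float(stats.f.sf(f_stat, dp, dfd))
    return float(f_stat), p_value


def flag_outlier_bursts(
    result: FitResult, threshold: float = 3.0
) -> dict[str, bool]:
    """Advisory per-burst outlier flags from residual magnitudes.

    A burst is flagged when its RMS residual exceeds ``threshold`` times
    the pooled RMS of the *other* bursts (leave-one-out pooling — a
    corrupted burst would otherwise inflate the very baseline it is
    compared against). Refitting after exclusion is an explicit user
    action; flags never silently alter the fit.
    """
    flags: dict[str, bool] = {}
    tbl = result.table
    for b in tbl["burst_id"].unique():
        own = tbl.loc[tbl["burst_id"] == b, "residual"].to_numpy()
        rest = tbl.loc[tbl["burst_id"] != b, "residual"].to_numpy()
        if rest.size == 0:
            flags[str(b)] = False
            continue
        rms_own = float(np.sqrt(np.mean(own**2)))
        rms_rest = float(np.sqrt(np.mean(rest**2)))
        if rms_rest == 0.0:
            flags[str(b)] = rms_own > 0.0 and np.isfinite(threshold)
        else:
            flags[str(b)] = rms_own > threshold * rms_rest
    return flags


def summarize_replicates(results: Mapping[str, FitResult]) -> ReplicateSummary:
    """Mean +/- sample SD of kon, koff and K_D across emitter replicates.

    K_D is koff/kon within each replicate before averaging. A single
    replicate yields means with the SD flagged undefined (NaN).
    """
    if not results:
        raise ValueError("no replicates")
    kons = np.array([r.rates.kon for r in results.values()])
    koffs = np.array([r.rates.koff for r in results.values()])
    kds = koffs / kons
    n = kons.size
    sd_defined = n >= 2
    if not sd_defined:
        logger.warning("single replicate: standard deviation undefined")

    def sd(v):
        return float(np.std(v, ddof=1)) if sd_defined else float("nan")

    return ReplicateSummary(
        n_replicates=n,
        kon_mean=float(kons.mean()),
        kon_sd=sd(kons),
        koff_mean=float(koffs.mean()),
        koff_sd=sd(koffs),
        kd_mean=float(kds.mean()),
        kd_sd=sd(kds),
        sd_defined=sd_defined,
        per_replicate=dict(results),
    )
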