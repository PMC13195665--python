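import numpy as np
import pytest

from thetakinetics import (
    AnalyteSystem,
    KineticDataset,
    RateConstants,
    SimulationConfig,
    SpectrumRecord,
    TimerSystem,
    f_test,
    fit_global,
    fit_irreversible,
    flag_outlier_bursts,
    simulate_dataset,
    summarize_replicates,
)


def _noise_free(truth, alpha=(0.4, 0.5, 0.6), seed=11, **kw):
    cfg = SimulationConfig(
        truth=truth, seed=seed, noise_sigma=0.0, n_bursts=len(alpha), alpha=list(alpha), **kw
    )
    return simulate_dataset(cfg)


class TestGlobalFit:
    def test_noise_free_recovery_shared_alpha(self, gfp_nb15_rates):
        dataset, _ = _noise_free(gfp_nb15_rates, alpha=(0.5, 0.5, 0.5))
        res = fit_global(dataset, "shared_alpha")
        assert res.rates.kon == pytest.approx(1.3e5, rel=1e-6)
        assert res.rates.koff == pytest.approx(1.3e-2, rel=1e-6)
        assert res.n_params == 3

    def test_noise_free_recovery_per_burst_alpha(self, gfp_nb15_rates):
        dataset, truth = _noise_free(gfp_nb15_rates)
        res = fit_global(dataset, "per_burst_alpha")
        assert res.rates.kon == pytest.approx(1.3e5, rel=1e-5)
        assert res.rates.koff == pytest.approx(1.3e-2, rel=1e-5)
        true_alphas = truth.groupby("burst_id")["alpha"].first().to_dict()
        for burst, a_true in true_alphas.items():
            assert res.alphas[burst] == pytest.approx(a_true, abs=1e-6)
        assert res.n_params == 2 + len(true_alphas)

    def test_per_burst_never_worse_than_shared(self, small_dataset):
        dataset, _ = small_dataset
        shared = fit_global(dataset, "shared_alpha")
        per_burst = fit_global(dataset, "per_burst_alpha")
        assert per_burst.rss <= shared.rss + 1e-12
        assert shared.n_points == per_burst.n_points

    def test_equilibrated_spectra_excluded(self, gfp_nb15_rates, fig_timer):
        # spectra with the timer at its plateau carry no time information
        cfg = SimulationConfig(
            truth=gfp_nb15_rates, seed=5, noise_sigma=0.0, time_bounds=(1.0, 200.0)
        )
        dataset, _ = simulate_dataset(cfg)
        res = fit_global(dataset, "shared_alpha")
        assert len(res.dropped) > 0
        assert res.n_points + len(res.dropped) == len(dataset.records)

    def test_underdetermined_dataset_rejected(self, gfp_nb15_rates):
        cfg = SimulationConfig(
            truth=gfp_nb15_rates, seed=1, noise_sigma=0.0, n_bursts=1, spectra_per_burst=3
        )
        dataset, _ = simulate_dataset(cfg)
        with pytest.raises(ValueError, match="underdetermined"):
            fit_global(dataset, "per_burst_alpha")

    def test_timer_independence_noise_free(self, gfp_nb15_rates):
        # recovered analyte kinetics must not depend on which valid timer
        # assigned the times, as long as spectra sit in its window
        fast = TimerSystem(1e-6, 2e-6, RateConstants(3.6e5, 9.4e-6))
        slow = TimerSystem(1e-6, 2e-6, RateConstants(1.2e5, 0.0))
        results = []
        for timer in (fast, slow):
            cfg = SimulationConfig(
                truth=gfp_nb15_rates,
                timer=timer,
                seed=3,
                noise_sigma=0.0,
                time_bounds=(0.5, 12.0),
            )
            dataset, _ = simulate_dataset(cfg)
            results.append(fit_global(dataset, "per_burst_alpha"))
        assert results[0].rates.kon == pytest.approx(results[1].rates.kon, rel=1e-4)
        assert results[0].rates.koff == pytest.approx(results[1].rates.koff, rel=1e-4)

    def test_fusion_mode_fits_like_nonfusion(self, gfp_nb15_rates):
        ds_fusion, _ = _noise_free(gfp_nb15_rates, mode="fusion")
        res = fit_global(ds_fusion, "per_burst_alpha")
        assert res.rates.kon == pytest.approx(1.3e5, rel=1e-5)


class TestIrreversibleFit:
    def test_noise_free_recovery(self):
        truth = RateConstants(8e5, 0.0)
        dataset, _ = _noise_free(truth, protein_total=4e-6, ligand_total=4e-6)
        res = fit_irreversible(dataset, "per_burst_alpha")
        assert res.rates.kon == pytest.approx(8e5, rel=1e-5)
        assert res.rates.koff == 0.0
        assert res.n_params == 1 + 3

    def test_reversible_data_shows_late_overshoot(self, gfp_nb15_rates):
        # without dissociation the model saturates too high, so late-time
        # residuals (observed - model) trend negative; alpha is held at
        # its known value — left free, it can disguise the missing
        # off-rate by shrinking the apparent ligand excess
        from thetakinetics import FitOptions

        dataset, _ = _noise_free(gfp_nb15_rates, alpha=(0.5, 0.5, 0.5))
        res = fit_irreversible(
            dataset, "shared_alpha", FitOptions(fixed_alpha=0.5)
        )
        tbl = res.table
        late = tbl[tbl["time_s"] > tbl["time_s"].median()]
        assert late["residual"].mean() < 0

    def test_zero_ligand_unidentifiable(self, fig_timer):
        records = [
            SpectrumRecord("E1", "B1", s, {
                "timer_apo": 60.0, "timer_bound": 40.0,
                "analyte_apo": 100.0, "analyte_bound": 0.0,
            })
            for s in range(5)
        ]
        dataset = KineticDataset(
            records=records,
            timer=fig_timer,
            analyte=AnalyteSystem(1e-6, 0.0, reversible=False),
        )
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_irreversible(dataset)


class TestFTest:
    def test_identical_models_give_null_result(self, small_dataset):
        dataset, _ = small_dataset
        res = fit_global(dataset, "shared_alpha")
        f_stat, p = f_test(res, _more_params(res))
        assert f_stat == 0.0 and p == 1.0

    def test_stated_formula_arithmetic(self):
        # RSS 2.0 -> 1.0, params 3 -> 7, n = 57: F = (1/4)/(1/50) = 12.5
        reduced = _stub(rss=2.0, n_points=57, n_params=3)
        full = _stub(rss=1.0, n_points=57, n_params=7)
        f_stat, p = f_test(reduced, full)
        assert f_stat == pytest.approx(12.5)
        assert 0 < p < 1e-6

    def test_full_model_with_higher_rss_clamped(self):
        reduced = _stub(rss=1.0, n_points=57, n_params=3)
        full = _stub(rss=1.1, n_points=57, n_params=7)
        f_stat, p = f_test(reduced, full)
        assert f_stat == 0.0 and p == 1.0

    def test_mismatched_datasets_rejected(self):
        with pytest.raises(ValueError):
            f_test(_stub(rss=1, n_points=50, n_params=3), _stub(rss=1, n_points=57, n_params=7))

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            f_test(_stub(rss=2, n_points=57, n_params=7), _stub(rss=1, n_points=57, n_params=3))

    def test_saturated_model_rejected(self):
        with pytest.raises(ValueError):
            f_test(_stub(rss=2, n_points=7, n_params=3), _stub(rss=1, n_points=7, n_params=7))


class TestOutlierFlagging:
    def test_noise_free_bursts_unflagged(self, gfp_nb15_rates):
        dataset, _ = _noise_free(gfp_nb15_rates)
        res = fit_global(dataset, "per_burst_alpha")
        assert not any(flag_outlier_bursts(res).values())

    def test_corrupted_burst_flagged(self, gfp_nb15_rates):
        dataset, _ = _noise_free(gfp_nb15_rates, alpha=(0.5, 0.5, 0.5, 0.5, 0.5), seed=2)
        rng = np.random.default_rng(0)
        records = []
        for rec in dataset.records:
            if rec.burst_id == "B3":
                ab = dict(rec.abundances)
                # scramble the analyte margin of one burst
                tot = ab["analyte_apo"] + ab["analyte_bound"]
                frac = rng.uniform(0, 1)
                ab["analyte_apo"], ab["analyte_bound"] = (1 - frac) * tot, frac * tot
                rec = SpectrumRecord(rec.emitter_id, rec.burst_id, rec.scan_index, ab)
            records.append(rec)
        corrupted = KineticDataset(
            records=records, timer=dataset.timer, analyte=dataset.analyte, mode=dataset.mode
        )
        res = fit_global(corrupted, "shared_alpha")
        flags = flag_outlier_bursts(res)
        assert flags["B3"]
        assert sum(flags.values()) == 1

    def test_infinite_threshold_flags_nothing(self, small_dataset):
        dataset, _ = small_dataset
        res = fit_global(dataset, "shared_alpha")
        assert not any(flag_outlier_bursts(res, threshold=np.inf).values())


class TestReplicateSummary:
    def test_identical_replicates_have_zero_sd(self, gfp_nb15_rates):
        r = _stub(rss=1.0, n_points=50, n_params=3, rates=gfp_nb15_rates)
        summary = summarize_replicates({"E1": r, "E2": r})
        assert summary.kon_sd == 0.0 and summary.koff_sd == 0.0 and summary.kd_sd == 0.0

    def test_mean_and_sample_sd(self):
        reps = {
            f"E{i}": _stub(rss=1, n_points=50, n_params=3, rates=RateConstants(k, 1.3e-2))
            for i, k in enumerate((1.0e5, 1.2e5, 1.4e5))
        }
        summary = summarize_replicates(reps)
        assert summary.kon_mean == pytest.approx(1.2e5)
        assert summary.kon_sd == pytest.approx(0.2e5)

    def test_kd_is_mean_of_ratios_not_ratio_of_means(self):
        # counterexample where the two orders of operations differ
        reps = {
            "E1": _stub(rss=1, n_points=50, n_params=3, rates=RateConstants(1e5, 1e-2)),
            "E2": _stub(rss=1, n_points=50, n_params=3, rates=RateConstants(4e5, 1e-3)),
        }
        summary = summarize_replicates(reps)
        mean_of_ratios = (1e-2 / 1e5 + 1e-3 / 4e5) / 2
        ratio_of_means = ((1e-2 + 1e-3) / 2) / ((1e5 + 4e5) / 2)
        assert summary.kd_mean == pytest.approx(mean_of_ratios, rel=1e-12)
        assert abs(summary.kd_mean - ratio_of_means) / mean_of_ratios > 0.1

    def test_single_replicate_sd_flagged_undefined(self, gfp_nb15_rates):
        summary = summarize_replicates(
            {"E1": _stub(rss=1, n_points=50, n_params=3, rates=gfp_nb15_rates)}
        )
        assert not summary.sd_defined
        assert np.isnan(summary.kon_sd)


def _stub(rss, n_points, n_params, rates=None):
    """Minimal FitResult for arithmetic-level tests."""
    import pandas as pd

    from thetakinetics.fitting import FitResult

    return FitResult(
        rates=rates or RateConstants(1e5, 1e-2),
        alphas={"B1": 0.5},
        rss=float(rss),
        n_points=n_points,
        n_params=n_params,
        model="shared_alpha",
        stderr={},
        table=pd.DataFrame(),
        dropped=[],
        success=True,
        message="",
    )


def _more_params(res):
    """Copy of a fit result posing as a larger nested model with equal RSS."""
    from dataclasses import replace

    return replace(res, n_params=res.n_params + 4)
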