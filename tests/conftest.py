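import pytest

from thetakinetics import RateConstants, SimulationConfig, TimerSystem, simulate_dataset


@pytest.fixture
def fig_timer() -> TimerSystem:
    """The illustrative timer pair: 1 uM epitope, 2 uM nanobody,
    kon 3.6e5 M^-1 s^-1, koff 9.4e-6 s^-1 (near-irreversible)."""
    return TimerSystem(
        epitope_total=1e-6, nb_total=2e-6, rates=RateConstants(3.6e5, 9.4e-6)
    )


@pytest.fixture
def gfp_nb15_rates() -> RateConstants:
    """GFP-Nb15 benchmark rate constants (kon 1.3e5, koff 1.3e-2)."""
    return RateConstants(kon=1.3e5, koff=1.3e-2)


@pytest.fixture
def small_dataset(gfp_nb15_rates):
    """One noisy synthetic emitter at the benchmark regime (seed 7)."""
    cfg = SimulationConfig(truth=gfp_nb15_rates, seed=7)
    return simulate_dataset(cfg)
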