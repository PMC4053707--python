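"""Generator properties: conservation, reproducibility, regime behaviour."""

import numpy as np
import pytest

from mcferm import cod, metrics
from mcferm import simulate as sim
from mcferm.metrics import FeedEvent, FeedSchedule, SteadyStateWindow


def _steady_cstr_config(seed=0, **overrides):
    base = dict(
        noise_cv=0.0,
        hrt_schedule=((0.0, 8.9),),
        ph_schedule=((0.0, 7.0),),
        horizon_d=60.0,
        initial="steady",
    )
    base.update(overrides)
    return sim.nominal_cstr_config(seed=seed, **base)


# ------------------------------------------------------- reproducibility --
def test_identical_config_and_seed_reproduce_byte_for_byte():
    a_truth, a_series = sim.simulate_cstr(sim.nominal_cstr_config(seed=7))
    b_truth, b_series = sim.simulate_cstr(sim.nominal_cstr_config(seed=7))
    assert a_series.to_tidy_csv() == b_series.to_tidy_csv()
    assert a_truth.frame.equals(b_truth.frame)


def test_different_seeds_differ_in_observations_not_truth():
    a_truth, a_series = sim.simulate_cstr(sim.nominal_cstr_config(seed=1))
    b_truth, b_series = sim.simulate_cstr(sim.nominal_cstr_config(seed=2))
    assert a_truth.frame.equals(b_truth.frame)  # noise is observation-only
    assert not a_series.data.equals(b_series.data)


# ---------------------------------------------------- COD conservation --
@pytest.mark.parametrize("mode", ["cstr", "fed-batch", "batch"])
def test_latent_state_conserves_cod_at_every_step(mode):
    factory = {
        "cstr": sim.nominal_cstr_config,
        "fed-batch": sim.nominal_fedbatch_config,
        "batch": sim.nominal_batch_config,
    }[mode]
    runner = {
        "cstr": sim.simulate_cstr,
        "fed-batch": sim.simulate_fedbatch,
        "batch": sim.simulate_batch,
    }[mode]
    truth, _ = runner(factory(seed=0))
    assert truth.max_cod_residual <= 1e-6


# --------------------------------------------------- steady-state CSTR --
def test_nominal_steady_state_matches_design_point():
    """At HRT 8.9 d and 9 g/L glucose the latent steady state sits at
    ~4.5 g/L acetate, >90% purity, P_H2 at the methanogen threshold."""
    truth, series = sim.simulate_cstr(_steady_cstr_config())
    final = truth.frame.iloc[-1]
    assert 4.0 <= final["acetate"] <= 5.0
    assert final["p_h2"] * 101325 <= 60.0 * 1.05
    assert metrics.purity(series.liquid_at(55.0)) >= 0.90
    assert final["glucose"] < 0.1


def test_washout_with_zero_influent_glucose():
    cfg = _steady_cstr_config(influent_glucose=0.0, initial="inoculum",
                              horizon_d=110.0)
    truth, _ = sim.simulate_cstr(cfg)
    final = truth.frame.iloc[-1]
    for m in ("glucose", "acetate", "ethanol", "biomass"):
        assert final[m] < 1e-3


def test_low_hrt_with_slow_methanogens_accumulates_h2_and_ethanol():
    """The start-up regime: at HRT 2.2 d a thin methanogen population
    cannot keep up, so H2 accumulates and the flux shifts to ethanol."""
    cfg = sim.nominal_cstr_config(
        seed=0, noise_cv=0.0, hrt_schedule=((0.0, 2.2),),
        ph_schedule=((0.0, 7.5),), horizon_d=10.0,
    )
    truth, _ = sim.simulate_cstr(cfg)
    frame = truth.frame
    assert frame["p_h2"].max() > 0.02
    assert frame["ethanol"].iloc[-1] > 0.5


def test_ethanol_never_decreases_when_h2_threshold_is_raised():
    finals = []
    for thr in (60.0, 2000.0, 8000.0, 20000.0):
        truth, _ = sim.simulate_cstr(
            _steady_cstr_config(h2_threshold_pa=thr, horizon_d=50.0)
        )
        finals.append(float(truth.frame["ethanol"].iloc[-1]))
    assert all(b >= a - 1e-12 for a, b in zip(finals, finals[1:]))


def test_noise_free_cstr_recovery_under_one_percent():
    truth, series = sim.simulate_cstr(_steady_cstr_config())
    est = metrics.cstr_yields(series, SteadyStateWindow(35, 60), 9.0)
    real = truth.realized_yields(35, 60)
    for m in ("acetate", "propionate", "butyrate", "methane", "biomass"):
        assert est[m] == pytest.approx(real[m], rel=0.01)
    assert cod.cod_balance(est) == pytest.approx(100.0, abs=0.5)


def test_noisy_cstr_recovery_within_five_percent_over_seeds():
    worst = 0.0
    for seed in range(20):
        truth, series = sim.simulate_cstr(_steady_cstr_config(seed=seed, noise_cv=0.05))
        est = metrics.cstr_yields(series, SteadyStateWindow(35, 60), 9.0)
        real = truth.realized_yields(35, 60)
        for m in ("acetate", "methane", "biomass"):
            worst = max(worst, abs(est[m] - real[m]) / real[m])
    assert worst < 0.05


# ------------------------------------------------------------ fed-batch --
def test_fedbatch_plateaus_near_inhibition_threshold_then_shifts_to_ethanol():
    cfg = sim.nominal_fedbatch_config(seed=2)
    truth, _ = sim.simulate_fedbatch(cfg)
    frame = truth.frame
    peak = frame["acetate"].max()
    assert cfg.acetate_inhibition_g_l - 2.0 <= peak <= cfg.acetate_inhibition_g_l + 4.0
    at_plateau = frame[frame["acetate"] >= cfg.acetate_inhibition_g_l].iloc[0]
    after = frame[frame["time_d"] >= at_plateau["time_d"] + 2.0].iloc[0]
    assert after["ethanol"] > at_plateau["ethanol"] + 0.5  # shift engages
    assert frame["p_h2"].iloc[-1] > 0.01  # hydrogen re-accumulates
    assert frame["glucose"].iloc[-1] > 4.0  # substrate piles up once inhibited


def test_no_feeds_after_start_approaches_single_batch_asymptote():
    feeds = FeedSchedule([FeedEvent(0.0, 6.0)])
    cfg = sim.nominal_fedbatch_config(seed=0, noise_cv=0.0, feed_schedule=feeds,
                                      horizon_d=8.0)
    truth, _ = sim.simulate_fedbatch(cfg)
    frame = truth.frame
    expected = 6.0 / 180.156 * 1.5 * 60.052  # all glucose at the true yield
    assert frame["acetate"].iloc[-1] == pytest.approx(expected, rel=0.02)
    late = frame[frame["time_d"] > 4.0]["acetate"]
    assert late.max() - late.min() < 0.01  # flat asymptote, no plateau shift


def test_noise_free_fedbatch_recovers_configured_yield_exactly():
    feeds = FeedSchedule([FeedEvent(t, 2.0) for t in (1.0, 2.0, 3.0, 4.0)])
    cfg = sim.nominal_fedbatch_config(
        seed=0, noise_cv=0.0, feed_schedule=feeds, horizon_d=10.0,
        acetate_inhibition_g_l=100.0,
    )
    truth, series = sim.simulate_fedbatch(cfg)
    res = metrics.fedbatch_yields(series, feeds, (0.5, 9.5))
    assert res.yields["acetate"] == pytest.approx(cfg.true_yields["acetate"], abs=1e-6)


# ---------------------------------------------------------------- batch --
def test_batch_hold_of_effluent_is_stable():
    """No aceticlastic activity: the effluent composition holds for 14 days
    (tolerance sized for the 5% CV measurement noise)."""
    _, series = sim.simulate_batch(sim.nominal_batch_config(seed=3))
    report = metrics.batch_stability(series, tolerance_g_l=1.0)
    assert report.stable
    assert report.p_ch4_increase < 0.05


def test_active_aceticlastic_consumer_destabilizes_the_batch():
    _, series = sim.simulate_batch(
        sim.nominal_batch_config(seed=3, aceticlastic_rate_g_l_d=0.3)
    )
    report = metrics.batch_stability(series, tolerance_g_l=1.0)
    assert not report.stable
    assert report.deltas["acetate"] > 1.0
    assert report.p_ch4_increase > 0.05


# ----------------------------------------------------------- validation --
def test_config_validation():
    with pytest.raises(ValueError):
        sim.GeneratorConfig(mode="chemostat")
    with pytest.raises(ValueError):
        sim.GeneratorConfig(h2_threshold_pa=0.0)
    with pytest.raises(ValueError):
        sim.GeneratorConfig(noise_cv=-0.1)
    with pytest.raises(ValueError, match="over-commits"):
        sim.GeneratorConfig(
            true_yields=cod.YieldTable({"acetate": 2.9, "biomass": 0.4})
        )
    with pytest.raises(ValueError):
        sim.simulate_cstr(sim.nominal_fedbatch_config())
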