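"""SSA engine: exactness, closed-form steady states, conservation, schedules."""

import numpy as np
import pytest
from scipy import stats

from circuitnoise import (
    RateSet,
    SimConfig,
    build_network,
    constant_series,
    simulate,
    simulate_schedule,
    summarize,
)
from circuitnoise.analysis import total_repressor
from circuitnoise.ssa import load_trajectory, save_trajectory


def test_zero_transcription_produces_nothing():
    net = build_network("i", rates=RateSet(kTX1=0.0))
    traj = simulate(net, SimConfig(duration=500, burn_in=0, seed=0))
    assert not traj.series("M1").any()
    assert not traj.series("P").any()


def test_unregulated_steady_state_matches_birth_death_closed_form():
    """<M1> = n_DNA * kTX1 / deg_M ~ 5.15 with Poisson statistics, and
    <P> = <M1> * kTL_P / deg_P ~ 20,700."""
    net = build_network("constitutive")
    traj = simulate(net, SimConfig(duration=16_000, burn_in=1_000, seed=42))
    m = summarize(traj, "M1")
    expected_m = 10 * 0.0017 / 0.0033
    assert m.mean == pytest.approx(expected_m, rel=0.05)
    # Poisson: Fano factor (CV^2 * mean) near 1
    assert m.noise * m.mean == pytest.approx(1.0, rel=0.1)
    p = summarize(traj, "P")
    assert p.mean == pytest.approx(expected_m * 0.67 / 1.6667e-4, rel=0.1)


def test_fully_induced_total_repressor_matches_rate_balance():
    """At saturating inducer, <R + R:I> = <M1> kTL_R / deg_R ~ 1.03e3."""
    net = build_network("iv", inducer_count=10**6)
    traj = simulate(net, SimConfig(duration=11_000, burn_in=1_000, seed=3))
    expected = (10 * 0.0017 / 0.0033) * 0.0333 / 1.6667e-4
    assert total_repressor(traj) == pytest.approx(expected, rel=0.05)


def test_event_counts_of_pure_birth_process_are_poisson():
    """Exactness oracle: a source-only reaction network accumulates counts
    that follow the analytic Poisson process (KS test over 60 runs)."""
    net = build_network("i", rates=RateSet(kTL_P=0.0, deg_M=0.0, deg_P=0.0))
    lam = 10 * 0.0017 * 60 * 500  # expected events in 500 min
    counts = np.array([
        simulate(net, SimConfig(duration=500, burn_in=0, seed=s)).series("M1")[-1]
        for s in range(60)
    ])
    p = stats.kstest(counts, lambda k: stats.poisson.cdf(k, lam)).pvalue
    assert p > 0.01


@pytest.mark.parametrize("mode", ["fast", "slow"])
def test_conservation_laws_hold_at_every_recorded_point(mode):
    net = build_network("iii", inducer_count=150, inducer_mode=mode)
    traj = simulate(net, SimConfig(duration=4_000, burn_in=0, seed=9))
    assert (traj.series("D1") + traj.series("D1R") == 10).all()
    assert (traj.series("D2") + traj.series("D2R") == 10).all()
    assert (traj.counts >= 0).all()
    if mode == "slow":
        assert (traj.series("I") + traj.series("RI") == 150).all()
    else:
        assert (traj.series("I") == 150).all()


def test_same_seed_is_bit_identical_and_seeds_differ():
    net = build_network("iv", inducer_count=100)
    cfg = SimConfig(duration=2_000, burn_in=0, seed=7)
    t1 = simulate(net, cfg)
    t2 = simulate(net, cfg)
    assert np.array_equal(t1.counts, t2.counts)
    t3 = simulate(net, SimConfig(duration=2_000, burn_in=0, seed=8))
    assert not np.array_equal(t1.counts, t3.counts)


def test_extrinsic_factor_modulates_only_translation():
    """Halving the extrinsic factor halves protein output but leaves the
    mRNA birth-death statistics untouched."""
    net = build_network("constitutive")
    cfg = SimConfig(duration=16_000, burn_in=1_000, seed=11)
    lo = simulate(net, cfg, 0.5 * np.ones(cfg.n_intervals))
    hi = simulate(net, cfg, np.ones(cfg.n_intervals))
    p_lo, p_hi = summarize(lo, "P").mean, summarize(hi, "P").mean
    assert p_lo / p_hi == pytest.approx(0.5, rel=0.1)
    assert summarize(lo, "M1").mean == pytest.approx(summarize(hi, "M1").mean, rel=0.1)


def test_extrinsic_series_too_short_raises():
    net = build_network("i")
    cfg = SimConfig(duration=1_000, burn_in=0, seed=0)
    with pytest.raises(ValueError, match="too short"):
        simulate(net, cfg, constant_series(10))


def test_single_step_schedule_equals_plain_simulate():
    net = build_network("iv", inducer_count=500)
    cfg = SimConfig(duration=500, burn_in=0, seed=5)
    t1 = simulate(net, cfg)
    t2 = simulate_schedule(net, cfg, [(0, 500)])
    assert np.array_equal(t1.counts, t2.counts)


def test_schedule_resets_free_inducer_level():
    net = build_network("iv", inducer_count=0)
    cfg = SimConfig(duration=300, burn_in=0, seed=5)
    traj = simulate_schedule(net, cfg, [(0, 0), (100, 2000), (200, 0)])
    i = traj.series("I")
    t = traj.times
    assert (i[(t >= 0) & (t < 100)] == 0).all()
    assert (i[(t >= 100) & (t < 200)] == 2000).all()
    assert (i[t >= 200] == 0).all()


@pytest.mark.parametrize(
    "schedule,match,mode",
    [
        ([(0, 10), (50, 20), (50, 30)], "strictly increasing", "fast"),
        ([(10, 5)], "start at time 0", "fast"),
        ([(0, 10), (600, 5)], "within the duration", "fast"),
        ([(0, 10), (50.5, 5)], "recording grid", "fast"),
        ([(0, 10), (50, 100)], "slow mode", "slow"),
        ([], "at least one step", "fast"),
    ],
)
def test_invalid_schedules_rejected(schedule, match, mode):
    net = build_network("iv", inducer_count=10, inducer_mode=mode)
    with pytest.raises(ValueError, match=match):
        simulate_schedule(net, SimConfig(duration=500, burn_in=0, seed=0), schedule)


def test_trajectory_tsv_round_trip(tmp_path):
    net = build_network("ii", inducer_count=50)
    cfg = SimConfig(duration=100, burn_in=0, seed=1)
    traj = simulate(net, cfg, constant_series(100))
    path = tmp_path / "traj.tsv"
    save_trajectory(traj, path)
    again = load_trajectory(path)
    assert np.array_equal(again.counts, traj.counts)
    assert np.allclose(again.times, traj.times)
    assert np.allclose(again.factors, traj.factors)
    assert again.network == traj.network
    assert again.config == traj.config
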