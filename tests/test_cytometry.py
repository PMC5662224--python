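"""Scatter gating and background-convolved log-normal fitting."""

import numpy as np
import pandas as pd
import pytest

from circuitnoise import (
    CytometryGroundTruth,
    GateSpec,
    NonIdentifiableError,
    SimConfig,
    bootstrap_fit,
    build_network,
    find_scatter_peak,
    fit_convolution,
    gate_events,
    moment_estimates,
    simulate,
    summarize,
    synth_cytometry,
)
from circuitnoise.synth import lognormal_params


def _cluster(rng, n, f0, s0, spread=0.05):
    return pd.DataFrame({
        "FSCA": f0 * np.exp(spread * rng.standard_normal(n)),
        "SSCH": s0 * np.exp(spread * rng.standard_normal(n)),
        "FL1A": np.full(n, 200.0),
    })


def test_scatter_peak_finds_tight_cluster():
    rng = np.random.default_rng(0)
    peak = find_scatter_peak(_cluster(rng, 20_000, 1e4, 1e3))
    assert peak[0] == pytest.approx(1e4, rel=0.15)
    assert peak[1] == pytest.approx(1e3, rel=0.15)


def test_scatter_peak_prefers_larger_cluster():
    rng = np.random.default_rng(1)
    events = pd.concat([_cluster(rng, 30_000, 1e4, 1e3),
                        _cluster(rng, 10_000, 1e3, 1e2)], ignore_index=True)
    peak = find_scatter_peak(events)
    assert peak[0] == pytest.approx(1e4, rel=0.2)


def test_scatter_peak_rejects_empty_and_warns_when_sparse():
    with pytest.raises(ValueError, match="empty"):
        find_scatter_peak(pd.DataFrame(columns=["FSCA", "SSCH", "FL1A"]))
    with pytest.warns(UserWarning, match="gateable"):
        find_scatter_peak(_cluster(np.random.default_rng(2), 200, 1e4, 1e3))


def test_gate_keeps_peak_and_excludes_boundary():
    gate = GateSpec(1e4, 1e3, 0.25)
    at_peak = pd.DataFrame({"FSCA": [1e4], "SSCH": [1e3], "FL1A": [1.0]})
    assert len(gate_events(at_peak, gate)) == 1
    # squared normalized radius exactly at the threshold: strict inequality
    boundary = pd.DataFrame({"FSCA": [1e4 * 1.5], "SSCH": [1e3], "FL1A": [1.0]})
    assert len(gate_events(boundary, gate)) == 0


def test_gate_is_idempotent_and_recovers_debris_fraction():
    truth = CytometryGroundTruth(log_mean=6.0, log_sd=0.3, n_events=30_000, seed=3)
    events = synth_cytometry(truth)
    gated = gate_events(events, truth.gate())
    frac = len(gated) / len(events)
    assert frac == pytest.approx(1.0 / 3.0, abs=0.02)
    again = gate_events(gated, truth.gate())
    pd.testing.assert_frame_equal(again, gated)


def test_convolution_fit_constant_background_recovery():
    """Constant background reduces to a shifted log-normal; parameters are
    recovered to well within 3% at n = 30,000."""
    mu, sd = lognormal_params(500.0, 0.05)
    rng = np.random.default_rng(7)
    signal = 191.0 + rng.lognormal(mu, sd, 30_000)
    fit = fit_convolution(signal, np.full(2_000, 191.0))
    assert fit.log_mean == pytest.approx(mu, rel=0.03)
    assert fit.log_sd == pytest.approx(sd, rel=0.03)
    assert fit.mean == pytest.approx(500.0, rel=0.03)


def test_convolution_fit_empirical_background_recovery():
    """Broad empirical background: fitted log-normal mean within 5% and
    CV^2 within 20% at n = 30,000."""
    mu, sd = lognormal_params(500.0, 0.05)
    rng = np.random.default_rng(8)
    background = 191.0 * (1 + 0.15 * rng.standard_normal(30_000))
    signal = 191.0 * (1 + 0.15 * rng.standard_normal(30_000)) \
        + rng.lognormal(mu, sd, 30_000)
    fit = fit_convolution(signal, background)
    assert fit.mean == pytest.approx(500.0, rel=0.05)
    assert fit.noise == pytest.approx(0.05, rel=0.20)
    # moment consistency: E[signal] = E[background] + fitted expression mean
    assert signal.mean() == pytest.approx(fit.background_mean + fit.mean, rel=0.02)


def test_signal_identical_to_background_is_non_identifiable():
    rng = np.random.default_rng(9)
    bg = 191.0 * (1 + 0.1 * rng.standard_normal(10_000))
    with pytest.raises(NonIdentifiableError):
        fit_convolution(bg[:5_000], bg[5_000:])


def test_convolution_fit_recovers_simulated_expression_mean():
    """End-to-end link between the halves: protein counts from the SSA,
    mapped through a linear fluorescence scale plus constant background,
    are deconvolved back to the trajectory's own mean within 10%."""
    net = build_network("constitutive")
    traj = simulate(net, SimConfig(duration=11_000, burn_in=1_000, seed=6))
    s = summarize(traj, "P")
    signal = 191.0 + traj.series("P")[traj.times >= 1_000].astype(float)
    fit = fit_convolution(signal, np.full(1_000, 191.0))
    assert fit.mean == pytest.approx(s.mean, rel=0.10)


def test_bootstrap_single_resample_collapses_ci_and_is_deterministic():
    mu, sd = lognormal_params(300.0, 0.08)
    rng = np.random.default_rng(10)
    signal = 191.0 + rng.lognormal(mu, sd, 2_000)
    bg = np.full(500, 191.0)
    one = bootstrap_fit(signal, bg, n_boot=1, seed=0)
    assert one.ci["mean"][0] == one.ci["mean"][1]
    a = bootstrap_fit(signal, bg, n_boot=20, seed=4)
    b = bootstrap_fit(signal, bg, n_boot=20, seed=4)
    assert a.ci == b.ci
    c = bootstrap_fit(signal, bg, n_boot=20, seed=5)
    assert a.ci != c.ci


def test_moment_estimates_match_sample_moments():
    x = np.array([10.0, 20.0, 30.0])
    mean, noise = moment_estimates(x)
    assert mean == pytest.approx(20.0)
    assert noise == pytest.approx(x.var() / 400.0)
    with pytest.raises(ValueError):
        moment_estimates([])
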