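"""Noise summaries, dose-response sweeps and curve-fit operators.

The central quantity is the gene-expression noise CV^2 = variance / mean^2
of a species' copy number over the post-burn-in samples of a trajectory.
For unregulated expression without extrinsic noise the stationary noise is
approximately the intrinsic limit (1 + b) / mu, where b = kTL / deg_M is
the translational burst size (proteins made per mRNA lifetime); regulated
schemes are compared against this limit and against the extrinsic plateau.

Dose-response and noise-vs-mean sweeps rerun the simulator over an inducer
(or rate) grid with replicate seeds; CV^2 is computed per replicate and
then averaged across replicates, which reduces the bias a single slow
extrinsic drift would otherwise impose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .circuits import NetworkSpec, RateSet, build_network, default_rates, resolve_scheme
from .extrinsic import OUParams, generate_extrinsic
from .ssa import SimConfig, Trajectory, simulate

__all__ = [
    "NoiseSummary",
    "DoseResponseCurve",
    "HillFit",
    "DecayFit",
    "NoiseUndefinedError",
    "FitError",
    "summarize",
    "intrinsic_limit",
    "burst_size",
    "dose_response",
    "transcription_sweep",
    "translation_sweep",
    "default_inducer_grid",
    "fit_hill",
    "fit_exp_decay",
]


class NoiseUndefinedError(ValueError):
    """Noise cannot be computed (zero mean expression)."""


class FitError(RuntimeError):
    """A curve fit failed or the data are degenerate for it."""


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSummary:
    """Mean, variance and noise (CV^2) of one species."""

    mean: float
    variance: float
    noise: float
    n_samples: int
    species: str = "P"


def _summarize_samples(samples: np.ndarray, species: str) -> NoiseSummary:
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("no samples to summarize")
    mu = float(samples.mean())
    if mu == 0.0:
        raise NoiseUndefinedError(
            f"mean of {species} is zero; noise is undefined at this expression level"
        )
    var = float(samples.var())
    return NoiseSummary(mean=mu, variance=var, noise=var / mu**2,
                        n_samples=int(samples.size), species=species)


def summarize(trajectory: Trajectory, species: str = "P",
              burn_in: float | None = None) -> NoiseSummary:
    """Mean/variance/CV^2 over post-burn-in samples of one species.

    ``burn_in`` defaults to the trajectory's configured burn-in; samples at
    times >= burn_in are kept.
    """
    if burn_in is None:
        burn_in = trajectory.config.burn_in
    if burn_in >= trajectory.times[-1]:
        raise ValueError("trajectory is not longer than the burn-in")
    keep = trajectory.times >= burn_in
    return _summarize_samples(trajectory.series(species)[keep], species)


def total_repressor(trajectory: Trajectory, burn_in: float | None = None) -> float:
    """Time-averaged total repressor, free plus inducer-bound (R + R:I)."""
    if burn_in is None:
        burn_in = trajectory.config.burn_in
    keep = trajectory.times >= burn_in
    total = trajectory.series("R")[keep] + trajectory.series("RI")[keep]
    return float(total.mean())


def burst_size(rates: RateSet) -> float:
    """Translational burst size b = kTL_P / deg_M (~203 at the defaults)."""
    return rates.kTL_P / rates.deg_M


def intrinsic_limit(b: float, mu: float) -> float:
    """Intrinsic noise limit (1 + b) / mu for unregulated expression."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if b < 0:
        raise ValueError("b must be >= 0")
    return (1.0 + b) / mu


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

def default_inducer_grid(n_points: int = 12, low: float = 1.0,
                         high: float = 1e4) -> np.ndarray:
    """Log-spaced integer inducer counts spanning four decades."""
    grid = np.unique(np.round(np.logspace(np.log10(low), np.log10(high),
                                          n_points)).astype(int))
    return grid


@dataclass(frozen=True)
class DoseResponseCurve:
    """Replicate-pooled response of one scheme over an inducer grid.

    ``summaries`` holds one pooled :class:`NoiseSummary` per inducer level
    (mean of replicate means; noise averaged across replicates), and
    ``replicates[i]`` the per-replicate summaries behind it.
    """

    scheme: str
    inducer_levels: np.ndarray
    summaries: tuple[NoiseSummary, ...]
    replicates: tuple[tuple[NoiseSummary, ...], ...]
    rates: RateSet = field(default_factory=RateSet)
    extrinsic: bool = True

    def __post_init__(self) -> None:
        lv = np.asarray(self.inducer_levels)
        if lv.size and np.any(np.diff(lv) <= 0):
            raise ValueError("inducer levels must be strictly increasing")

    @property
    def means(self) -> np.ndarray:
        return np.array([s.mean for s in self.summaries])

    @property
    def noises(self) -> np.ndarray:
        return np.array([s.noise for s in self.summaries])

    def noise_se(self) -> np.ndarray:
        """Standard error of the pooled noise across replicates."""
        out = []
        for reps in self.replicates:
            vals = np.array([r.noise for r in reps])
            out.append(vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan)
        return np.array(out)

    def intermediate_index(self, reference_mean: float | None = None) -> int:
        """Grid point whose mean is nearest half the fully induced mean."""
        ref = self.means[-1] if reference_mean is None else reference_mean
        return int(np.argmin(np.abs(self.means - 0.5 * ref)))

    @property
    def dynamic_range(self) -> float:
        m = self.means
        return float(m.max() / m.min())

    def to_frame(self):
        """Tidy per-replicate table (scheme, inducer, replicate, mean, variance, noise)."""
        import pandas as pd

        rows = []
        for level, reps in zip(self.inducer_levels, self.replicates):
            for j, s in enumerate(reps):
                rows.append({"scheme": self.scheme, "inducer": int(level),
                             "replicate": j, "mean": s.mean,
                             "variance": s.variance, "noise": s.noise})
        return pd.DataFrame(rows)


def _replicate_summaries(
    network: NetworkSpec,
    config: SimConfig,
    extrinsic: bool,
    replicates: int,
    seed_seq: np.random.SeedSequence,
    ou_params: OUParams | None,
    species: str = "P",
) -> tuple[NoiseSummary, ...]:
    """Run ``replicates`` independent realizations and summarize each."""
    out = []
    children = seed_seq.spawn(replicates)
    for child in children:
        sim_seed, ou_seed = (int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(2))
        cfg = SimConfig(duration=config.duration, record_interval=config.record_interval,
                        burn_in=config.burn_in, seed=sim_seed)
        series = None
        if extrinsic:
            params = ou_params or OUParams()
            params = OUParams(tau=params.tau, c=params.c, dt=config.record_interval,
                              seed=ou_seed, c_units=params.c_units)
            series = generate_extrinsic(params, cfg.n_intervals)
        traj = simulate(network, cfg, series)
        out.append(summarize(traj, species=species))
    return tuple(out)


def _pool(reps: tuple[NoiseSummary, ...], species: str = "P") -> NoiseSummary:
    means = np.array([r.mean for r in reps])
    noises = np.array([r.noise for r in reps])
    variances = np.array([r.variance for r in reps])
    n = sum(r.n_samples for r in reps)
    return NoiseSummary(mean=float(means.mean()), variance=float(variances.mean()),
                        noise=float(noises.mean()), n_samples=n, species=species)


def dose_response(
    scheme: str,
    inducer_grid: np.ndarray | None = None,
    config: SimConfig | None = None,
    extrinsic: bool = True,
    replicates: int = 3,
    rates: RateSet | None = None,
    inducer_mode: str = "fast",
    ou_params: OUParams | None = None,
    seed: int = 0,
    species: str = "P",
) -> DoseResponseCurve:
    """Simulate the inducer dose-response of one scheme.

    One pooled :class:`NoiseSummary` per inducer level for the protein of
    interest; each level is simulated ``replicates`` times with independent
    seeds (and independent extrinsic realizations when extrinsic noise is
    on).
    """
    scheme = resolve_scheme(scheme)
    if inducer_grid is None:
        inducer_grid = default_inducer_grid()
    inducer_grid = np.asarray(inducer_grid)
    if inducer_grid.size == 0:
        raise ValueError("inducer grid must be non-empty")
    if config is None:
        config = SimConfig()
    if rates is None:
        rates = default_rates(scheme)

    top = np.random.SeedSequence(seed)
    level_seqs = top.spawn(inducer_grid.size)
    all_reps = []
    pooled = []
    for level, seq in zip(inducer_grid, level_seqs):
        network = build_network(scheme, rates=rates, inducer_count=int(level),
                                inducer_mode=inducer_mode)
        reps = _replicate_summaries(network, config, extrinsic, replicates, seq,
                                    ou_params, species)
        all_reps.append(reps)
        pooled.append(_pool(reps, species))
    return DoseResponseCurve(scheme=scheme, inducer_levels=inducer_grid,
                             summaries=tuple(pooled), replicates=tuple(all_reps),
                             rates=rates, extrinsic=extrinsic)


def transcription_sweep(
    ktx1_values: np.ndarray,
    config: SimConfig | None = None,
    extrinsic: bool = False,
    replicates: int = 3,
    seed: int = 0,
) -> list[tuple[NoiseSummary, tuple[NoiseSummary, ...]]]:
    """Noise-vs-mean sweep of unregulated expression over kTX1.

    Emulates weakening constitutive expression by lowering the
    transcription rate (the published range is 6.5e-6 .. 1.7e-3 s^-1).
    Returns ``(pooled, replicates)`` per value.
    """
    ktx1_values = np.asarray(ktx1_values, dtype=float)
    if ktx1_values.size == 0:
        raise ValueError("kTX1 grid must be non-empty")
    if config is None:
        config = SimConfig()
    top = np.random.SeedSequence(seed)
    out = []
    for ktx1, seq in zip(ktx1_values, top.spawn(ktx1_values.size)):
        network = build_network("constitutive", rates=RateSet(kTX1=float(ktx1)))
        reps = _replicate_summaries(network, config, extrinsic, replicates, seq, None)
        out.append((_pool(reps), reps))
    return out


def translation_sweep(
    ktl_values: np.ndarray,
    scheme: str = "bicistronic_autoregulation",
    inducer_grid: np.ndarray | None = None,
    config: SimConfig | None = None,
    extrinsic: bool = True,
    replicates: int = 3,
    seed: int = 0,
) -> dict[float, DoseResponseCurve]:
    """Dose-response curves at several kTL_P values (RBS-variant sweep)."""
    ktl_values = np.asarray(ktl_values, dtype=float)
    if ktl_values.size == 0:
        raise ValueError("kTL grid must be non-empty")
    curves = {}
    for i, ktl in enumerate(ktl_values):
        rates = default_rates(scheme).replace(kTL_P=float(ktl))
        curves[float(ktl)] = dose_response(
            scheme, inducer_grid=inducer_grid, config=config, extrinsic=extrinsic,
            replicates=replicates, rates=rates, seed=seed + i,
        )
    return curves


# ---------------------------------------------------------------------------
# Fit operators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HillFit:
    """Least-squares Hill fit y = y0 + (ymax - y0) d^n / (K^n + d^n)."""

    n_h: float
    K: float
    y_max: float
    y_0: float
    stderr: dict[str, float]

    def predict(self, dose: np.ndarray) -> np.ndarray:
        d = np.asarray(dose, dtype=float)
        return _hill(d, self.y_0, self.y_max, self.K, self.n_h)


def _hill(d, y0, ymax, K, n):
    dn = np.power(d, n)
    return y0 + (ymax - y0) * dn / (np.power(K, n) + dn)


def fit_hill(dose: np.ndarray, response: np.ndarray,
             normalize_at_max: bool = False) -> HillFit:
    """Fit the Hill equation to a (dose, response) curve.

    Uniformly weighted least squares on the mean response.  With
    ``normalize_at_max`` the returned y0/ymax are divided by the fitted
    value at the largest dose (the convention used when comparing
    induction curves across strains).
    """
    d = np.asarray(dose, dtype=float)
    y = np.asarray(response, dtype=float)
    if d.size < 4:
        raise FitError("need at least 4 points for a Hill fit")
    if np.unique(d).size < 2:
        raise FitError("need at least 2 distinct doses")
    if np.allclose(y, y[0], rtol=1e-12, atol=0):
        raise FitError("constant response: Hill coefficient is unidentifiable")
    if np.any(d < 0):
        raise FitError("doses must be >= 0")

    y0_guess = float(y[np.argmin(d)])
    ymax_guess = float(y[np.argmax(d)])
    half = 0.5 * (y0_guess + ymax_guess)
    K_guess = float(d[np.argmin(np.abs(y - half))])
    K_guess = max(K_guess, np.min(d[d > 0], initial=1.0))
    p0 = [y0_guess, ymax_guess, K_guess, 1.0]
    lo = [-np.inf, -np.inf, np.min(d[d > 0]) * 1e-3 if np.any(d > 0) else 1e-12, 1e-3]
    hi = [np.inf, np.inf, np.max(d) * 1e3, 20.0]
    try:
        popt, pcov = optimize.curve_fit(_hill, d, y, p0=p0, bounds=(lo, hi),
                                        maxfev=20000)
    except (RuntimeError, ValueError) as err:
        raise FitError(f"Hill fit did not converge: {err}") from err
    perr = np.sqrt(np.diag(pcov))
    y0, ymax, K, n = popt
    if normalize_at_max:
        scale = _hill(np.max(d), y0, ymax, K, n)
        y0, ymax = y0 / scale, ymax / scale
        perr = perr.copy()
        perr[0] /= scale
        perr[1] /= scale
    return HillFit(n_h=float(n), K=float(K), y_max=float(ymax), y_0=float(y0),
                   stderr={"y_0": float(perr[0]), "y_max": float(perr[1]),
                           "K": float(perr[2]), "n_h": float(perr[3])})


@dataclass(frozen=True)
class DecayFit:
    """Exponential decay fit v(t) = A * 2^(-t / t_half) + offset."""

    half_time: float
    amplitude: float
    offset: float
    residual: float

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.amplitude * np.power(2.0, -t / self.half_time) + self.offset


def fit_exp_decay(times: np.ndarray, values: np.ndarray) -> DecayFit:
    """Fit exponential decay and report the half-time in the time unit given.

    Requires at least 3 points and an overall decreasing trend.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 3:
        raise FitError("need at least 3 points for a decay fit")
    slope = np.polyfit(t, v, 1)[0]
    scale = max(np.ptp(v), abs(v).max(), 1e-300)
    if np.ptp(v) == 0 or slope >= -1e-12 * scale / max(np.ptp(t), 1e-300):
        raise FitError("data show no decreasing trend; cannot fit a decay")

    def model(t, A, t_half, off):
        return A * np.power(2.0, -t / t_half) + off

    A0 = float(v.max() - v.min())
    off0 = float(v.min())
    # crude half-time guess from the time at which v crosses halfway down
    half_val = off0 + 0.5 * A0
    th0 = float(t[np.argmin(np.abs(v - half_val))])
    th0 = max(th0, (t[1] - t[0]) if t.size > 1 else 1.0)
    try:
        popt, _ = optimize.curve_fit(model, t, v, p0=[A0, th0, off0],
                                     bounds=([0, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
                                     maxfev=20000)
    except (RuntimeError, ValueError) as err:
        raise FitError(f"decay fit did not converge: {err}") from err
    resid = float(np.sqrt(np.mean((model(t, *popt) - v) ** 2)))
    return DecayFit(half_time=float(popt[1]), amplitude=float(popt[0]),
                    offset=float(popt[2]), residual=resid)
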