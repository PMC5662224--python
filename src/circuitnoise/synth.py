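"""Synthetic single-cell data with the statistical structure the pipelines assume.

These generators are first-class, tested code: they emit flow-cytometry
event tables (2-D scatter cloud around a peak plus a debris fraction;
fluorescence = autofluorescence background + log-normal expression),
microscopy spot-intensity lists (gamma-distributed) and per-cell
measurements (log-normal molecule counts co-varying with cell area), and
noiseless or noisy Hill/decay curves.  Every generator is a pure function
of its ground-truth parameters and seed, and the ground truth is carried
alongside the data so recovery can be checked end to end.

Defaults mirror the measurement conditions the pipelines were designed
around: 30,000 cytometry events of which about one third fall inside the
scatter gate, a constant autofluorescence background of 191 counts, and
300-cell microscopy samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cytometry import GateSpec

__all__ = [
    "CytometryGroundTruth",
    "MicroscopyGroundTruth",
    "synth_cytometry",
    "synth_microscopy",
    "synth_curve_data",
    "lognormal_params",
]


def lognormal_params(mean: float, noise: float) -> tuple[float, float]:
    """(log-mean, log-sd) of a log-normal with the given mean and CV^2."""
    if not (mean > 0 and noise > 0):
        raise ValueError("mean and noise must be > 0")
    sigma2 = np.log1p(noise)
    mu = np.log(mean) - 0.5 * sigma2
    return float(mu), float(np.sqrt(sigma2))


@dataclass(frozen=True)
class CytometryGroundTruth:
    """Generating model for a synthetic flow-cytometry event table.

    Fluorescence of in-gate cells is ``background + LogNormal(log_mean,
    log_sd)``; debris events carry background only.  The background is a
    constant (default 191 counts) optionally widened by a Gaussian jitter
    of relative width ``background_width``.  The scatter cloud is 2-D
    log-normal around (peak_FSCA, peak_SSCH): cells tight enough to fall
    inside the gate, debris rejected outside it.
    """

    log_mean: float
    log_sd: float
    n_events: int = 30_000
    background_level: float = 191.0
    background_width: float = 0.0
    peak_FSCA: float = 1e4
    peak_SSCH: float = 1e3
    scatter_log_sd: float = 0.08
    debris_log_sd: float = 1.0
    debris_fraction: float = 2.0 / 3.0
    radius2_threshold: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if not self.log_sd > 0:
            raise ValueError("log_sd must be > 0")
        if not 0.0 <= self.debris_fraction < 1.0:
            raise ValueError("debris_fraction must be in [0, 1)")

    @property
    def expression_mean(self) -> float:
        return float(np.exp(self.log_mean + 0.5 * self.log_sd**2))

    @property
    def expression_noise(self) -> float:
        return float(np.expm1(self.log_sd**2))

    def gate(self) -> GateSpec:
        return GateSpec(self.peak_FSCA, self.peak_SSCH, self.radius2_threshold)


def _scatter_cloud(rng, n, peak_f, peak_s, log_sd, gate: GateSpec, inside: bool):
    """Rejection-sample 2-D log-normal scatter strictly inside/outside the gate."""
    out_f = np.empty(n)
    out_s = np.empty(n)
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 256)
        f = peak_f * np.exp(log_sd * rng.standard_normal(m))
        s = peak_s * np.exp(log_sd * rng.standard_normal(m))
        r2 = ((f - gate.peak_FSCA) / gate.peak_FSCA) ** 2 \
            + ((s - gate.peak_SSCH) / gate.peak_SSCH) ** 2
        ok = (r2 < gate.radius2_threshold) if inside else (r2 >= gate.radius2_threshold)
        k = min(int(ok.sum()), n - filled)
        out_f[filled : filled + k] = f[ok][:k]
        out_s[filled : filled + k] = s[ok][:k]
        filled += k
    return out_f, out_s


def _background_draw(rng, n, level, width):
    if width == 0.0:
        return np.full(n, float(level))
    return level * (1.0 + width * rng.standard_normal(n))


def synth_cytometry(truth: CytometryGroundTruth) -> pd.DataFrame:
    """Generate an event table (columns FSCA, SSCH, FL1A) from the model."""
    rng = np.random.default_rng(truth.seed)
    n = truth.n_events
    is_debris = rng.random(n) < truth.debris_fraction
    n_debris = int(is_debris.sum())
    n_cells = n - n_debris
    gate = truth.gate()

    fsca = np.empty(n)
    ssch = np.empty(n)
    fl1a = np.empty(n)

    cf, cs = _scatter_cloud(rng, n_cells, truth.peak_FSCA, truth.peak_SSCH,
                            truth.scatter_log_sd, gate, inside=True)
    df_, ds = _scatter_cloud(rng, n_debris, truth.peak_FSCA, truth.peak_SSCH,
                             truth.debris_log_sd, gate, inside=False)
    fsca[~is_debris], ssch[~is_debris] = cf, cs
    fsca[is_debris], ssch[is_debris] = df_, ds

    bg = _background_draw(rng, n, truth.background_level, truth.background_width)
    expr = np.exp(truth.log_mean + truth.log_sd * rng.standard_normal(n))
    fl1a = bg + np.where(is_debris, 0.0, expr)
    return pd.DataFrame({"FSCA": fsca, "SSCH": ssch, "FL1A": fl1a})


@dataclass(frozen=True)
class MicroscopyGroundTruth:
    """Generating model for synthetic microscopy data.

    Spots are gamma(shape, scale); cells draw a log-normal relative area
    (unit mean) and a molecule count proportional to that area around
    ``molecule_mean`` with expression noise ``molecule_noise`` (CV^2);
    integrated intensity = molecules * counts_per_molecule + Gaussian
    background residual of width ``background_sd`` (intensities are
    background-subtracted, so the residual has zero mean).
    """

    molecule_mean: float = 300.0
    molecule_noise: float = 0.06
    counts_per_molecule: float = 1101.0
    spot_shape: float = 4.0
    spot_scale: float = 917.25
    area_log_sd: float = 0.25
    background_sd: float = 0.0
    n_cells: int = 300
    n_spots: int = 858
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("molecule_mean", "molecule_noise", "counts_per_molecule",
                     "spot_shape", "spot_scale"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


def synth_microscopy(truth: MicroscopyGroundTruth) -> tuple[np.ndarray, pd.DataFrame]:
    """Generate (spot intensities, per-cell table with integrated_counts, area)."""
    rng = np.random.default_rng(truth.seed)
    spots = rng.gamma(truth.spot_shape, truth.spot_scale, size=truth.n_spots)

    # unit-mean log-normal relative areas
    area = np.exp(truth.area_log_sd * rng.standard_normal(truth.n_cells)
                  - 0.5 * truth.area_log_sd**2)
    mu, sd = lognormal_params(truth.molecule_mean, truth.molecule_noise)
    molecules = np.exp(mu + sd * rng.standard_normal(truth.n_cells)) * area
    counts = molecules * truth.counts_per_molecule
    if truth.background_sd > 0:
        counts = counts + truth.background_sd * rng.standard_normal(truth.n_cells)
    cells = pd.DataFrame({"integrated_counts": counts, "area": area})
    return spots, cells


def synth_curve_data(
    kind: str,
    params: dict,
    noise_level: float = 0.0,
    n_points: int = 12,
    seed: int = 0,
) -> pd.DataFrame:
    """Hill or exponential-decay curve samples, optional multiplicative noise.

    ``kind="hill"`` needs params y_0, y_max, K, n_h (x is a log grid over
    [K/100, 100K] unless x_min/x_max given); ``kind="decay"`` needs
    amplitude, half_time and optional offset (x is a linear time grid over
    [0, 4 half-times] unless overridden).  Zero-noise output is independent
    of the seed.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    p = dict(params)
    if kind == "hill":
        K, n_h = float(p["K"]), float(p["n_h"])
        if not (K > 0 and n_h > 0):
            raise ValueError("K and n_h must be > 0")
        x = np.logspace(np.log10(p.get("x_min", K / 100.0)),
                        np.log10(p.get("x_max", K * 100.0)), n_points)
        y0, ymax = float(p.get("y_0", 0.0)), float(p["y_max"])
        y = y0 + (ymax - y0) * x**n_h / (K**n_h + x**n_h)
    elif kind == "decay":
        t_half = float(p["half_time"])
        if not t_half > 0:
            raise ValueError("half_time must be > 0")
        x = np.linspace(p.get("x_min", 0.0), p.get("x_max", 4.0 * t_half), n_points)
        y = float(p["amplitude"]) * 2.0 ** (-x / t_half) + float(p.get("offset", 0.0))
    else:
        raise ValueError(f"unknown curve kind {kind!r}; expected 'hill' or 'decay'")
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        y = y * (1.0 + noise_level * rng.standard_normal(n_points))
    return pd.DataFrame({"x": x, "y": y})


# ---------------------------------------------------------------------------
# I/O: generators write the same CSV dialects the pipelines read, with the
# ground truth as a JSON sidecar for recovery tests.
# ---------------------------------------------------------------------------

def save_with_truth(data, truth, path) -> None:
    path = str(path)
    if isinstance(data, pd.DataFrame):
        data.to_csv(path, index=False)
    else:
        np.savetxt(path, np.asarray(data), header="intensity", comments="")
    with open(path + ".json", "w") as fh:
        json.dump(asdict(truth), fh, indent=2)
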