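"""mEPSC amplitude filtering and multiplicative scaling fits.

Miniature EPSC amplitudes proxy synaptic strength.  Homeostatic scaling is
classically *multiplicative*: the deprived amplitude distribution should
equal the control distribution with every value (or a fraction of values)
multiplied by a constant factor.  This module implements the standard event
filters, a grid search over scaling factors scored by the two-sample
Kolmogorov-Smirnov test, and the model comparison between scaling 100% of
the distribution and scaling only 50% of it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MepscSample",
    "ScalingFit",
    "FractionComparison",
    "filter_events",
    "scale_sample",
    "fit_scaling",
    "compare_fraction_models",
    "default_factor_grid",
]

AMPLITUDE_MIN_PA = 5.0
RISE_TIME_MAX_MS = 1.0


def default_factor_grid() -> np.ndarray:
    """Multiplicative factors 1.00-2.00 in steps of 0.01."""
    return np.round(np.arange(1.00, 2.00 + 1e-9, 0.01), 2)


@dataclass
class MepscSample:
    """Filtered mEPSC events for one cell/condition."""

    amplitudes: np.ndarray  # pA
    rise_times: np.ndarray  # 20-80% rise, ms
    cell_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.rise_times = np.asarray(self.rise_times, dtype=float)
        if self.amplitudes.shape != self.rise_times.shape:
            raise ValueError("amplitudes and rise_times must have equal length")
        if np.any(self.amplitudes <= 0):
            raise ValueError("amplitudes must be positive")
        n = self.amplitudes.size
        if n and not 30 <= n <= 50:
            warnings.warn(
                f"{n} events in sample {self.cell_id or '<unnamed>'}; "
                "30-50 events per cell expected", stacklevel=2)

    def __len__(self) -> int:
        return int(self.amplitudes.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": self.cell_id,
            "condition": self.condition,
            "amplitude_pA": self.amplitudes,
            "rise_ms": self.rise_times,
        })


def filter_events(amplitudes: Iterable[float], rise_times: Iterable[float],
                  cell_id: str = "", condition: str = "") -> MepscSample:
    """Keep events with amplitude > 5 pA and 20-80% rise time < 1 ms."""
    amp = np.asarray(list(amplitudes), dtype=float)
    rise = np.asarray(list(rise_times), dtype=float)
    if amp.shape != rise.shape:
        raise ValueError("amplitudes and rise_times must have equal length")
    keep = (amp > AMPLITUDE_MIN_PA) & (rise < RISE_TIME_MAX_MS)
    if not keep.any():
        warnings.warn("no events survived the amplitude/rise-time filters",
                      stacklevel=2)
    return MepscSample(amp[keep], rise[keep], cell_id=cell_id, condition=condition)


def scale_sample(control: np.ndarray, factor: float, fraction: float,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Build a scaled version of the control amplitude distribution.

    fraction 1.0: every amplitude multiplied by ``factor`` (deterministic).
    fraction 0.5: half of the output is drawn with replacement from the
    empirical control distribution and multiplied by ``factor``; the other
    half is drawn unscaled.  Output size equals the control size.
    """
    control = np.asarray(control, dtype=float)
    if factor <= 0:
        raise ValueError("factor must be positive")
    if fraction == 1.0:
        return control * factor
    if fraction != 0.5:
        raise ValueError("fraction must be 0.5 or 1.0")
    if rng is None:
        raise ValueError("fraction 0.5 requires an rng (the draw is stochastic)")
    n = control.size
    n_scaled = n // 2
    scaled = rng.choice(control, size=n_scaled, replace=True) * factor
    unscaled = rng.choice(control, size=n - n_scaled, replace=True)
    return np.concatenate([scaled, unscaled])


@dataclass
class ScalingFit:
    """Result of the K-S grid search for one scaled fraction."""

    factor_grid: np.ndarray
    p_by_factor: np.ndarray
    d_by_factor: np.ndarray
    scaled_fraction: float
    alpha: float
    n_resamples: int
    best_factor: float | None
    best_p: float | None

    @property
    def fitted(self) -> bool:
        return self.best_factor is not None

    def to_dict(self) -> dict:
        return {
            "scaled_fraction": self.scaled_fraction,
            "alpha": self.alpha,
            "n_resamples": self.n_resamples,
            "best_factor": self.best_factor,
            "best_p": self.best_p,
            "factor_grid": [float(f) for f in self.factor_grid],
            "p_by_factor": [float(p) for p in self.p_by_factor],
            "d_by_factor": [float(d) for d in self.d_by_factor],
        }


def fit_scaling(control: np.ndarray, deprived: np.ndarray, fraction: float = 1.0,
                factor_grid: Sequence[float] | None = None, alpha: float = 0.05,
                rng: np.random.Generator | None = None, n_resamples: int = 100,
                aggregate: str = "median") -> ScalingFit:
    """Grid-search the multiplicative factor best mapping control onto deprived.

    For each candidate factor the (100% or 50%) scaled control distribution
    is compared with the deprived distribution by a two-sample K-S test; the
    best factor is the one with the highest non-significant p value
    (p > alpha).  In the 50% mode the scaled sample is stochastic, so the
    K-S p per factor is the median (or mean) over ``n_resamples``
    constructions.
    """
    control = np.asarray(control, dtype=float)
    deprived = np.asarray(deprived, dtype=float)
    if control.size < 20 or deprived.size < 20:
        raise ValueError("need at least 20 events per sample")
    grid = default_factor_grid() if factor_grid is None else np.asarray(factor_grid, float)
    if grid.size == 0:
        raise ValueError("factor grid is empty")
    agg = {"median": np.median, "mean": np.mean}[aggregate]
    if fraction == 0.5 and rng is None:
        raise ValueError("fraction 0.5 requires an rng")

    p_by = np.empty(grid.size)
    d_by = np.empty(grid.size)
    for k, f in enumerate(grid):
        if fraction == 1.0:
            d, p = stats.ks_2samp(control * f, deprived)
        else:
            ps = np.empty(n_resamples)
            ds = np.empty(n_resamples)
            for r in range(n_resamples):
                scaled = scale_sample(control, f, 0.5, rng)
                ds[r], ps[r] = stats.ks_2samp(scaled, deprived)
            p, d = agg(ps), agg(ds)
        p_by[k], d_by[k] = p, d

    ok = p_by > alpha
    if ok.any():
        best_idx = int(np.argmax(np.where(ok, p_by, -np.inf)))
        best_factor, best_p = float(grid[best_idx]), float(p_by[best_idx])
    else:
        best_factor = best_p = None
    return ScalingFit(grid, p_by, d_by, fraction, alpha, n_resamples,
                      best_factor, best_p)


@dataclass
class FractionComparison:
    fit_full: ScalingFit
    fit_half: ScalingFit
    preferred: str  # "1.0", "0.5", "tie", or "none"

    def to_dict(self) -> dict:
        return {"preferred": self.preferred,
                "fit_full": self.fit_full.to_dict(),
                "fit_half": self.fit_half.to_dict()}


def compare_fraction_models(control: np.ndarray, deprived: np.ndarray,
                            factor_grid: Sequence[float] | None = None,
                            alpha: float = 0.05,
                            rng: np.random.Generator | None = None,
                            n_resamples: int = 100) -> FractionComparison:
    """Fit both scaled fractions and prefer the one with the higher best p."""
    fit_full = fit_scaling(control, deprived, 1.0, factor_grid, alpha)
    fit_half = fit_scaling(control, deprived, 0.5, factor_grid, alpha,
                           rng=rng, n_resamples=n_resamples)
    pf = fit_full.best_p if fit_full.fitted else -np.inf
    ph = fit_half.best_p if fit_half.fitted else -np.inf
    if pf == -np.inf and ph == -np.inf:
        preferred = "none"
    elif pf == ph:
        preferred = "tie"
    else:
        preferred = "1.0" if pf > ph else "0.5"
    return FractionComparison(fit_full, fit_half, preferred)
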