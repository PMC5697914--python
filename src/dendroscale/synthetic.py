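"""Synthetic data generators for every analysis stage.

The generators emulate the statistical structure of deprivation-induced
homeostatic scaling measurements so that each downstream analysis can be
exercised and validated without any experimental data:

* spine censuses with lognormal-like sizes, ~4 um interspine spacing, and a
  deprivation coupling in which the fractional spine loss L of a branch
  multiplies its survivors' sizes by (1 + coupling * L) — producing the
  negative density-vs-size relation across branches;
* mEPSC amplitude samples where the deprived sample multiplies a chosen
  fraction of control-distributed draws by a known factor;
* paired dendritic calcium traces with shared global events, slow drift,
  and rare branch-specific events, plus a ground-truth event log;
* per-spine GFP/GluA2/GRIP1 intensity profiles with rotated backgrounds.

Every generator is deterministic under its seed, and ground truth (lost and
increased labels, the true scaling factor, the event log) is always emitted
alongside the data to enable parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .calcium import BranchPairRecording
from .mepsc import MepscSample
from .spines import IntensityProfileSet, SpineDataset, SPINE_COLUMNS

__all__ = [
    "SpineGenParams",
    "MepscGenParams",
    "CalciumGenParams",
    "gen_spine_dataset",
    "gen_mepsc_samples",
    "gen_calcium_pair",
    "gen_intensity_profiles",
]


def _check_finite(obj, names) -> None:
    for name in names:
        v = getattr(obj, name)
        if v is None:
            continue
        if not math.isfinite(float(v)):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass
class SpineGenParams:
    """Spine-census generator parameters.

    Defaults emulate an inhibitory-like census: ~14 spines per branch
    spaced ~4 um apart, deprivation between 0 and 24 h on half of the
    branches with ~15% spine loss, and survivor sizes multiplied by
    (1 + coupling * fractional branch loss).  Measurement noise has a
    per-spine component (``measurement_cv``) and a per-branch per-session
    component (``branch_cv``); with both at 0.05 the normalized-size ratio
    has SD ~0.078, so ~10% of control spines exceed 1.1 — the control
    calibration the classification thresholds assume.
    """

    n_cells: int = 6
    branches_per_cell: int = 5
    spines_per_branch: int = 14
    interspine_spacing_mean: float = 4.0
    spacing_min: float = 0.5
    size_scale: float = 10.0        # lognormal scale of baseline brightness, a.u.
    size_sigma: float = 0.5         # lognormal sigma of baseline brightness
    timepoints: tuple[float, ...] = (-24.0, 0.0, 24.0, 48.0)
    deprived: bool = False
    branch_loss_prob: float = 0.5
    spine_loss_prob: float = 0.15
    coupling: float = 1.0
    new_spine_prob: float = 0.05
    measurement_cv: float = 0.05
    branch_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        _check_finite(self, ("interspine_spacing_mean", "spacing_min", "size_scale",
                             "size_sigma", "branch_loss_prob", "spine_loss_prob",
                             "coupling", "new_spine_prob", "measurement_cv",
                             "branch_cv"))
        for name in ("branch_loss_prob", "spine_loss_prob", "new_spine_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.interspine_spacing_mean <= 0:
            raise ValueError("interspine_spacing_mean must be positive")
        if self.spacing_min >= self.interspine_spacing_mean:
            raise ValueError("spacing_min must be below the mean spacing")
        if self.coupling < 0:
            raise ValueError("coupling must be >= 0")
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size < 2 or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be strictly increasing (>= 2 of them)")

    @classmethod
    def inhibitory(cls, **kw) -> "SpineGenParams":
        """The default parameterization (day-scale deprivation timepoints)."""
        return cls(**kw)

    @classmethod
    def excitatory(cls, **kw) -> "SpineGenParams":
        """Fast-mode preset: denser spines, sub-day deprivation timepoints."""
        kw.setdefault("spines_per_branch", 16)
        kw.setdefault("interspine_spacing_mean", 3.5)
        kw.setdefault("timepoints", (-4.0, 0.0, 4.0, 24.0))
        return cls(**kw)


@dataclass
class SpineGroundTruth:
    """Per-branch deprivation truth emitted with every generated census."""

    branches: pd.DataFrame  # cell_id, branch_id, lossy, loss_fraction, size_factor


def gen_spine_dataset(params: SpineGenParams
                      ) -> tuple[SpineDataset, SpineGroundTruth]:
    """Generate a longitudinal spine census plus its ground truth.

    Positions accumulate shifted-exponential gaps (minimum ``spacing_min``,
    mean ``interspine_spacing_mean``); loss is spatially unclustered
    (independent per spine) on lossy branches and happens between the 0 h
    timepoint and the next one; survivors on a branch with fractional loss
    L carry true sizes multiplied by (1 + coupling * L) from then on.
    """
    rng = np.random.default_rng(params.seed)
    tp = np.asarray(params.timepoints, dtype=float)
    post = tp[tp > 0]
    loss_time = post[0] if post.size else None

    rows = []
    truth_rows = []
    for ci in range(params.n_cells):
        cell = f"c{ci:02d}"
        for bi in range(params.branches_per_cell):
            branch = f"b{bi:02d}"
            n = max(3, int(rng.poisson(params.spines_per_branch)))
            gaps = params.spacing_min + rng.exponential(
                params.interspine_spacing_mean - params.spacing_min, size=n)
            pos = np.cumsum(gaps)
            base = rng.lognormal(math.log(params.size_scale), params.size_sigma,
                                 size=n)
            lossy = bool(params.deprived and loss_time is not None
                         and rng.random() < params.branch_loss_prob)
            lost = (rng.random(n) < params.spine_loss_prob) if lossy else np.zeros(n, bool)
            if lost.all():
                lost[rng.integers(n)] = False  # keep at least one survivor
            L = lost.mean() if lossy else 0.0
            factor = 1.0 + params.coupling * L
            # optional new spines appearing at the loss timepoint
            n_new = (rng.binomial(n, params.new_spine_prob)
                     if params.deprived and loss_time is not None else 0)
            new_pos = []
            if n_new:
                span = pos.max()
                for _ in range(n_new):
                    while True:
                        p = rng.uniform(0, span + params.interspine_spacing_mean)
                        if np.min(np.abs(np.r_[pos, new_pos] - p)) > params.spacing_min:
                            new_pos.append(p)
                            break
            branch_noise = {t: rng.normal(0.0, params.branch_cv) for t in tp}
            sid = 0

            def emit(position, fate, first_tp, true_base):
                nonlocal sid
                name = f"s{sid:03d}"
                sid += 1
                for t in tp:
                    if t < first_tp:
                        continue
                    if fate == "lost" and loss_time is not None and t >= loss_time:
                        continue
                    true = true_base
                    if (fate != "lost" and lossy and loss_time is not None
                            and t >= loss_time):
                        true = true_base * factor
                    meas = true * math.exp(branch_noise[t]) \
                        * math.exp(rng.normal(0.0, params.measurement_cv))
                    rows.append((cell, branch, name, float(position), float(t),
                                 float(meas), fate))

            for k in range(n):
                emit(pos[k], "lost" if lost[k] else "stable", tp[0], base[k])
            for p in new_pos:
                emit(p, "new", loss_time,
                     rng.lognormal(math.log(params.size_scale), params.size_sigma))
            truth_rows.append({"cell_id": cell, "branch_id": branch,
                               "lossy": lossy, "loss_fraction": float(L),
                               "size_factor": float(factor)})

    df = pd.DataFrame(rows, columns=SPINE_COLUMNS)
    df = df.sort_values(["cell_id", "branch_id", "position_um", "timepoint_hr"]
                        ).reset_index(drop=True)
    return SpineDataset(df), SpineGroundTruth(pd.DataFrame(truth_rows))


@dataclass
class MepscGenParams:
    """mEPSC generator parameters.

    Control amplitudes are 5 pA plus a lognormal (all events pass the 5 pA
    filter); the deprived sample multiplies a ``scaled_fraction`` subset of
    control-distributed draws by ``true_factor``.
    """

    n_control: int = 40
    n_deprived: int = 40
    amp_scale: float = 7.0        # lognormal scale of the amplitude excess, pA
    amp_sigma: float = 0.4
    rise_mean: float = 0.6        # ms
    rise_sd: float = 0.15
    true_factor: float = 1.0
    scaled_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check_finite(self, ("amp_scale", "amp_sigma", "rise_mean", "rise_sd",
                             "true_factor", "scaled_fraction"))
        if self.true_factor < 1.0:
            raise ValueError("true_factor must be >= 1")
        if self.scaled_fraction not in (0.5, 1.0):
            raise ValueError("scaled_fraction must be 0.5 or 1.0")
        if self.n_control < 1 or self.n_deprived < 1:
            raise ValueError("sample sizes must be >= 1")


def _draw_amps(params: MepscGenParams, rng: np.random.Generator, n: int) -> np.ndarray:
    return 5.0 + rng.lognormal(math.log(params.amp_scale), params.amp_sigma, size=n)


def _draw_rise(params: MepscGenParams, rng: np.random.Generator, n: int) -> np.ndarray:
    return np.clip(rng.normal(params.rise_mean, params.rise_sd, size=n), 0.1, 0.99)


def gen_mepsc_samples(params: MepscGenParams) -> tuple[MepscSample, MepscSample]:
    """Generate (control, deprived) samples; deprived scales a known subset."""
    rng = np.random.default_rng(params.seed)
    ctrl = MepscSample(_draw_amps(params, rng, params.n_control),
                       _draw_rise(params, rng, params.n_control),
                       cell_id="ctrl", condition="control")
    amps = _draw_amps(params, rng, params.n_deprived)
    n_scaled = int(round(params.scaled_fraction * params.n_deprived))
    idx = rng.choice(params.n_deprived, size=n_scaled, replace=False)
    amps[idx] *= params.true_factor
    depr = MepscSample(amps, _draw_rise(params, rng, params.n_deprived),
                       cell_id="depr", condition="deprived")
    return ctrl, depr


@dataclass
class CalciumGenParams:
    """Calcium trace-pair generator parameters.

    Shared events appear in branch1, branch2 and the within-branch region
    with correlated amplitudes; branch-specific events appear in exactly one
    branch of the pair; the different-cell trace carries independent events.
    Amplitudes are in %dF/F0 of the 100 a.u. baseline; events rise over two
    frames and decay exponentially with ``tau_s``.
    """

    duration_s: float = 240.0
    rate_hz: float = 10.0
    shared_event_rate: float = 1.5     # events/min
    specific_event_rate: float = 0.5   # events/min
    event_amp_range: tuple[float, float] = (20.0, 60.0)  # %dF/F0
    tau_s: float = 1.0
    drift_amp: float = 5.0             # raw units, slow sinusoid
    drift_period_s: float = 120.0
    noise_sd: float = 2.0              # raw units
    baseline: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check_finite(self, ("duration_s", "rate_hz", "shared_event_rate",
                             "specific_event_rate", "tau_s", "drift_amp",
                             "drift_period_s", "noise_sd", "baseline"))
        if self.shared_event_rate < 0 or self.specific_event_rate < 0:
            raise ValueError("event rates must be >= 0")
        if self.duration_s < 60.0:
            raise ValueError(
                "duration must be >= 60 s (the +/-15 s detrend window)")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")


def _kernel(n_frames: int, onset: int, amp: float, rate_hz: float,
            tau_s: float) -> np.ndarray:
    """Two-frame linear rise then exponential decay, in %dF/F0 units."""
    out = np.zeros(n_frames)
    t = np.arange(n_frames - onset) / rate_hz
    rise = min(2, n_frames - onset)
    decay = amp * np.exp(-(t - (rise - 1) / rate_hz) / tau_s)
    seg = np.where(t < (rise - 1) / rate_hz,
                   amp * (t * rate_hz + 1) / rise, decay)
    out[onset:] = seg
    return out


def gen_calcium_pair(params: CalciumGenParams
                     ) -> tuple[BranchPairRecording, pd.DataFrame]:
    """Generate the four-ROI recording plus the ground-truth event log.

    The log has one row per injected event and ROI with its onset time,
    amplitude, kind (shared / specific / other_cell) and analytic kernel
    integral in %dF/F0*s.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.rate_hz))
    t = np.arange(n) / params.rate_hz
    drift = params.drift_amp * np.sin(2 * np.pi * t / params.drift_period_s)

    signals = {roi: np.zeros(n) for roi in
               ("branch1", "branch2", "within_branch1", "different_cell")}
    log_rows = []

    def inject(roi: str, time_s: float, amp: float, kind: str) -> None:
        onset = int(round(time_s * params.rate_hz))
        if onset >= n:
            return
        signals[roi] += _kernel(n, onset, amp, params.rate_hz, params.tau_s)
        integral = amp * (params.tau_s + 0.5 / params.rate_hz)
        log_rows.append({"roi": roi, "time_s": time_s, "amp_pct": amp,
                         "kind": kind, "integral_pct_s": integral})

    def event_times(rate_per_min: float) -> np.ndarray:
        lam = rate_per_min / 60.0 * params.duration_s
        k = rng.poisson(lam)
        return np.sort(rng.uniform(0, params.duration_s, size=k))

    lo, hi = params.event_amp_range
    for time_s in event_times(params.shared_event_rate):
        amp = rng.uniform(lo, hi)
        for roi in ("branch1", "branch2", "within_branch1"):
            jitter = 1.0 + rng.normal(0.0, 0.1)
            inject(roi, time_s, amp * max(jitter, 0.1), "shared")
    for time_s in event_times(params.specific_event_rate):
        roi = "branch1" if rng.random() < 0.5 else "branch2"
        inject(roi, time_s, rng.uniform(lo, hi), "specific")
    for time_s in event_times(params.shared_event_rate
                              + params.specific_event_rate):
        inject("different_cell", time_s, rng.uniform(lo, hi), "other_cell")

    traces = {}
    for roi, sig in signals.items():
        raw = (params.baseline + drift
               + sig / 100.0 * params.baseline
               + rng.normal(0.0, params.noise_sd, size=n))
        traces[roi] = raw
    rec = BranchPairRecording(traces=traces, rate_hz=params.rate_hz)
    log = pd.DataFrame(log_rows,
                       columns=["roi", "time_s", "amp_pct", "kind",
                                "integral_pct_s"])
    return rec, log


def gen_intensity_profiles(n_spines: int, coloc_fraction: float, snr: float,
                           seed: int = 0, profile_len: int = 21,
                           bg_mean: float = 100.0, bg_sd: float = 10.0
                           ) -> IntensityProfileSet:
    """Generate per-spine intensity profiles with rotated backgrounds.

    Co-localizing spines carry GluA2/GRIP1 peaks ``snr`` background-SDs
    above the background mean at the GFP peak; the rest sit at background.
    """
    if not 0.0 <= coloc_fraction <= 1.0:
        raise ValueError("coloc_fraction must be in [0, 1]")
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    x = np.arange(profile_len)
    center = profile_len // 2
    shape = np.exp(-0.5 * ((x - center) / (profile_len / 8.0)) ** 2)

    coloc = rng.random(n_spines) < coloc_fraction
    gfp = bg_mean + 400.0 * shape[None, :] + rng.normal(0, bg_sd, (n_spines, profile_len))
    peak = snr * bg_sd

    def channel(flags):
        base = rng.normal(bg_mean, bg_sd, (n_spines, profile_len))
        base[flags] += peak * shape[None, :]
        return base

    glua2 = channel(coloc)
    grip1 = channel(coloc)
    bg1 = rng.normal(bg_mean, bg_sd, (n_spines, profile_len))
    bg2 = rng.normal(bg_mean, bg_sd, (n_spines, profile_len))
    sizes = rng.lognormal(math.log(10.0), 0.5, n_spines)
    return IntensityProfileSet(gfp=gfp, glua2=glua2, grip1=grip1,
                               glua2_background=bg1, grip1_background=bg2,
                               spine_sizes=sizes, truth_coloc=coloc)
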