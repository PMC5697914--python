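"""Two-layer dendritic-nonlinearity model of homeostatic synaptic scaling.

A model neuron consists of ``n_branches`` dendritic branches carrying
``n_syn`` synapses each.  Each branch computes the weighted sum of its
active inputs, normalized by the synapse count, and passes it through a
sigmoidal branch nonlinearity; the branch outputs are averaged (optionally
with per-branch weights) and passed through a somatic sigmoid::

    y = f_n( (1/Nbr) * sum_i  w_ib * f_b( (1/Nsyn) * sum_j w_ij x_ij ) )

with ``f(x) = 1 / (1 + exp(-beta (x - mu)))``.

Sensory deprivation is simulated by zeroing a random subset of synaptic
weights on half of the branches.  Two homeostatic compensations are then
compared:

* **branch-specific** scaling — each deprived branch multiplies its
  surviving weights so that the branch regains its own pre-loss total;
  intact branches are untouched;
* **global** scaling — every surviving weight on the cell is multiplied by
  a single factor restoring the cell-wide total.

Both conditions conserve the cell's total synaptic weight; they differ in
how the compensation is distributed across branches.  The comparison
statistic is the mutual information between the (random) input pattern and
the discretized somatic output.  Because the input->output map is
deterministic and the 1000 input patterns are almost surely distinct, that
mutual information equals the entropy of the binned output distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ModelConfig",
    "WeightMatrix",
    "InputPattern",
    "LossRecord",
    "MIComparison",
    "init_weights",
    "generate_patterns",
    "compute_output",
    "compute_outputs",
    "apply_deprivation",
    "rescale",
    "mutual_information_output",
    "run_experiment",
    "sweep_active_fraction",
]

Condition = Literal["branch_specific", "global"]


class RescaleError(ValueError):
    """A branch lost all of its synapses; the branch-specific factor is undefined."""


@dataclass
class ModelConfig:
    """All symbols of the two-layer model.

    The weight distribution is a lognormal with scale (median) parameter
    ``weight_mean`` and log-space sigma ``weight_sigma``, rejection-resampled
    into ``[weight_min, weight_max]``.  With the defaults the truncated
    sample mean is ~32.7 a.u. (within 10% of ``weight_mean``), which places
    the per-branch operating point at the midpoint of the branch sigmoid —
    the regime in which global scaling pushes branches onto the sigmoid
    plateaus while branch-specific scaling keeps them in the linear range.

    ``active_fraction`` selects how many synapses per branch are active in
    each input pattern (``round(active_fraction * n_syn)``).  The branch sum
    is divided by ``n_syn`` as written in the model equation; with
    ``normalize_by_active=True`` it is divided by the active count instead,
    which keeps the operating point independent of the active fraction and
    is the convention used by :func:`sweep_active_fraction`.
    """

    n_branches: int = 20
    n_syn: int = 15
    input_low: float = 0.5
    input_high: float = 1.5
    weight_mean: float = 30.0
    weight_min: float = 20.0
    weight_max: float = 150.0
    weight_sigma: float = 0.3
    beta_branch: float = 0.7
    mu_branch: float = 33.0
    beta_soma: float = 5.0
    mu_soma: float = 0.5
    branch_weights: np.ndarray | None = None  # w_ib; default all ones
    deprived_branch_fraction: float = 0.5
    loss_prob: float = 0.1
    n_patterns: int = 1000
    n_bins: int = 10
    n_reps: int = 100
    active_fraction: float = 1.0
    normalize_by_active: bool = False
    common_branch_target: bool = False  # branch-specific: common per-branch total
    paired_test: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("input_low", "input_high", "weight_mean", "weight_min",
                     "weight_max", "weight_sigma", "beta_branch", "mu_branch",
                     "beta_soma", "mu_soma", "deprived_branch_fraction",
                     "loss_prob", "active_fraction"):
            v = getattr(self, name)
            if not math.isfinite(float(v)):
                raise ValueError(f"{name} must be finite, got {v!r}")
        for name in ("n_branches", "n_syn", "n_patterns", "n_bins", "n_reps"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.active_fraction <= 1.0:
            raise ValueError("active_fraction must be in (0, 1]")
        if not 0.0 <= self.loss_prob <= 1.0:
            raise ValueError("loss_prob must be in [0, 1]")
        if not 0.0 <= self.deprived_branch_fraction <= 1.0:
            raise ValueError("deprived_branch_fraction must be in [0, 1]")
        if not self.weight_min <= self.weight_mean <= self.weight_max:
            raise ValueError(
                "weight_mean must lie inside [weight_min, weight_max]; got "
                f"{self.weight_mean} outside [{self.weight_min}, {self.weight_max}]"
            )
        if self.input_low > self.input_high:
            raise ValueError("input_low must be <= input_high")
        if self.branch_weights is not None:
            self.branch_weights = np.asarray(self.branch_weights, dtype=float)
            if self.branch_weights.shape != (self.n_branches,):
                raise ValueError("branch_weights must have shape (n_branches,)")

    @property
    def n_active(self) -> int:
        return int(round(self.active_fraction * self.n_syn))

    @property
    def w_ib(self) -> np.ndarray:
        if self.branch_weights is None:
            return np.ones(self.n_branches)
        return self.branch_weights

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["branch_weights"] is not None:
            d["branch_weights"] = list(d["branch_weights"])
        return d


@dataclass
class WeightMatrix:
    """Synaptic weights w_ij with a provenance tag.

    Zeros introduced by deprivation stay zero through any rescaling.
    """

    w: np.ndarray
    provenance: str = "initial"

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 2:
            raise ValueError("weight matrix must be 2-D (branches x synapses)")
        if np.any(self.w < 0):
            raise ValueError("weights must be non-negative")

    @property
    def branch_totals(self) -> np.ndarray:
        return self.w.sum(axis=1)

    @property
    def total(self) -> float:
        return float(self.w.sum())


@dataclass
class InputPattern:
    """One input pattern: values x_ij and the boolean active mask."""

    x: np.ndarray
    active: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.active = np.asarray(self.active, dtype=bool)
        if self.x.shape != self.active.shape:
            raise ValueError("x and active mask must share a shape")


@dataclass
class LossRecord:
    deprived_branches: np.ndarray
    zeroed: list[tuple[int, int]]


@dataclass
class MIComparison:
    """Per-repetition mutual information under both scaling conditions."""

    mi_global: np.ndarray
    mi_branch: np.ndarray
    t_statistic: float
    p_value: float
    paired: bool

    @property
    def mean_global(self) -> float:
        return float(np.mean(self.mi_global))

    @property
    def mean_branch(self) -> float:
        return float(np.mean(self.mi_branch))

    @property
    def sd_global(self) -> float:
        return float(np.std(self.mi_global, ddof=1))

    @property
    def sd_branch(self) -> float:
        return float(np.std(self.mi_branch, ddof=1))

    def to_dict(self) -> dict:
        return {
            "mi_global": [float(v) for v in self.mi_global],
            "mi_branch": [float(v) for v in self.mi_branch],
            "mean_global": self.mean_global,
            "mean_branch": self.mean_branch,
            "sd_global": self.sd_global,
            "sd_branch": self.sd_branch,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "paired": self.paired,
        }


def _sigmoid(x: np.ndarray | float, beta: float, mu: float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-beta * (np.asarray(x, dtype=float) - mu)))


def init_weights(config: ModelConfig, rng: np.random.Generator) -> WeightMatrix:
    """Draw the Nbr x Nsyn weight matrix.

    Lognormal with scale ``weight_mean`` and sigma ``weight_sigma``,
    rejection-resampled into ``[weight_min, weight_max]``.  The degenerate
    range ``weight_min == weight_max`` yields constant weights.
    """
    n = config.n_branches * config.n_syn
    lo, hi = config.weight_min, config.weight_max
    if lo == hi:
        return WeightMatrix(np.full((config.n_branches, config.n_syn), lo))
    mu_log = math.log(config.weight_mean)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu_log, config.weight_sigma, size=2 * (n - filled) + 16)
        draw = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled : filled + draw.size] = draw
        filled += draw.size
    return WeightMatrix(out.reshape(config.n_branches, config.n_syn))


def generate_patterns(config: ModelConfig, rng: np.random.Generator,
                      n_patterns: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Draw input patterns.

    Returns ``(x, active)`` with shapes ``(n_patterns, Nbr, Nsyn)``; values
    are uniform on ``[input_low, input_high]`` and exactly
    ``round(active_fraction * Nsyn)`` synapses per branch are active.
    """
    npat = config.n_patterns if n_patterns is None else n_patterns
    shape = (npat, config.n_branches, config.n_syn)
    x = rng.uniform(config.input_low, config.input_high, size=shape)
    if config.n_active >= config.n_syn:
        active = np.ones(shape, dtype=bool)
    else:
        # first n_active slots of a random permutation per (pattern, branch)
        active = np.argsort(rng.random(shape), axis=2) < config.n_active
    return x, active


def compute_output(weights: WeightMatrix | np.ndarray, pattern: InputPattern,
                   config: ModelConfig) -> float:
    """Somatic output y for a single input pattern (scalar in (0, 1))."""
    w = weights.w if isinstance(weights, WeightMatrix) else np.asarray(weights, float)
    if w.shape != pattern.x.shape:
        raise ValueError(
            f"shape mismatch: weights {w.shape} vs pattern {pattern.x.shape}"
        )
    y = compute_outputs(w, pattern.x[None], pattern.active[None], config)
    return float(y[0])


def compute_outputs(w: np.ndarray, x: np.ndarray, active: np.ndarray,
                    config: ModelConfig) -> np.ndarray:
    """Vectorized somatic outputs for a batch of patterns.

    ``x`` and ``active`` have shape ``(n_patterns, Nbr, Nsyn)``.
    """
    xa = np.where(active, x, 0.0)
    denom = config.n_active if config.normalize_by_active else config.n_syn
    s = np.einsum("pij,ij->pi", xa, w) / denom
    b = _sigmoid(s, config.beta_branch, config.mu_branch)
    a = (b * config.w_ib).sum(axis=1) / config.n_branches
    return _sigmoid(a, config.beta_soma, config.mu_soma)


def apply_deprivation(weights: WeightMatrix, config: ModelConfig,
                      rng: np.random.Generator) -> tuple[WeightMatrix, LossRecord]:
    """Zero synapses on a random subset of branches.

    Exactly ``round(deprived_branch_fraction * Nbr)`` branches are selected;
    on each, every synapse is zeroed independently with ``loss_prob``.
    """
    if weights.provenance != "initial":
        raise ValueError("deprivation applies to the initial weight matrix")
    n_depr = int(round(config.deprived_branch_fraction * config.n_branches))
    deprived = np.sort(rng.choice(config.n_branches, size=n_depr, replace=False))
    w = weights.w.copy()
    zeroed: list[tuple[int, int]] = []
    if n_depr:
        lost = rng.random((n_depr, config.n_syn)) < config.loss_prob
        for k, i in enumerate(deprived):
            js = np.nonzero(lost[k])[0]
            w[i, js] = 0.0
            zeroed.extend((int(i), int(j)) for j in js)
    return WeightMatrix(w, provenance="post_loss"), LossRecord(deprived, zeroed)


def rescale(post_loss: WeightMatrix, initial: WeightMatrix,
            condition: Condition, *, common_branch_target: bool = False) -> WeightMatrix:
    """Homeostatically rescale surviving weights.

    branch_specific
        Each branch whose total dropped multiplies its surviving weights by
        (initial branch total) / (post-loss branch total); intact branches
        are returned bit-identical.  With ``common_branch_target=True`` every
        branch is instead driven to the common target total
        (cell total / Nbr).
    global
        Every surviving weight is multiplied by
        (initial cell total) / (post-loss cell total).

    Zeros stay zero in both conditions and the cell total equals the initial
    total to floating tolerance.
    """
    if condition not in ("branch_specific", "global"):
        raise ValueError(f"unknown condition {condition!r}")
    w0, w1 = initial.w, post_loss.w
    if w0.shape != w1.shape:
        raise ValueError("initial and post-loss matrices must share a shape")
    if condition == "global":
        factor = w0.sum() / w1.sum()
        return WeightMatrix(w1 * factor, provenance="rescaled(global)")

    init_tot = w0.sum(axis=1)
    post_tot = w1.sum(axis=1)
    target = (np.full_like(init_tot, w0.sum() / w0.shape[0])
              if common_branch_target else init_tot)
    out = w1.copy()
    for i in range(w0.shape[0]):
        if not common_branch_target and post_tot[i] == init_tot[i]:
            continue  # intact branch: bit-identical
        if post_tot[i] == 0.0:
            raise RescaleError(
                f"branch {i} lost all synapses; branch-specific factor undefined"
            )
        out[i] *= target[i] / post_tot[i]
    return WeightMatrix(out, provenance="rescaled(branch_specific)")


def mutual_information_output(y_values: Sequence[float] | np.ndarray,
                              n_bins: int) -> float:
    """Mutual information (bits) between stimulus and discretized output.

    Outputs are binned into ``n_bins`` equal-width bins on [0, 1], the
    codomain of the somatic sigmoid.  The input->output map is deterministic
    and input patterns are almost surely distinct, so the mutual information
    reduces to the entropy of the binned output distribution.
    """
    y = np.asarray(y_values, dtype=float)
    if y.size == 0:
        raise ValueError("mutual information of an empty output set is undefined")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    counts, _ = np.histogram(y, bins=n_bins, range=(0.0, 1.0))
    p = counts[counts > 0] / y.size
    return float(-(p * np.log2(p)).sum())


def _one_repetition(config: ModelConfig, rng: np.random.Generator) -> tuple[float, float]:
    w0 = init_weights(config, rng)
    post, _ = apply_deprivation(w0, config, rng)
    w_branch = rescale(post, w0, "branch_specific",
                       common_branch_target=config.common_branch_target)
    w_global = rescale(post, w0, "global")
    x, active = generate_patterns(config, rng)
    mi_b = mutual_information_output(
        compute_outputs(w_branch.w, x, active, config), config.n_bins)
    mi_g = mutual_information_output(
        compute_outputs(w_global.w, x, active, config), config.n_bins)
    return mi_g, mi_b


def run_experiment(config: ModelConfig,
                   rng: np.random.Generator | None = None) -> MIComparison:
    """Run the full scaling-condition comparison.

    Each repetition draws fresh weights, a fresh loss pattern shared by both
    rescaling conditions, and a fresh set of input patterns shared by both
    conditions; the mutual information is computed per condition and the two
    per-repetition samples are compared with a t test (Welch by default,
    paired if ``config.paired_test``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mi_g = np.empty(config.n_reps)
    mi_b = np.empty(config.n_reps)
    for r in range(config.n_reps):
        mi_g[r], mi_b[r] = _one_repetition(config, rng)
    if config.paired_test:
        t, p = stats.ttest_rel(mi_b, mi_g)
    else:
        t, p = stats.ttest_ind(mi_b, mi_g, equal_var=False)
    return MIComparison(mi_global=mi_g, mi_branch=mi_b,
                        t_statistic=float(t), p_value=float(p),
                        paired=config.paired_test)


def sweep_active_fraction(config: ModelConfig, fractions: Sequence[float],
                          seed: int | None = None) -> list[dict]:
    """Re-run the experiment across active fractions.

    The sweep normalizes branch sums by the active synapse count so that the
    dendritic operating point stays fixed while the fraction varies; this
    checks the robustness of the branch-vs-global direction to the
    (unreported) fraction of simultaneously active inputs.
    """
    results = []
    for f in fractions:
        cfg = ModelConfig(**{**config.to_dict(),
                             "active_fraction": f,
                             "normalize_by_active": True,
                             "seed": config.seed if seed is None else seed})
        cmp_ = run_experiment(cfg)
        results.append({"active_fraction": f,
                        "mean_branch": cmp_.mean_branch,
                        "mean_global": cmp_.mean_global,
                        "t_statistic": cmp_.t_statistic,
                        "p_value": cmp_.p_value})
    return results
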