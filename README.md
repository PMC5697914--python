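# dendroscale

Analysis toolkit for **branch-specific homeostatic synaptic scaling**:
when sensory deprivation removes synaptic input, neurons strengthen their
remaining synapses — and this compensation can be confined to the
dendritic branches that actually lost input rather than applied cell-wide.
dendroscale implements the computational machinery for studying that
question: a two-layer dendritic-nonlinearity model that compares the two
scaling regimes by information capacity, longitudinal spine-census
statistics, multiplicative mEPSC scaling fits, dendritic calcium event
analysis, and synthetic-data generators so the whole pipeline runs without
any experimental data. It is aimed at systems neuroscientists analyzing
longitudinal two-photon spine imaging, patch-clamp mEPSC recordings, or
dendritic calcium imaging.

## The model

A model neuron has N_br = 20 branches with N_syn = 15 synapses each.
Inputs x_ij ~ U(0.5, 1.5) drive the somatic output

    y = f_n( (1/N_br) Σ_i w_ib · f_b( (1/N_syn) Σ_j w_ij x_ij ) ),
    f(x) = 1 / (1 + e^(−β(x−μ)))

with a branch nonlinearity (β = 0.7, μ = 33) and a somatic nonlinearity
(β = 5, μ = 0.5). Weights are lognormal on [20, 150] a.u. Deprivation
zeroes ~10% of the weights on half of the branches; compensation either
restores each deprived branch's own total (*branch-specific*) or rescales
every surviving weight by one cell-wide factor (*global*) — both conserve
the cell's total synaptic weight. Because the input→output map is
deterministic, the mutual information between the input pattern and the
10-bin discretized output is the entropy of the output distribution; 100
repetitions of 1000 patterns give an MI sample per condition, compared by
a t test. Branch-specific scaling keeps every branch in the linear range
of its sigmoid and carries reliably more information than global scaling,
which pushes intact branches toward the high plateau and deprived ones
toward the low plateau.

The other modules implement the self-defined statistics of the same
experimental program: per-spine size normalization to baseline and the
joint mean/fraction criterion for "increasing" branches (with a
control-percentile derivation and a resampling chance level), spatial
clustering of increasing and lost spines against position-shuffle and
different-branch nulls, per-branch density-vs-size relations,
Kolmogorov–Smirnov grid fits of 100% or 50% multiplicative mEPSC scaling,
rolling-percentile ΔF/F₀ detrending with branch-specific calcium event
detection, and the 2-SD GluA2/GRIP1 co-localization rule.
See `docs/methods.md` for the full specification of every estimator.

## Worked example

```python
>>> from dendroscale.model import ModelConfig, run_experiment
>>> res = run_experiment(ModelConfig(seed=1))
>>> print(f"MI branch-specific {res.mean_branch:.3f} ± {res.sd_branch:.3f} bits")
MI branch-specific 1.645 ± 0.087 bits
>>> print(f"MI global          {res.mean_global:.3f} ± {res.sd_global:.3f} bits")
MI global          1.547 ± 0.080 bits
>>> print(f"Welch t = {res.t_statistic:.2f}, p = {res.p_value:.1e}")
Welch t = 8.27, p = 2.0e-14
```

Across 100 repetitions the branch-specific condition retains ~0.1 bit more
stimulus information than global scaling, a difference of about one
within-condition standard deviation and overwhelmingly significant — the
local compensation preserves the cell's input–output resolution.

The full synthetic pipeline (generation, model, spine statistics, mEPSC
fits, calcium analysis) runs from the command line with a single seed and
writes JSON summaries plus a manifest:

```bash
dendroscale all --seed 7 --out results_run
dendroscale spines --seed 7 --out results_run   # single stage
```

For example, `spines_analysis.json` from seed 7 reports the thresholds
derived from the synthetic control (size 1.125, fraction 0.254), the
fraction of deprived branches classified increasing (0.37) against its
chance level (0.05 ± 0.04), and the negative branch-wise density–size
rank correlation (ρ = −0.82) that the loss-coupled generator builds in.

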