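"""End-to-end synthetic pipeline: generate -> analyze -> report.

A single YAML/JSON config with per-stage blocks drives every stage; all
randomness derives from the mandatory global seed, so a fixed (config,
seed) pair reproduces every output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, io
from .calcium import activity_integral, branch_specific_fraction, detrend_dff, \
    event_summary, pair_similarity
from .mepsc import compare_fraction_models
from .model import ModelConfig, run_experiment
from .spines import ClassificationCriteria, chance_increasing_fraction, \
    classify_branches, cluster_profile, coloc_summary, colocalized_glua2, \
    density_size_relation, derive_thresholds, lost_spine_nn, normalize_sizes
from .synthetic import CalciumGenParams, MepscGenParams, SpineGenParams, \
    gen_calcium_pair, gen_intensity_profiles, gen_mepsc_samples, gen_spine_dataset

logger = logging.getLogger(__name__)

STAGES = ("generate", "model", "spines", "mepsc", "calcium")

_STAGE_BLOCKS = {
    "stages", "seed",
    "spine_gen", "mepsc_gen", "calcium_gen", "profiles_gen",
    "model", "spines", "mepsc", "calcium",
}


class ConfigError(ValueError):
    """The run configuration is invalid; nothing was computed."""


class StageError(RuntimeError):
    """A pipeline stage failed."""


@dataclass
class RunConfig:
    stages: list[str]
    seed: int
    blocks: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _STAGE_BLOCKS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ConfigError("a global seed is mandatory")
        stages = raw.get("stages", ["all"])
        if stages == ["all"] or stages == "all":
            stages = list(STAGES)
        bad = [s for s in stages if s not in STAGES]
        if bad:
            raise ConfigError(f"unknown stages: {bad}")
        blocks = {k: v for k, v in raw.items() if k not in ("stages", "seed")}
        for name, params_cls in (("spine_gen", SpineGenParams),
                                 ("mepsc_gen", MepscGenParams),
                                 ("calcium_gen", CalciumGenParams),
                                 ("model", ModelConfig)):
            blk = blocks.get(name, {})
            known = set(params_cls.__dataclass_fields__)
            unknown = set(blk) - known
            if unknown:
                raise ConfigError(f"unknown keys in block {name!r}: {sorted(unknown)}")
        return cls(stages=list(stages), seed=int(raw["seed"]), blocks=blocks)


def _stage_seed(seed: int, stage: str) -> int:
    # stable per-stage derivation, independent of stage selection
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(raw_config: dict, out_dir) -> dict:
    """Execute the selected stages and write a run manifest.

    Returns the manifest (also written to ``manifest.json``): package
    version, per-stage seeds, and every output file with its SHA-256.
    """
    config = RunConfig.from_dict(raw_config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}, "outputs": {}}

    def record(stage: str, name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}
        manifest["stages"].setdefault(stage, []).append(name)

    for stage in config.stages:
        seed = _stage_seed(config.seed, stage)
        manifest.setdefault("stage_seeds", {})[stage] = seed
        try:
            _run_stage(stage, seed, config, out, record)
        except (ConfigError, ValueError, KeyError) as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
    io.write_json(manifest, out / "manifest.json")
    return manifest


def _gen_spines(config: RunConfig, seed: int):
    blk = dict(config.blocks.get("spine_gen", {}))
    blk.setdefault("seed", seed)
    deprived = gen_spine_dataset(SpineGenParams(**{**blk, "deprived": True}))
    control = gen_spine_dataset(SpineGenParams(**{**blk, "deprived": False,
                                                  "seed": blk["seed"] + 1}))
    return control, deprived


def _run_stage(stage: str, seed: int, config: RunConfig, out: Path, record) -> None:
    if stage == "generate":
        (control, _), (deprived, truth) = _gen_spines(config, seed)
        control.to_csv(out / "spines_control.tsv")
        deprived.to_csv(out / "spines_deprived.tsv")
        io.write_json({"branches": truth.branches}, out / "spines_truth.json")
        record(stage, "spines_control", out / "spines_control.tsv")
        record(stage, "spines_deprived", out / "spines_deprived.tsv")
        record(stage, "spines_truth", out / "spines_truth.json")

        blk = dict(config.blocks.get("mepsc_gen", {}))
        blk.setdefault("seed", seed)
        ctrl, depr = gen_mepsc_samples(MepscGenParams(**blk))
        io.write_mepsc_table([ctrl, depr], out / "mepsc_events.tsv")
        record(stage, "mepsc_events", out / "mepsc_events.tsv")

        blk = dict(config.blocks.get("calcium_gen", {}))
        blk.setdefault("seed", seed)
        rec_, log = gen_calcium_pair(CalciumGenParams(**blk))
        io.write_calcium_bundle(rec_, out / "calcium_bundle.json")
        log.to_csv(out / "calcium_truth.tsv", sep="\t", index=False)
        record(stage, "calcium_bundle", out / "calcium_bundle.json")
        record(stage, "calcium_truth", out / "calcium_truth.tsv")

    elif stage == "model":
        blk = dict(config.blocks.get("model", {}))
        blk.setdefault("seed", seed)
        result = run_experiment(ModelConfig(**blk))
        io.write_json(result.to_dict(), out / "model_mi.json")
        record(stage, "model_mi", out / "model_mi.json")

    elif stage == "spines":
        opts = dict(config.blocks.get("spines", {}))
        n_shuffles = int(opts.pop("n_shuffles", 1000))
        if opts:
            raise ConfigError(f"unknown keys in block 'spines': {sorted(opts)}")
        rng = np.random.default_rng(seed)
        (control, _), (deprived, truth) = _gen_spines(config, _stage_seed(config.seed, "generate"))
        eval_tp = float(deprived.timepoints[-1])
        control = normalize_sizes(control)
        deprived = normalize_sizes(deprived)
        crit = derive_thresholds(control, eval_tp)
        classes = classify_branches(deprived, eval_tp, crit)
        pop = deprived.at_timepoint(eval_tp)["size_norm"].dropna().to_numpy()
        chance_mean, chance_sd, _ = chance_increasing_fraction(pop, crit, rng=rng)
        profile = cluster_profile(deprived, eval_tp, crit, rng=rng,
                                  n_shuffles=n_shuffles)
        lo, hi = profile.shuffled_band()
        density = density_size_relation(deprived, eval_tp)
        nn = lost_spine_nn(deprived, rng=rng, n_shuffles=n_shuffles)
        profiles = gen_intensity_profiles(100, 0.5, 6.0, seed=seed)
        coloc = colocalized_glua2(profiles)
        io.write_json({
            "criteria": {"size_threshold": crit.size_threshold,
                         "fraction_threshold": crit.fraction_threshold},
            "classification": classes,
            "fraction_increasing": float((classes["classification"] == "increasing").mean()),
            "chance_increasing": {"mean": chance_mean, "sd": chance_sd},
            "cluster": {"bin_edges": profile.bin_edges,
                        "observed": profile.observed_fraction,
                        "population": profile.population_fraction,
                        "shuffle_lo": lo, "shuffle_hi": hi,
                        "db_probability": profile.db_probability},
            "density_size": {"rho": density["rho"], "p_value": density["p_value"]},
            "lost_spine_nn": {"observed_mean": nn.observed_mean,
                              "shuffled_mean": float(np.nanmean(nn.shuffled_means))},
            "coloc": coloc_summary(coloc),
        }, out / "spines_analysis.json")
        record(stage, "spines_analysis", out / "spines_analysis.json")

    elif stage == "mepsc":
        opts = dict(config.blocks.get("mepsc", {}))
        n_resamples = int(opts.pop("n_resamples", 100))
        if opts:
            raise ConfigError(f"unknown keys in block 'mepsc': {sorted(opts)}")
        blk = dict(config.blocks.get("mepsc_gen", {}))
        blk.setdefault("seed", _stage_seed(config.seed, "generate"))
        ctrl, depr = gen_mepsc_samples(MepscGenParams(**blk))
        rng = np.random.default_rng(seed)
        report = compare_fraction_models(ctrl.amplitudes, depr.amplitudes,
                                         rng=rng, n_resamples=n_resamples)
        io.write_json(report.to_dict(), out / "mepsc_fit.json")
        record(stage, "mepsc_fit", out / "mepsc_fit.json")

    elif stage == "calcium":
        opts = dict(config.blocks.get("calcium", {}))
        if opts and set(opts) - {"threshold_pct", "simultaneity_window_s"}:
            raise ConfigError(f"unknown keys in block 'calcium': {sorted(opts)}")
        blk = dict(config.blocks.get("calcium_gen", {}))
        blk.setdefault("seed", _stage_seed(config.seed, "generate"))
        rec_, _ = gen_calcium_pair(CalciumGenParams(**blk))
        dffs = {roi: detrend_dff(tr, rec_.rate_hz)
                for roi, tr in rec_.traces.items()}
        integrals = {roi: activity_integral(d, rec_.rate_hz)
                     for roi, d in dffs.items()}
        b1 = integrals["branch1"]
        sims = {roi: pair_similarity(dffs["branch1"], dffs[roi])
                for roi in ("branch2", "within_branch1", "different_cell")}
        bs = branch_specific_fraction(rec_, **opts)
        events = bs.pop("events")
        io.write_json({
            "activity_integrals": integrals,
            "normalized_to_branch1": {roi: v / b1 for roi, v in integrals.items()},
            "similarity": {roi: {"pearson_r": r, "mi_bits": mi}
                           for roi, (r, mi) in sims.items()},
            "branch_specific": bs,
            "event_summary": event_summary(events, rec_.duration_s),
        }, out / "calcium_analysis.json")
        record(stage, "calcium_analysis", out / "calcium_analysis.json")

    else:  # pragma: no cover
        raise ConfigError(f"unknown stage {stage!r}")
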