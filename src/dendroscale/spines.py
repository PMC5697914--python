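"""Dendritic spine census statistics.

Spine size is measured as integrated brightness (background-subtracted,
normalized to the adjacent dendrite) and expressed per spine relative to
its own pre-deprivation baseline.  A branch counts as *increasing* when its
mean normalized spine size reaches a threshold (default 1.1) AND more than
a threshold fraction (default 45%) of its spines individually exceed the
size threshold — the joint criterion guards against single large outlier
spines.  Both thresholds correspond to the 90th percentile of control
distributions and can be re-derived from any control dataset.

The module also implements the chance-level bootstrap for increasing
branches, the spatial cluster analysis of increasing spines with its
position-shuffle and different-branch nulls, nearest-neighbor clustering of
lost spines, the per-branch density-vs-size relation, and the
GluA2/GRIP1 co-localization rule for immunostained spines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SpineDataset",
    "ClassificationCriteria",
    "ClusterProfile",
    "IntensityProfileSet",
    "normalize_sizes",
    "size_from_intensity",
    "classify_branch",
    "classify_branches",
    "derive_thresholds",
    "chance_increasing_fraction",
    "cluster_profile",
    "lost_spine_nn",
    "density_size_relation",
    "colocalized_glua2",
]

SPINE_COLUMNS = ["cell_id", "branch_id", "spine_id", "position_um",
                 "timepoint_hr", "size", "fate"]


@dataclass
class SpineDataset:
    """Tidy longitudinal spine census.

    One row per spine x timepoint at which the spine exists.  Columns:
    cell_id, branch_id, spine_id, position_um, timepoint_hr, size, fate
    (``stable``, ``lost`` or ``new``); ``size_norm`` is added by
    :func:`normalize_sizes`.  Positions are constant per spine and strictly
    increasing along each branch.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SPINE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"spine table is missing columns: {missing}")
        self.validate()

    def validate(self) -> None:
        pos = (self.df.groupby(["cell_id", "branch_id", "spine_id"])["position_um"]
               .nunique())
        if (pos > 1).any():
            raise ValueError("spine positions must be constant over time")
        for (c, b), grp in self.df.groupby(["cell_id", "branch_id"]):
            p = (grp.drop_duplicates("spine_id")
                    .sort_values("spine_id")["position_um"].to_numpy())
            if np.any(np.diff(np.sort(p)) <= 0):
                raise ValueError(
                    f"positions on cell {c} branch {b} are not strictly increasing")

    @property
    def timepoints(self) -> np.ndarray:
        return np.sort(self.df["timepoint_hr"].unique())

    def spine_table(self) -> pd.DataFrame:
        """One row per spine: identity, position and fate."""
        return (self.df.drop_duplicates(["cell_id", "branch_id", "spine_id"])
                [["cell_id", "branch_id", "spine_id", "position_um", "fate"]]
                .reset_index(drop=True))

    def at_timepoint(self, timepoint: float) -> pd.DataFrame:
        return self.df[self.df["timepoint_hr"] == timepoint]

    def to_csv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_csv(cls, path) -> "SpineDataset":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class ClassificationCriteria:
    """Thresholds for the increasing-branch classification."""

    size_threshold: float = 1.1
    fraction_threshold: float = 0.45
    same_band: tuple[float, float] = (0.9, 1.1)

    def __post_init__(self) -> None:
        if not self.size_threshold > 1.0:
            raise ValueError("size_threshold must exceed 1")
        if not 0.0 < self.fraction_threshold < 1.0:
            raise ValueError("fraction_threshold must be in (0, 1)")


def size_from_intensity(spine_integrated: float, background: float,
                        dendrite_intensity: float) -> float:
    """Spine size: background-subtracted integrated brightness over dendrite."""
    if dendrite_intensity <= 0:
        raise ValueError("dendrite intensity must be positive")
    return (spine_integrated - background) / dendrite_intensity


def normalize_sizes(dataset: SpineDataset,
                    baseline_timepoints: Sequence[float] | None = None,
                    log10: bool = False) -> SpineDataset:
    """Normalize each spine's size to its own baseline mean.

    Baseline defaults to all timepoints <= 0 h.  Spines with a zero or
    missing baseline are excluded (size_norm left NaN) with a log entry.
    With ``log10=True`` an additional ``size_norm_log10`` column is added
    for downstream statistics.
    """
    df = dataset.df.copy()
    if baseline_timepoints is None:
        baseline_timepoints = [t for t in dataset.timepoints if t <= 0]
    if not len(baseline_timepoints):
        raise ValueError("no baseline timepoints")
    base = (df[df["timepoint_hr"].isin(baseline_timepoints)]
            .groupby(["cell_id", "branch_id", "spine_id"])["size"].mean()
            .rename("baseline"))
    df = df.merge(base, on=["cell_id", "branch_id", "spine_id"], how="left")
    bad = df["baseline"].isna() | (df["baseline"] <= 0)
    n_bad = df.loc[bad].drop_duplicates(["cell_id", "branch_id", "spine_id"]).shape[0]
    if n_bad:
        logger.info("excluded %d spines with zero/missing baseline", n_bad)
    df["size_norm"] = np.where(bad, np.nan, df["size"] / df["baseline"])
    if log10:
        df["size_norm_log10"] = np.log10(df["size_norm"])
    return SpineDataset(df.drop(columns="baseline"))


def classify_branch(normalized_sizes: Sequence[float] | np.ndarray,
                    criteria: ClassificationCriteria | None = None
                    ) -> Literal["increasing", "same", "decreasing"]:
    """Classify one branch from its surviving spines' normalized sizes.

    increasing: mean >= size_threshold and more than fraction_threshold of
    spines strictly exceed size_threshold.  Otherwise *decreasing* when the
    mean falls below the lower edge of the same-band, else *same*.
    """
    crit = criteria or ClassificationCriteria()
    sizes = np.asarray(normalized_sizes, dtype=float)
    sizes = sizes[~np.isnan(sizes)]
    if sizes.size == 0:
        raise ValueError("empty branch: unclassifiable")
    mean = sizes.mean()
    frac = (sizes > crit.size_threshold).mean()
    if mean >= crit.size_threshold and frac > crit.fraction_threshold:
        return "increasing"
    if mean < crit.same_band[0]:
        return "decreasing"
    return "same"


def classify_branches(dataset: SpineDataset, timepoint: float,
                      criteria: ClassificationCriteria | None = None
                      ) -> pd.DataFrame:
    """Per-branch classification at one evaluation timepoint."""
    rows = []
    snap = dataset.at_timepoint(timepoint)
    for (c, b), grp in snap.groupby(["cell_id", "branch_id"]):
        sizes = grp["size_norm"].dropna().to_numpy()
        if sizes.size == 0:
            logger.info("cell %s branch %s unclassifiable (no surviving spines)", c, b)
            rows.append({"cell_id": c, "branch_id": b, "n_spines": 0,
                         "mean_size_norm": np.nan, "fraction_increasing": np.nan,
                         "classification": "unclassifiable"})
            continue
        crit = criteria or ClassificationCriteria()
        rows.append({
            "cell_id": c, "branch_id": b, "n_spines": sizes.size,
            "mean_size_norm": sizes.mean(),
            "fraction_increasing": (sizes > crit.size_threshold).mean(),
            "classification": classify_branch(sizes, crit),
        })
    return pd.DataFrame(rows)


def derive_thresholds(control: SpineDataset, timepoint: float) -> ClassificationCriteria:
    """Derive classification thresholds from a control dataset.

    size_threshold: 90th percentile of control per-spine normalized sizes.
    fraction_threshold: 90th percentile of the per-branch fraction of spines
    exceeding that size threshold.
    """
    snap = control.at_timepoint(timepoint)
    sizes = snap["size_norm"].dropna().to_numpy()
    if sizes.size < 10:
        raise ValueError("need at least 10 control spines to derive thresholds")
    size_thr = float(np.percentile(sizes, 90))
    if size_thr <= 1.0:
        logger.warning("degenerate control distribution: 90th percentile %.3f <= 1",
                       size_thr)
        crit = object.__new__(ClassificationCriteria)
        crit.size_threshold = size_thr
        crit.fraction_threshold = 0.45
        crit.same_band = (0.9, 1.1)
        return crit
    fracs = (snap.dropna(subset=["size_norm"])
             .groupby(["cell_id", "branch_id"])["size_norm"]
             .apply(lambda s: (s.to_numpy() > size_thr).mean()))
    frac_thr = float(np.percentile(fracs.to_numpy(), 90))
    frac_thr = min(max(frac_thr, 1e-6), 1 - 1e-6)
    return ClassificationCriteria(size_threshold=size_thr,
                                  fraction_threshold=frac_thr,
                                  same_band=(2 - size_thr, size_thr))


def chance_increasing_fraction(population: Sequence[float] | np.ndarray,
                               criteria: ClassificationCriteria | None = None,
                               n_datasets: int = 100, n_branches: int = 30,
                               n_spines: int = 25,
                               rng: np.random.Generator | None = None
                               ) -> tuple[float, float, np.ndarray]:
    """Chance level of increasing branches given the pooled spine population.

    Builds ``n_datasets`` sets of ``n_branches`` simulated branches of
    ``n_spines`` spines resampled with replacement from the population, and
    returns (mean, sd, per-dataset fractions) of the proportion of simulated
    branches meeting the increasing criteria.
    """
    crit = criteria or ClassificationCriteria()
    pop = np.asarray(population, dtype=float)
    pop = pop[~np.isnan(pop)]
    if pop.size == 0:
        raise ValueError("empty population")
    if rng is None:
        rng = np.random.default_rng()
    draws = rng.choice(pop, size=(n_datasets, n_branches, n_spines), replace=True)
    means = draws.mean(axis=2)
    fracs = (draws > crit.size_threshold).mean(axis=2)
    increasing = (means >= crit.size_threshold) & (fracs > crit.fraction_threshold)
    per_dataset = increasing.mean(axis=1)
    return float(per_dataset.mean()), float(per_dataset.std(ddof=1)), per_dataset


@dataclass
class ClusterProfile:
    """Distance-binned co-increase profile with its null conditions."""

    bin_edges: np.ndarray                  # um, half-open [k*w, (k+1)*w)
    observed_fraction: np.ndarray          # per bin
    observed_counts: np.ndarray            # neighbor counts per bin
    population_fraction: np.ndarray        # all spines as Sp0
    shuffled_fractions: np.ndarray         # (n_shuffles, n_bins)
    db_probability: float                  # different-branch condition
    n_seed_spines: int

    def shuffled_band(self, lower: float = 2.5, upper: float = 97.5
                      ) -> tuple[np.ndarray, np.ndarray]:
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            lo = np.nanpercentile(self.shuffled_fractions, lower, axis=0)
            hi = np.nanpercentile(self.shuffled_fractions, upper, axis=0)
        return lo, hi


def _branch_arrays(dataset: SpineDataset, timepoint: float):
    """Per-branch (cell_id, positions, increase flags, norm sizes) at a timepoint."""
    snap = dataset.at_timepoint(timepoint).dropna(subset=["size_norm"])
    out = []
    for (c, b), grp in snap.groupby(["cell_id", "branch_id"]):
        grp = grp.sort_values("position_um")
        out.append((c, b, grp["position_um"].to_numpy(),
                    grp["size_norm"].to_numpy()))
    return out


def _seed_flags(sizes: np.ndarray, crit: ClassificationCriteria,
                seed_type: str) -> np.ndarray:
    if seed_type == "increasing":
        return sizes > crit.size_threshold
    if seed_type == "all":
        return np.ones_like(sizes, dtype=bool)
    if seed_type == "same":
        return (sizes >= crit.same_band[0]) & (sizes <= crit.size_threshold)
    if seed_type == "decreasing":
        return sizes < crit.same_band[0]
    raise ValueError(f"unknown seed_type {seed_type!r}")


def cluster_profile(dataset: SpineDataset, timepoint: float,
                    criteria: ClassificationCriteria | None = None,
                    bin_width_um: float = 4.0,
                    seed_type: str = "increasing",
                    rng: np.random.Generator | None = None,
                    n_shuffles: int = 1000,
                    n_db_resamples: int = 10) -> ClusterProfile:
    """Fraction of neighbors that increased, by distance from seed spines.

    For every seed spine Sp0 (of ``seed_type``), neighbors on the same
    branch are assigned to half-open distance bins of ``bin_width_um``
    (distance measured along the dendrite between attachment points; Sp0
    itself excluded) and the fraction of neighbors exceeding the size
    threshold is pooled over branches.  Null conditions: a position-shuffle
    permutation null that preserves each branch's position multiset and
    spine count, and a different-branch (DB) probability from
    ``n_db_resamples`` resamples per Sp0 of single spines on other branches
    of the same cell.
    """
    crit = criteria or ClassificationCriteria()
    if rng is None:
        rng = np.random.default_rng()
    branches = _branch_arrays(dataset, timepoint)
    usable = []
    for c, b, pos, sizes in branches:
        if pos.size < 2:
            logger.info("cell %s branch %s skipped (<2 spines)", c, b)
            continue
        usable.append((c, b, pos, sizes))
    if not usable:
        raise ValueError("no branch with >= 2 spines")

    max_d = max(p.max() - p.min() for _, _, p, _ in usable)
    n_bins = max(1, int(math.floor(max_d / bin_width_um)) + 1)
    edges = np.arange(n_bins + 1) * bin_width_um

    num_obs = np.zeros(n_bins)
    den_obs = np.zeros(n_bins)
    num_pop = np.zeros(n_bins)
    den_pop = np.zeros(n_bins)
    num_sh = np.zeros((n_shuffles, n_bins))
    den_sh = np.zeros((n_shuffles, n_bins))
    n_seed_total = 0
    db_vals = []

    cells: dict = {}
    for c, b, pos, sizes in usable:
        cells.setdefault(c, []).append((b, sizes))

    for c, b, pos, sizes in usable:
        g = sizes > crit.size_threshold          # neighbor increased
        s = _seed_flags(sizes, crit, seed_type)  # seed spines
        n = pos.size
        n_seed_total += int(s.sum())
        d = np.abs(pos[:, None] - pos[None, :])
        bins = np.floor(d / bin_width_um).astype(int)
        np.fill_diagonal(bins, -1)               # Sp0 excluded from its own bins
        sf, gf = s.astype(float), g.astype(float)
        # per-bin incidence matrices
        for k in range(n_bins):
            M = (bins == k).astype(float)
            num_obs[k] += float(sf @ M @ gf)
            den_obs[k] += float(sf @ M.sum(axis=1))
            num_pop[k] += float((M @ gf).sum())
            den_pop[k] += float(M.sum())
        # position-shuffle null: permute spine identities on the fixed positions
        if s.any():
            perms = np.argsort(rng.random((n_shuffles, n)), axis=1)
            Sp = s[perms].astype(float)          # (S, n)
            Gp = g[perms].astype(float)
            for k in range(n_bins):
                M = (bins == k).astype(float)
                num_sh[:, k] += np.einsum("sn,nm,sm->s", Sp, M, Gp)
                den_sh[:, k] += Sp @ M.sum(axis=1)
        # different-branch condition
        others = [flags for (b2, sz) in cells[c] if b2 != b
                  for flags in [sz > crit.size_threshold]]
        if others and s.any():
            other_flags = np.concatenate(others)
            for _ in range(int(s.sum())):
                draws = rng.choice(other_flags, size=n_db_resamples, replace=True)
                db_vals.append(draws.mean())

    with np.errstate(invalid="ignore"):
        obs = np.where(den_obs > 0, num_obs / np.maximum(den_obs, 1), np.nan)
        pop = np.where(den_pop > 0, num_pop / np.maximum(den_pop, 1), np.nan)
        sh = np.where(den_sh > 0, num_sh / np.maximum(den_sh, 1), np.nan)
    db = float(np.mean(db_vals)) if db_vals else float("nan")
    return ClusterProfile(bin_edges=edges, observed_fraction=obs,
                          observed_counts=den_obs, population_fraction=pop,
                          shuffled_fractions=sh, db_probability=db,
                          n_seed_spines=n_seed_total)


@dataclass
class LostSpineNN:
    observed: np.ndarray            # pooled nearest-neighbor distances, um
    shuffled_means: np.ndarray      # mean NN distance per shuffle

    @property
    def observed_mean(self) -> float:
        return float(np.mean(self.observed)) if self.observed.size else float("nan")


def lost_spine_nn(dataset: SpineDataset, rng: np.random.Generator | None = None,
                  n_shuffles: int = 1000) -> LostSpineNN:
    """Nearest-neighbor distances among lost spines, with a position shuffle null.

    Branches contribute when they carry >= 2 lost spines.  The null shuffles
    the positions of *all* spines on the branch (lost, stable and new) and
    recomputes the lost-lost nearest-neighbor distances.
    """
    if rng is None:
        rng = np.random.default_rng()
    spines = dataset.spine_table()
    obs: list[float] = []
    per_branch = []
    for (c, b), grp in spines.groupby(["cell_id", "branch_id"]):
        pos = grp["position_um"].to_numpy()
        lost = (grp["fate"] == "lost").to_numpy()
        if lost.sum() >= 2:
            lp = np.sort(pos[lost])
            d = np.diff(lp)
            nn = np.minimum(np.r_[d, np.inf], np.r_[np.inf, d])
            obs.extend(nn.tolist())
            per_branch.append((pos, int(lost.sum())))
    sh_means = np.full(n_shuffles, np.nan)
    if per_branch:
        for s in range(n_shuffles):
            pool: list[float] = []
            for pos, n_lost in per_branch:
                lp = np.sort(rng.choice(pos, size=n_lost, replace=False))
                d = np.diff(lp)
                nn = np.minimum(np.r_[d, np.inf], np.r_[np.inf, d])
                pool.extend(nn.tolist())
            sh_means[s] = float(np.mean(pool))
    return LostSpineNN(np.asarray(obs), sh_means)


def density_size_relation(dataset: SpineDataset, timepoint: float,
                          baseline_timepoint: float = 0.0) -> dict:
    """Per-branch spine density vs. mean spine size, both normalized to baseline.

    Density ratio = surviving spine count at ``timepoint`` over the count at
    ``baseline_timepoint``; size = branch mean of per-spine normalized sizes.
    Returns the per-branch table and the Spearman rank correlation.
    """
    snap = dataset.at_timepoint(timepoint)
    base = dataset.at_timepoint(baseline_timepoint)
    rows = []
    for (c, b), grp in base.groupby(["cell_id", "branch_id"]):
        n0 = grp["spine_id"].nunique()
        now = snap[(snap["cell_id"] == c) & (snap["branch_id"] == b)]
        if n0 == 0:
            continue
        sizes = now["size_norm"].dropna()
        rows.append({"cell_id": c, "branch_id": b,
                     "density_ratio": now["spine_id"].nunique() / n0,
                     "mean_size_ratio": sizes.mean() if len(sizes) else np.nan})
    table = pd.DataFrame(rows).dropna()
    if len(table) < 3:
        logger.warning("fewer than 3 branches: correlation undefined")
        return {"table": table, "rho": float("nan"), "p_value": float("nan")}
    x = table["density_ratio"].to_numpy()
    y = table["mean_size_ratio"].to_numpy()
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("degenerate (constant) branch values: correlation undefined")
        return {"table": table, "rho": float("nan"), "p_value": float("nan")}
    rho, p = stats.spearmanr(x, y)
    return {"table": table, "rho": float(rho), "p_value": float(p)}


@dataclass
class IntensityProfileSet:
    """Per-spine line profiles for GFP, GluA2 and GRIP1 with rotated backgrounds.

    Arrays are (n_spines, profile_len).  ``spine_sizes`` are the integrated
    brightnesses used for the GluA2-per-size ratio.  ``truth_coloc`` is the
    generator's ground-truth flag when the set is synthetic.
    """

    gfp: np.ndarray
    glua2: np.ndarray
    grip1: np.ndarray
    glua2_background: np.ndarray
    grip1_background: np.ndarray
    spine_sizes: np.ndarray
    truth_coloc: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.gfp, self.glua2, self.grip1,
                                    self.glua2_background, self.grip1_background)}
        if len(shapes) != 1:
            raise ValueError("all profile arrays must share a shape")
        if self.spine_sizes.shape[0] != self.gfp.shape[0]:
            raise ValueError("spine_sizes length must match the profile count")

    @property
    def n_spines(self) -> int:
        return int(self.gfp.shape[0])


def colocalized_glua2(profiles: IntensityProfileSet) -> pd.DataFrame:
    """Apply the 2-SD co-localization rule at the GFP peak of each spine.

    A spine co-localizes when both its GluA2 and GRIP1 intensities at the
    GFP peak exceed their rotated-background mean by more than two standard
    deviations.  Normalized peaks are peak / background mean; the
    GluA2-per-size ratio divides the normalized GluA2 value by the spine's
    integrated brightness.
    """
    rows = []
    for i in range(profiles.n_spines):
        k = int(np.argmax(profiles.gfp[i]))
        vals = {}
        ok = True
        for name, prof, bg in (("glua2", profiles.glua2, profiles.glua2_background),
                               ("grip1", profiles.grip1, profiles.grip1_background)):
            m, s = float(bg[i].mean()), float(bg[i].std(ddof=0))
            if s == 0:
                raise ValueError(f"flat {name} background for spine {i} (SD = 0)")
            v = float(prof[i][k])
            vals[name] = (v, m, s, v > m + 2 * s)
        coloc = vals["glua2"][3] and vals["grip1"][3]
        norm_glua2 = vals["glua2"][0] / vals["glua2"][1]
        rows.append({
            "spine": i,
            "coloc": coloc,
            "glua2_peak": vals["glua2"][0],
            "glua2_normalized": norm_glua2,
            "grip1_normalized": vals["grip1"][0] / vals["grip1"][1],
            "glua2_per_size": norm_glua2 / float(profiles.spine_sizes[i]),
        })
    return pd.DataFrame(rows)


def coloc_summary(table: pd.DataFrame) -> dict:
    """Averages over co-localized spines only, as used per dendrite."""
    hit = table[table["coloc"]]
    return {
        "fraction_coloc": float(table["coloc"].mean()) if len(table) else float("nan"),
        "mean_glua2_normalized": float(hit["glua2_normalized"].mean()) if len(hit) else float("nan"),
        "mean_glua2_per_size": float(hit["glua2_per_size"].mean()) if len(hit) else float("nan"),
    }
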