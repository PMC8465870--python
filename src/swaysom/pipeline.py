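"""End-to-end orchestration of the sway-clustering protocol.

The protocol pairs each mCTSIB condition (2, 3, 4) against condition 1 (the
reference with all sensory systems available) and, per sway direction
(ML, AP, or both combined), clusters the 46-row feature matrix (23 subjects
x 2 conditions) with a batch SOM followed by K-means over the active
prototypes.  K is chosen once, on the reference pair (1 vs 4), from the
local minima of the Davies-Bouldin curve by the highest mean F-measure, and
reused for the other pairs.  The clustering is repeated (default 30 times)
with the data reshuffled and fresh SOM/K-means seeds, and the external
measures are summarised as medians and interquartile ranges; finally the ML
and AP measure distributions are compared with a normality-gated test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import cluster as cluster_mod
from . import evaluate as eval_mod
from . import screen as screen_mod
from . import som as som_mod
from . import sway as sway_mod
from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

DIRECTIONS = ("ML", "AP")


@dataclass
class PipelineConfig:
    """All knobs of the protocol with the study's defaults."""

    output_dir: str = "swaysom_output"
    # cohort
    n_subjects: int = 23
    fs: float = 60.0
    duration: float = 30.0
    sensitivity: float = 16384.0
    full_scale: float = 2.0
    noise_sd: float = 0.0005
    conditions: tuple = cohort_mod.DEFAULT_CONDITIONS
    # filtering
    cutoff: float = 4.0
    filter_order: int = 2
    zero_phase: bool = False
    # screening
    corr_threshold: float = 0.85
    alpha: float = 0.05
    # SOM
    som_rows: int = 10
    som_cols: int = 10
    som_iterations: int = 1000
    neighborhood0: float = 3.0
    zscore: bool = True
    # K selection
    k_min: int = 2
    k_max: int = 30
    scan_reps: int = 10
    kmeans_restarts: int = 10
    reference_pair: int = 4
    # evaluation
    n_reps: int = 30
    pairs: tuple = (2, 3, 4)
    directions: tuple = DIRECTIONS
    reference_condition: int = 1
    seed: int = 0

    def validate(self) -> None:
        checks = [
            (self.n_subjects >= 2, "n_subjects must be >= 2"),
            (self.fs > 0, "fs must be positive"),
            (self.duration > 0, "duration must be positive"),
            (0 < self.cutoff < self.fs / 2, "cutoff must lie in (0, fs/2)"),
            (self.som_rows >= 1 and self.som_cols >= 1, "SOM grid must be non-empty"),
            (self.som_iterations >= 1, "som_iterations must be >= 1"),
            (2 <= self.k_min <= self.k_max, "need 2 <= k_min <= k_max"),
            (self.n_reps >= 1, "n_reps must be >= 1"),
            (len(self.conditions) == 4, "exactly 4 condition specs required"),
            (
                all(d in ("ML", "AP", "combined") for d in self.directions),
                "directions must be among ML, AP, combined",
            ),
            (
                all(p in (1, 2, 3, 4) for p in self.pairs),
                "pairs must reference mCTSIB conditions 1..4",
            ),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "conditions" in raw:
            raw["conditions"] = tuple(
                cohort_mod.ConditionSpec(**c) for c in raw["conditions"]
            )
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def cohort_config(self) -> cohort_mod.CohortConfig:
        return cohort_mod.CohortConfig(
            n_subjects=self.n_subjects,
            fs=self.fs,
            duration=self.duration,
            sensitivity=self.sensitivity,
            full_scale=self.full_scale,
            noise_sd=self.noise_sd,
            rng_seed=self.seed,
        )


def zscore_columns(X: np.ndarray) -> np.ndarray:
    """Z-score each column; zero-variance columns are left centred only."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def simulate(config: PipelineConfig):
    """Generate the synthetic cohort under the configured conditions."""
    return cohort_mod.generate_cohort(config.cohort_config(), tuple(config.conditions))


def extract(config: PipelineConfig, recordings, profiles) -> pd.DataFrame:
    """Raw recordings -> RMS feature table."""
    L_by_subject = {p.subject_id: p.com_height_L for p in profiles}
    return sway_mod.extract_cohort_features(
        recordings,
        L_by_subject,
        sensitivity=config.sensitivity,
        cutoff=config.cutoff,
        order=config.filter_order,
        zero_phase=config.zero_phase,
    )


def screen_direction(
    config: PipelineConfig, features: pd.DataFrame, direction: str
):
    """Feature screening on samples pooled across conditions within a direction."""
    sub = features[features["direction"] == direction]
    if sub.empty:
        raise DataError(f"no features for direction {direction!r}")
    return screen_mod.select_features(
        sub[sway_mod.FEATURE_COLUMNS].reset_index(drop=True),
        threshold=config.corr_threshold,
        alpha=config.alpha,
    )


def pair_matrix(
    features: pd.DataFrame,
    condition_b: int,
    direction: str,
    retained: dict[str, list[str]],
    condition_a: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """46-row feature matrix and class labels for one condition pair.

    ``direction`` is "ML", "AP" or "combined"; combined concatenates the
    retained ML and AP features per subject into one vector.
    """
    conds = (condition_a, condition_b)
    dirs = ("ML", "AP") if direction == "combined" else (direction,)
    blocks = []
    labels = None
    for d in dirs:
        sub = features[
            (features["direction"] == d) & (features["condition"].isin(conds))
        ].sort_values(["condition", "subject_id"])
        if set(sub["condition"]) != set(conds):
            raise DataError(f"conditions {conds} missing for direction {d}")
        blocks.append(sub[retained[d]].to_numpy(dtype=float))
        lab = sub["condition"].to_numpy()
        if labels is None:
            labels = lab
        elif not np.array_equal(labels, lab):
            raise DataError("ML/AP rows misaligned in combined mode")
    return np.hstack(blocks), labels


def cluster_once(
    X: np.ndarray,
    class_labels: np.ndarray,
    K: int,
    seed,
    config: PipelineConfig,
    return_model: bool = False,
):
    """One randomized pass: shuffle rows, z-score, batch-train the SOM,
    K-means the active prototypes, propagate, evaluate."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(X))
    Xp = X[perm]
    yp = np.asarray(class_labels)[perm]
    Xs = zscore_columns(Xp) if config.zscore else Xp
    grid = som_mod.SOMGrid(config.som_rows, config.som_cols)
    model = som_mod.train_batch(
        Xs,
        grid,
        iterations=config.som_iterations,
        neighborhood0=config.neighborhood0,
        seed=rng,
    )
    protos = cluster_mod.active_prototypes(model, Xs)
    k_eff = min(K, protos.n_prototypes)
    if k_eff < K:
        logger.warning("only %d prototypes; using K=%d", protos.n_prototypes, k_eff)
    km = cluster_mod.kmeans(
        protos.vectors, k_eff, seed=rng, n_init=config.kmeans_restarts
    )
    assignment = cluster_mod.propagate(km.labels, protos, n_points=len(Xs))
    table = eval_mod.contingency(assignment, yp)
    measures = eval_mod.external_measures(table)
    if return_model:
        return measures, model, protos, km, assignment, Xs, yp
    return measures


def choose_k(
    config: PipelineConfig,
    features: pd.DataFrame,
    direction: str,
    retained: dict[str, list[str]],
) -> tuple[int, pd.DataFrame]:
    """Davies-Bouldin K-scan on the reference pair (1 vs reference_pair),
    then the highest-F rule among the curve's local minima."""
    X, labels = pair_matrix(
        features, config.reference_pair, direction, retained,
        condition_a=config.reference_condition,
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    Xs = zscore_columns(X) if config.zscore else X
    grid = som_mod.SOMGrid(config.som_rows, config.som_cols)
    model = som_mod.train_batch(
        Xs, grid, iterations=config.som_iterations,
        neighborhood0=config.neighborhood0, seed=rng,
    )
    protos = cluster_mod.active_prototypes(model, Xs)
    curve, minima = cluster_mod.scan_k(
        protos.vectors,
        k_range=range(config.k_min, config.k_max + 1),
        reps=config.scan_reps,
        seed=rng,
        n_init=config.kmeans_restarts,
    )
    candidates = set(minima) | {int(curve.loc[curve["mean_db"].idxmin(), "K"])}
    f_by_k = {}
    for k in sorted(candidates):
        reps = eval_mod.repeat_pipeline(
            X, labels, k,
            lambda X_, y_, K_, s_: cluster_once(X_, y_, K_, s_, config),
            n_reps=config.scan_reps,
            master_seed=config.seed * 1000 + k,
        )
        f_by_k[k] = float(reps["f"].mean())
    chosen = cluster_mod.select_k(curve, minima, f_by_k)
    logger.info("direction %s: DB minima %s, F by K %s -> K=%d",
                direction, minima, f_by_k, chosen)
    return chosen, curve


def run_pair(
    config: PipelineConfig,
    features: pd.DataFrame,
    condition_b: int,
    direction: str,
    retained: dict[str, list[str]],
    K: int,
) -> pd.DataFrame:
    """Repeated clustering of one condition pair in one direction."""
    X, labels = pair_matrix(
        features, condition_b, direction, retained,
        condition_a=config.reference_condition,
    )
    per_rep = eval_mod.repeat_pipeline(
        X, labels, K,
        lambda X_, y_, K_, s_: cluster_once(X_, y_, K_, s_, config),
        n_reps=config.n_reps,
        master_seed=config.seed * 10000 + condition_b * 10
        + {"ML": 0, "AP": 1, "combined": 2}[direction],
    )
    per_rep.insert(0, "direction", direction)
    per_rep.insert(0, "pair", f"1v{condition_b}")
    return per_rep


@dataclass
class RunResult:
    features: pd.DataFrame
    retained: dict[str, list[str]]
    chosen_k: dict[str, int]
    db_curves: dict[str, pd.DataFrame]
    per_rep: pd.DataFrame
    summary: pd.DataFrame
    comparisons: pd.DataFrame


def run_all(config: PipelineConfig, write: bool = True) -> RunResult:
    """Full protocol: simulate -> extract -> screen -> choose K -> repeat
    clustering for every pair x direction -> summarise and compare."""
    config.validate()
    outdir = Path(config.output_dir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)

    recordings, profiles = simulate(config)
    features = extract(config, recordings, profiles)

    retained: dict[str, list[str]] = {}
    reports = {}
    for d in DIRECTIONS:
        retained[d], reports[d] = screen_direction(config, features, d)

    # K is decided once per run, on the reference pair in the direction with
    # the largest expected sway differences (AP when present), and shared by
    # every pair and direction thereafter.
    select_dir = "AP" if "AP" in config.directions else config.directions[0]
    k_shared, db_curve = choose_k(config, features, select_dir, retained)
    chosen_k = {d: k_shared for d in config.directions}
    db_curves = {select_dir: db_curve}
    frames = []
    for direction in config.directions:
        for condition_b in config.pairs:
            frames.append(
                run_pair(config, features, condition_b, direction, retained,
                         k_shared)
            )
    per_rep = pd.concat(frames, ignore_index=True)

    summary_rows = []
    for (pair, direction), grp in per_rep.groupby(["pair", "direction"]):
        s = eval_mod.summarize_measures(grp)
        s.insert(0, "direction", direction)
        s.insert(0, "pair", pair)
        summary_rows.append(s)
    summary = pd.concat(summary_rows, ignore_index=True)

    comp_rows = []
    if "ML" in config.directions and "AP" in config.directions:
        ml = per_rep[per_rep["direction"] == "ML"]
        ap = per_rep[per_rep["direction"] == "AP"]
        for measure in ("purity", "precision", "recall", "f"):
            name, statv, p = eval_mod.compare_directions(
                ml[measure], ap[measure], alpha=config.alpha
            )
            comp_rows.append(
                {"measure": measure, "test": name, "statistic": statv, "p": p}
            )
    comparisons = pd.DataFrame(comp_rows)

    result = RunResult(
        features=features, retained=retained, chosen_k=chosen_k,
        db_curves=db_curves, per_rep=per_rep, summary=summary,
        comparisons=comparisons,
    )
    if write:
        _write_artifacts(config, result, recordings, profiles, reports, outdir)
    return result


def _write_artifacts(config, result, recordings, profiles, reports, outdir: Path):
    from . import plotting

    cohort_mod.write_cohort(recordings, profiles, outdir / "cohort")
    result.features.to_csv(outdir / "features.csv", index=False)
    for d, rep in reports.items():
        rep.to_csv(outdir / f"correlation_{d}.csv")
    for d, curve in result.db_curves.items():
        curve.to_csv(outdir / f"db_curve_{d}.csv", index=False)
    result.per_rep.to_csv(outdir / "measures_per_rep.csv", index=False)
    result.summary.to_csv(outdir / "summary.csv", index=False)
    if len(result.comparisons):
        result.comparisons.to_csv(outdir / "direction_comparison.csv", index=False)

    # one representative trained map per direction for the diagnostics plots
    for direction in config.directions:
        X, labels = pair_matrix(
            result.features, config.reference_pair, direction, result.retained,
            condition_a=config.reference_condition,
        )
        _, model, protos, km, assignment, Xs, yp = cluster_once(
            X, labels, result.chosen_k[direction],
            np.random.SeedSequence([config.seed, 999]), config, return_model=True,
        )
        model.save(outdir / f"som_{direction}.json")
        plotting.plot_u_matrix(model, outdir / f"u_matrix_{direction}.png")
        plotting.plot_hits(model, Xs, outdir / f"hits_{direction}.png")
        plotting.plot_weight_planes(
            model, outdir / f"weight_planes_{direction}.png",
            feature_names=(result.retained[direction]
                           if direction != "combined"
                           else [f"{d}:{f}" for d in ("ML", "AP")
                                 for f in result.retained[d]]),
        )
        pd.DataFrame(
            {
                "point_id": np.arange(len(assignment)),
                "condition": yp,
                "cluster": assignment,
            }
        ).to_csv(outdir / f"clusters_{direction}.csv", index=False)

    log = {
        "seed": config.seed,
        "chosen_k": result.chosen_k,
        "retained": result.retained,
        "n_reps": config.n_reps,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=1))
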