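"""End-to-end orchestration: synthetic data -> cohort -> preprocessing ->
architecture search -> evaluation, plus the prediction-horizon sweep."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cellspace import Chromosome
from .childmodel import SharedWeightStore, TrainConfig, materialize_model, train_child
from .cohort import CohortResult, EpisodeSet, build_cohort
from .evaluation import RocResult, baseline_recurrent, evaluate_scores
from .ga_engine import GaConfig, GenerationStats, run_search
from .preprocess import (
    DaeConfig,
    Denoiser,
    GprConfig,
    Normalizer,
    denoise,
    impute_episodes,
    train_dae,
)
from .synthdata import SynthConfig, generate_cohort

SPLITS = ("train", "validation", "test")


@dataclass
class PreparedData:
    """Imputed, normalized, denoised splits ready for model training."""

    x: dict[str, np.ndarray]
    y: dict[str, np.ndarray]
    normalizer: Normalizer
    denoiser: Denoiser
    feature_means: np.ndarray


def preprocess_splits(
    episode_set: EpisodeSet,
    gpr_config: GprConfig | None = None,
    dae_config: DaeConfig | None = None,
) -> PreparedData:
    """Impute (GP), normalize (train statistics) and denoise all splits."""
    raw = {s: episode_set.arrays(s) for s in SPLITS}
    train_x = raw["train"][0]
    feature_means = np.nanmean(train_x.reshape(-1, train_x.shape[-1]), axis=0)
    feature_means = np.nan_to_num(feature_means, nan=0.0)
    imputed = {
        s: impute_episodes(x, feature_means, gpr_config) for s, (x, _y) in raw.items()
    }
    normalizer = Normalizer.fit(imputed["train"])
    normalized = {s: normalizer.apply(x) for s, x in imputed.items()}
    denoiser = train_dae(normalized["train"], dae_config)
    denoised = {s: denoise(x, denoiser) for s, x in normalized.items()}
    return PreparedData(
        x=denoised,
        y={s: y for s, (_x, y) in raw.items()},
        normalizer=normalizer,
        denoiser=denoiser,
        feature_means=feature_means,
    )


@dataclass
class PipelineResult:
    horizon: int
    best_chromosome: Chromosome
    stats: list[GenerationStats]
    store: SharedWeightStore
    searched: RocResult
    baseline: RocResult | None
    cohort: CohortResult
    data: PreparedData


def retrain_and_score(
    chromosome: Chromosome,
    data: PreparedData,
    train_config: TrainConfig,
    store: SharedWeightStore,
    replicates: int = 500,
) -> RocResult:
    """Retrain the chosen cell (warm-started from the store) and score the
    held-out test split."""
    model = materialize_model(
        chromosome, store, train_config, n_features=data.x["train"].shape[2]
    )
    train_child(
        model,
        data.x["train"],
        data.y["train"],
        data.x["validation"],
        data.y["validation"],
        train_config,
    )
    scores = model.predict_proba(data.x["test"])
    return evaluate_scores(
        scores, data.y["test"], replicates=replicates, seed=train_config.seed
    )


def run_end_to_end(
    synth_config: SynthConfig,
    horizon: int,
    ga_config: GaConfig,
    train_config: TrainConfig,
    retrain_config: TrainConfig | None = None,
    gpr_config: GprConfig | None = None,
    dae_config: DaeConfig | None = None,
    with_baseline: bool = True,
    replicates: int = 500,
    tables=None,
    demographics=None,
) -> PipelineResult:
    """Full desk-scale run on one synthetic cohort at one horizon.

    ``tables``/``demographics`` may be passed to reuse a generated cohort
    (the horizon sweep re-windows the same underlying data).
    """
    if tables is None:
        tables, demographics, _truth = generate_cohort(synth_config)
    cohort = build_cohort(tables, demographics, horizon, seed=synth_config.seed)
    data = preprocess_splits(cohort.episode_set, gpr_config, dae_config)
    best, stats, store = run_search(
        data.x["train"],
        data.y["train"],
        data.x["validation"],
        data.y["validation"],
        ga_config,
        train_config,
    )
    retrain_config = retrain_config or replace(
        train_config, max_epochs=max(train_config.max_epochs, 30)
    )
    searched = retrain_and_score(best, data, retrain_config, store, replicates)
    baseline = None
    if with_baseline:
        baseline = baseline_recurrent(
            data.x["train"],
            data.y["train"],
            data.x["validation"],
            data.y["validation"],
            data.x["test"],
            data.y["test"],
            retrain_config,
            replicates=replicates,
        )
    return PipelineResult(
        horizon=horizon,
        best_chromosome=best,
        stats=stats,
        store=store,
        searched=searched,
        baseline=baseline,
        cohort=cohort,
        data=data,
    )


@dataclass
class SweepResult:
    rows: list[dict] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def auroc(self, horizon: int) -> float:
        for row in self.rows:
            if row["horizon"] == horizon:
                return row["auroc"]
        raise KeyError(horizon)


def horizon_sweep(
    synth_config: SynthConfig,
    horizons: list[int],
    ga_config: GaConfig,
    train_config: TrainConfig,
    retrain_config: TrainConfig | None = None,
    gpr_config: GprConfig | None = None,
    dae_config: DaeConfig | None = None,
    with_baseline: bool = False,
    replicates: int = 500,
) -> SweepResult:
    """Re-run cohorting, preprocessing, search and evaluation per horizon on
    the same underlying synthetic cohort."""
    tables, demographics, _truth = generate_cohort(synth_config)
    result = SweepResult()
    for horizon in horizons:
        try:
            r = run_end_to_end(
                synth_config,
                horizon,
                ga_config,
                train_config,
                retrain_config,
                gpr_config,
                dae_config,
                with_baseline=with_baseline,
                replicates=replicates,
                tables=tables,
                demographics=demographics,
            )
        except Exception as exc:  # annotate failing stage with its horizon
            raise RuntimeError(f"horizon {horizon}: {exc}") from exc
        result.rows.append(
            {
                "horizon": horizon,
                "n_test": len(r.data.y["test"]),
                "auroc": r.searched.auroc,
                "auroc_ci_lower": r.searched.ci_lower,
                "auroc_ci_upper": r.searched.ci_upper,
                "sensitivity": r.searched.sensitivity,
                "specificity": r.searched.specificity,
            }
        )
    return result
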