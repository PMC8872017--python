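"""Cohort construction: harmonize event tables, detect the inflammatory
syndrome, label sepsis onset, window episodes, filter, balance and split.

Conventions (all config-overridable where noted): hours are 0-based and
floored from event timestamps; windows are half-open ``[s, s + 5)``; the
prediction target of a window starting at ``s`` with horizon ``T`` is hour
``s + 5 + T``; a window is labeled positive iff onset falls exactly on its
target hour; windows overlapping or following onset are not emitted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import ANTIBIOTICS, CatalogError, FeatureCatalog, default_catalog

logger = logging.getLogger(__name__)

WINDOW_HOURS = 5

#: two-of-four criteria; each entry: feature -> (lower, upper) normal range,
#: a criterion is met when the value falls outside it
DEFAULT_SIRS_THRESHOLDS: dict[str, tuple[float, float]] = {
    "temperature": (36.0, 38.0),
    "heart_rate": (-math.inf, 90.0),
    "respiratory_rate": (-math.inf, 20.0),
    "wbc": (4.0, 12.0),
}


class CohortError(ValueError):
    pass


@dataclass
class TimeSeriesGrid:
    patient_id: str
    admission_id: str
    data: np.ndarray  # hours x n_features, NaN where missing
    age: int
    gender: str
    start: float = 0.0

    @property
    def n_hours(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class SirsAnnotation:
    flags: np.ndarray  # bool per hour
    counts: np.ndarray  # criteria met per hour, 0..4


@dataclass
class Episode:
    data: np.ndarray  # 5 x n_features
    label: int
    horizon: int
    patient_id: str
    start: int

    def __post_init__(self) -> None:
        if self.data.shape[0] != WINDOW_HOURS:
            raise CohortError(f"episode window must have {WINDOW_HOURS} rows")
        if self.label not in (0, 1):
            raise CohortError("label must be binary")


@dataclass
class EpisodeSet:
    episodes: list[Episode]
    splits: list[str]  # train | validation | test, parallel to episodes

    def __post_init__(self) -> None:
        if len(self.episodes) != len(self.splits):
            raise CohortError("episodes and split tags must be parallel")

    def subset(self, split: str) -> list[Episode]:
        return [e for e, s in zip(self.episodes, self.splits) if s == split]

    def arrays(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        eps = self.subset(split)
        if not eps:
            return np.zeros((0, WINDOW_HOURS, 0)), np.zeros(0, dtype=int)
        x = np.stack([e.data for e in eps])
        y = np.array([e.label for e in eps], dtype=int)
        return x, y

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "episode_id": range(len(self.episodes)),
                "patient_id": [e.patient_id for e in self.episodes],
                "start": [e.start for e in self.episodes],
                "label": [e.label for e in self.episodes],
                "split": self.splits,
            }
        )


# ---------------------------------------------------------------------------
# event harmonization
# ---------------------------------------------------------------------------


def merge_features(events: pd.DataFrame, catalog: FeatureCatalog) -> pd.DataFrame:
    """Map source feature ids to canonical names; drop unmapped events."""
    if catalog.n_features == 0:
        raise CohortError("empty catalog")
    events = events.copy()
    events["feature"] = events["feature_id"].astype(str).map(catalog.id_to_name)
    dropped = int(events["feature"].isna().sum())
    if dropped:
        logger.info("merge_features: dropped %d events with unmapped ids", dropped)
    return events.dropna(subset=["feature"]).reset_index(drop=True)


def harmonize_units(events: pd.DataFrame, catalog: FeatureCatalog) -> pd.DataFrame:
    """Per feature, elect the majority unit by record count and convert all
    values to it.  Records in unknown units are dropped and logged."""
    events = events.copy()
    known = np.ones(len(events), dtype=bool)
    for name, group in events.groupby("feature"):
        units_ok = group["unit"].isin(catalog.known_units(name))
        if not units_ok.all():
            n_bad = int((~units_ok).sum())
            logger.warning("harmonize_units: dropping %d %s records in unknown units", n_bad, name)
            known[group.index[~units_ok]] = False
    events = events.loc[known].reset_index(drop=True)
    for name, group in events.groupby("feature"):
        majority = group["unit"].value_counts().idxmax()
        for unit, sub in group.groupby("unit"):
            if unit == majority:
                continue
            converted = [
                catalog.convert(name, v, str(unit), str(majority)) for v in sub["value"]
            ]
            events.loc[sub.index, "value"] = converted
            events.loc[sub.index, "unit"] = majority
    return events


def resolve_conflicts(events: pd.DataFrame) -> pd.DataFrame:
    """When the same feature has chart and lab records in the same hour of
    the same admission, keep only the lab records."""
    events = events.copy()
    events["hour"] = np.floor(events["time"]).astype(int)
    keys = ["admission_id", "feature", "hour"]
    has_lab = events[events["source"] == "lab"].drop_duplicates(keys)[keys]
    merged = events.merge(has_lab.assign(_lab=True), on=keys, how="left")
    drop = (merged["_lab"] == True) & (merged["source"] == "chart")  # noqa: E712
    return events.loc[~drop.to_numpy()].reset_index(drop=True)


def resample_hourly(
    events: pd.DataFrame, demographics: pd.DataFrame, catalog: FeatureCatalog
) -> list[TimeSeriesGrid]:
    """Per admission, an hourly grid over the catalog's feature columns.

    Multiple values in the same hour are averaged; empty hours are NaN.
    """
    events = events.copy()
    if "hour" not in events.columns:
        events["hour"] = np.floor(events["time"]).astype(int)
    demo = demographics.set_index("admission_id")
    grids: list[TimeSeriesGrid] = []
    grouped = events.groupby("admission_id") if len(events) else []
    seen = set()
    for adm, group in grouped:
        seen.add(adm)
        n_hours = int(group["hour"].max()) + 1
        data = np.full((n_hours, catalog.n_features), np.nan)
        agg = group.groupby(["hour", "feature"])["value"].mean()
        for (hour, feature), value in agg.items():
            data[int(hour), catalog.column(str(feature))] = value
        row = demo.loc[adm]
        grids.append(
            TimeSeriesGrid(
                patient_id=str(row["patient_id"]),
                admission_id=str(adm),
                data=data,
                age=int(row["age"]),
                gender=str(row["gender"]),
            )
        )
    for adm in demo.index:
        if adm not in seen:
            logger.warning("resample_hourly: admission %s has no events", adm)
    grids.sort(key=lambda g: g.admission_id)
    return grids


# ---------------------------------------------------------------------------
# onset labeling
# ---------------------------------------------------------------------------


def detect_sirs(
    grid: TimeSeriesGrid,
    catalog: FeatureCatalog,
    thresholds: dict[str, tuple[float, float]] | None = None,
) -> SirsAnnotation:
    """Per-hour count of criteria met (value outside its normal range);
    flag true iff count >= 2.  A missing feature contributes zero."""
    thresholds = thresholds if thresholds is not None else DEFAULT_SIRS_THRESHOLDS
    counts = np.zeros(grid.n_hours, dtype=int)
    for feature, (lower, upper) in thresholds.items():
        col = grid.data[:, catalog.column(feature)]
        abnormal = (col < lower) | (col > upper)
        counts += np.where(np.isnan(col), 0, abnormal.astype(int))
    return SirsAnnotation(flags=counts >= 2, counts=counts)


def find_sepsis_onset(
    sirs: SirsAnnotation, infection_hours: list[float], min_run: int = 5
) -> int | None:
    """Start hour of the earliest run of >= ``min_run`` consecutive flagged
    hours, provided infection evidence exists for the admission."""
    if not infection_hours:
        return None
    flags = np.asarray(sirs.flags, dtype=bool)
    run = 0
    for h, flag in enumerate(flags):
        run = run + 1 if flag else 0
        if run >= min_run:
            return h - min_run + 1
    return None


def infection_evidence_hours(
    prescriptions: pd.DataFrame, admission_id: str, antibiotics: tuple[str, ...] = ANTIBIOTICS
) -> list[float]:
    """Hours of antibiotic prescription events for the admission."""
    sub = prescriptions[prescriptions["admission_id"] == admission_id]
    mask = sub["feature_id"].astype(str).str.lower().isin({a.lower() for a in antibiotics})
    return sorted(float(t) for t in sub.loc[mask, "time"])


def filter_cohort(
    grids: list[TimeSeriesGrid],
    run_starts: dict[str, int | None],
    infection_any: dict[str, bool],
    horizon: int,
) -> list[TimeSeriesGrid]:
    """Keep adults with record length >= 5 + T.  Admissions with a
    qualifying >= 5 h flagged run but no infection evidence cannot be
    labeled either way and are excluded; a case requires both."""
    kept = []
    for grid in grids:
        if grid.age < 18:
            continue
        if grid.n_hours < WINDOW_HOURS + horizon:
            continue
        adm = grid.admission_id
        if run_starts.get(adm) is not None and not infection_any.get(adm, False):
            continue
        kept.append(grid)
    return kept


def extract_episodes(
    grid: TimeSeriesGrid,
    onset: int | None,
    horizon: int,
    tolerance_h: int = 0,
) -> list[Episode]:
    """Slide a 5 h window forward 1 h at a time.

    A window at start ``s`` is emitted iff ``s + 5 + T <= L`` and neither
    the window nor its target hour lies past onset (a window whose target
    falls after onset cannot be a truthful negative under exact-hour
    labeling); its label is 1 iff onset equals the target hour
    ``s + 5 + T`` (within ``tolerance_h``, default exact).
    """
    if not 0 <= horizon <= 12:
        raise CohortError("horizon must lie in [0, 12]")
    episodes = []
    length = grid.n_hours
    for s in range(0, length - WINDOW_HOURS - horizon + 1):
        if onset is not None and s + WINDOW_HOURS + horizon > onset:
            continue
        target = s + WINDOW_HOURS + horizon
        label = int(onset is not None and abs(onset - target) <= tolerance_h)
        episodes.append(
            Episode(
                data=grid.data[s : s + WINDOW_HOURS].copy(),
                label=label,
                horizon=horizon,
                patient_id=grid.patient_id,
                start=s,
            )
        )
    return episodes


def filter_episodes(episodes: list[Episode], min_feature_fraction: float = 0.5) -> list[Episode]:
    """Keep episodes where >= half the features have at least one value."""
    kept = []
    for e in episodes:
        observed = np.any(~np.isnan(e.data), axis=0).mean()
        if observed >= min_feature_fraction:
            kept.append(e)
    return kept


def balance_classes(episodes: list[Episode], seed: int) -> list[Episode]:
    """Equalize class counts at the geometric mean of the class sizes:
    the minority class is oversampled with replacement (originals kept),
    the majority class subsampled without replacement."""
    positives = [e for e in episodes if e.label == 1]
    negatives = [e for e in episodes if e.label == 0]
    if not positives or not negatives:
        raise CohortError("balance_classes requires both classes")
    target = round(math.sqrt(len(positives) * len(negatives)))
    rng = np.random.default_rng(seed)

    def resize(group: list[Episode]) -> list[Episode]:
        if len(group) == target:
            return list(group)
        if len(group) < target:
            extra = rng.integers(0, len(group), size=target - len(group))
            return list(group) + [group[i] for i in extra]
        idx = rng.choice(len(group), size=target, replace=False)
        return [group[i] for i in sorted(idx)]

    return resize(positives) + resize(negatives)


def split_dataset(
    episodes: list[Episode], seed: int, ratios: tuple[float, float, float] = (0.5, 0.3, 0.2)
) -> EpisodeSet:
    """Random disjoint train/validation/test split at the given ratios,
    rounded by largest remainder."""
    n = len(episodes)
    if n < 10:
        raise CohortError("split_dataset requires at least 10 episodes")
    quotas = [n * r for r in ratios]
    counts = [math.floor(q) for q in quotas]
    remainders = sorted(range(3), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in range(n - sum(counts)):
        counts[remainders[i % 3]] += 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    tags = ["train"] * counts[0] + ["validation"] * counts[1] + ["test"] * counts[2]
    splits = [""] * n
    for pos, idx in enumerate(order):
        splits[idx] = tags[pos]
    return EpisodeSet(episodes=list(episodes), splits=splits)


# ---------------------------------------------------------------------------
# end-to-end cohort build
# ---------------------------------------------------------------------------


@dataclass
class CohortResult:
    episode_set: EpisodeSet
    onsets: dict[str, int | None]  # per admission
    grids: list[TimeSeriesGrid]


def detect_onsets(
    tables: dict[str, pd.DataFrame],
    demographics: pd.DataFrame,
    catalog: FeatureCatalog | None = None,
    thresholds: dict[str, tuple[float, float]] | None = None,
    antibiotics: tuple[str, ...] = ANTIBIOTICS,
) -> tuple[list[TimeSeriesGrid], dict[str, int | None], dict[str, int | None], dict[str, bool]]:
    """Harmonize chart+lab events, grid them, and label onset per admission."""
    catalog = catalog or default_catalog()
    events = pd.concat([tables["chartevents"], tables["labevents"]], ignore_index=True)
    events = merge_features(events, catalog)
    events = harmonize_units(events, catalog)
    events = resolve_conflicts(events)
    grids = resample_hourly(events, demographics, catalog)
    onsets: dict[str, int | None] = {}
    run_starts: dict[str, int | None] = {}
    infection_any: dict[str, bool] = {}
    rx = tables["prescriptions"]
    for grid in grids:
        sirs = detect_sirs(grid, catalog, thresholds)
        infection = infection_evidence_hours(rx, grid.admission_id, antibiotics)
        # earliest qualifying run regardless of infection, for the
        # unlabelable-case exclusion
        run_starts[grid.admission_id] = find_sepsis_onset(sirs, [0.0])
        onsets[grid.admission_id] = find_sepsis_onset(sirs, infection)
        infection_any[grid.admission_id] = bool(infection)
    return grids, onsets, run_starts, infection_any


def build_cohort(
    tables: dict[str, pd.DataFrame],
    demographics: pd.DataFrame,
    horizon: int,
    seed: int,
    catalog: FeatureCatalog | None = None,
    balance: str = "post_split",
) -> CohortResult:
    """Full cohort pipeline: harmonize -> label -> filter -> window ->
    filter episodes -> balance -> split.

    ``balance`` selects the balancing protocol: ``"pre_split"`` balances the
    whole episode pool before splitting (oversampled duplicates then land in
    every split, so held-out metrics partly measure memorization);
    ``"post_split"`` (default) splits the distinct episodes first and
    balances only the train and validation subsets, leaving the test split
    untouched; ``"none"`` skips balancing.
    """
    if balance not in ("pre_split", "post_split", "none"):
        raise CohortError(f"unknown balancing protocol {balance!r}")
    catalog = catalog or default_catalog()
    grids, onsets, run_starts, infection_any = detect_onsets(tables, demographics, catalog)
    grids = filter_cohort(grids, run_starts, infection_any, horizon)
    episodes: list[Episode] = []
    for grid in grids:
        episodes.extend(extract_episodes(grid, onsets[grid.admission_id], horizon))
    episodes = filter_episodes(episodes)
    if balance == "pre_split":
        episodes = balance_classes(episodes, seed)
        episode_set = split_dataset(episodes, seed + 1)
    else:
        episode_set = split_dataset(episodes, seed + 1)
        if balance == "post_split":
            balanced_eps: list[Episode] = []
            balanced_tags: list[str] = []
            for offset, split in enumerate(("train", "validation"), start=2):
                subset = episode_set.subset(split)
                subset = balance_classes(subset, seed + offset)
                balanced_eps.extend(subset)
                balanced_tags.extend([split] * len(subset))
            test = episode_set.subset("test")
            balanced_eps.extend(test)
            balanced_tags.extend(["test"] * len(test))
            episode_set = EpisodeSet(balanced_eps, balanced_tags)
    return CohortResult(episode_set=episode_set, onsets=onsets, grids=grids)
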