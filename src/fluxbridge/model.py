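"""Random-forest flux models with grouped cross-validation.

One model ("RFM") is trained per (category, split, fold, scenario, target)
on all days of the training-fold stations; hyperparameters are picked by
random search scored on out-of-bag R^2. Each trained model is then evaluated
separately at every test-fold station, yielding one (R^2, RMSE) pair per
(model, test station) — the grouped-CV skill samples that downstream
transferability regression consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .partition import CVPlan
from .registry import FactorRegistry

logger = logging.getLogger(__name__)

_TARGET_COLUMN = {"NEE": "nee", "WF": "wf"}


@dataclass(frozen=True)
class HyperSearchConfig:
    """Random-search space for forest hyperparameters.

    ``n_iter`` configurations are drawn uniformly from the ranges below and
    scored by out-of-bag R^2; the best is refit on the full training rows.
    With ``n_iter=1`` the single draw is used directly (no OOB scoring),
    which is how miniature test runs stay cheap. ``max_train_rows``
    subsamples training rows (without replacement, deterministically) before
    fitting, bounding the cost of large networks.
    """

    n_iter: int = 20
    n_estimators: tuple[int, int] = (100, 500)
    max_depth: tuple[int, int] = (5, 30)
    allow_unlimited_depth: bool = True
    min_samples_leaf: tuple[int, int] = (1, 10)
    max_features: tuple[float, float] = (0.3, 1.0)
    max_train_rows: int | None = None

    def draw(self, rng: np.random.Generator) -> dict:
        depth: int | None
        if self.allow_unlimited_depth and rng.random() < 0.25:
            depth = None
        else:
            depth = int(rng.integers(self.max_depth[0], self.max_depth[1] + 1))
        return {
            "n_estimators": int(
                rng.integers(self.n_estimators[0], self.n_estimators[1] + 1)
            ),
            "max_depth": depth,
            "min_samples_leaf": int(
                rng.integers(self.min_samples_leaf[0], self.min_samples_leaf[1] + 1)
            ),
            "max_features": float(
                rng.uniform(self.max_features[0], self.max_features[1])
            ),
        }


#: Cheap settings for miniature pipelines and tests: one 3-tree draw.
TINY_HYPER = HyperSearchConfig(
    n_iter=1,
    n_estimators=(3, 3),
    max_depth=(8, 8),
    allow_unlimited_depth=False,
    min_samples_leaf=(2, 2),
    max_features=(0.8, 0.8),
    max_train_rows=1500,
)


@dataclass(frozen=True)
class TrainedRFM:
    """A fitted forest plus the provenance needed to transfer it."""

    rfm_id: str
    category: str
    scenario: str
    target: str
    split: int
    fold: int
    training_station_ids: tuple[str, ...]
    features: tuple[str, ...]
    model: RandomForestRegressor = field(repr=False, compare=False)
    hyperparameters: dict = field(compare=False)
    seed: int = 0

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.model.predict(X[list(self.features)].to_numpy())


@dataclass(frozen=True)
class StationEvaluation:
    """Skill of one model at one held-out station."""

    rfm_id: str
    category: str
    scenario: str
    target: str
    split: int
    fold: int
    station_id: str
    r2: float  # may be negative; NaN when undefined (zero-variance obs)
    rmse: float
    n_days: int

    @property
    def valid(self) -> bool:
        return np.isfinite(self.r2)


def _design_matrix(
    records: pd.DataFrame, features: tuple[str, ...], target_col: str
) -> tuple[np.ndarray, np.ndarray]:
    """Rows with every feature and the target present; others are dropped."""
    cols = list(features) + [target_col]
    sub = records[cols].dropna()
    return sub[list(features)].to_numpy(), sub[target_col].to_numpy()


def train_rfm(
    records: pd.DataFrame,
    features: tuple[str, ...],
    target: str,
    hyper: HyperSearchConfig,
    seed: int = 0,
) -> tuple[RandomForestRegressor, dict]:
    """Fit one forest on the complete-case rows of ``records``.

    Random search over ``hyper.n_iter`` draws scored by out-of-bag R^2,
    then a refit of the best configuration on all (possibly row-capped)
    training rows. Deterministic given ``seed``.
    """
    target_col = _TARGET_COLUMN[target]
    X, y = _design_matrix(records, features, target_col)
    n_total = len(records)
    if len(X) == 0:
        raise ValueError("no complete training rows (all rows dropped)")
    if len(X) < n_total:
        logger.debug("train_rfm: dropped %d incomplete rows", n_total - len(X))

    rng = np.random.default_rng(seed)
    if hyper.max_train_rows is not None and len(X) > hyper.max_train_rows:
        pick = rng.choice(len(X), size=hyper.max_train_rows, replace=False)
        X, y = X[pick], y[pick]

    candidates = [hyper.draw(rng) for _ in range(hyper.n_iter)]
    if len(candidates) == 1:
        best = candidates[0]
    else:
        best, best_score = None, -np.inf
        for params in candidates:
            rf = RandomForestRegressor(
                **params,
                oob_score=True,
                bootstrap=True,
                n_jobs=1,
                random_state=int(rng.integers(2**31)),
            )
            rf.fit(X, y)
            if rf.oob_score_ > best_score:
                best, best_score = params, rf.oob_score_
    final = RandomForestRegressor(
        **best,
        n_jobs=1,
        random_state=int(rng.integers(2**31)),
    )
    final.fit(X, y)
    return final, best


def evaluate_station(
    rfm: TrainedRFM, station_records: pd.DataFrame
) -> StationEvaluation:
    """R^2 and RMSE of a model at one held-out station.

    R^2 = 1 - SSres/SStot over the station's complete-case days, with SStot
    taken about the station's own observed mean; RMSE = sqrt(SSres/n).
    A station whose observations have zero variance gets r2 = NaN (flagged,
    excluded downstream).
    """
    sid = station_records["station_id"].iloc[0]
    if sid in rfm.training_station_ids:
        raise ValueError(f"station {sid} was in the training set of {rfm.rfm_id}")
    target_col = _TARGET_COLUMN[rfm.target]
    cols = list(rfm.features) + [target_col]
    sub = station_records[cols].dropna()
    if len(sub) < 2:
        raise ValueError(f"station {sid}: need >= 2 valid days, got {len(sub)}")
    obs = sub[target_col].to_numpy()
    pred = rfm.model.predict(sub[list(rfm.features)].to_numpy())
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    rmse = float(np.sqrt(ss_res / len(obs)))
    if ss_tot == 0.0:
        logger.warning("evaluate_station: zero-variance observations at %s", sid)
        r2 = np.nan
    else:
        r2 = 1.0 - ss_res / ss_tot
    return StationEvaluation(
        rfm_id=rfm.rfm_id,
        category=rfm.category,
        scenario=rfm.scenario,
        target=rfm.target,
        split=rfm.split,
        fold=rfm.fold,
        station_id=sid,
        r2=r2,
        rmse=rmse,
        n_days=len(sub),
    )


def run_cv(
    records: pd.DataFrame,
    plan: CVPlan,
    scenario: str,
    target: str,
    registry: FactorRegistry,
    hyper: HyperSearchConfig | None = None,
    seed: int = 0,
) -> tuple[list[TrainedRFM], list[StationEvaluation]]:
    """Train and evaluate the full p x k grouped-CV grid for one category.

    Returns the k*p trained models and the n*p per-station evaluations
    (zero-variance stations are flagged NaN, kept in the list, and logged).
    ``records`` must contain the plan's stations, preprocessed.
    """
    hyper = hyper or HyperSearchConfig()
    features = registry.feature_names(scenario)
    by_station = {sid: block for sid, block in records.groupby("station_id", sort=False)}
    missing = [s for amap in plan.assignment for s in amap if s not in by_station]
    if missing:
        raise ValueError(f"records missing stations: {sorted(set(missing))[:5]}")

    ss = np.random.SeedSequence(seed)
    seeds = [int(np.random.default_rng(c).integers(2**31)) for c in ss.spawn(plan.p * plan.k)]
    models: list[TrainedRFM] = []
    evals: list[StationEvaluation] = []
    for split in range(plan.p):
        for fold in range(plan.k):
            train_ids = plan.train_stations(split, fold)
            test_ids = plan.test_stations(split, fold)
            train_df = pd.concat([by_station[s] for s in train_ids], ignore_index=True)
            model, params = train_rfm(
                train_df, features, target, hyper, seed=seeds[split * plan.k + fold]
            )
            rfm = TrainedRFM(
                rfm_id=f"{plan.category}-{scenario}-{target}-s{split + 1:02d}f{fold + 1:02d}",
                category=plan.category,
                scenario=scenario,
                target=target,
                split=split,
                fold=fold,
                training_station_ids=tuple(train_ids),
                features=features,
                model=model,
                hyperparameters=params,
                seed=seeds[split * plan.k + fold],
            )
            models.append(rfm)
            for sid in test_ids:
                evals.append(evaluate_station(rfm, by_station[sid]))
    n_invalid = sum(not e.valid for e in evals)
    if n_invalid:
        logger.info("run_cv[%s]: %d zero-variance evaluations flagged", plan.category, n_invalid)
    return models, evals


@dataclass(frozen=True)
class CVSummary:
    """Aggregate skill of one category's CV grid."""

    frac_evals_r2_ge_05: float
    station_max_r2: dict[str, float]
    frac_stations_max_ge_05: float
    n_evaluations: int


def summarize_cv(evaluations: list[StationEvaluation]) -> CVSummary:
    """Fraction of evaluations with R^2 >= 0.5 (inclusive), the per-station
    maximum R^2 across all splits, and the fraction of stations whose
    maximum reaches 0.5. NaN (zero-variance) evaluations are excluded."""
    valid = [e for e in evaluations if e.valid]
    if not valid:
        raise ValueError("no valid evaluations")
    r2s = np.array([e.r2 for e in valid])
    station_max: dict[str, float] = {}
    for e in valid:
        station_max[e.station_id] = max(station_max.get(e.station_id, -np.inf), e.r2)
    maxes = np.array(list(station_max.values()))
    return CVSummary(
        frac_evals_r2_ge_05=float(np.mean(r2s >= 0.5)),
        station_max_r2=station_max,
        frac_stations_max_ge_05=float(np.mean(maxes >= 0.5)),
        n_evaluations=len(valid),
    )


def evaluations_to_frame(evals: list[StationEvaluation]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in evals])


def save_models(models: list[TrainedRFM], store_dir) -> None:
    """Persist trained models to a directory, one pickle per rfm_id."""
    import pickle
    from pathlib import Path

    store = Path(store_dir)
    store.mkdir(parents=True, exist_ok=True)
    for m in models:
        with open(store / f"{m.rfm_id}.pkl", "wb") as fh:
            pickle.dump(m, fh)


def load_models(store_dir) -> dict[str, TrainedRFM]:
    """Load every model pickle in a store directory, keyed by rfm_id."""
    import pickle
    from pathlib import Path

    out: dict[str, TrainedRFM] = {}
    for path in sorted(Path(store_dir).glob("*.pkl")):
        with open(path, "rb") as fh:
            m = pickle.load(fh)
        out[m.rfm_id] = m
    return out
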