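"""Transferability scoring: distances between stations and training sets,
and the regression that predicts a model's R^2 from those distances.

The chain has three links:

1. **DOY climatology** — each station's daily factors are averaged by day
   of year over all its years (leap day dropped, so DOY runs 1..365);
   static factors collapse to a single value.
2. **Euclidean distances** — for one factor, the distance between two
   stations is the root-sum-of-squares of their climatology difference over
   their common observed DOYs (ds); the distance between a station and a
   model's training set is the mean of ds over the training stations (d_j).
   Stacking d_1..d_w over the factor registry gives the station-model
   distance vector.
3. **R^2-simulation model (RSM)** — per (category, scenario, target), an
   ordinary-least-squares regression R^2 = a0 + a1 d1 + ... + aw dw fitted
   on the grouped-CV skill samples (Dataset 1), later used to predict the
   R^2 a model would attain at an unmeasured meteorological station.

Distances are computed on raw factor units, exactly as the distance
definition is stated; an optional z-scoring flag exists because the linear
regression absorbs scale either way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr

from .model import StationEvaluation, TrainedRFM
from .registry import FactorRegistry

logger = logging.getLogger(__name__)

DEFAULT_T_MIN = 30  # minimum common-DOY overlap for a daily-factor distance


@dataclass(frozen=True)
class DOYClimatology:
    """Multi-year day-of-year means for one station.

    ``daily`` is a (365, n_daily_factors) frame indexed by DOY 1..365 with
    NaN where a DOY was never observed; ``static`` holds the time-invariant
    factors as single values.
    """

    station_id: str
    daily: pd.DataFrame
    static: dict[str, float]

    def factor_series(self, name: str) -> np.ndarray:
        if name in self.static:
            return np.array([self.static[name]])
        return self.daily[name].to_numpy()


def doy_climatology(
    station_records: pd.DataFrame, registry: FactorRegistry
) -> DOYClimatology:
    """Average each daily factor by DOY over years; drop leap day (DOY 366).

    Static factors are reduced to their (first observed) value. A factor
    with no valid data anywhere stays all-NaN and is flagged in the log.
    """
    sid = str(station_records["station_id"].iloc[0])
    sub = station_records[station_records["doy"] <= 365]
    daily_names = [n for n in registry.daily_names() if n in sub.columns]
    grouped = sub.groupby("doy")[daily_names].mean()
    daily = grouped.reindex(range(1, 366))
    daily.index.name = "doy"
    static = {}
    for name in registry.static_names():
        if name in station_records.columns:
            vals = station_records[name].dropna()
            static[name] = float(vals.iloc[0]) if len(vals) else np.nan
    empty = [n for n in daily_names if daily[n].isna().all()]
    if empty:
        logger.warning("doy_climatology[%s]: no data for factors %s", sid, empty)
    return DOYClimatology(sid, daily, static)


def build_climatologies(
    records: pd.DataFrame, registry: FactorRegistry
) -> dict[str, DOYClimatology]:
    return {
        str(sid): doy_climatology(block, registry)
        for sid, block in records.groupby("station_id", sort=False)
    }


def pairwise_ds(
    x: DOYClimatology,
    y: DOYClimatology,
    factor: str,
    t_min: int = DEFAULT_T_MIN,
) -> tuple[float, int]:
    """Euclidean distance for one factor between two stations.

    Root-sum-of-squares of the climatology difference over the DOYs both
    stations observed; static factors compare their single values (t = 1).
    Returns (distance, t_used); the distance is NaN when the common overlap
    falls below ``t_min`` for a daily factor.
    """
    a = x.factor_series(factor)
    b = y.factor_series(factor)
    is_static = factor in x.static
    mask = np.isfinite(a) & np.isfinite(b)
    t = int(mask.sum())
    required = 1 if is_static else t_min
    if t < required:
        return np.nan, t
    diff = a[mask] - b[mask]
    return float(np.sqrt(np.sum(diff**2))), t


class DistanceCache:
    """Precomputed pairwise per-factor distances over a station set.

    Distance-vector assembly touches the same station pairs many times
    (every model sharing training stations reuses them), so all pairwise
    ds values are computed once per factor.
    """

    def __init__(
        self,
        climatologies: dict[str, DOYClimatology],
        registry: FactorRegistry,
        t_min: int = DEFAULT_T_MIN,
    ):
        self.registry = registry
        self.t_min = t_min
        self.station_ids = list(climatologies.keys())
        self._index = {s: i for i, s in enumerate(self.station_ids)}
        n = len(self.station_ids)
        self._ds: dict[str, np.ndarray] = {}
        self._t: dict[str, np.ndarray] = {}
        clims = [climatologies[s] for s in self.station_ids]
        for factor in registry.names:
            mat = np.full((n, n), np.nan)
            tmat = np.zeros((n, n), dtype=int)
            for i in range(n):
                for j in range(i + 1, n):
                    d, t = pairwise_ds(clims[i], clims[j], factor, t_min=t_min)
                    mat[i, j] = mat[j, i] = d
                    tmat[i, j] = tmat[j, i] = t
                mat[i, i] = 0.0
            self._ds[factor] = mat
            self._t[factor] = tmat

    def ds(self, factor: str, a: str, b: str) -> float:
        return float(self._ds[factor][self._index[a], self._index[b]])

    def training_set_distance(
        self, station_id: str, training_ids, factor: str
    ) -> float:
        """Mean of the defined pairwise ds between a station and each
        training station; NaN when no pair is defined."""
        row = self._ds[factor][self._index[station_id]]
        vals = row[[self._index[t] for t in training_ids]]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            return np.nan
        return float(np.mean(vals))

    def distance_vector(
        self, station_id: str, training_ids, scenario: str
    ) -> np.ndarray:
        """d_1..d_w aligned with the registry's scenario factor ordering."""
        names = self.registry.feature_names(scenario)
        return np.array(
            [self.training_set_distance(station_id, training_ids, f) for f in names]
        )


def training_set_distance(
    station: DOYClimatology,
    training: list[DOYClimatology],
    factor: str,
    t_min: int = DEFAULT_T_MIN,
) -> float:
    """Cache-free form of the station-to-training-set distance (mean of the
    defined pairwise ds values)."""
    vals = [pairwise_ds(station, t, factor, t_min=t_min)[0] for t in training]
    vals = [v for v in vals if np.isfinite(v)]
    if not vals:
        raise ValueError(f"no defined pairwise distance for factor {factor!r}")
    return float(np.mean(vals))


def build_dataset1(
    evaluations: list[StationEvaluation],
    rfms_by_id: dict[str, TrainedRFM],
    cache: DistanceCache,
    scenario: str,
) -> pd.DataFrame:
    """Pair every valid CV evaluation with its station-model distance vector.

    One row per (model, test station): the realized R^2 plus d_<factor>
    columns. Zero-variance evaluations, and rows whose distance vector has
    any undefined entry, are excluded and logged. Per category the expected
    row count is n x p minus exclusions.
    """
    names = cache.registry.feature_names(scenario)
    rows = []
    n_excluded = 0
    for ev in evaluations:
        if not ev.valid:
            n_excluded += 1
            continue
        rfm = rfms_by_id[ev.rfm_id]
        dvec = cache.distance_vector(ev.station_id, rfm.training_station_ids, scenario)
        if not np.all(np.isfinite(dvec)):
            n_excluded += 1
            continue
        rows.append(
            {
                "station_id": ev.station_id,
                "rfm_id": ev.rfm_id,
                "category": ev.category,
                "split": ev.split,
                "r2": ev.r2,
                **{f"d_{n}": v for n, v in zip(names, dvec)},
            }
        )
    if n_excluded:
        logger.info("build_dataset1: excluded %d samples", n_excluded)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RSModel:
    """Fitted R^2-simulation regression for one (category, scenario, target).

    ``coefficients`` is aligned with the scenario's registry factor order;
    factors dropped for collinearity keep a zero coefficient and are listed
    in ``dropped``.
    """

    category: str
    scenario: str
    target: str
    intercept: float
    coefficients: np.ndarray
    factor_names: tuple[str, ...]
    dropped: tuple[str, ...]
    n_samples: int
    r2_rsm: float
    adj_r2: float
    f_stat: float
    p_value: float


def _independent_columns(X: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (pivoted QR)."""
    if X.shape[1] == 0:
        return np.array([], dtype=int)
    r = np.linalg.matrix_rank(X)
    if r == X.shape[1]:
        return np.arange(X.shape[1])
    _, _, piv = qr(X, mode="economic", pivoting=True)
    return np.sort(piv[:r])


def _vif_prune(X: np.ndarray, max_vif: float) -> np.ndarray:
    """Indices of columns kept after iterative variance-inflation pruning.

    Distance columns are strongly correlated (factors share the station
    offsets that drive them), and with modest sample sizes the resulting
    near-collinearity makes OLS coefficients explosive when the regression
    is applied outside the fitted cloud. Columns are dropped one at a time
    (highest VIF first) until every remaining VIF <= ``max_vif``.
    """
    keep = list(range(X.shape[1]))
    while len(keep) > 1:
        Z = X[:, keep]
        Z = (Z - Z.mean(axis=0)) / Z.std(axis=0)
        corr = (Z.T @ Z) / len(Z)
        try:
            vif = np.diag(np.linalg.inv(corr))
        except np.linalg.LinAlgError:
            vif = np.full(len(keep), np.inf)
        worst = int(np.argmax(vif))
        if vif[worst] <= max_vif:
            break
        keep.pop(worst)
    return np.array(keep, dtype=int)


def fit_rsm(
    dataset1: pd.DataFrame,
    registry: FactorRegistry,
    scenario: str,
    category: str,
    target: str,
    max_vif: float | None = 5.0,
    backward_alpha: float | None = None,
) -> RSModel:
    """Ordinary least squares of realized R^2 on the distance vector.

    Collinear distance columns — exact duplicates, constants (which are
    indistinguishable from the intercept) and, when ``max_vif`` is set,
    near-collinear columns by iterative variance-inflation pruning — are
    dropped with a log message before fitting. With ``backward_alpha`` set,
    backward elimination additionally removes terms whose coefficient is
    insignificant at that level (highest p value first); this stabilises
    predictions outside the fitted cloud at small sample sizes and is what
    the transfer pipeline uses. The default is the plain full regression.
    Reports the regression's R^2, adjusted R^2, F statistic and p value
    alongside the coefficients.
    """
    names = registry.feature_names(scenario)
    w = len(names)
    if len(dataset1) < w + 2:
        raise ValueError(
            f"need at least w+2={w + 2} samples to fit the RSM, got {len(dataset1)}"
        )
    y = dataset1["r2"].to_numpy(dtype=float)
    X = dataset1[[f"d_{n}" for n in names]].to_numpy(dtype=float)
    # centre-test for constant columns: they carry no slope information
    varying = X.std(axis=0) > 1e-12
    keep = np.flatnonzero(varying)
    sub = _independent_columns(X[:, keep])
    keep = keep[sub]
    if max_vif is not None and len(keep) > 1:
        keep = keep[_vif_prune(X[:, keep], max_vif)]
    design = sm.add_constant(X[:, keep], has_constant="add")
    res = sm.OLS(y, design).fit()
    if backward_alpha is not None:
        while len(keep) > 0:
            pvals = res.pvalues[1:]  # slope terms only
            worst = int(np.argmax(pvals))
            if pvals[worst] <= backward_alpha:
                break
            keep = np.delete(keep, worst)
            design = sm.add_constant(X[:, keep], has_constant="add")
            res = sm.OLS(y, design).fit()
    dropped = tuple(n for i, n in enumerate(names) if i not in set(keep))
    if dropped:
        logger.info("fit_rsm[%s/%s/%s]: dropped columns %s",
                    category, scenario, target, dropped)
    coefs = np.zeros(w)
    coefs[keep] = res.params[1:]
    return RSModel(
        category=category,
        scenario=scenario,
        target=target,
        intercept=float(res.params[0]),
        coefficients=coefs,
        factor_names=names,
        dropped=dropped,
        n_samples=len(dataset1),
        r2_rsm=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        f_stat=float(res.fvalue),
        p_value=float(res.f_pvalue),
    )


def predict_r2(rsm: RSModel, distance_vector: np.ndarray) -> float:
    """Predicted R^2 = a0 + a . d. Unclamped — values above 1 or below 0 are
    reported as-is."""
    d = np.asarray(distance_vector, dtype=float)
    if d.shape != rsm.coefficients.shape:
        raise ValueError(
            f"distance vector length {d.shape} != coefficients {rsm.coefficients.shape}"
        )
    return float(rsm.intercept + rsm.coefficients @ d)


def quality_class(r2: float) -> int:
    """Quality classes: 1 (R^2 < 0.5), 2 (0.5 <= R^2 < 0.7), 3 (R^2 >= 0.7)."""
    if r2 >= 0.7:
        return 3
    if r2 >= 0.5:
        return 2
    return 1


def classification_accuracy(true_r2, predicted_r2) -> float:
    """Fraction of samples whose true and predicted R^2 land in the same
    quality class."""
    t = np.asarray(true_r2, dtype=float)
    p = np.asarray(predicted_r2, dtype=float)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("true and predicted lists must have equal nonzero length")
    tc = np.array([quality_class(v) for v in t])
    pc = np.array([quality_class(v) for v in p])
    return float(np.mean(tc == pc))


def rsm_table(rsms: list[RSModel]) -> pd.DataFrame:
    """Summary table mirroring a regression-information file: model name,
    category, N, R^2, adjusted R^2, F, p, and the fitted equation."""
    rows = []
    for m in rsms:
        terms = " + ".join(
            f"({c:.4g})*d_{n}" for n, c in zip(m.factor_names, m.coefficients) if c != 0
        )
        rows.append(
            {
                "model": f"RSM-{m.target}-{m.scenario}-{m.category}",
                "category": m.category,
                "scenario": m.scenario,
                "target": m.target,
                "n": m.n_samples,
                "r2_rsm": m.r2_rsm,
                "adj_r2_rsm": m.adj_r2,
                "f_statistic": m.f_stat,
                "p_value": m.p_value,
                "equation": f"R2 = {m.intercept:.4g}" + (f" + {terms}" if terms else ""),
            }
        )
    return pd.DataFrame(rows)
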