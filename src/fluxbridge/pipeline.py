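"""End-to-end orchestration: screen candidate models at meteorological
stations, simulate daily fluxes with the winners, and write station datasets.

The screening rule: every model whose category matches one of the station's
four memberships is a candidate; each candidate's R^2 at the station is
predicted from the station-to-training-set distance vector with the
candidate category's fitted regression; the candidate with the maximum
predicted R^2 wins, but only if that maximum is at least 0.5 — otherwise
the station gets no model and no simulated fluxes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    CVSummary,
    HyperSearchConfig,
    StationEvaluation,
    TrainedRFM,
    evaluations_to_frame,
    run_cv,
    summarize_cv,
)
from .partition import (
    CategoryPartition,
    assign_categories,
    build_partitions,
    make_category_plans,
    write_cv_plans,
)
from .preprocess import preprocess_records
from .registry import CATEGORIES, FactorRegistry, default_registry
from .synthetic import NetworkConfig, StationMeta, generate_network, metas_to_frame
from .transferability import (
    DistanceCache,
    RSModel,
    build_climatologies,
    build_dataset1,
    classification_accuracy,
    fit_rsm,
    predict_r2,
    quality_class,
    rsm_table,
)

logger = logging.getLogger(__name__)

_CATEGORY_RANK = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class TransferDecision:
    """Outcome of screening one (station, scenario, target)."""

    station_id: str
    scenario: str
    target: str
    rfm_id: str | None
    predicted_r2: float | None
    quality: int  # 1 when no model was chosen
    n_candidates: int
    reason: str = ""

    @property
    def transferred(self) -> bool:
        return self.rfm_id is not None


def candidate_rfms(
    meta: StationMeta,
    rfms: list[TrainedRFM],
    scenario: str,
    target: str,
) -> list[TrainedRFM]:
    """Models of the given scenario/target whose category is one of the
    station's four memberships."""
    cats = assign_categories(meta)
    return [
        m
        for m in rfms
        if m.scenario == scenario and m.target == target and m.category in cats
    ]


def screen(
    meta: StationMeta,
    candidates: list[TrainedRFM],
    rsms: dict[tuple[str, str, str], RSModel],
    cache: DistanceCache,
) -> TransferDecision:
    """Pick the candidate with the maximum predicted R^2, if it reaches 0.5.

    Candidates whose distance vector has undefined entries, or whose
    category has no fitted regression, are unscorable and skipped. Ties are
    broken deterministically: earlier category in canonical order first,
    then lexicographically smaller model id; ties are logged.
    """
    scored: list[tuple[float, int, str, TrainedRFM]] = []
    for m in candidates:
        rsm = rsms.get((m.category, m.scenario, m.target))
        if rsm is None:
            continue
        dvec = cache.distance_vector(meta.station_id, m.training_station_ids, m.scenario)
        if not np.all(np.isfinite(dvec)):
            continue
        scored.append((predict_r2(rsm, dvec), _CATEGORY_RANK[m.category], m.rfm_id, m))
    scenario = candidates[0].scenario if candidates else ""
    target = candidates[0].target if candidates else ""
    if not scored:
        return TransferDecision(
            meta.station_id, scenario, target, None, None, 1,
            n_candidates=len(candidates), reason="no scorable candidate",
        )
    best = max(scored, key=lambda s: (s[0], -s[1], _neg_str(s[2])))
    ties = [s for s in scored if s[0] == best[0]]
    if len(ties) > 1:
        logger.info(
            "screen[%s]: %d candidates tied at predicted R2=%.4f; chose %s",
            meta.station_id, len(ties), best[0], best[3].rfm_id,
        )
    pred, _, _, model = best
    if pred < 0.5:
        return TransferDecision(
            meta.station_id, model.scenario, model.target, None, None, 1,
            n_candidates=len(candidates), reason=f"max predicted R2 {pred:.3f} < 0.5",
        )
    # predicted R2 above 1 is reported as-is but clamped for class binning
    return TransferDecision(
        meta.station_id, model.scenario, model.target, model.rfm_id, pred,
        quality_class(min(pred, 1.0)), n_candidates=len(candidates),
    )


class _neg_str:
    """Ordering adapter: max() with this key prefers the smaller string."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_neg_str") -> bool:
        return self.s > other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _neg_str) and self.s == other.s


def simulate_fluxes(rfm: TrainedRFM, station_records: pd.DataFrame) -> pd.DataFrame:
    """Predict the model's target for every feature-complete day.

    Days missing any feature are omitted (and counted in the log). Returns
    the calendar columns plus a ``prediction`` column.
    """
    feats = list(rfm.features)
    complete = station_records[feats].notna().all(axis=1)
    n_skipped = int((~complete).sum())
    if complete.sum() == 0:
        raise ValueError("no feature-complete days to simulate")
    if n_skipped:
        logger.info("simulate_fluxes[%s]: omitted %d incomplete days",
                    station_records['station_id'].iloc[0], n_skipped)
    sub = station_records.loc[complete]
    out = sub[["station_id", "year", "month", "day", "doy"]].copy()
    out["prediction"] = rfm.model.predict(sub[feats].to_numpy())
    return out


def write_station_outputs(
    decisions: list[TransferDecision],
    predictions: dict[tuple[str, str, str], pd.DataFrame],
    metas: list[StationMeta],
    out_dir: str | Path,
) -> list[Path]:
    """Write per-station daily flux CSVs and the station-information table.

    One CSV per (station, scenario) under ``<target>-<scenario>/<id>.csv``
    with columns id, lon, lat, year, month, day, doy, NEE, WF (the target
    not simulated for that station/scenario stays empty). Stations with no
    chosen model get no flux CSV but still appear in the information table
    with quality class 1.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_by_id = {m.station_id: m for m in metas}
    written: list[Path] = []

    by_station_scenario: dict[tuple[str, str], dict[str, pd.DataFrame]] = {}
    for (sid, scenario, target), preds in predictions.items():
        by_station_scenario.setdefault((sid, scenario), {})[target] = preds
    for (sid, scenario), targets in by_station_scenario.items():
        m = meta_by_id[sid]
        frames = []
        for target, preds in targets.items():
            f = preds.rename(columns={"prediction": target})
            frames.append(f.set_index(["year", "month", "day", "doy"])[[target]])
        merged = pd.concat(frames, axis=1).reset_index()
        for col in ("NEE", "WF"):
            if col not in merged.columns:
                merged[col] = np.nan
        merged.insert(0, "id", sid)
        merged.insert(1, "lon", m.lon)
        merged.insert(2, "lat", m.lat)
        merged = merged[["id", "lon", "lat", "year", "month", "day", "doy", "NEE", "WF"]]
        subdir = out / scenario
        subdir.mkdir(exist_ok=True)
        path = subdir / f"{sid}.csv"
        merged.to_csv(path, index=False)
        written.append(path)

    info_rows = []
    dec_by_station: dict[str, dict[tuple[str, str], TransferDecision]] = {}
    for d in decisions:
        dec_by_station.setdefault(d.station_id, {})[(d.scenario, d.target)] = d
    for sid, dmap in dec_by_station.items():
        m = meta_by_id[sid]
        row = {
            "id": sid,
            "station_name": sid,
            "longitude": m.lon,
            "latitude": m.lat,
            "elevation": m.elevation,
            "continent": m.continent,
            "drought_situation": "Arid" if m.aridity_index < 0.65 else "NonArid",
            "landscape": m.landscape,
            "data_source": "synthetic",
        }
        for target in ("NEE", "WF"):
            for scenario in ("RS", "WRS"):
                d = dmap.get((scenario, target))
                row[f"class_{target}_{scenario}"] = d.quality if d else 1
        info_rows.append(row)
    info_path = out / "station_info.csv"
    pd.DataFrame(info_rows).to_csv(info_path, index=False)
    written.append(info_path)
    return written


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one full framework run."""

    network: NetworkConfig = field(default_factory=NetworkConfig)
    k: int = 10
    p: int = 10
    scenarios: tuple[str, ...] = ("RS", "WRS")
    targets: tuple[str, ...] = ("NEE", "WF")
    #: restrict CV/RSM/screening to these categories (None = all nine)
    categories: tuple[str, ...] | None = None
    hyper: HyperSearchConfig = field(default_factory=HyperSearchConfig)
    qc_threshold: float = 0.8
    max_gap: int = 7
    t_min: int = 30
    #: minimum Dataset-1 rows per regression term (w+1) before an RSM is
    #: trusted; under-sampled category RSMs are skipped and their models
    #: become unscorable rather than scored by an unstable regression
    min_rsm_rows_per_term: float = 3.0
    #: backward-elimination level for RSM terms (None = keep all terms).
    #: Strict by default: with tens of samples and ~20 candidate distance
    #: columns, a loose level retains chance correlates whose slopes
    #: misprice stations far from the fitted cloud.
    rsm_backward_alpha: float | None = 0.01
    seed: int = 0


@dataclass
class RunReport:
    """Machine-readable summary of one full run."""

    model_count: int
    evaluation_counts: dict[str, int]  # per category (pooled over scen/target)
    dataset1_counts: dict[str, int]
    frac_evals_r2_ge_05: dict[str, float]  # per "target-scenario"
    frac_stations_max_r2_ge_05: dict[str, float]
    rsm_accuracy: dict[str, float]
    transfer_pct: dict[str, float]
    n_flux_stations: int
    n_met_stations: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    """Everything a run produced, for inspection or further analysis."""

    report: RunReport
    metas: list[StationMeta]
    records: pd.DataFrame
    models: list[TrainedRFM]
    evaluations: list[StationEvaluation]
    rsms: dict[tuple[str, str, str], RSModel]
    dataset1: dict[tuple[str, str, str], pd.DataFrame]
    decisions: list[TransferDecision]
    predictions: dict[tuple[str, str, str], pd.DataFrame]
    truths: dict


def run_full_pipeline(
    config: PipelineConfig,
    registry: FactorRegistry | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute generate -> preprocess -> partition -> CV -> Dataset 1 ->
    RSM -> screen -> simulate -> write, returning a result bundle with a
    machine-readable report. Deterministic given the config."""
    registry = registry or default_registry()
    ss = np.random.SeedSequence(config.seed)
    seed_plan, seed_cv = (
        int(np.random.default_rng(c).integers(2**31)) for c in ss.spawn(2)
    )

    logger.info("stage 1/6: generating synthetic network")
    metas, raw, truths = generate_network(config.network)
    records = preprocess_records(
        raw, registry, qc_threshold=config.qc_threshold, max_gap=config.max_gap
    )

    logger.info("stage 2/6: partitioning and CV planning")
    partitions = build_partitions(metas, role="flux")
    if config.categories is not None:
        partitions = [p for p in partitions if p.category in config.categories]
    usable = [p for p in partitions if p.n >= config.k]
    skipped = [p.category for p in partitions if 0 < p.n < config.k]
    if skipped:
        logger.warning("categories with fewer than k stations skipped: %s", skipped)
    plans = make_category_plans(usable, k=config.k, p=config.p, seed=seed_plan)

    flux_ids = {m.station_id for m in metas if m.role == "flux"}
    flux_records = records[records["station_id"].isin(flux_ids)]

    logger.info("stage 3/6: grouped cross-validation (%d categories)", len(plans))
    models: list[TrainedRFM] = []
    evaluations: list[StationEvaluation] = []
    cv_rng = np.random.default_rng(seed_cv)
    for category in [c for c in CATEGORIES if c in plans]:
        plan = plans[category]
        cat_records = flux_records[
            flux_records["station_id"].isin(plan.assignment[0].keys())
        ]
        for scenario in config.scenarios:
            for target in config.targets:
                ms, evs = run_cv(
                    cat_records, plan, scenario, target, registry,
                    hyper=config.hyper, seed=int(cv_rng.integers(2**31)),
                )
                models.extend(ms)
                evaluations.extend(evs)

    logger.info("stage 4/6: climatologies, Dataset 1 and RSM fits")
    clims = build_climatologies(records, registry)
    cache = DistanceCache(clims, registry, t_min=config.t_min)
    rfms_by_id = {m.rfm_id: m for m in models}
    rsms: dict[tuple[str, str, str], RSModel] = {}
    dataset1: dict[tuple[str, str, str], pd.DataFrame] = {}
    for category in plans:
        for scenario in config.scenarios:
            for target in config.targets:
                evs = [
                    e for e in evaluations
                    if e.category == category and e.scenario == scenario
                    and e.target == target
                ]
                ds1 = build_dataset1(evs, rfms_by_id, cache, scenario)
                dataset1[(category, scenario, target)] = ds1
                w = len(registry.feature_names(scenario))
                needed = max(w + 2, int(np.ceil(config.min_rsm_rows_per_term * (w + 1))))
                if len(ds1) < needed:
                    logger.info(
                        "RSM fit skipped for %s/%s/%s: %d samples < %d required",
                        category, scenario, target, len(ds1), needed,
                    )
                    continue
                rsms[(category, scenario, target)] = fit_rsm(
                    ds1, registry, scenario, category, target,
                    backward_alpha=config.rsm_backward_alpha,
                )

    logger.info("stage 5/6: screening %d meteorological stations",
                sum(m.role == "meteorological" for m in metas))
    met_metas = [m for m in metas if m.role == "meteorological"]
    decisions: list[TransferDecision] = []
    predictions: dict[tuple[str, str, str], pd.DataFrame] = {}
    for meta in met_metas:
        st_records = records[records["station_id"] == meta.station_id]
        for scenario in config.scenarios:
            for target in config.targets:
                cands = candidate_rfms(meta, models, scenario, target)
                if not cands:
                    decisions.append(TransferDecision(
                        meta.station_id, scenario, target, None, None, 1,
                        n_candidates=0, reason="no candidate models",
                    ))
                    continue
                dec = screen(meta, cands, rsms, cache)
                decisions.append(dec)
                if dec.transferred:
                    preds = simulate_fluxes(rfms_by_id[dec.rfm_id], st_records)
                    predictions[(meta.station_id, scenario, target)] = preds

    logger.info("stage 6/6: reporting%s", " and writing outputs" if out_dir else "")
    report = _build_report(
        config, metas, models, evaluations, dataset1, rsms, decisions, cache, rfms_by_id
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metas_to_frame(metas).to_csv(out / "stations.csv", index=False)
        write_cv_plans(plans, out / "cv_plans.csv")
        evaluations_to_frame(evaluations).to_csv(out / "evaluations.csv", index=False)
        if rsms:
            rsm_table(list(rsms.values())).to_csv(out / "rsms.csv", index=False)
        ds1_dir = out / "dataset1"
        ds1_dir.mkdir(exist_ok=True)
        for (cat, scen, targ), df in dataset1.items():
            df.to_csv(ds1_dir / f"{cat}-{targ}-{scen}.csv", index=False)
        write_station_outputs(decisions, predictions, metas, out / "fluxes")
        (out / "report.json").write_text(report.to_json())

    return PipelineResult(
        report=report, metas=metas, records=records, models=models,
        evaluations=evaluations, rsms=rsms, dataset1=dataset1,
        decisions=decisions, predictions=predictions, truths=truths,
    )


def _build_report(
    config, metas, models, evaluations, dataset1, rsms, decisions, cache, rfms_by_id
) -> RunReport:
    eval_counts: dict[str, int] = {}
    for e in evaluations:
        eval_counts[e.category] = eval_counts.get(e.category, 0) + 1
    ds1_counts = {}
    for (cat, scen, targ), df in dataset1.items():
        ds1_counts[f"{cat}-{targ}-{scen}"] = len(df)

    frac_ge: dict[str, float] = {}
    frac_max: dict[str, float] = {}
    rsm_acc: dict[str, float] = {}
    for scenario in config.scenarios:
        for target in config.targets:
            key = f"{target}-{scenario}"
            evs = [e for e in evaluations
                   if e.scenario == scenario and e.target == target and e.valid]
            if evs:
                summary = summarize_cv(evs)
                frac_ge[key] = summary.frac_evals_r2_ge_05
                frac_max[key] = summary.frac_stations_max_ge_05
            # pooled RSM classification accuracy over categories
            true_all, pred_all = [], []
            for (cat, scen, targ), rsm in rsms.items():
                if scen != scenario or targ != target:
                    continue
                df = dataset1[(cat, scen, targ)]
                names = [f"d_{n}" for n in rsm.factor_names]
                preds = rsm.intercept + df[names].to_numpy() @ rsm.coefficients
                true_all.extend(df["r2"].tolist())
                pred_all.extend(preds.tolist())
            if true_all:
                rsm_acc[key] = classification_accuracy(true_all, pred_all)
    transfer_pct = {}
    for scenario in config.scenarios:
        for target in config.targets:
            key = f"{target}-{scenario}"
            decs = [d for d in decisions
                    if d.scenario == scenario and d.target == target]
            if decs:
                transfer_pct[key] = 100.0 * float(np.mean([d.transferred for d in decs]))

    return RunReport(
        model_count=len(models),
        evaluation_counts=eval_counts,
        dataset1_counts=ds1_counts,
        frac_evals_r2_ge_05=frac_ge,
        frac_stations_max_r2_ge_05=frac_max,
        rsm_accuracy=rsm_acc,
        transfer_pct=transfer_pct,
        n_flux_stations=sum(m.role == "flux" for m in metas),
        n_met_stations=sum(m.role == "meteorological" for m in metas),
    )
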