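"""Record-level transformations applied to daily station tables.

Four operations: vapour-pressure-deficit derivation from air and dew-point
temperature, latent-heat to water-flux conversion, quality-control filtering
of flux values, and gap-limited linear interpolation of remote-sensing
factor series.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .registry import FactorRegistry

logger = logging.getLogger(__name__)

#: Conversion from a daily-mean latent-heat flux density (W m-2) to a daily
#: water flux (mm d-1): the daily energy total (x 86400 s) times the
#: evaporation equivalent of one joule per square metre, 0.408e-6 mm
#: (i.e. 1/lambda with lambda ~ 2.45 MJ kg-1).
LE_TO_WF_FACTOR = 0.408e-6
SECONDS_PER_DAY = 86400.0


def saturation_vapour_pressure(temp_c):
    """Magnus (FAO-56) saturation vapour pressure in kPa at ``temp_c`` degC."""
    t = np.asarray(temp_c, dtype=float)
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def compute_vpd(air_temp, dewpoint):
    """Vapour pressure deficit (kPa) from air and dew-point temperature (degC).

    vpd = es(Ta) - es(Td) with the Magnus saturation curve. A dew point
    above the air temperature is physically a saturated (or supersaturated)
    reading, so the deficit is clamped at zero; the clamp is logged.

    Accepts scalars or array-likes; returns a scalar for scalar input.
    """
    ta = np.asarray(air_temp, dtype=float)
    td = np.asarray(dewpoint, dtype=float)
    if not (np.all(np.isfinite(ta)) and np.all(np.isfinite(td))):
        raise ValueError("compute_vpd requires finite temperatures")
    vpd = saturation_vapour_pressure(ta) - saturation_vapour_pressure(td)
    clamped = vpd < 0
    n_clamped = int(np.count_nonzero(clamped))
    if n_clamped:
        logger.warning(
            "compute_vpd: dew point above air temperature for %d value(s); "
            "deficit clamped to 0",
            n_clamped,
        )
        vpd = np.where(clamped, 0.0, vpd)
    if np.ndim(air_temp) == 0 and np.ndim(dewpoint) == 0:
        return float(vpd)
    return vpd


def le_to_wf(le_daily_mean):
    """Convert a daily-mean latent-heat flux (W m-2) to water flux (mm d-1).

    Linear and sign-preserving: negative LE (condensation) maps to negative
    water flux.
    """
    le = np.asarray(le_daily_mean, dtype=float)
    if not np.all(np.isfinite(le)):
        raise ValueError("le_to_wf requires finite input")
    wf = le * SECONDS_PER_DAY * LE_TO_WF_FACTOR
    if np.ndim(le_daily_mean) == 0:
        return float(wf)
    return wf


def qc_filter(records: pd.DataFrame, threshold: float = 0.8) -> pd.DataFrame:
    """Mask flux values whose quality-control flag falls below ``threshold``.

    The threshold is inclusive: a flag exactly equal to it keeps the flux.
    Rows without a QC flag (NaN) pass unchanged — sources without QC
    information are trusted as-is. Covariate columns are never touched.
    Returns a copy.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    out = records.copy()
    n_masked = 0
    for qc_col, flux_col in (("qc_nee", "nee"), ("qc_le", "wf")):
        if qc_col not in out.columns or flux_col not in out.columns:
            continue
        bad = out[qc_col].notna() & (out[qc_col] < threshold)
        n_masked += int(bad.sum())
        out.loc[bad, flux_col] = np.nan
    if n_masked:
        logger.info("qc_filter: masked %d flux values below %.2f", n_masked, threshold)
    return out


def interpolate_series(values, max_gap: int = 7) -> np.ndarray:
    """Linearly fill interior NaN runs of length <= ``max_gap``.

    Runs longer than ``max_gap`` days, and leading/trailing runs (which lack
    a flanking observation on one side), are left missing. Observed values
    are never altered. The default of 7 implements a "fill only gaps of
    fewer than 8 consecutive missing days" rule.
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    v = np.asarray(values, dtype=float).copy()
    isna = np.isnan(v)
    if not isna.any():
        return v
    n = len(v)
    i = 0
    while i < n:
        if not isna[i]:
            i += 1
            continue
        j = i
        while j < n and isna[j]:
            j += 1
        run = j - i
        # interior run with both flanks observed, short enough to trust
        if i > 0 and j < n and run <= max_gap:
            left, right = v[i - 1], v[j]
            frac = np.arange(1, run + 1) / (run + 1)
            v[i:j] = left + frac * (right - left)
        i = j
    return v


def interpolate_rs(
    records: pd.DataFrame,
    registry: FactorRegistry,
    max_gap: int = 7,
) -> pd.DataFrame:
    """Gap-fill remote-sensing factor columns station by station.

    Applies :func:`interpolate_series` to each (station, RS factor) daily
    series in chronological order. Only remote-sensing factors are filled —
    meteorological gaps are left to the source, static factors have no time
    dimension. Returns a copy; fill counts are logged.
    """
    rs_cols = [c for c in registry.rs_names() if c in records.columns]
    if not rs_cols:
        return records.copy()
    out = records.sort_values(["station_id", "year", "doy"], kind="stable").copy()
    n_filled = 0
    for _, idx in out.groupby("station_id", sort=False).groups.items():
        block = out.loc[idx, rs_cols]
        for col in rs_cols:
            filled = interpolate_series(block[col].to_numpy(), max_gap=max_gap)
            n_filled += int(np.isnan(block[col].to_numpy()).sum() - np.isnan(filled).sum())
            out.loc[idx, col] = filled
    if n_filled:
        logger.info("interpolate_rs: filled %d values (max_gap=%d)", n_filled, max_gap)
    return out


def add_vpd(records: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``vpd`` column derived from ``ta``/``td``; rows with either
    temperature missing get a missing VPD."""
    out = records.copy()
    ta = out["ta"].to_numpy(dtype=float)
    td = out["td"].to_numpy(dtype=float)
    ok = np.isfinite(ta) & np.isfinite(td)
    vpd = np.full(len(out), np.nan)
    if ok.any():
        vpd[ok] = compute_vpd(ta[ok], td[ok])
    out["vpd"] = vpd
    return out


def preprocess_records(
    records: pd.DataFrame,
    registry: FactorRegistry,
    qc_threshold: float = 0.8,
    max_gap: int = 7,
) -> pd.DataFrame:
    """Standard preprocessing chain: VPD derivation, QC filtering of fluxes,
    then gap-limited interpolation of remote-sensing factors."""
    out = add_vpd(records)
    out = qc_filter(out, threshold=qc_threshold)
    out = interpolate_rs(out, registry, max_gap=max_gap)
    return out
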