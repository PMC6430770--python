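"""CSV schemas and readers/writers for pipeline tables.

Two input schemas:

``pools.csv``
    columns: metabolite, fraction, value, sd, n_replicates, units

``mids.csv``
    columns: metabolite, compartment_or_fraction, time_min, m0..m{n},
    sd_m0..sd_m{n}; metabolites with fewer carbons leave the higher
    m-columns empty.

MID rows are validated against sum-to-one: deviations up to
``RENORM_TOL`` are silently normalized, larger ones (still summing to
something sensible) are renormalized with a logged warning, and rows whose
sum is off by more than 0.5 are rejected as schema errors.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

__all__ = [
    "RENORM_TOL",
    "SchemaError",
    "read_pools_csv",
    "write_pools_csv",
    "read_mids_csv",
    "write_mids_csv",
    "measurements_to_frames",
]

logger = logging.getLogger("spatialflux")

RENORM_TOL = 0.05
_HARD_TOL = 0.5

POOLS_COLUMNS = ["metabolite", "fraction", "value", "sd", "n_replicates", "units"]
_MID_META = ["metabolite", "compartment_or_fraction", "time_min"]


class SchemaError(ValueError):
    """An input table does not conform to its documented schema."""


def read_pools_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in POOLS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"pools table {path}: missing column(s) {missing}")
    bad = df.index[(df["value"] < 0) | (df["sd"] < 0)]
    if len(bad):
        raise SchemaError(
            f"pools table {path}: negative value/sd in row(s) {list(bad)}"
        )
    logger.info("read %d pool rows from %s", len(df), path)
    return df


def write_pools_csv(path, rows) -> None:
    """Write pool measurements (iterable of dicts or PoolMeasurement)."""
    records = []
    for r in rows:
        if hasattr(r, "metabolite"):
            records.append(
                {
                    "metabolite": r.metabolite,
                    "fraction": r.fraction,
                    "value": r.value,
                    "sd": r.sd,
                    "n_replicates": r.n_replicates,
                    "units": getattr(r, "units", "relative"),
                }
            )
        else:
            records.append({c: r[c] for c in POOLS_COLUMNS})
    pd.DataFrame(records, columns=POOLS_COLUMNS).to_csv(path, index=False)


def _mid_columns(df: pd.DataFrame):
    m_cols = sorted(
        (c for c in df.columns if re.fullmatch(r"m\d+", c)),
        key=lambda c: int(c[1:]),
    )
    sd_cols = [f"sd_{c}" for c in m_cols]
    if not m_cols:
        raise SchemaError("MID table: no m0..mN columns found")
    missing_sd = [c for c in sd_cols if c not in df.columns]
    if missing_sd:
        raise SchemaError(f"MID table: missing SD column(s) {missing_sd}")
    return m_cols, sd_cols


def read_mids_csv(path, renorm_tol: float = RENORM_TOL) -> pd.DataFrame:
    """Read and validate a MID table; renormalize rows toward sum = 1."""
    df = pd.read_csv(path)
    missing = [c for c in _MID_META if c not in df.columns]
    if missing:
        raise SchemaError(f"MID table {path}: missing column(s) {missing}")
    m_cols, sd_cols = _mid_columns(df)
    vals = df[m_cols].to_numpy(dtype=float)
    present = ~np.isnan(vals)
    sums = np.nansum(vals, axis=1)
    off = np.abs(sums - 1.0)
    bad = off > _HARD_TOL
    if bad.any():
        raise SchemaError(
            f"MID table {path}: row(s) {list(df.index[bad])} sum to "
            f"{sums[bad]} (beyond tolerance {_HARD_TOL})"
        )
    warn_rows = np.flatnonzero(off > renorm_tol)
    for i in warn_rows:
        logger.warning(
            "MID row %d (%s, %s, t=%s) sums to %.4f; renormalizing",
            i,
            df.loc[i, "metabolite"],
            df.loc[i, "compartment_or_fraction"],
            df.loc[i, "time_min"],
            sums[i],
        )
    vals = np.where(present, vals / sums[:, None], vals)
    df[m_cols] = vals
    logger.info("read %d MID rows from %s", len(df), path)
    return df


def write_mids_csv(path, records) -> None:
    """Write MID records: dicts with metabolite, compartment_or_fraction,
    time_min, and ``mid`` / ``sd`` vectors."""
    n_max = max(len(np.atleast_1d(r["mid"])) for r in records)
    m_cols = [f"m{i}" for i in range(n_max)]
    sd_cols = [f"sd_m{i}" for i in range(n_max)]
    rows = []
    for r in records:
        mid = np.atleast_1d(np.asarray(r["mid"], dtype=float))
        sd = np.atleast_1d(np.asarray(r.get("sd", np.zeros_like(mid)), dtype=float))
        row = {
            "metabolite": r["metabolite"],
            "compartment_or_fraction": r["compartment_or_fraction"],
            "time_min": r["time_min"],
        }
        for i in range(n_max):
            row[m_cols[i]] = mid[i] if i < mid.size else np.nan
            row[sd_cols[i]] = sd[i] if i < sd.size else np.nan
        rows.append(row)
    pd.DataFrame(rows, columns=_MID_META + m_cols + sd_cols).to_csv(
        path, index=False
    )


def measurements_to_frames(meas) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert synthetic :class:`FractionMeasurements` to schema tables."""
    pool_rows = []
    for (met, frac), (value, sd, reps) in meas.pools.items():
        pool_rows.append(
            {
                "metabolite": met,
                "fraction": frac,
                "value": value,
                "sd": sd,
                "n_replicates": len(reps),
                "units": "relative",
            }
        )
    mid_records = []
    for (met, frac), series in meas.mids.items():
        for ti, t in enumerate(series.times):
            mid_records.append(
                {
                    "metabolite": met,
                    "compartment_or_fraction": frac,
                    "time_min": float(t),
                    "mid": series.mean[ti],
                    "sd": series.sd[ti],
                }
            )
    pools_df = pd.DataFrame(pool_rows, columns=POOLS_COLUMNS)
    n_max = max(len(r["mid"]) for r in mid_records)
    rows = []
    for r in mid_records:
        row = {
            "metabolite": r["metabolite"],
            "compartment_or_fraction": r["compartment_or_fraction"],
            "time_min": r["time_min"],
        }
        for i in range(n_max):
            row[f"m{i}"] = r["mid"][i] if i < len(r["mid"]) else np.nan
            row[f"sd_m{i}"] = r["sd"][i] if i < len(r["sd"]) else np.nan
        rows.append(row)
    mids_df = pd.DataFrame(rows)
    return pools_df, mids_df
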