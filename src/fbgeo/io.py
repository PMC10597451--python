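"""Tabular I/O and the run report.

Site tables and plate tables travel as plain UTF-8, decimal-point CSV.
Loading is strict about mandatory columns and loud (warnings, not
errors) about implausible units; the F:B ratio is derived on load when
both densities are present but the ratio column is not.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version, PackageNotFoundError

import numpy as np
import pandas as pd

from .qpcr import PLATE_COLUMNS

logger = logging.getLogger(__name__)

SITE_MANDATORY = ["site_id", "x_km", "y_km"]
SITE_NUMERIC = [
    "x_km", "y_km", "pH", "organic_C", "CN_ratio", "clay", "silt", "sand",
    "coarse_elements", "avail_P", "total_Ni", "total_Cu",
    "bacterial_density", "fungal_density", "fb_ratio",
]


class SiteTableError(ValueError):
    pass


def _tool_version() -> str:
    try:
        return version("fbgeo")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def read_sites(path) -> pd.DataFrame:
    """Load a site table, deriving the F:B ratio when densities allow.

    Raises on missing mandatory columns or unparseable rows; warns on
    out-of-range units (pH outside [3, 10], negative densities) and on
    ratio/density inconsistency beyond 1e-9 relative.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise SiteTableError(f"malformed CSV {path}: {exc}") from exc
    missing = [c for c in SITE_MANDATORY if c not in df.columns]
    if missing:
        raise SiteTableError(f"{path}: missing mandatory columns {missing}")
    for col in SITE_NUMERIC:
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
                line = int(bad[0]) + 2 if len(bad) else "?"
                raise SiteTableError(
                    f"{path}: column {col!r} not numeric (first bad row: line {line})"
                ) from exc
    if df["site_id"].duplicated().any():
        raise SiteTableError(f"{path}: duplicate site_id values")
    if "pH" in df.columns:
        bad = df["pH"].dropna()
        if ((bad < 3) | (bad > 10)).any():
            logger.warning("%s: pH values outside [3, 10]", path)
    have_dens = {"bacterial_density", "fungal_density"} <= set(df.columns)
    if have_dens:
        if (df["bacterial_density"].dropna() <= 0).any():
            logger.warning("%s: non-positive bacterial densities", path)
        derived = 100.0 * df["fungal_density"] / df["bacterial_density"]
        if "fb_ratio" not in df.columns:
            df["fb_ratio"] = derived
        else:
            both = df["fb_ratio"].notna() & derived.notna()
            rel = np.abs(df.loc[both, "fb_ratio"] - derived[both]) / derived[both].abs()
            if (rel > 1e-9).any():
                logger.warning(
                    "%s: fb_ratio inconsistent with densities at %d sites",
                    path,
                    int((rel > 1e-9).sum()),
                )
    return df


def write_sites(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_plates(path) -> pd.DataFrame:
    """Load a qPCR plate table (one row per well)."""
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise SiteTableError(f"{path}: missing plate columns {missing}")
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    df["known_conc"] = pd.to_numeric(df["known_conc"], errors="coerce")
    return df[PLATE_COLUMNS]


def write_plates(df: pd.DataFrame, path) -> None:
    df[PLATE_COLUMNS].to_csv(path, index=False)


@dataclass
class RunReport:
    """Everything needed to re-execute a pipeline run bit-identically."""

    seed: int
    config: dict
    responses: dict = field(default_factory=dict)  # per-response stage summaries
    tool_version: str = field(default_factory=_tool_version)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
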