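"""Inter-plate qPCR calibration by the master-curve method.

Raw threshold cycles (Ct) from many plates are made comparable by
re-centring every plate on a shared reference DNA sample: each plate
carries replicate wells of the same environmental reference DNA, the
per-plate mean reference Ct is compared with the grand mean over all
plates, and the difference (the plate *derivation*) is subtracted from
every Ct on that plate.  A single calibration line ("master curve") is
then fitted by ordinary least squares to the corrected Cts of all
plasmid-standard wells pooled across plates, and sample copy numbers are
read off that line.

The 16S (bacterial) and 18S (fungal) assays use different chemistry and
are calibrated independently; nothing in this module ever mixes targets.

Plate tables are plain :class:`pandas.DataFrame` objects with columns
``plate_id, target, role, sample_id, replicate, ct, known_conc``
(``known_conc`` is copies per reaction, present for standards only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TARGETS = ("16S", "18S")
ROLES = ("standard", "reference", "sample")

#: Column layout of a plate table.
PLATE_COLUMNS = ["plate_id", "target", "role", "sample_id", "replicate", "ct", "known_conc"]

#: Replicate scatter (cycles) above which a diagnostic is emitted.
REPLICATE_SD_WARN = 0.5


class CalibrationError(ValueError):
    """Raised when a plate set cannot be calibrated (missing references,
    degenerate standards, unknown plate)."""


@dataclass(frozen=True)
class PlateCorrection:
    """Per-plate Ct offset relative to the pooled reference mean."""

    plate_id: str
    target: str
    derivation: float  # cycles; plate reference mean minus global mean


@dataclass(frozen=True)
class MasterCurve:
    """Pooled calibration line ``Ct = slope * log10(copies) + intercept``."""

    target: str
    slope: float  # cycles per log10(copies); negative for a working assay
    intercept: float  # cycles at 1 copy per reaction
    r_squared: float
    n_standards: int

    @property
    def efficiency(self) -> float:
        """Amplification efficiency, ``10**(-1/slope) - 1`` (1.0 = perfect doubling)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass(frozen=True)
class DensityRecord:
    """Absolute rDNA copy density for one sample and one target."""

    sample_id: str
    target: str
    copies_per_g: float


@dataclass
class CalibrationReport:
    """Everything needed to audit or re-apply one target's calibration."""

    target: str
    global_reference_mean: float
    corrections: list[PlateCorrection]
    curve: MasterCurve
    conversion: float
    n_samples: int
    n_quantified: int
    diagnostics: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "global_reference_mean": self.global_reference_mean,
            "derivations": {c.plate_id: c.derivation for c in self.corrections},
            "curve": {
                "slope": self.curve.slope,
                "intercept": self.curve.intercept,
                "r_squared": self.curve.r_squared,
                "efficiency": self.curve.efficiency,
                "n_standards": self.curve.n_standards,
            },
            "conversion": self.conversion,
            "n_samples": self.n_samples,
            "n_quantified": self.n_quantified,
            "diagnostics": list(self.diagnostics),
        }


def _wells_for(wells: pd.DataFrame, target: str, role: str | None = None) -> pd.DataFrame:
    sub = wells[wells["target"] == target]
    if role is not None:
        sub = sub[sub["role"] == role]
    return sub


def global_reference_mean(wells: pd.DataFrame, target: str) -> float:
    """Arithmetic mean Ct over every reference well of ``target``, all plates pooled."""
    refs = _wells_for(wells, target, "reference").dropna(subset=["ct"])
    if refs.empty:
        raise CalibrationError(f"no reference wells for target {target!r}")
    return float(refs["ct"].mean())


def plate_derivations(
    wells: pd.DataFrame, target: str, global_mean: float | None = None
) -> list[PlateCorrection]:
    """Per-plate Ct offsets: plate reference mean minus the pooled reference mean.

    Every plate that carries sample or standard wells must also carry
    reference wells, otherwise its drift is unobservable.
    """
    if global_mean is None:
        global_mean = global_reference_mean(wells, target)
    sub = _wells_for(wells, target)
    corrections = []
    for plate_id, plate in sub.groupby("plate_id", sort=True):
        refs = plate[plate["role"] == "reference"].dropna(subset=["ct"])
        if refs.empty:
            raise CalibrationError(
                f"plate {plate_id!r} has {target} wells but no reference wells"
            )
        corrections.append(
            PlateCorrection(
                plate_id=plate_id,
                target=target,
                derivation=float(refs["ct"].mean()) - global_mean,
            )
        )
    return corrections


def correct_ct(
    ct: float | np.ndarray, correction: PlateCorrection
) -> float | np.ndarray:
    """Subtract the plate derivation from a raw Ct."""
    return ct - correction.derivation


def apply_corrections(
    wells: pd.DataFrame, corrections: list[PlateCorrection]
) -> pd.DataFrame:
    """Return a copy of ``wells`` with a ``ct_corrected`` column.

    Rows whose (plate, target) has no correction raise; other targets'
    rows are passed through untouched.
    """
    lookup = {(c.plate_id, c.target): c.derivation for c in corrections}
    targets = {c.target for c in corrections}
    out = wells.copy()
    deriv = np.zeros(len(out))
    for i, (plate_id, target) in enumerate(zip(out["plate_id"], out["target"])):
        if target not in targets:
            deriv[i] = 0.0
            continue
        key = (plate_id, target)
        if key not in lookup:
            raise CalibrationError(f"no correction for plate {plate_id!r}, target {target!r}")
        deriv[i] = lookup[key]
    out["ct_corrected"] = out["ct"] - deriv
    return out


def fit_master_curve(standards: pd.DataFrame, target: str) -> MasterCurve:
    """OLS of corrected Ct on log10(known copies) over all pooled standards.

    ``standards`` must already carry ``ct_corrected``; wells with missing
    Ct are ignored.  At least two distinct concentrations are required.
    """
    sub = _wells_for(standards, target, "standard").dropna(subset=["ct_corrected", "known_conc"])
    if (sub["known_conc"] <= 0).any():
        raise CalibrationError("standard concentrations must be positive")
    if sub["known_conc"].nunique() < 2:
        raise CalibrationError(
            f"need >=2 distinct standard concentrations for target {target!r}, "
            f"got {sub['known_conc'].nunique()}"
        )
    x = np.log10(sub["known_conc"].to_numpy(float))
    y = sub["ct_corrected"].to_numpy(float)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return MasterCurve(
        target=target,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        n_standards=len(sub),
    )


def quantify(
    corrected_ct: float | np.ndarray, curve: MasterCurve, conversion: float
) -> float | np.ndarray:
    """Copies per gram of soil from a corrected Ct.

    ``copies_per_reaction = 10**((ct - intercept) / slope)``; the
    ``conversion`` factor (copies per g soil per copy per reaction)
    rescales reaction-volume counts to soil-mass density.  The mapping is
    strictly decreasing in Ct for any working (negative-slope) assay.
    """
    if curve.slope >= 0:
        raise CalibrationError("master curve slope must be negative to quantify")
    if conversion <= 0:
        raise CalibrationError("conversion factor must be positive")
    copies_rxn = 10.0 ** ((corrected_ct - curve.intercept) / curve.slope)
    return copies_rxn * conversion


def fb_ratio(fungal: float, bacterial: float) -> float:
    """F:B ratio: 100 x (18S copies per g) / (16S copies per g)."""
    if not (bacterial > 0):
        raise ValueError("bacterial density must be positive")
    if not (fungal > 0):
        raise ValueError("fungal density must be positive")
    return 100.0 * fungal / bacterial


def replicate_sd_diagnostics(wells: pd.DataFrame, target: str) -> list[str]:
    """Flag reference/standard replicate groups whose Ct SD exceeds 0.5 cycles."""
    msgs = []
    sub = _wells_for(wells, target)
    sub = sub[sub["role"].isin(["reference", "standard"])].dropna(subset=["ct"])
    for (plate_id, role, sid), grp in sub.groupby(["plate_id", "role", "sample_id"], sort=True):
        if len(grp) >= 2:
            sd = float(grp["ct"].std(ddof=1))
            if sd > REPLICATE_SD_WARN:
                msgs.append(
                    f"plate {plate_id} {role} {sid}: replicate Ct SD "
                    f"{sd:.2f} > {REPLICATE_SD_WARN} cycles"
                )
    return msgs


def calibrate_plates(
    wells: pd.DataFrame, target: str, conversion: float
) -> tuple[pd.DataFrame, CalibrationReport]:
    """Full master-curve calibration of one target.

    Steps: pooled reference mean -> per-plate derivations -> Ct
    correction -> pooled master curve -> sample quantification.  Returns
    a density table (``sample_id, target, copies_per_g``; NaN for wells
    whose Ct is missing) and the calibration report.  Sample wells are
    averaged on the corrected-Ct scale when replicated.
    """
    gmean = global_reference_mean(wells, target)
    corrections = plate_derivations(wells, target, gmean)
    corrected = apply_corrections(wells, corrections)
    curve = fit_master_curve(corrected, target)
    diagnostics = replicate_sd_diagnostics(wells, target)
    if curve.slope >= 0:
        diagnostics.append(f"positive master-curve slope {curve.slope:.3f}: assay unusable")

    samples = _wells_for(corrected, target, "sample")
    rows = []
    n_quant = 0
    for sid, grp in samples.groupby("sample_id", sort=True):
        cts = grp["ct_corrected"].dropna()
        if cts.empty:
            rows.append({"sample_id": sid, "target": target, "copies_per_g": np.nan})
            continue
        dens = float(quantify(float(cts.mean()), curve, conversion))
        rows.append({"sample_id": sid, "target": target, "copies_per_g": dens})
        n_quant += 1
    densities = pd.DataFrame(rows, columns=["sample_id", "target", "copies_per_g"])
    report = CalibrationReport(
        target=target,
        global_reference_mean=gmean,
        corrections=corrections,
        curve=curve,
        conversion=conversion,
        n_samples=len(rows),
        n_quantified=n_quant,
        diagnostics=diagnostics,
    )
    return densities, report


def fb_ratio_table(dens_16s: pd.DataFrame, dens_18s: pd.DataFrame) -> pd.DataFrame:
    """Merge per-target density tables into sample rows with the F:B ratio.

    Samples missing either density get ``NaN`` ratios rather than being
    dropped, so the success count stays visible downstream.
    """
    b = dens_16s.rename(columns={"copies_per_g": "bacterial_density"})[
        ["sample_id", "bacterial_density"]
    ]
    f = dens_18s.rename(columns={"copies_per_g": "fungal_density"})[
        ["sample_id", "fungal_density"]
    ]
    merged = b.merge(f, on="sample_id", how="outer").sort_values("sample_id")
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["fb_ratio"] = 100.0 * merged["fungal_density"] / merged["bacterial_density"]
    merged.loc[~(merged["bacterial_density"] > 0), "fb_ratio"] = np.nan
    return merged.reset_index(drop=True)
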