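"""Synthetic soil-monitoring datasets with known ground truth.

Emulates a national systematic soil survey: ~2,171 sites at the centers
of a 16 x 16 km grid (small uniform jitter), soil covariates with
realistic marginals and spatial/land-use structure, spatially
autocorrelated log densities of bacterial (16S) and fungal (18S) rDNA
driven by a Matérn Gaussian random field plus linear covariate effects,
and raw qPCR plates with per-plate Ct drift, triplicate reference DNA
and 10-fold dilution standard ladders.

Planted structure (defaults):

* the log F:B ratio responds negatively to pH and organic carbon,
  positively to the C:N ratio, coarse elements and available
  phosphorus, and negatively to silt;
* land-use class medians are ordered grassland < vineyard_orchard <
  crop < forest, centred so the overall F:B median sits near 2.72
  (the x100 copy-ratio scale);
* one Mediterranean climate class has a positive effect;
* fungal and bacterial log densities share one spatial component and
  each has its own, so the ratio carries spatial structure distinct
  from either density;
* covariates themselves have spatial and land-use structure, which is
  what generates a sizeable jointly-explained ("interactions") fraction
  in variance partitioning.

Every generated table is accompanied by a :class:`GroundTruth` that
records all planted parameters, so each pipeline stage has a recovery
test against a known answer.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field as dc_field, asdict

import numpy as np
import pandas as pd

from .geostat import matern_correlation
from .qpcr import PLATE_COLUMNS

logger = logging.getLogger(__name__)

#: exponential practical range multiplier: effective = -ln(0.05) * a
_EXP_PRACTICAL = -math.log(0.05)


@dataclass(frozen=True)
class FieldConfig:
    """Matérn random-field parameters (normalized variance units)."""

    nugget: float = 0.2
    partial_sill: float = 0.8
    effective_range_km: float = 84.0
    nu: float = 0.5

    @property
    def range_param(self) -> float:
        if self.nu == 0.5:
            return self.effective_range_km / _EXP_PRACTICAL
        # invert the 95% level numerically for other smoothness values
        from .geostat import VariogramModel, effective_range

        lo, hi = self.effective_range_km / 100.0, self.effective_range_km
        def f(a):
            m = VariogramModel(nugget=0.0, partial_sill=1.0, range_param=a, nu=self.nu)
            return effective_range(m) - self.effective_range_km
        from scipy.optimize import brentq

        while f(hi) < 0:
            hi *= 2
        return float(brentq(f, lo, hi))


@dataclass(frozen=True)
class PlateConfig:
    """Layout and noise model of the simulated qPCR plates."""

    samples_per_plate: int = 24
    offset_sd: float = 0.5  # cycles, per-plate drift
    ct_noise_sd: float = 0.15  # cycles, per-well
    standard_decades: tuple[int, ...] = (2, 3, 4, 5, 6, 7)  # log10 copies/reaction
    standard_reps: int = 3
    reference_reps: int = 3
    fail_rate: float = 0.066  # fraction of sample wells with no usable Ct


# land-use class frequencies and multiplicative F:B median effects
LANDUSE_CLASSES = ("crop", "grassland", "forest", "vineyard_orchard")
LANDUSE_PROBS = (0.45, 0.27, 0.22, 0.06)
FINE_CLASSES = {
    "crop": ("crop_rotation", "crop_no_rotation", "fixed_fallow"),
    "grassland": ("permanent_grassland", "temporary_grassland"),
    "forest": ("deciduous_forest", "coniferous_forest"),
    "vineyard_orchard": ("vineyard", "orchard"),
}
CLIMATE_CLASSES = ("oceanic", "continental", "mountain", "mediterranean")

SOIL_COVARIATES = (
    "pH", "organic_C", "CN_ratio", "clay", "silt", "coarse_elements",
    "avail_P", "total_Ni", "total_Cu",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """All planted parameters of a synthetic survey."""

    n_sites: int = 2171
    grid_spacing_km: float = 16.0
    jitter_km: float = 2.0
    field: FieldConfig = dc_field(default_factory=FieldConfig)
    # standardized effects of soil covariates on ln(F:B)
    fb_effects: dict = dc_field(
        default_factory=lambda: {
            "pH": -0.17,
            "organic_C": -0.08,
            "CN_ratio": 0.08,
            "coarse_elements": 0.07,
            "silt": -0.04,
            "avail_P": 0.045,
        }
    )
    # standardized effects on ln(bacterial density)
    bact_effects: dict = dc_field(
        default_factory=lambda: {"organic_C": 0.35, "CN_ratio": -0.15, "pH": 0.10}
    )
    # multiplicative land-use medians for F:B, ordered grassland < v&o < crop < forest
    fb_class_medians: dict = dc_field(
        default_factory=lambda: {
            "grassland": 2.12,
            "vineyard_orchard": 2.40,
            "crop": 2.54,
            "forest": 3.91,
        }
    )
    fb_median_target: float = 2.72
    mediterranean_effect: float = 0.15  # ln-scale, the only climate effect
    north_south_trend: float = -0.10  # ln-scale per sd of y (lower ratios northward)
    fb_spatial_sd: float = 0.35  # sd of the ratio-specific Matérn component
    shared_spatial_sd: float = 0.30  # sd of the field common to both densities
    bact_spatial_sd: float = 0.25
    noise_sd: float = 0.34  # ln-scale site noise on the ratio
    bact_noise_sd: float = 0.35
    bact_median: float = 3e9  # 16S copies per g soil
    # qPCR assay truth
    slope_16s: float = -3.3219  # perfect doubling
    intercept_16s: float = 40.0
    slope_18s: float = -3.4
    intercept_18s: float = 39.0
    conversion: float = 1e4  # copies/g per copy/reaction (20 ug DNA/g, 2 ng template)
    plates: PlateConfig = dc_field(default_factory=PlateConfig)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Every planted parameter needed to verify recovery, JSON-serialisable."""

    config: dict
    fb_intercept: float
    class_effects: dict
    field_range_param: float
    true_copies_per_g: dict  # target -> {sample_id: copies}
    plate_offsets: dict = dc_field(default_factory=dict)  # target -> {plate: offset}
    reference_copies: dict = dc_field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=float)


# ---------------------------------------------------------------------------
# Random fields
# ---------------------------------------------------------------------------

def simulate_field(
    xy: np.ndarray,
    range_param: float,
    nu: float,
    nugget: float,
    partial_sill: float,
    rng: np.random.Generator,
    chol_cache: dict | None = None,
) -> np.ndarray:
    """Exact draw of a Matérn Gaussian field at the given locations.

    Covariance c*rho(h) + c0 at h=0; the Cholesky factor of the
    correlation part can be cached across replicate draws on fixed
    locations (``chol_cache`` keyed by (range_param, nu)).
    """
    from scipy.spatial.distance import pdist, squareform

    n = len(xy)
    key = (float(range_param), float(nu))
    L = chol_cache.get(key) if chol_cache is not None else None
    if L is None:
        D = squareform(pdist(xy))
        C = matern_correlation(D, range_param, nu)
        np.fill_diagonal(C, 1.0)
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            logger.info("covariance not PSD at machine precision; adding 1e-10 jitter")
            L = np.linalg.cholesky(C + 1e-10 * np.eye(n))
        if chol_cache is not None:
            chol_cache[key] = L
    smooth = math.sqrt(partial_sill) * (L @ rng.standard_normal(n))
    if nugget > 0:
        smooth = smooth + math.sqrt(nugget) * rng.standard_normal(n)
    return smooth


def grid_sites(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Cell centers of a near-square national grid, with uniform jitter."""
    if cfg.n_sites < 10:
        raise ValueError("need at least 10 sites")
    ncol = math.ceil(math.sqrt(cfg.n_sites))
    nrow = math.ceil(cfg.n_sites / ncol)
    ix, iy = np.meshgrid(np.arange(ncol), np.arange(nrow))
    order = rng.permutation(ncol * nrow)[: cfg.n_sites]
    cx = (ix.ravel()[order] + 0.5) * cfg.grid_spacing_km
    cy = (iy.ravel()[order] + 0.5) * cfg.grid_spacing_km
    jit = min(cfg.jitter_km, cfg.grid_spacing_km / 2)
    xy = np.column_stack(
        [cx + rng.uniform(-jit, jit, cfg.n_sites), cy + rng.uniform(-jit, jit, cfg.n_sites)]
    )
    return xy


# ---------------------------------------------------------------------------
# Sites
# ---------------------------------------------------------------------------

def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def simulate_sites(
    cfg: SyntheticConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the site table and its ground truth.

    Covariates are drawn with land-use shifts plus a smooth spatial
    component (one long-range carrier field reused with independent
    loadings), then the planted linear model produces ln densities and
    the F:B ratio.  Standardized copies of the covariates enter the
    linear predictor so the planted coefficients are directly comparable
    to standardized regression estimates.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(seed)
    xy = grid_sites(cfg, rng)
    n = cfg.n_sites
    a = cfg.field.range_param
    nu = cfg.field.nu
    cache: dict = {}

    # spatially clustered land use: one smooth field thresholded by class share
    lu_field = simulate_field(xy, a * 2.0, nu, 0.0, 1.0, rng, cache)
    lu_noise = lu_field + 0.8 * rng.standard_normal(n)
    qs = np.quantile(lu_noise, np.cumsum(LANDUSE_PROBS)[:-1])
    landuse = np.array(LANDUSE_CLASSES)[np.searchsorted(qs, lu_noise)]
    fine = np.array(
        [rng.choice(FINE_CLASSES[c]) for c in landuse]
    )

    # climate: latitudinal bands, Mediterranean in the far south
    ybreaks = np.quantile(xy[:, 1], [0.15, 0.55, 0.85])
    climate = np.where(
        xy[:, 1] < ybreaks[0],
        "mediterranean",
        np.where(
            xy[:, 1] < ybreaks[1],
            "oceanic",
            np.where(xy[:, 1] < ybreaks[2], "continental", "mountain"),
        ),
    )

    # soil covariates: base marginal + land-use shift + smooth spatial part
    carrier = simulate_field(xy, a * 1.5, nu, 0.0, 1.0, rng, cache)
    lu_idx = {c: i for i, c in enumerate(LANDUSE_CLASSES)}
    shifts = {
        # per-class additive shifts in marginal units
        "pH": {"crop": 0.5, "grassland": 0.1, "forest": -0.8, "vineyard_orchard": 0.7},
        "organic_C": {"crop": -6.0, "grassland": 6.0, "forest": 10.0, "vineyard_orchard": -8.0},
        "CN_ratio": {"crop": -1.0, "grassland": 0.5, "forest": 3.5, "vineyard_orchard": -0.5},
        "coarse_elements": {"crop": -2.0, "grassland": 0.0, "forest": 5.0, "vineyard_orchard": 4.0},
    }
    cov = {}
    cov["pH"] = 6.4 + 0.9 * (0.6 * carrier + 0.8 * rng.standard_normal(n))
    cov["pH"] += np.array([shifts["pH"][c] for c in landuse])
    cov["pH"] = np.clip(cov["pH"], 3.8, 8.6)
    cov["organic_C"] = np.exp(
        3.2 + 0.45 * (0.5 * carrier + 0.87 * rng.standard_normal(n))
    )  # g/kg, lognormal around ~25
    cov["organic_C"] += np.array([shifts["organic_C"][c] for c in landuse])
    cov["organic_C"] = np.clip(cov["organic_C"], 2.0, None)
    cov["CN_ratio"] = 11.0 + 2.2 * (0.4 * carrier + 0.92 * rng.standard_normal(n))
    cov["CN_ratio"] += np.array([shifts["CN_ratio"][c] for c in landuse])
    cov["CN_ratio"] = np.clip(cov["CN_ratio"], 6.0, 30.0)
    # texture: clay/silt/sand fractions of 1000 g/kg via a softmax-ish draw
    tex = rng.dirichlet((4.0, 5.0, 4.5), size=n) * 1000.0
    cov["clay"], cov["silt"], sand = tex[:, 0], tex[:, 1], tex[:, 2]
    cov["coarse_elements"] = np.clip(
        np.exp(2.0 + 0.8 * rng.standard_normal(n))
        + np.array([shifts["coarse_elements"][c] for c in landuse]),
        0.0,
        None,
    )
    cov["avail_P"] = np.exp(3.5 + 0.7 * rng.standard_normal(n))  # mg/kg
    cov["total_Ni"] = np.exp(3.0 + 0.6 * (0.3 * carrier + 0.95 * rng.standard_normal(n)))
    cov["total_Cu"] = np.exp(2.6 + 0.7 * rng.standard_normal(n))

    std_cov = {k: _standardize(v) for k, v in cov.items()}

    # covariate, climate and trend channels of ln(F:B)
    base = np.zeros(n)
    for k, beta in cfg.fb_effects.items():
        base += beta * std_cov[k]
    base += np.where(climate == "mediterranean", cfg.mediterranean_effect, 0.0)
    ys = (xy[:, 1] - xy[:, 1].mean()) / xy[:, 1].std(ddof=1)
    base += cfg.north_south_trend * ys

    # direct land-use effects carry only what the covariate channels do not
    # already express of the configured class medians, so the *realized*
    # class medians track the configured ones
    class_eff = {}
    for c, m in cfg.fb_class_medians.items():
        mask = landuse == c
        med_base = float(np.median(base[mask])) if mask.any() else 0.0
        class_eff[c] = math.log(m) - med_base
    lin_fb = base + np.array([class_eff[c] for c in landuse])

    fb_field = (
        simulate_field(xy, a, nu, cfg.field.nugget, cfg.field.partial_sill, rng, cache)
        * cfg.fb_spatial_sd
    )
    ln_fb = lin_fb + fb_field + cfg.noise_sd * rng.standard_normal(n)
    # recentre so the sample median hits the configured target exactly
    fb_intercept = math.log(cfg.fb_median_target) - float(np.median(ln_fb))
    ln_fb += fb_intercept

    lin_b = np.full(n, math.log(cfg.bact_median))
    for k, beta in cfg.bact_effects.items():
        lin_b += beta * std_cov[k]
    shared = simulate_field(xy, a, nu, 0.0, 1.0, rng, cache) * cfg.shared_spatial_sd
    own_b = simulate_field(xy, a * 0.7, nu, 0.0, 1.0, rng, cache) * cfg.bact_spatial_sd
    ln_b = lin_b + shared + own_b + cfg.bact_noise_sd * rng.standard_normal(n)

    fb = np.exp(ln_fb)
    bact = np.exp(ln_b)
    fung = fb / 100.0 * bact

    sites = pd.DataFrame(
        {
            "site_id": [f"S{i:04d}" for i in range(n)],
            "x_km": xy[:, 0],
            "y_km": xy[:, 1],
            "landuse_coarse": landuse,
            "landuse_fine": fine,
            "climate_class": climate,
            **cov,
            "sand": sand,
            "bacterial_density": bact,
            "fungal_density": fung,
            "fb_ratio": fb,
        }
    )
    truth = GroundTruth(
        config=cfg.to_dict(),
        fb_intercept=fb_intercept,
        class_effects=class_eff,
        field_range_param=a,
        true_copies_per_g={
            "16S": dict(zip(sites["site_id"], bact)),
            "18S": dict(zip(sites["site_id"], fung)),
        },
    )
    return sites, truth


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

def simulate_plates(
    cfg: SyntheticConfig,
    true_copies_per_g: dict[str, float],
    target: str,
    seed: int = 0,
    truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Raw qPCR wells for one target from true copy densities.

    Samples are assigned to plates round-robin; each plate carries the
    triplicate reference DNA and a triplicate 10-fold standard ladder.
    Ct = intercept + slope*log10(copies/reaction) + plate offset +
    Gaussian well noise; a ``fail_rate`` fraction of sample wells is
    reported with missing Ct (failed amplification).
    """
    if any(c <= 0 for c in true_copies_per_g.values()):
        raise ValueError("true copy densities must be positive")
    rng = np.random.default_rng(seed)
    pc = cfg.plates
    slope = cfg.slope_16s if target == "16S" else cfg.slope_18s
    intercept = cfg.intercept_16s if target == "16S" else cfg.intercept_18s
    sample_ids = list(true_copies_per_g)
    n_plates = max(1, math.ceil(len(sample_ids) / pc.samples_per_plate))
    offsets = rng.normal(0.0, pc.offset_sd, n_plates)
    # reference DNA: one environmental sample re-run on every plate
    ref_copies_g = float(np.median(list(true_copies_per_g.values())))
    ref_copies_rxn = ref_copies_g / cfg.conversion

    def ct_of(copies_rxn: float, plate: int) -> float:
        return (
            intercept
            + slope * math.log10(copies_rxn)
            + offsets[plate]
            + (rng.normal(0.0, pc.ct_noise_sd) if pc.ct_noise_sd > 0 else 0.0)
        )

    rows = []
    for p in range(n_plates):
        pid = f"{target}_P{p:03d}"
        for rep in range(pc.reference_reps):
            rows.append((pid, target, "reference", f"REF_{target}", rep, ct_of(ref_copies_rxn, p), np.nan))
        for dec in pc.standard_decades:
            conc = 10.0**dec
            for rep in range(pc.standard_reps):
                rows.append((pid, target, "standard", f"STD_1e{dec}", rep, ct_of(conc, p), conc))
    for i, sid in enumerate(sample_ids):
        p = i % n_plates
        pid = f"{target}_P{p:03d}"
        copies_rxn = true_copies_per_g[sid] / cfg.conversion
        failed = pc.fail_rate > 0 and rng.random() < pc.fail_rate
        ct = np.nan if failed else ct_of(copies_rxn, p)
        rows.append((pid, target, "sample", sid, 0, ct, np.nan))
    wells = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    if truth is not None:
        truth.plate_offsets[target] = {
            f"{target}_P{p:03d}": float(offsets[p]) for p in range(n_plates)
        }
        truth.reference_copies[target] = ref_copies_rxn
    return wells


def simulate_survey(
    cfg: SyntheticConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Full synthetic survey: sites plus raw 16S and 18S plate tables."""
    cfg = cfg or SyntheticConfig()
    sites, truth = simulate_sites(cfg, seed=seed)
    plates_16s = simulate_plates(
        cfg, truth.true_copies_per_g["16S"], "16S", seed=seed + 1, truth=truth
    )
    plates_18s = simulate_plates(
        cfg, truth.true_copies_per_g["18S"], "18S", seed=seed + 2, truth=truth
    )
    return sites, plates_16s, plates_18s, truth


def noiseless_config(cfg: SyntheticConfig | None = None) -> SyntheticConfig:
    """Copy of a config with all qPCR noise and failures switched off."""
    import dataclasses

    cfg = cfg or SyntheticConfig()
    plates = dataclasses.replace(cfg.plates, offset_sd=0.0, ct_noise_sd=0.0, fail_rate=0.0)
    return dataclasses.replace(cfg, plates=plates)
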