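"""End-to-end pipeline: conditioning, geostatistics, drivers, contrasts.

For each response (F:B ratio, bacterial density, fungal density) the
run executes, in order: normality screen and transform, Grubbs outlier
removal, ML Matérn variogram fit with LOO cross-validation and a kriged
grid, variance partitioning of environmental driver groups, and
land-use contrasts.  Everything stochastic is driven by one seed and
all stage summaries land in a :class:`~fbgeo.io.RunReport`.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geostat, groups, stats_prep, varpart
from .io import RunReport

logger = logging.getLogger(__name__)

RESPONSES_DEFAULT = ("fb_ratio", "bacterial_density", "fungal_density")
SOIL_QUANTITATIVE = [
    "pH", "organic_C", "CN_ratio", "clay", "silt", "coarse_elements",
    "avail_P", "total_Ni", "total_Cu",
]


@dataclass(frozen=True)
class PipelineConfig:
    responses: tuple[str, ...] = RESPONSES_DEFAULT
    nu_grid: tuple[float, ...] = geostat.NU_GRID_DEFAULT
    neighborhood: int = geostat.NEIGHBORHOOD_DEFAULT
    lag_width_km: float = 10.0
    grid_resolution_km: float = 16.0
    n_perm: int = 199
    vif_threshold: float = 5.0
    grubbs_alpha: float = 0.05
    max_fit_sites: int | None = 1500  # subsample cap for the ML variogram fit

    def to_dict(self) -> dict:
        return {
            "responses": list(self.responses),
            "nu_grid": list(self.nu_grid),
            "neighborhood": self.neighborhood,
            "lag_width_km": self.lag_width_km,
            "grid_resolution_km": self.grid_resolution_km,
            "n_perm": self.n_perm,
            "vif_threshold": self.vif_threshold,
            "grubbs_alpha": self.grubbs_alpha,
            "max_fit_sites": self.max_fit_sites,
        }


def spatial_descriptors(sites: pd.DataFrame) -> pd.DataFrame:
    """Standardized coordinates and their second-order polynomial terms.

    The spatial explanatory set is a convention (x, y, x^2, y^2, xy on
    the standardized scale); reports flag it as such.
    """
    x = sites["x_km"].to_numpy(float)
    y = sites["y_km"].to_numpy(float)
    xs = (x - x.mean()) / x.std(ddof=1)
    ys = (y - y.mean()) / y.std(ddof=1)
    out = pd.DataFrame(
        {"sp_x": xs, "sp_y": ys, "sp_x2": xs**2, "sp_y2": ys**2, "sp_xy": xs * ys},
        index=sites.index,
    )
    return out.apply(lambda c: (c - c.mean()) / c.std(ddof=1))


def build_driver_groups(
    sites: pd.DataFrame, vif_threshold: float = 5.0
) -> tuple[dict[str, pd.DataFrame], list[dict]]:
    """Assemble the four explanatory sets used in variance partitioning.

    soil: standardized quantitative soil covariates after VIF filtering
    (sand never enters: it is the complement of clay + silt and would be
    exactly collinear); land_management and climate: treatment dummies;
    spatial: polynomial coordinate surface.
    """
    soil_cols = [c for c in SOIL_QUANTITATIVE if c in sites.columns]
    soil, _ = varpart.prepare_predictors(sites, soil_cols)
    soil, trace = varpart.vif_filter(soil, threshold=vif_threshold)
    gm, _ = varpart.prepare_predictors(sites, [], ["landuse_coarse"])
    cl, _ = varpart.prepare_predictors(sites, [], ["climate_class"])
    sp = spatial_descriptors(sites)
    return {"soil": soil, "land_management": gm, "climate": cl, "spatial": sp}, trace


def run_pipeline(
    sites: pd.DataFrame,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> RunReport:
    """Run the full analysis chain on a site table.

    Each response is conditioned (transform + outlier removal) and then
    analysed on the transformed scale; group contrasts additionally get
    the rank-based land-use comparison.  Stage failures abort with a
    stage-tagged error message.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    report = RunReport(seed=seed, config=config.to_dict())
    for response in config.responses:
        if response not in sites.columns:
            raise KeyError(f"[{response}] response column missing from site table")
        t0 = time.perf_counter()
        stage = "stats_prep"
        try:
            sub = sites.dropna(subset=[response]).reset_index(drop=True)
            prep = stats_prep.prepare_response(
                sub[response].to_numpy(float), grubbs_alpha=config.grubbs_alpha
            )
            kept = sub.iloc[prep.kept_indices].reset_index(drop=True)
            values = prep.values

            stage = "geostatistics"
            samples = pd.DataFrame(
                {
                    "site_id": kept["site_id"],
                    "x_km": kept["x_km"],
                    "y_km": kept["y_km"],
                    "value": values,
                }
            )
            fit_samples = samples
            if config.max_fit_sites is not None and len(samples) > config.max_fit_sites:
                pick = rng.choice(len(samples), config.max_fit_sites, replace=False)
                fit_samples = samples.iloc[np.sort(pick)].reset_index(drop=True)
            model = geostat.fit_variogram_ml(fit_samples, nu_candidates=config.nu_grid)
            cv = geostat.loo_cross_validation(
                model, samples, neighborhood_size=config.neighborhood
            )
            grid = geostat.map_grid(
                model,
                samples,
                resolution_km=config.grid_resolution_km,
                neighborhood_size=config.neighborhood,
            )

            stage = "variance_partitioning"
            driver_groups, vif_trace = build_driver_groups(kept, config.vif_threshold)
            part = varpart.variance_partition(
                values,
                driver_groups,
                n_perm=config.n_perm,
                seed=int(rng.integers(2**31)),
            )

            stage = "group_comparison"
            comparison = None
            if "landuse_coarse" in kept.columns:
                comparison = groups.pairwise_posthoc(
                    values, kept["landuse_coarse"].to_numpy()
                )
        except Exception as exc:
            raise RuntimeError(f"pipeline stage [{stage}] failed for {response}: {exc}") from exc
        report.responses[response] = {
            "n_sites": int(len(kept)),
            "n_missing": int(sites[response].isna().sum()),
            "transform": prep.spec.to_dict(),
            "shapiro": {"W": prep.shapiro_w, "p": prep.shapiro_p},
            "outliers": prep.outliers.to_dict(),
            "variogram": model.to_dict(),
            "cross_validation": cv.to_dict(),
            "grid_nodes": int(len(grid)),
            "variance_partition": part.to_dict(),
            "spatial_descriptors": "standardized x, y, x^2, y^2, xy (convention)",
            "landuse_comparison": comparison.to_dict() if comparison is not None else None,
            "seconds": round(time.perf_counter() - t0, 2),
        }
        logger.info(
            "[%s] done in %.1fs", response, report.responses[response]["seconds"]
        )
    return report
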