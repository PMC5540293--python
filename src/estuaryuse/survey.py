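"""Strip-transect aerial-survey design math and density analysis.

Surveys fly parallel transects perpendicular to shore; observers count
whales within a fixed strip either side of the track line, summed per
15-second interval (≈1 km of transect). Each interval becomes one
1.0 × 0.7 km block (both sides pooled), the sampling unit for density.
Counts are an uncorrected index — no perception or availability bias
adjustment — so the abundance index is simply total count divided by the
areal coverage fraction of the design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geodesy import LocalProjection
from .geospatial import PORT_NELSON

__all__ = [
    "SurveyDesign",
    "default_design",
    "coverage_fraction",
    "bin_to_blocks",
    "density_weighted_distance",
    "abundance_index",
    "density_model",
]

#: block footprint: 1 km of transect × 0.35 km strip per side = 0.7 km²
BLOCK_AREA_KM2 = 0.7


@dataclass(frozen=True)
class SurveyDesign:
    """Transect layout: start/end (lon, lat) pairs plus strip geometry."""

    transects: tuple  # ((start_lonlat, end_lonlat), ...)
    spacing_km: float = 3.7
    strip_halfwidth_km: float = 0.35
    altitude_m: float = 305.0  # metadata only
    interval_length_km: float = 1.0
    #: observers scanned 100–450 m; 350 m is the effective half-width
    strip_range_m: tuple = (100.0, 450.0)

    def __post_init__(self):
        if self.spacing_km <= 0 or self.interval_length_km <= 0:
            raise ValueError("spacing_km and interval_length_km must be positive")
        if self.strip_halfwidth_km < 0:
            raise ValueError("strip_halfwidth_km must be >= 0")


def default_design(
    n_transects: int = 10,
    transect_length_km: float = 40.0,
    river_mouth=PORT_NELSON,
) -> SurveyDesign:
    """Study-like design: transects 3.7 km apart running seaward (NE axis)
    from the coast, extending 40 km offshore."""
    proj = LocalProjection(*river_mouth)
    axis = np.radians(35.0)  # offshore direction
    u = np.array([np.sin(axis), np.cos(axis)])
    n_perp = np.array([-u[1], u[0]])  # alongshore
    transects = []
    for i in range(n_transects):
        offset = (i - (n_transects - 1) / 2) * 3.7
        start_xy = offset * n_perp + 2.0 * u  # starts just seaward of shore
        end_xy = start_xy + transect_length_km * u
        start = tuple(float(v) for v in proj.inverse(*start_xy))
        end = tuple(float(v) for v in proj.inverse(*end_xy))
        transects.append((start, end))
    return SurveyDesign(transects=tuple(transects))


def coverage_fraction(design: SurveyDesign) -> float:
    """Areal coverage of the design: (2 × half-width)/spacing, capped at 1."""
    return min(1.0, 2.0 * design.strip_halfwidth_km / design.spacing_km)


def bin_to_blocks(
    records: pd.DataFrame,
    design: SurveyDesign,
    survey_date=None,
    shoreline=None,
    river_mouth=PORT_NELSON,
) -> pd.DataFrame:
    """Pool sighting records into 1.0 × 0.7 km survey blocks.

    Each (transect, interval) pair — both aircraft sides pooled — becomes one
    block with the summed count, a density (count / 0.7 km²), the block
    centre location, and distances to the river mouth and (when a shoreline
    is given) to the nearest shore. Records naming transects outside the
    design are rejected with their ids. Intervals with no record are still
    emitted with count 0, since empty blocks carry information for density
    models.
    """
    n_tr = len(design.transects)
    if len(records) and not records["transect"].between(0, n_tr - 1).all():
        bad = records.loc[~records["transect"].between(0, n_tr - 1)].index.tolist()
        raise ValueError(f"records reference unknown transects (rows {bad})")
    if len(records) and (records["count"] < 0).any():
        raise ValueError("counts must be non-negative")

    proj = LocalProjection(*river_mouth)
    shoreline_line = None
    if shoreline is not None:
        from shapely.geometry import LineString

        xs, ys = proj.forward(
            [v[0] for v in shoreline.vertices], [v[1] for v in shoreline.vertices]
        )
        shoreline_line = LineString(np.column_stack([xs, ys])).segmentize(0.1)

    pooled = (
        records.groupby(["transect", "interval"])["count"].sum()
        if len(records)
        else pd.Series(dtype=int)
    )
    from shapely.geometry import Point

    from ._geodesy import great_circle_km

    rows = []
    for t_idx, (start, end) in enumerate(design.transects):
        sx, sy = proj.forward(*start)
        ex, ey = proj.forward(*end)
        length = float(np.hypot(ex - sx, ey - sy))
        # round to absorb projection round-trip error in the nominal length
        n_int = max(1, int(round(length / design.interval_length_km)))
        u = np.array([float(ex - sx), float(ey - sy)]) / length
        for i in range(n_int):
            centre_xy = np.array([float(sx), float(sy)]) + (
                (i + 0.5) * design.interval_length_km
            ) * u
            lon, lat = proj.inverse(*centre_xy)
            count = int(pooled.get((t_idx, i), 0))
            d_mouth = float(
                great_circle_km(float(lon), float(lat), river_mouth[0], river_mouth[1])
            )
            d_shore = (
                float(shoreline_line.distance(Point(*centre_xy)))
                if shoreline_line is not None
                else np.nan
            )
            rows.append(
                {
                    "block_id": f"T{t_idx:02d}I{i:03d}",
                    "survey_date": survey_date,
                    "transect": t_idx,
                    "interval": i,
                    "centre_lon": float(lon),
                    "centre_lat": float(lat),
                    "count": count,
                    "density_per_km2": count / BLOCK_AREA_KM2,
                    "dist_mouth_km": d_mouth,
                    "dist_shore_km": d_shore,
                }
            )
    blocks = pd.DataFrame(rows)
    if len(records) and blocks["count"].sum() != records["count"].sum():
        raise AssertionError("count conservation violated in binning")
    return blocks


def density_weighted_distance(blocks: pd.DataFrame, which: str = "dist_mouth_km") -> dict:
    """Count-weighted mean distance over blocks, with a standard error.

    Weighted mean Σcᵢdᵢ/Σcᵢ; the SE treats each counted whale as one
    observation of its block's distance: SE = s_w/√Σc with s_w the
    count-weighted standard deviation.
    """
    c = blocks["count"].to_numpy(float)
    d = blocks[which].to_numpy(float)
    total = c.sum()
    if total <= 0:
        raise ValueError("all block counts are zero")
    mean = float((c * d).sum() / total)
    var = float((c * (d - mean) ** 2).sum() / total)
    se = float(np.sqrt(var / total))
    return {"weighted_mean_km": mean, "se_km": se, "n_whales": int(total)}


def abundance_index(blocks: pd.DataFrame, coverage: float) -> float:
    """Uncorrected abundance index: total count scaled by areal coverage.

    No perception or availability bias correction is applied; the value
    indexes relative abundance between surveys, not true population size.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    return float(blocks["count"].sum() / coverage)


def density_model(
    blocks: pd.DataFrame,
    candidate_sets=None,
    covariates=("year", "survey", "dist_shore_km", "dist_mouth_km"),
) -> tuple[list, dict]:
    """Quasi-Poisson (log link) block-count models, ranked by QAICc.

    Counts are overdispersed relative to Poisson, so each candidate
    covariate subset is fit as a Poisson GLM with offset log(block area) and
    ranked by QAICc: −2·logLik/ĉ + 2k + small-sample correction, where the
    dispersion ĉ is the Pearson χ²/df of the richest candidate and k counts
    the regression coefficients plus one for ĉ. Requires at least two
    distinct surveys.
    """
    import statsmodels.api as sm

    from .inference import ModelScore, rank_models

    if blocks["survey_date"].nunique() < 2:
        raise ValueError("density_model requires at least two surveys")
    if candidate_sets is None:
        candidate_sets = [
            covariates,
            tuple(c for c in covariates if c != "survey"),
            ("year",),
            (),
        ]

    def _design(subset):
        cols = {"(Int)": np.ones(len(blocks))}
        for cov in subset:
            s = blocks[cov]
            if pd.api.types.is_numeric_dtype(s):
                cols[cov] = s.to_numpy(float)
            else:
                for lv in pd.unique(s.astype(str))[1:]:
                    cols[f"{cov}[{lv}]"] = (s.astype(str) == lv).to_numpy(float)
        return pd.DataFrame(cols)

    offset = np.full(len(blocks), np.log(BLOCK_AREA_KM2))
    y = blocks["count"].to_numpy(float)

    fits = {}
    for subset in candidate_sets:
        X = _design(subset)
        model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
        try:
            res = model.fit()
        except Exception as exc:  # non-convergence is reported, not hidden
            warnings.warn(f"model {subset!r} failed to converge: {exc}")
            continue
        fits[subset] = res

    if not fits:
        raise RuntimeError("no density model converged")
    richest = max(fits, key=lambda s: len(s))
    rich = fits[richest]
    c_hat = max(1.0, float(rich.pearson_chi2 / rich.df_resid))

    n = len(blocks)
    scores = []
    for subset, res in fits.items():
        k = int(res.df_model + 1) + 1  # coefficients + dispersion
        qll = float(res.llf) / c_hat
        q_aicc = -2.0 * qll + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)
        name = " + ".join(["(Int)"] + list(subset))
        scores.append(ModelScore(name=name, k=k, loglik=qll, aicc=q_aicc))
    ranked = rank_models(scores)
    return ranked, {"c_hat": c_hat, "fits": fits}
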