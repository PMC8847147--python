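"""Continuous phenology traits from discrete census observations.

Leaf-out day and first flowering day are only observed up to a bracketing
interval between two census visits.  Within that interval each plant is
placed by an empirical-percentile rule: the deviation of its observed
unfolded-leaflet count from a quadratic unfolding model (for leaf-out), or
the size of its largest bud at the previous visit (for flowering), is
mapped through the within-year empirical distribution of that quantity to a
fraction of the interval.  Larger deviations / larger buds always map to
earlier assigned days, assigned days are continuous, and every assignment
stays inside the half-open interval (previous visit, detection visit].

Also provides the cylinder-volume size measure, the grazed-plant
imputation models, and the orchestration that turns a census table plus a
shoot table into one trait row per plant and season.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .selection import OLSFit, fit_ols

__all__ = [
    "UnfoldingModel",
    "BudPercentileModel",
    "GrazedFfdModel",
    "HeightDiameterModel",
    "fit_unfolding_model",
    "assign_leaf_out_day",
    "assign_ffd_from_bud",
    "fit_grazed_ffd_model",
    "estimate_ffd_grazed",
    "aboveground_volume",
    "fit_height_diameter_model",
    "impute_grazed_height",
    "estimate_plant_seasons",
]

#: Offset keeping percentile-mapped days strictly after the previous visit.
_EDGE_EPS = 1e-6


def _midrank_percentile(value: float, pool: np.ndarray) -> float:
    """Mid-rank percentile of ``value`` within ``pool``, in (0, 1)."""
    pool = np.asarray(pool, dtype=float)
    if pool.size == 0:
        raise ValueError("empty percentile pool")
    below = np.sum(pool < value)
    ties = np.sum(pool == value)
    return float((below + 0.5 * ties) / pool.size)


def _percentile_day(p: float, prev_day: float, event_visit_day: float) -> float:
    """Map percentile ``p`` to a day in (prev_day, event_visit_day].

    ``p = 0`` gives the detection visit itself, larger percentiles give
    earlier days, and the result is clamped just inside the open lower
    bound so the bracketing-interval invariant holds exactly.
    """
    length = event_visit_day - prev_day
    day = event_visit_day - p * length
    return max(day, prev_day + _EDGE_EPS * max(length, 1.0))


@dataclass
class UnfoldingModel:
    """Quadratic least-squares model of unfolded leaflets vs. total leaflets.

    Fitted on each plant's first observation after leaf-out; the stored
    residuals are the within-year empirical deviation pool used for
    percentile mapping.
    """

    fit: OLSFit

    @property
    def coefficients(self) -> np.ndarray:
        return self.fit.params.to_numpy()

    @property
    def residuals(self) -> np.ndarray:
        return self.fit.residuals

    @property
    def residual_scale(self) -> float:
        return float(np.std(self.fit.residuals, ddof=min(3, len(self.fit.residuals) - 1)))

    def predict(self, leaflets_total) -> np.ndarray:
        t = np.asarray(leaflets_total, dtype=float)
        c = self.coefficients
        return c[0] + c[1] * t + c[2] * t**2


def fit_unfolding_model(first_observations: pd.DataFrame) -> UnfoldingModel:
    """OLS fit of ``unfolded ~ 1 + total + total^2`` on first detections.

    ``first_observations`` must contain ``leaflets_total`` and
    ``leaflets_unfolded`` and hold one row per plant: the first visit at
    which any leaflet was unfolded.  Requires at least three distinct
    leaflet totals, otherwise the quadratic design is rank deficient.
    """
    total = first_observations["leaflets_total"].to_numpy(dtype=float)
    unfolded = first_observations["leaflets_unfolded"].to_numpy(dtype=float)
    if np.unique(total).size < 3:
        raise ValueError(
            "fit_unfolding_model needs >= 3 distinct leaflet totals; "
            f"got {np.unique(total).size}"
        )
    X = pd.DataFrame(
        {"intercept": np.ones_like(total), "total": total, "total^2": total**2}
    )
    return UnfoldingModel(fit=fit_ols(X, unfolded))


def assign_leaf_out_day(
    prev_visit_day: float,
    first_unfolded_visit_day: float,
    observed_unfolded: float,
    leaflets_total: float,
    model: UnfoldingModel,
) -> float:
    """Place leaf-out within (previous visit, first-unfolded visit].

    The deviation ``observed - predicted`` unfolded count is mapped through
    the model's empirical residual distribution: a plant whose unfolding is
    further ahead of expectation is assigned an earlier day.  The mapping
    applies at every interval length (assigned days are continuous even
    under daily censusing, so accuracy improves monotonically with census
    density); a zero-length interval returns its single day.
    """
    if model is None:
        raise ValueError("an UnfoldingModel is required to assign leaf-out days")
    if prev_visit_day >= first_unfolded_visit_day:
        raise ValueError(
            "prev_visit_day must precede first_unfolded_visit_day "
            f"({prev_visit_day} >= {first_unfolded_visit_day})"
        )
    if observed_unfolded < 1:
        raise ValueError("observed_unfolded must be >= 1 at the detection visit")
    deviation = observed_unfolded - float(model.predict(leaflets_total))
    p = _midrank_percentile(deviation, model.residuals)
    return _percentile_day(p, prev_visit_day, first_unfolded_visit_day)


@dataclass
class BudPercentileModel:
    """Within-year empirical distribution of pre-flowering bud sizes."""

    pool: np.ndarray

    def percentile(self, bud_size: float) -> float:
        return _midrank_percentile(bud_size, self.pool)


def assign_ffd_from_bud(
    bud_size_at_prev_visit: float | None,
    prev_visit_day: float,
    first_flower_visit_day: float,
    bud_model: BudPercentileModel,
) -> tuple[float, bool]:
    """Place first flowering within (previous visit, first-flower visit].

    A larger bud at the previous visit means flowering started earlier in
    the interval; the mapping contract mirrors :func:`assign_leaf_out_day`.
    Returns ``(day, midpoint_fallback)`` where the flag marks a missing bud
    size resolved to the interval midpoint.
    """
    if prev_visit_day >= first_flower_visit_day:
        raise ValueError(
            "prev_visit_day must precede first_flower_visit_day "
            f"({prev_visit_day} >= {first_flower_visit_day})"
        )
    if bud_size_at_prev_visit is None or (
        isinstance(bud_size_at_prev_visit, float) and math.isnan(bud_size_at_prev_visit)
    ):
        return _percentile_day(0.5, prev_visit_day, first_flower_visit_day), True
    p = bud_model.percentile(float(bud_size_at_prev_visit))
    return _percentile_day(p, prev_visit_day, first_flower_visit_day), False


@dataclass
class GrazedFfdModel:
    """OLS model predicting flowering day for plants grazed before flowering.

    Fitted on intact plants: ``ffd ~ bud_size + observation_day +
    ln(aboveground_volume)``.
    """

    fit: OLSFit

    def predict(self, bud_size, observation_day, aboveground_volume) -> float:
        if aboveground_volume <= 0:
            raise ValueError("aboveground_volume must be positive")
        c = self.fit.params
        return float(
            c["intercept"]
            + c["bud_size"] * bud_size
            + c["observation_day"] * observation_day
            + c["ln_volume"] * math.log(aboveground_volume)
        )


def fit_grazed_ffd_model(intact: pd.DataFrame) -> GrazedFfdModel:
    """Fit the grazed-plant flowering-day model on intact individuals.

    ``intact`` needs columns ``first_flowering_day``, ``bud_size``,
    ``observation_day`` and ``aboveground_volume``.
    """
    if len(intact) == 0:
        raise ValueError("no intact plants available to fit the grazed-FFD model")
    X = pd.DataFrame(
        {
            "intercept": np.ones(len(intact)),
            "bud_size": intact["bud_size"].to_numpy(dtype=float),
            "observation_day": intact["observation_day"].to_numpy(dtype=float),
            "ln_volume": np.log(intact["aboveground_volume"].to_numpy(dtype=float)),
        }
    )
    return GrazedFfdModel(fit=fit_ols(X, intact["first_flowering_day"].to_numpy(dtype=float)))


def estimate_ffd_grazed(
    bud_size: float,
    observation_day: float,
    aboveground_volume: float,
    grazed_ffd_model: GrazedFfdModel,
) -> float:
    """Point prediction of first flowering day for a grazed plant."""
    for name, value in (
        ("bud_size", bud_size),
        ("observation_day", observation_day),
        ("aboveground_volume", aboveground_volume),
    ):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise ValueError(f"missing predictor {name!r} for grazed-FFD estimation")
    return grazed_ffd_model.predict(bud_size, observation_day, aboveground_volume)


def aboveground_volume(diameter, height, n_shoots):
    """Cylinder volume of the focal shoot times the number of shoots.

    ``(0.5 * diameter)^2 * height * pi * n_shoots``; any zero input gives
    zero volume, negative inputs raise.
    """
    d = np.asarray(diameter, dtype=float)
    h = np.asarray(height, dtype=float)
    n = np.asarray(n_shoots, dtype=float)
    if (d < 0).any() or (h < 0).any() or (n < 0).any():
        raise ValueError("diameter, height and n_shoots must all be >= 0")
    result = (0.5 * d) ** 2 * h * np.pi * n
    return float(result) if result.ndim == 0 else result


@dataclass
class HeightDiameterModel:
    """Linear height~diameter relationship fitted on nongrazed plants."""

    intercept: float
    slope: float

    def predict(self, diameter: float) -> float:
        return self.intercept + self.slope * diameter


def fit_height_diameter_model(nongrazed: pd.DataFrame) -> HeightDiameterModel:
    if len(nongrazed) == 0:
        raise ValueError("no nongrazed plants available to fit height ~ diameter")
    X = pd.DataFrame(
        {
            "intercept": np.ones(len(nongrazed)),
            "diameter": nongrazed["shoot_diameter"].to_numpy(dtype=float),
        }
    )
    fit = fit_ols(X, nongrazed["shoot_height"].to_numpy(dtype=float))
    return HeightDiameterModel(
        intercept=float(fit.params["intercept"]), slope=float(fit.params["diameter"])
    )


def impute_grazed_height(
    diameter: float,
    height_diameter_model: HeightDiameterModel,
    grazed_after_last_recording: bool = False,
    max_spring_height: float | None = None,
) -> float:
    """Final height for a grazed plant.

    Plants grazed after the last spring recording keep their maximum
    recorded spring height (the model is ignored); otherwise the height is
    predicted from the nongrazed height-diameter relationship.
    """
    if grazed_after_last_recording:
        if max_spring_height is None:
            raise ValueError(
                "max_spring_height is required for plants grazed after the last recording"
            )
        return float(max_spring_height)
    if height_diameter_model is None:
        raise ValueError("a HeightDiameterModel is required")
    return float(height_diameter_model.predict(diameter))


# ---------------------------------------------------------------------------
# Orchestration: census + shoots -> one trait row per plant-season
# ---------------------------------------------------------------------------


def _validate_census(census: pd.DataFrame) -> pd.DataFrame:
    required = [
        "individual_id",
        "year",
        "day",
        "leaflets_total",
        "leaflets_unfolded",
        "flowers_open",
    ]
    missing = [c for c in required if c not in census.columns]
    if missing:
        raise ValueError(f"census table is missing columns: {missing}")
    bad = census["leaflets_unfolded"] > census["leaflets_total"]
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} census rows have leaflets_unfolded > leaflets_total"
        )
    if (census["leaflets_unfolded"] < 0).any():
        raise ValueError("leaflets_unfolded must be >= 0")
    out = census.sort_values(["year", "individual_id", "day"], kind="mergesort")
    dup = out.duplicated(subset=["year", "individual_id", "day"])
    if dup.any():
        raise ValueError("census days must be strictly increasing per individual")
    return out.reset_index(drop=True)


def estimate_plant_seasons(
    census: pd.DataFrame, shoots: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Estimate leaf-out day, first flowering day and size for every plant.

    Models (unfolding, bud percentile pool, grazed-FFD) are fitted within
    each year, since census schedules differ among years.  Returns one row
    per (individual, year) with continuous event-day estimates, the
    development time, size measures and boolean quality flags
    (``leaf_out_missing``, ``ffd_missing``, ``ffd_midpoint``,
    ``ffd_imputed_grazed``).  Hidden truth columns present in the census
    (``true_leaf_out_day``, ``true_ffd``) are carried through unchanged.
    """
    census = _validate_census(census)
    has_bud = "bud_size" in census.columns
    has_grazed = "grazed" in census.columns
    carry_truth = [c for c in ("true_leaf_out_day", "true_ffd") if c in census.columns]

    rows = []
    for year, ydf in census.groupby("year", sort=False):
        groups = dict(tuple(ydf.groupby("individual_id", sort=False)))

        # -- leaf-out: first detection rows train the unfolding model ------
        detections = {}
        for ind, g in groups.items():
            g = g.reset_index(drop=True)
            unfolded_idx = np.flatnonzero(g["leaflets_unfolded"].to_numpy() >= 1)
            if unfolded_idx.size == 0 or unfolded_idx[0] == 0:
                detections[ind] = None  # never unfolded, or no visit before leaf-out
            else:
                i = unfolded_idx[0]
                detections[ind] = (g.loc[i - 1], g.loc[i])
        training = pd.DataFrame(
            [
                {
                    "individual_id": ind,
                    "leaflets_total": det[1]["leaflets_total"],
                    "leaflets_unfolded": det[1]["leaflets_unfolded"],
                }
                for ind, det in detections.items()
                if det is not None
            ]
        )
        unfolding = fit_unfolding_model(training) if len(training) >= 3 else None

        # -- flowering: bud sizes at the visit before first open flower ----
        flower_obs = {}
        for ind, g in groups.items():
            g = g.reset_index(drop=True)
            fl_idx = np.flatnonzero(g["flowers_open"].to_numpy() >= 1)
            if fl_idx.size == 0 or fl_idx[0] == 0:
                flower_obs[ind] = None
            else:
                i = fl_idx[0]
                flower_obs[ind] = (g.loc[i - 1], g.loc[i])
        bud_pool = np.array(
            [
                float(obs[0]["bud_size"])
                for obs in flower_obs.values()
                if obs is not None and has_bud and not pd.isna(obs[0]["bud_size"])
            ]
        )
        bud_model = BudPercentileModel(pool=bud_pool) if bud_pool.size else None

        for ind, g in groups.items():
            rec: dict = {"individual_id": ind, "year": year}
            det = detections[ind]
            if det is None or unfolding is None:
                rec["leaf_out_day"] = np.nan
                rec["leaf_out_missing"] = True
            else:
                prev, cur = det
                rec["leaf_out_day"] = assign_leaf_out_day(
                    float(prev["day"]),
                    float(cur["day"]),
                    float(cur["leaflets_unfolded"]),
                    float(cur["leaflets_total"]),
                    unfolding,
                )
                rec["leaf_out_missing"] = False

            obs = flower_obs[ind]
            grazed_before_flowering = (
                has_grazed and obs is None and bool(g["grazed"].any())
            )
            rec["ffd_midpoint"] = False
            rec["ffd_imputed_grazed"] = False
            if obs is not None:
                prev, cur = obs
                bud = float(prev["bud_size"]) if has_bud and not pd.isna(prev["bud_size"]) else None
                if bud_model is None and bud is not None:
                    bud_model_local = BudPercentileModel(pool=np.array([bud]))
                else:
                    bud_model_local = bud_model
                day, midpoint = assign_ffd_from_bud(
                    bud, float(prev["day"]), float(cur["day"]), bud_model_local
                )
                rec["first_flowering_day"] = day
                rec["ffd_midpoint"] = midpoint
                rec["ffd_missing"] = False
            else:
                rec["first_flowering_day"] = np.nan
                rec["ffd_missing"] = True
                rec["_grazed_before_flowering"] = grazed_before_flowering
                if grazed_before_flowering:
                    # stash the last bud observation for the grazed model
                    not_grazed = g[~g["grazed"].astype(bool)]
                    if has_bud and len(not_grazed) and not pd.isna(not_grazed.iloc[-1]["bud_size"]):
                        rec["_graze_bud"] = float(not_grazed.iloc[-1]["bud_size"])
                        rec["_graze_day"] = float(not_grazed.iloc[-1]["day"])
            for col in carry_truth:
                rec[col] = float(g.iloc[0][col])
            rows.append(rec)

    seasons = pd.DataFrame(rows)
    if "_grazed_before_flowering" not in seasons.columns:
        seasons["_grazed_before_flowering"] = False
    seasons["_grazed_before_flowering"] = np.array(
        [False if pd.isna(v) else bool(v) for v in seasons["_grazed_before_flowering"]]
    )

    # -- size ---------------------------------------------------------------
    if shoots is not None:
        seasons = seasons.merge(
            shoots[["individual_id", "year", "shoot_height", "shoot_diameter", "n_shoots"]],
            on=["individual_id", "year"],
            how="left",
        )
        seasons["aboveground_volume"] = aboveground_volume(
            seasons["shoot_diameter"].fillna(0.0),
            seasons["shoot_height"].fillna(0.0),
            seasons["n_shoots"].fillna(0.0),
        )
    else:
        seasons["shoot_height"] = np.nan
        seasons["shoot_diameter"] = np.nan
        seasons["n_shoots"] = np.nan
        seasons["aboveground_volume"] = np.nan

    # -- grazed-plant flowering-day imputation ------------------------------
    graze_mask = seasons["_grazed_before_flowering"] & seasons["first_flowering_day"].isna()
    if graze_mask.any():
        for year in seasons.loc[graze_mask, "year"].unique():
            ymask = graze_mask & (seasons["year"] == year)
            intact = _intact_training_frame(census, seasons, year)
            if len(intact) == 0:
                continue
            model = fit_grazed_ffd_model(intact)
            for i in seasons.index[ymask]:
                bud = seasons.at[i, "_graze_bud"] if "_graze_bud" in seasons.columns else np.nan
                day = seasons.at[i, "_graze_day"] if "_graze_day" in seasons.columns else np.nan
                vol = seasons.at[i, "aboveground_volume"]
                if pd.isna(bud) or pd.isna(day) or pd.isna(vol) or vol <= 0:
                    continue  # excluded, stays missing
                seasons.at[i, "first_flowering_day"] = estimate_ffd_grazed(
                    float(bud), float(day), float(vol), model
                )
                seasons.at[i, "ffd_imputed_grazed"] = True
                seasons.at[i, "ffd_missing"] = False

    seasons["development_time"] = seasons["first_flowering_day"] - seasons["leaf_out_day"]
    drop = [c for c in seasons.columns if c.startswith("_")]
    return seasons.drop(columns=drop)


def _intact_training_frame(
    census: pd.DataFrame, seasons: pd.DataFrame, year
) -> pd.DataFrame:
    """Training rows (bud, day, volume, ffd) for the grazed-FFD model."""
    ok = seasons[
        (seasons["year"] == year)
        & ~seasons["first_flowering_day"].isna()
        & ~seasons["ffd_imputed_grazed"].astype(bool)
        & (seasons["aboveground_volume"] > 0)
    ]
    rows = []
    ydf = census[census["year"] == year]
    for _, srow in ok.iterrows():
        g = ydf[ydf["individual_id"] == srow["individual_id"]].reset_index(drop=True)
        fl_idx = np.flatnonzero(g["flowers_open"].to_numpy() >= 1)
        if fl_idx.size == 0 or fl_idx[0] == 0:
            continue
        prev = g.loc[fl_idx[0] - 1]
        if "bud_size" not in g.columns or pd.isna(prev["bud_size"]):
            continue
        rows.append(
            {
                "first_flowering_day": srow["first_flowering_day"],
                "bud_size": float(prev["bud_size"]),
                "observation_day": float(prev["day"]),
                "aboveground_volume": float(srow["aboveground_volume"]),
            }
        )
    return pd.DataFrame(rows)
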