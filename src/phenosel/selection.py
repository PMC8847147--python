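"""Lande-Arnold phenotypic selection estimation.

Implements trait standardization and fitness relativization under a local
(within-year) or global (pooled across-years) scheme, the six regression
model families used for total, direct, development-time, correlational and
nonlinear selection, the convention of doubling squared-term coefficients,
variance inflation factors, trait correlations, and the rule for flagging
indirect selection by comparing direct gradients against the BCa interval
of the corresponding total differential.

Fits are per year. Linear (first-order) estimates are taken from the
linear-only models and quadratic/correlational estimates from the extended
models; zero-fitness individuals are retained and inference relies on the
case bootstrap rather than normal-theory standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import qr as _qr
from scipy.stats import t as _t_dist

from .bootstrap import (
    BootstrapConfig,
    bca_interval,
    bootstrap_linear_model,
    jackknife_linear_model,
    significance,
)

__all__ = [
    "SCHEMES",
    "MODEL_FAMILIES",
    "SelectionEstimate",
    "SelectionTable",
    "ComparisonResult",
    "CorrelationTest",
    "OLSFit",
    "standardize",
    "relativize",
    "fit_ols",
    "vif",
    "pearson_correlation",
    "prepare_analysis_frame",
    "fit_selection_model",
    "total_selection",
    "direct_selection",
    "devtime_selection",
    "compare_direct_vs_total",
]

SCHEMES = ("local", "global")

#: Model families: three single-trait ("total") families, the multi-trait
#: gradient model, the model adding the trait interaction, and the full
#: model adding both squared terms to the interaction model.
MODEL_FAMILIES = (
    "total_leafout",
    "total_ffd",
    "total_devtime",
    "direct_linear",
    "direct_correlational",
    "direct_full",
)

_TRAIT_OF_TOTAL = {
    "total_leafout": "leaf_out_day",
    "total_ffd": "first_flowering_day",
    "total_devtime": "development_time",
}

_ZCOL = {
    "leaf_out_day": "z_leafout",
    "first_flowering_day": "z_ffd",
    "development_time": "z_devtime",
}

SIZE_TERM = "plant_size"
INTERACTION_TERM = "leaf_out_day:first_flowering_day"


def _check_scheme(scheme: str) -> str:
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    return scheme


# ---------------------------------------------------------------------------
# Standardization / relativization
# ---------------------------------------------------------------------------


def standardize(values, scheme: str = "local", grouping=None) -> np.ndarray:
    """Scale to mean 0 and unit sample SD (n-1 denominator).

    With ``scheme="local"`` moments are computed within each level of
    ``grouping`` (typically year); with ``scheme="global"`` moments are
    pooled.  Raises on zero within-group (or pooled) variance, naming the
    offending group.
    """
    _check_scheme(scheme)
    x = np.asarray(values, dtype=float)
    if scheme == "global" or grouping is None:
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError("zero variance in pooled values; cannot standardize")
        return (x - x.mean()) / sd
    g = np.asarray(grouping)
    out = np.empty_like(x)
    for level in pd.unique(g):
        mask = g == level
        sd = x[mask].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"zero variance in group {level!r}; cannot standardize")
        out[mask] = (x[mask] - x[mask].mean()) / sd
    return out


def relativize(fitness, scheme: str = "local", grouping=None) -> np.ndarray:
    """Divide fitness by its group (local) or pooled (global) mean.

    Output has mean exactly 1 per reference group; zeros stay zeros.
    Raises when a reference group has mean fitness of zero.
    """
    _check_scheme(scheme)
    w = np.asarray(fitness, dtype=float)
    if np.any(w < 0):
        raise ValueError("fitness values must be nonnegative")
    if scheme == "global" or grouping is None:
        m = w.mean()
        if m <= 0:
            raise ValueError("pooled mean fitness is zero; cannot relativize")
        return w / m
    g = np.asarray(grouping)
    out = np.empty_like(w)
    for level in pd.unique(g):
        mask = g == level
        m = w[mask].mean()
        if m <= 0:
            raise ValueError(f"mean fitness is zero in group {level!r}; cannot relativize")
        out[mask] = w[mask] / m
    return out


# ---------------------------------------------------------------------------
# OLS and diagnostics
# ---------------------------------------------------------------------------


@dataclass
class OLSFit:
    """Least-squares fit: named coefficients plus fitted values/residuals."""

    params: pd.Series
    fitted: np.ndarray
    residuals: np.ndarray

    @property
    def names(self) -> list[str]:
        return list(self.params.index)


def fit_ols(X, y, names: list[str] | None = None) -> OLSFit:
    """Ordinary least squares with an explicit full-rank requirement.

    ``X`` is the complete design matrix (include an intercept column if one
    is wanted).  A rank-deficient design raises a ``ValueError`` naming the
    dependent column(s), identified by pivoted QR.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if names is None:
            names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design matrix and response have incompatible shapes")

    _, r, piv = _qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        dependent = [names[j] for j in sorted(piv[rank:])]
        raise ValueError(
            f"design matrix is rank deficient; dependent column(s): {dependent}"
        )

    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    return OLSFit(params=pd.Series(coef, index=names), fitted=fitted, residuals=y - fitted)


def vif(design) -> pd.Series:
    """Variance inflation factor for each predictor in ``design``.

    ``design`` holds the non-intercept predictors (at least two).  Each
    VIF_j is 1/(1-R^2_j) from regressing predictor j on the others plus an
    intercept; perfect collinearity yields ``inf``.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF requires at least two non-intercept predictors")
    out = {}
    for j in range(p):
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ coef
        ss_tot = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        if ss_tot == 0:
            raise ValueError(f"predictor {names[j]!r} has zero variance")
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[names[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


@dataclass(frozen=True)
class CorrelationTest:
    r: float
    t: float
    df: int
    p: float


def pearson_correlation(x, y) -> CorrelationTest:
    """Product-moment correlation with the two-sided t-test.

    ``t = r sqrt(n-2) / sqrt(1-r^2)`` on ``n-2`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("pearson_correlation requires n >= 3")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("zero variance input to pearson_correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))
    df = n - 2
    if abs(r) >= 1.0:
        return CorrelationTest(r=float(np.sign(r)), t=np.inf * np.sign(r), df=df, p=0.0)
    t = r * np.sqrt(df) / np.sqrt(1.0 - r**2)
    p = 2.0 * float(_t_dist.sf(abs(t), df))
    return CorrelationTest(r=r, t=float(t), df=df, p=p)


# ---------------------------------------------------------------------------
# Selection models
# ---------------------------------------------------------------------------


@dataclass
class SelectionEstimate:
    """One reported coefficient with its BCa interval and flags."""

    term: str
    estimate: float
    bca_lower: float | None = None
    bca_upper: float | None = None
    significant: bool | None = None
    doubled: bool = False
    vif: float = 1.0
    source_model: str = "linear"


@dataclass
class SelectionTable:
    """All reported estimates for one model family, year and scheme."""

    family: str
    year: object
    scheme: str
    n: int
    estimates: list[SelectionEstimate] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __getitem__(self, term: str) -> SelectionEstimate:
        for est in self.estimates:
            if est.term == term:
                return est
        raise KeyError(term)

    @property
    def terms(self) -> list[str]:
        return [e.term for e in self.estimates]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "family": self.family,
                "year": self.year,
                "scheme": self.scheme,
                "n": self.n,
                "term": e.term,
                "estimate": e.estimate,
                "bca_lower": e.bca_lower,
                "bca_upper": e.bca_upper,
                "significant": e.significant,
                "doubled": e.doubled,
                "vif": e.vif,
                "source_model": e.source_model,
            }
            for e in self.estimates
        ]
        return pd.DataFrame(rows)


def prepare_analysis_frame(plant_seasons: pd.DataFrame, scheme: str = "local") -> pd.DataFrame:
    """Standardize traits and relativize fitness for selection analysis.

    Expects columns ``individual_id, year, leaf_out_day,
    first_flowering_day, development_time, aboveground_volume,
    fitness_intact_seeds``.  Size is ln-transformed before standardization
    under the same scheme as the phenology traits.  Returns a copy with
    ``z_leafout, z_ffd, z_devtime, z_size, w`` columns appended.
    """
    _check_scheme(scheme)
    required = [
        "year",
        "leaf_out_day",
        "first_flowering_day",
        "development_time",
        "aboveground_volume",
        "fitness_intact_seeds",
    ]
    missing = [c for c in required if c not in plant_seasons.columns]
    if missing:
        raise ValueError(f"plant-season table is missing columns: {missing}")
    df = plant_seasons.copy()
    if (df["aboveground_volume"] <= 0).any():
        raise ValueError("aboveground_volume must be positive to take logarithms")
    years = df["year"].to_numpy()
    df["z_leafout"] = standardize(df["leaf_out_day"], scheme, years)
    df["z_ffd"] = standardize(df["first_flowering_day"], scheme, years)
    df["z_devtime"] = standardize(df["development_time"], scheme, years)
    df["z_size"] = standardize(np.log(df["aboveground_volume"]), scheme, years)
    df["w"] = relativize(df["fitness_intact_seeds"], scheme, years)
    return df


def _model_terms(family: str, include_size: bool) -> tuple[list[str], list[str]]:
    """(linear-model terms, extended-model terms) excluding the intercept."""
    if family in _TRAIT_OF_TOTAL:
        trait = _TRAIT_OF_TOTAL[family]
        linear = [trait]
        extended = [trait, f"{trait}^2"]
    elif family == "direct_linear":
        linear = ["leaf_out_day", "first_flowering_day"]
        extended = []
    elif family == "direct_correlational":
        linear = ["leaf_out_day", "first_flowering_day", INTERACTION_TERM]
        extended = []
    elif family == "direct_full":
        linear = [
            "leaf_out_day",
            "first_flowering_day",
            "leaf_out_day^2",
            "first_flowering_day^2",
            INTERACTION_TERM,
        ]
        extended = []
    else:
        raise ValueError(f"unknown model family {family!r}; choose from {MODEL_FAMILIES}")
    if include_size:
        linear = linear + [SIZE_TERM]
        extended = (extended + [SIZE_TERM]) if extended else []
    return linear, extended


def _term_column(df: pd.DataFrame, term: str) -> np.ndarray:
    if term == SIZE_TERM:
        return df["z_size"].to_numpy()
    if term == INTERACTION_TERM:
        return (df["z_leafout"] * df["z_ffd"]).to_numpy()
    if term.endswith("^2"):
        base = term[:-2]
        return df[_ZCOL[base]].to_numpy() ** 2
    return df[_ZCOL[term]].to_numpy()


def _build_design(df: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    cols = {"intercept": np.ones(len(df))}
    for term in terms:
        cols[term] = _term_column(df, term)
    return pd.DataFrame(cols, index=df.index)


def _is_squared(term: str) -> bool:
    return term.endswith("^2")


def _fit_with_intervals(
    design: pd.DataFrame,
    w: np.ndarray,
    bootstrap: BootstrapConfig | None,
    multipliers: dict[str, float],
    table: SelectionTable,
    source_model: str,
) -> dict[str, SelectionEstimate]:
    """Fit one model, bootstrap every coefficient, return named estimates."""
    fit = fit_ols(design, w)
    names = list(design.columns)

    vifs = {t: 1.0 for t in names}
    predictors = design.drop(columns="intercept")
    if predictors.shape[1] >= 2:
        vifs.update(vif(predictors).to_dict())

    intervals: dict[str, tuple[float, float] | None] = {t: None for t in names}
    if bootstrap is not None:
        X = design.to_numpy(dtype=float)
        reps = bootstrap_linear_model(X, w, bootstrap)
        jack = jackknife_linear_model(X, w)
        for j, term in enumerate(names):
            mult = multipliers.get(term, 1.0)
            lo, hi = bca_interval(
                reps[:, j] * mult,
                fit.params[term] * mult,
                jack[:, j] * mult,
                bootstrap.confidence_level,
            )
            intervals[term] = (lo, hi)
            est = fit.params[term] * mult
            if not lo <= est <= hi:
                table.warnings.append(
                    f"BCa interval for {term!r} does not contain the point estimate "
                    f"({est:.4g} outside [{lo:.4g}, {hi:.4g}])"
                )

    out = {}
    for term in names:
        if term == "intercept":
            continue
        mult = multipliers.get(term, 1.0)
        ci = intervals[term]
        out[term] = SelectionEstimate(
            term=term,
            estimate=float(fit.params[term] * mult),
            bca_lower=None if ci is None else ci[0],
            bca_upper=None if ci is None else ci[1],
            significant=None if ci is None else significance(ci),
            doubled=mult == 2.0,
            vif=float(vifs[term]),
            source_model=source_model,
        )
    return out


def fit_selection_model(
    data: pd.DataFrame,
    family: str,
    year=None,
    scheme: str = "local",
    include_size: bool = True,
    bootstrap: BootstrapConfig | None = None,
    double_interaction: bool = False,
) -> SelectionTable:
    """Fit one model family for one year and return its selection table.

    ``data`` is the full plant-season table (all years); standardization
    moments follow ``scheme`` and are computed before subsetting to
    ``year``, so the global scheme sees pooled moments.  Squared-term
    coefficients are doubled in the report; the interaction is doubled only
    when ``double_interaction`` is set.

    For the single-trait ("total_*") families the first-order estimates
    come from the linear-only model and the squared-term estimate from the
    model that adds the square; both models are bootstrapped.
    """
    years = pd.unique(data["year"])
    if year is None:
        if len(years) != 1:
            raise ValueError("year must be given when the table spans several years")
        year = years[0]
    elif year not in set(years):
        raise ValueError(f"year {year!r} not present in the data")

    frame = prepare_analysis_frame(data, scheme)
    sub = frame[frame["year"] == year].reset_index(drop=True)

    linear_terms, extended_terms = _model_terms(family, include_size)
    multipliers = {t: 2.0 for t in linear_terms + extended_terms if _is_squared(t)}
    if double_interaction:
        multipliers[INTERACTION_TERM] = 2.0

    table = SelectionTable(family=family, year=year, scheme=scheme, n=len(sub))
    w = sub["w"].to_numpy()

    def _boot_cfg(offset: int) -> BootstrapConfig | None:
        if bootstrap is None:
            return None
        return BootstrapConfig(
            n_replicates=bootstrap.n_replicates,
            confidence_level=bootstrap.confidence_level,
            rng_seed=bootstrap.rng_seed + offset,
        )

    linear_design = _build_design(sub, linear_terms)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        linear_est = _fit_with_intervals(
            linear_design, w, _boot_cfg(0), multipliers, table, "linear"
        )
        extended_est: dict[str, SelectionEstimate] = {}
        if extended_terms:
            extended_design = _build_design(sub, extended_terms)
            extended_est = _fit_with_intervals(
                extended_design, w, _boot_cfg(1), multipliers, table, "extended"
            )
    table.warnings.extend(str(c.message) for c in caught)

    # Report order: first-order terms from the linear model, then squared /
    # interaction terms from the extended model (if any).
    for term in linear_terms:
        table.estimates.append(linear_est[term])
    for term in extended_terms:
        if not _is_squared(term):
            continue
        table.estimates.append(extended_est[term])
    return table


def total_selection(
    data: pd.DataFrame,
    trait: str,
    year=None,
    scheme: str = "local",
    include_size: bool = True,
    include_quadratic: bool = True,
    bootstrap: BootstrapConfig | None = None,
) -> SelectionTable:
    """Total selection on one trait: differential plus quadratic coefficient.

    ``trait`` is one of ``leaf_out_day``, ``first_flowering_day`` or
    ``development_time``.  ``include_size=False`` reproduces the
    covariate-free model variant.
    """
    family = {v: k for k, v in _TRAIT_OF_TOTAL.items()}.get(trait)
    if family is None:
        raise ValueError(f"unknown trait {trait!r}; choose from {sorted(_ZCOL)}")
    table = fit_selection_model(
        data, family, year=year, scheme=scheme, include_size=include_size, bootstrap=bootstrap
    )
    if not include_quadratic:
        table.estimates = [e for e in table.estimates if not _is_squared(e.term)]
    return table


def direct_selection(
    data: pd.DataFrame,
    year=None,
    scheme: str = "local",
    full: bool = False,
    include_size: bool = True,
    bootstrap: BootstrapConfig | None = None,
    double_interaction: bool = False,
) -> SelectionTable:
    """Direct selection gradients; ``full=True`` adds squares + interaction."""
    family = "direct_full" if full else "direct_linear"
    return fit_selection_model(
        data,
        family,
        year=year,
        scheme=scheme,
        include_size=include_size,
        bootstrap=bootstrap,
        double_interaction=double_interaction,
    )


def devtime_selection(
    data: pd.DataFrame,
    year=None,
    scheme: str = "local",
    include_size: bool = True,
    bootstrap: BootstrapConfig | None = None,
) -> SelectionTable:
    """Selection on development time (first flowering minus leaf-out)."""
    return total_selection(
        data,
        "development_time",
        year=year,
        scheme=scheme,
        include_size=include_size,
        bootstrap=bootstrap,
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of the direct-vs-total comparison for one trait and year."""

    term: str
    year: object
    scheme: str
    direct_estimate: float
    total_interval: tuple[float, float]
    differs: bool

    @property
    def interpretation(self) -> str:
        return "indirect via other trait" if self.differs else "no difference"


def compare_direct_vs_total(
    direct: SelectionTable | SelectionEstimate,
    total: SelectionTable | SelectionEstimate,
    term: str | None = None,
    year=None,
    scheme: str | None = None,
) -> ComparisonResult:
    """Flag indirect selection: direct gradient outside the total BCa interval.

    The interval is treated as closed, so a direct estimate exactly at a
    bound is *not* flagged.  When both arguments are tables, their year and
    scheme must agree and ``term`` selects the trait to compare.
    """
    if isinstance(direct, SelectionTable) and isinstance(total, SelectionTable):
        if direct.year != total.year:
            raise ValueError(
                f"year mismatch: direct is {direct.year!r}, total is {total.year!r}"
            )
        if direct.scheme != total.scheme:
            raise ValueError(
                f"scheme mismatch: direct is {direct.scheme!r}, total is {total.scheme!r}"
            )
        if term is None:
            raise ValueError("term must be given when comparing whole tables")
        year, scheme = direct.year, direct.scheme
        direct_est, total_est = direct[term], total[term]
    else:
        if not isinstance(direct, SelectionEstimate) or not isinstance(total, SelectionEstimate):
            raise TypeError("pass two SelectionTables or two SelectionEstimates")
        direct_est, total_est = direct, total
        term = term or direct_est.term
        if direct_est.term != total_est.term:
            raise ValueError(
                f"term mismatch: direct is {direct_est.term!r}, total is {total_est.term!r}"
            )
    if total_est.bca_lower is None or total_est.bca_upper is None:
        raise ValueError("total estimate has no BCa interval; run with a bootstrap config")
    inside = total_est.bca_lower <= direct_est.estimate <= total_est.bca_upper
    return ComparisonResult(
        term=term,
        year=year,
        scheme=scheme or "",
        direct_estimate=direct_est.estimate,
        total_interval=(total_est.bca_lower, total_est.bca_upper),
        differs=not inside,
    )
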