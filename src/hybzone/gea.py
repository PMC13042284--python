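"""Genotype–environment association via a composite RDA predictor.

The environmental side is reduced first: variables are greedily pruned so no
retained pair correlates at |r| >= 0.7, terrain (slope/aspect) comes from a
DEM by Horn's 8-neighbor method, and snow melt day is extracted from daily
snow-cover series.  With a single response variable (the hybrid index), the
constrained ordination RDA reduces to an ordinary least-squares regression
of h on the standardized variables, and the first axis RDA1 is the fitted
linear combination — the environmental gradient that best explains
introgression.  RDA1 then drives a per-SNP likelihood-ratio test: dosages
are modelled as Binomial(2, logit^-1(.)), the null model is intercept-only,
the alternative adds RDA1 (df = 1).  A structure-corrected variant
conditions both models on PC1 and adds an RDA1 x PC1 interaction (df = 2);
when structure and environment are confounded this variant trades most of
the power for false-positive control.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._glm import binomial_lrt
from .io_anchor import GenotypeMatrix

__all__ = [
    "prune_env",
    "aspect_to_components",
    "slope_aspect",
    "snow_melt_day",
    "smooth_neighbors",
    "RDA1",
    "fit_rda1",
    "GeaScan",
    "gea_lrt",
    "gea_outliers",
]


# ---------------------------------------------------------------------------
# Environmental preprocessing
# ---------------------------------------------------------------------------

def prune_env(env: pd.DataFrame, r_max: float = 0.7, order=None):
    """Greedy correlation pruning of environmental variables.

    Variables are scanned in ``order`` (default: column order, i.e. the
    user's priority order); a variable is dropped when its absolute Pearson
    correlation with any already-retained variable reaches ``r_max``.
    Constant columns are dropped with a warning (correlation undefined).

    Returns ``(pruned DataFrame, dropped)`` where ``dropped`` lists
    ``(variable, conflicting_variable, r)`` tuples (conflicting variable
    ``None`` for constant columns).
    """
    if env.shape[1] < 2:
        raise ValueError("need at least two variables to prune")
    order = list(order) if order is not None else list(env.columns)
    retained: list[str] = []
    dropped: list[tuple] = []
    for col in order:
        x = env[col].to_numpy(dtype=float)
        if np.nanstd(x) == 0.0:
            warnings.warn(f"constant column {col!r} dropped", stacklevel=2)
            dropped.append((col, None, np.nan))
            continue
        conflict = None
        for kept in retained:
            r = np.corrcoef(x, env[kept].to_numpy(dtype=float))[0, 1]
            if np.abs(r) >= r_max:
                conflict = (col, kept, float(r))
                break
        if conflict is None:
            retained.append(col)
        else:
            dropped.append(conflict)
    return env[retained].copy(), dropped


def aspect_to_components(aspect_deg) -> pd.DataFrame:
    """Encode the circular aspect variable as (sin, cos) for linear models."""
    rad = np.deg2rad(np.asarray(aspect_deg, dtype=float))
    return pd.DataFrame({"aspect_sin": np.sin(rad), "aspect_cos": np.cos(rad)})


def slope_aspect(dem: np.ndarray, cellsize: float):
    """Slope and aspect grids from a DEM (Horn's 8-neighbor gradient).

    The grid is north-up (row 0 is the northern edge).  Slope is
    atan(|grad z|) in degrees; aspect is the compass bearing of the
    downslope direction in degrees [0, 360) (0 = north, 90 = east), nan on
    flat cells and on the one-cell border.  Non-finite DEM cells propagate.
    """
    dem = np.asarray(dem, dtype=float)
    if dem.ndim != 2 or min(dem.shape) < 3:
        raise ValueError("DEM must be a grid of at least 3x3 cells")
    z = dem
    slope = np.full(z.shape, np.nan)
    aspect = np.full(z.shape, np.nan)
    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dzdx = ((ne + 2.0 * e_ + se) - (nw + 2.0 * w_ + sw)) / (8.0 * cellsize)
    dzdy_north = ((nw + 2.0 * n_ + ne) - (sw + 2.0 * s_ + se)) / (8.0 * cellsize)
    mag = np.hypot(dzdx, dzdy_north)
    slope[1:-1, 1:-1] = np.degrees(np.arctan(mag))
    with np.errstate(invalid="ignore"):
        asp = np.degrees(np.arctan2(-dzdx, -dzdy_north)) % 360.0
    asp[~(mag > 1e-12)] = np.nan
    aspect[1:-1, 1:-1] = asp
    return slope, aspect


def snow_melt_day(
    series,
    second_half_start: int | None = None,
    min_free: int = 15,
    window: int = 30,
) -> float:
    """Mean snow-melt day from daily binary snow series (1 = snow-covered).

    Per snow year, the melt day is the first day d in the second half of
    the year for which at least ``min_free`` of the previous ``window``
    days (d-window .. d-1) were snow-free.  ``series`` is one year (1D) or
    several (2D, years x days, or a list).  Years without a qualifying day
    are skipped with a warning; the mean over qualifying years is returned
    (nan if none qualify).
    """
    arr = np.atleast_2d(np.asarray(series, dtype=float))
    days_found = []
    for year in arr:
        n = year.shape[0]
        if n < 300:
            raise ValueError("each snow year needs at least 300 days")
        start = second_half_start if second_half_start is not None else n // 2 + 1
        free = (year == 0).astype(int)
        csum = np.concatenate([[0], np.cumsum(free)])
        found = None
        for d in range(start, n + 1):
            lo = max(0, d - 1 - window)
            if csum[d - 1] - csum[lo] >= min_free:
                found = d
                break
        if found is None:
            warnings.warn("no qualifying melt day in a snow year; skipped", stacklevel=2)
        else:
            days_found.append(found)
    return float(np.mean(days_found)) if days_found else float("nan")


def smooth_neighbors(grid: np.ndarray) -> np.ndarray:
    """Average each pixel with its 8 neighbors (nan-aware, edge-truncated).

    Used to spatially smooth per-pixel melt-day rasters before averaging.
    """
    grid = np.asarray(grid, dtype=float)
    out = np.full(grid.shape, np.nan)
    rows, cols = grid.shape
    for i in range(rows):
        for j in range(cols):
            block = grid[max(0, i - 1) : i + 2, max(0, j - 1) : j + 2]
            if np.isfinite(block).any():
                out[i, j] = np.nanmean(block)
    return out


# ---------------------------------------------------------------------------
# RDA1 (single-response constrained ordination = OLS on standardized vars)
# ---------------------------------------------------------------------------

class RDA1(BaseEstimator):
    """First redundancy-analysis axis for a single response variable.

    ``fit(X, y)`` regresses the response (hybrid index) on the
    standardized columns of X by least squares.  Fitted attributes:
    ``loadings_`` (standardized coefficients, a Series when X is a
    DataFrame), ``r2_`` (proportion of response variance explained),
    ``scores_`` (centered fitted values for the training samples).
    ``transform(X)`` projects new samples onto the axis using the training
    standardization.
    """

    def fit(self, X, y):
        cols = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            warnings.warn(f"{n_dropped} sample(s) with missing values dropped", stacklevel=2)
        X, y = X[keep], y[keep]
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=0)
        if (self.scale_ == 0).any():
            raise ValueError("constant environmental column; prune first")
        Z = (X - self.mean_) / self.scale_
        coef, _, rank, _ = np.linalg.lstsq(Z, y - y.mean(), rcond=None)
        if rank < Z.shape[1]:
            warnings.warn(
                "collinear design: minimum-norm least-squares solution used", stacklevel=2
            )
        fitted = Z @ coef
        sst = ((y - y.mean()) ** 2).sum()
        self.r2_ = float(1.0 - ((y - y.mean() - fitted) ** 2).sum() / sst) if sst > 0 else 0.0
        self.coef_ = coef
        self.loadings_ = pd.Series(coef, index=cols) if cols is not None else coef
        self.scores_ = fitted - fitted.mean()
        self.kept_mask_ = keep
        return self

    def transform(self, X) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        scores = Z @ self.coef_
        return scores - scores.mean()


def fit_rda1(h, env: pd.DataFrame) -> RDA1:
    """Fit the RDA1 axis of the hybrid index on a pruned environment table."""
    return RDA1().fit(env, np.asarray(h, dtype=float))


# ---------------------------------------------------------------------------
# Per-SNP likelihood-ratio GEA
# ---------------------------------------------------------------------------

class GeaScan(BaseEstimator):
    """Per-SNP binomial likelihood-ratio GEA scan.

    ``fit(X, y)`` with X the (individuals x loci) dosage matrix and y the
    environmental predictor (RDA1 scores).  Plain variant: null =
    intercept, alternative = intercept + predictor (df = 1).  With a
    structure covariate (``fit(X, y, covariate=pc1)``): null = intercept +
    covariate, alternative adds predictor and predictor x covariate
    (df = 2; ``interaction=False`` drops the interaction, df = 1).

    Fitted attributes: ``lrt_``, ``pvalues_``, ``df_``, ``converged_``,
    ``n_called_``.  Loci with fewer than ``min_called`` genotypes get nan
    statistics.
    """

    def __init__(self, interaction: bool = True, ridge: float = 1e-6, min_called: int = 20):
        self.interaction = interaction
        self.ridge = ridge
        self.min_called = min_called

    def fit(self, X, y, covariate=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if not np.isfinite(y).all():
            raise ValueError("predictor must be finite for every individual")
        n = X.shape[0]
        ones = np.ones(n)
        if covariate is None:
            X_null = ones[:, None]
            X_alt = np.column_stack([ones, y])
            self.df_ = 1
        else:
            cov = np.asarray(covariate, dtype=float)
            X_null = np.column_stack([ones, cov])
            cols = [ones, cov, y] + ([y * cov] if self.interaction else [])
            X_alt = np.column_stack(cols)
            self.df_ = 2 if self.interaction else 1
        dosage = X.T  # (L, n)
        mask = (~np.isnan(dosage)).astype(float)
        yy = np.nan_to_num(dosage, nan=0.0)
        res = binomial_lrt(yy, mask, X_null, X_alt, ridge=self.ridge)
        n_called = mask.sum(axis=1)
        low = n_called < self.min_called
        self.lrt_ = np.where(low, np.nan, res["lrt"])
        self.pvalues_ = np.where(low, np.nan, res["p"])
        self.converged_ = res["converged"] & ~low
        self.n_called_ = n_called.astype(int)
        return self

    def to_frame(self, loci: pd.DataFrame | None = None) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "lrt": self.lrt_,
                "df": self.df_,
                "p": self.pvalues_,
                "converged": self.converged_,
                "n_called": self.n_called_,
            }
        )
        if loci is not None:
            out = pd.concat([loci[["scaffold", "pos"]].reset_index(drop=True), out], axis=1)
        return out


def gea_lrt(
    matrix: GenotypeMatrix, predictor, covariate=None, interaction: bool = True, **kwargs
) -> pd.DataFrame:
    """Per-locus GEA LRT table (scaffold, pos, lrt, df, p, converged)."""
    scan = GeaScan(interaction=interaction, **kwargs).fit(
        matrix.dosage, predictor, covariate=covariate
    )
    return scan.to_frame(matrix.loci)


def gea_outliers(pvalues, percentile: float = 1.0) -> np.ndarray:
    """Boolean mask of loci at or below the empirical p-value percentile.

    Ties at the cutoff are all included, so the outlier count may exceed
    the nominal fraction.  Requires at least 100 defined p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    defined = np.isfinite(p)
    if defined.sum() < 100:
        raise ValueError("need at least 100 defined p-values")
    cut = np.percentile(p[defined], percentile)
    return defined & (p <= cut)
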