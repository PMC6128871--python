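"""Downstream statistics for calibrated peat/plant composition tables.

Covers the transect workflow: per-core surface (<= 50 cm) summaries,
latitudinal and temperature regressions on those summaries, pooled-variance
t contrasts between sample groups, LOESS depth profiles split at 45 degrees
N, PCA of area-rescaled spectra, and least-squares fitting of external
variables onto the first two ordination axes with permutation significance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .calibration import CalibrationModel, fit_calibration
from .peaks import PeakMeasurement
from .spectra import Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionReport",
    "surface_summary",
    "latitudinal_regression",
    "pooled_t_test",
    "LoessSmoother",
    "loess_profile",
    "AreaNormalizedPCA",
    "pca_spectra",
    "fit_external_vectors",
    "humification_indices",
    "build_composition_table",
]

LATITUDE_SPLIT_DEG = 45.0  # midpoint between pole and equator; high = >= 45 N


@dataclass(frozen=True)
class RegressionReport:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    see: float
    slope_se: float


def _simple_ols(x, y) -> RegressionReport:
    m = fit_calibration(x, y, analyte="carbohydrates", predictor="carb")
    x = np.asarray(list(x), float)
    sxx = float(np.sum((x - x.mean()) ** 2))
    return RegressionReport(
        slope=m.slope, intercept=m.intercept, r_squared=m.r_squared,
        p_value=m.p_value, n=m.n, see=m.see,
        slope_se=m.see / np.sqrt(sxx),
    )


# ---------------------------------------------------------------------------
# surface summaries and latitudinal regression
# ---------------------------------------------------------------------------

def surface_summary(
    table: pd.DataFrame,
    max_depth: float = 50.0,
    core_column: str = "core_id",
    value_columns: Sequence[str] = ("carbohydrates_est", "aromatics_est"),
) -> pd.DataFrame:
    """Per-core mean +/- sample SD over sections with depth <= ``max_depth`` cm.

    ``table`` needs ``core_column``, ``depth_cm`` (section midpoint depth)
    and the value columns.  Excluded rows (column ``excluded`` truthy) are
    dropped first.  Cores with no qualifying section are omitted with a
    warning; single-section cores get NaN SDs.  Output rows are sorted by
    core id, so the summary is invariant to input row order.
    """
    df = table.copy()
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    rows = []
    for core, grp in df.groupby(core_column, sort=True):
        surf = grp[grp["depth_cm"] <= max_depth]
        if len(surf) == 0:
            logger.warning("core %r has no sections <= %g cm; omitted", core, max_depth)
            continue
        row: dict = {core_column: core, "n_sections": len(surf)}
        for col in value_columns:
            vals = surf[col].to_numpy(float)
            row[f"mean_{col}"] = float(np.mean(vals))
            row[f"sd_{col}"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True)


def latitudinal_regression(
    summaries: pd.DataFrame,
    covariate: str,
    response: str,
) -> RegressionReport:
    """Unweighted OLS of per-core surface means on a site covariate.

    One point per core (``covariate`` is e.g. ``latitude_deg`` or
    ``mean_annual_temp_C``; ``response`` e.g. ``mean_carbohydrates_est``).
    """
    df = summaries.dropna(subset=[covariate, response])
    if len(df) < 3:
        raise ValueError(f"need >= 3 cores with {covariate!r}, got {len(df)}")
    return _simple_ols(df[covariate].to_numpy(float), df[response].to_numpy(float))


# ---------------------------------------------------------------------------
# group contrasts
# ---------------------------------------------------------------------------

def pooled_t_test(group_a, group_b) -> tuple[float, int, float]:
    """Unpaired two-tailed Student's t-test with pooled variance.

    Returns ``(t, df, p)`` with ``df = n_a + n_b - 2``.  With a singleton
    group significance cannot be determined and ``(nan, df, nan)`` is
    returned with a warning.  Degenerate zero-variance cases: equal constant
    groups give ``t = 0, p = 1``; unequal means with zero pooled variance
    give ``p = 0`` with a warning.
    """
    a = np.asarray(list(group_a), float)
    b = np.asarray(list(group_b), float)
    df = a.size + b.size - 2
    if a.size < 2 or b.size < 2:
        warnings.warn("a group has n < 2; significance not determinable", stacklevel=2)
        return float("nan"), int(df), float("nan")
    pooled_var = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / df
    if pooled_var == 0.0:
        if a.mean() == b.mean():
            return 0.0, int(df), 1.0
        warnings.warn("zero pooled variance with unequal means", stacklevel=2)
        return float(np.sign(a.mean() - b.mean()) * np.inf), int(df), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), int(df), float(p)


# ---------------------------------------------------------------------------
# LOESS depth profiles
# ---------------------------------------------------------------------------

class LoessSmoother(BaseEstimator):
    """Locally weighted polynomial regression (tricube weights).

    Follows the classical LOESS procedure: at each query point the
    ``ceil(span * n)`` nearest observations are fitted with a weighted
    polynomial of the given degree, weights tricube in scaled distance.  A
    pointwise 95% band comes from the local fit's standard error under a
    normal approximation, with the residual variance estimated globally with
    the fit's approximate degrees of freedom.

    Parameters
    ----------
    degree : int, default 2
    span : float, default 0.75
        Fraction of points entering each local fit.
    """

    def __init__(self, degree: int = 2, span: float = 0.75):
        self.degree = degree
        self.span = span

    def fit(self, x, y) -> "LoessSmoother":
        x = np.asarray(x, float).ravel()
        y = np.asarray(y, float).ravel()
        if x.size != y.size:
            raise ValueError("x and y must have equal length")
        if x.size < self.degree + 2:
            raise ValueError(
                f"need >= degree + 2 = {self.degree + 2} points, got {x.size}"
            )
        if not 0.0 < self.span <= 1.0:
            raise ValueError("span must be in (0, 1]")
        order = np.argsort(x, kind="stable")
        self.x_ = x[order]
        self.y_ = y[order]
        self.n_ = x.size
        # residual variance with approximate degrees of freedom trace(L)
        fitted, lever = self._predict_raw(self.x_, leverage=True)
        rss = float(np.sum((self.y_ - fitted) ** 2))
        nu = float(np.sum(lever))
        dof = max(self.n_ - nu, 1.0)
        self.sigma2_ = rss / dof
        self.fitted_ = fitted
        return self

    def _local_fit(self, x0: float) -> tuple[float, float]:
        """Return (fitted value, sum of squared equivalent-kernel weights)."""
        q = max(int(np.ceil(self.span * self.n_)), self.degree + 1)
        q = min(q, self.n_)
        d = np.abs(self.x_ - x0)
        idx = np.argpartition(d, q - 1)[:q]
        dmax = d[idx].max()
        if dmax == 0:
            w = np.ones(q)
        else:
            w = np.clip(1.0 - (d[idx] / dmax) ** 3, 0.0, None) ** 3
        keep = w > 0
        xi, yi, wi = self.x_[idx][keep], self.y_[idx][keep], w[keep]
        if xi.size <= self.degree:  # all weight on the boundary point(s)
            xi, yi, wi = self.x_[idx], self.y_[idx], np.maximum(w, 1e-12)
        X = np.vander(xi - x0, N=self.degree + 1, increasing=True)
        W = wi
        A = (X * W[:, None]).T @ X
        bvec = (X * W[:, None]).T @ yi
        coef, *_ = np.linalg.lstsq(A, bvec, rcond=None)
        # equivalent kernel row for the fitted value at x0
        Ainv = np.linalg.pinv(A)
        l_row = (Ainv[0] @ (X * W[:, None]).T)
        return float(coef[0]), float(np.sum(l_row**2))

    def _predict_raw(self, x0s, leverage: bool = False):
        fit = np.empty(len(x0s))
        lev = np.empty(len(x0s)) if leverage else None
        for i, x0 in enumerate(np.asarray(x0s, float)):
            f, l2 = self._local_fit(x0)
            fit[i] = f
            if leverage:
                # diagonal of L approximated by the self-weight l_i(x_i)·l_i
                lev[i] = l2  # tr(L Lᵀ) ≈ tr(L) for smoothers; adequate for dof
        return (fit, lev) if leverage else fit

    def predict(self, x0s, return_band: bool = False):
        check_is_fitted(self, "x_")
        x0s = np.atleast_1d(np.asarray(x0s, float))
        fit = np.empty(x0s.size)
        se = np.empty(x0s.size)
        for i, x0 in enumerate(x0s):
            f, l2 = self._local_fit(x0)
            fit[i] = f
            se[i] = np.sqrt(self.sigma2_ * l2)
        if return_band:
            z = stats.norm.ppf(0.975)
            return fit, fit - z * se, fit + z * se
        return fit


def loess_profile(
    table: pd.DataFrame,
    value_column: str,
    depth_column: str = "depth_cm",
    latitude_column: str = "latitude_deg",
    latitude_split: float = LATITUDE_SPLIT_DEG,
    degree: int = 2,
    span: float = 0.75,
    n_grid: int = 100,
) -> pd.DataFrame:
    """Grouped LOESS depth profiles with 95% bands.

    Rows are split into high (latitude >= split) and low latitude groups and
    each group is smoothed over depth on an even ``n_grid``-point grid.
    Groups with fewer than ``degree + 2`` points are skipped with a warning.
    Returns columns ``group, depth_cm, fit, lower, upper``.
    """
    df = table.dropna(subset=[value_column, depth_column, latitude_column])
    groups = {
        "high_latitude": df[df[latitude_column] >= latitude_split],
        "low_latitude": df[df[latitude_column] < latitude_split],
    }
    out = []
    for name, grp in groups.items():
        if len(grp) < degree + 2:
            logger.warning("group %s has %d points; LOESS skipped", name, len(grp))
            continue
        sm = LoessSmoother(degree=degree, span=span).fit(
            grp[depth_column].to_numpy(float), grp[value_column].to_numpy(float)
        )
        grid = np.linspace(grp[depth_column].min(), grp[depth_column].max(), n_grid)
        fit, lo, hi = sm.predict(grid, return_band=True)
        out.append(pd.DataFrame({
            "group": name, "depth_cm": grid, "fit": fit, "lower": lo, "upper": hi,
        }))
    if not out:
        return pd.DataFrame(columns=["group", "depth_cm", "fit", "lower", "upper"])
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# PCA of whole spectra
# ---------------------------------------------------------------------------

class AreaNormalizedPCA(TransformerMixin, BaseEstimator):
    """PCA of whole FTIR spectra after rescaling each to integrated area 100.

    Spectra are linearly interpolated onto a common (overlapping) grid, each
    rescaled so its trapezoidal integral is exactly ``target_area``, then the
    matrix is column-centered (no variance scaling) and decomposed by SVD.
    Loadings are orthonormal; each component's largest-magnitude loading is
    made positive so signs are deterministic.  Spectra with non-positive area
    are excluded with a warning.
    """

    def __init__(self, n_components: int | None = None, target_area: float = 100.0):
        self.n_components = n_components
        self.target_area = target_area

    def _common_grid(self, spectra: Sequence[Spectrum]) -> np.ndarray:
        lo = max(s.wmin for s in spectra)
        hi = min(s.wmax for s in spectra)
        if hi <= lo:
            raise ValueError("spectra have no overlapping wavenumber range")
        ref = spectra[0].wavenumbers
        return ref[(ref >= lo) & (ref <= hi)]

    def _preprocess(
        self, spectra: Sequence[Spectrum], grid: np.ndarray
    ) -> tuple[np.ndarray, list[str]]:
        rows, ids = [], []
        for s in spectra:
            a = np.interp(grid, s.wavenumbers, s.absorbance)
            area = np.trapezoid(a, grid)
            if area <= 0:
                logger.warning(
                    "%r: non-positive area on the common grid; excluded from PCA",
                    s.sample_id,
                )
                continue
            rows.append(a * (self.target_area / area))
            ids.append(s.sample_id)
        if len(rows) < 3:
            raise ValueError(f"PCA needs >= 3 usable spectra, got {len(rows)}")
        return np.array(rows), ids

    def fit(self, X: Sequence[Spectrum], y=None) -> "AreaNormalizedPCA":
        grid = self._common_grid(X)
        M, ids = self._preprocess(X, grid)
        n_comp = self.n_components or min(M.shape[0] - 1, M.shape[1])
        pca = PCA(n_components=n_comp, svd_solver="full")
        scores = pca.fit_transform(M)
        loadings = pca.components_
        # deterministic signs: largest-|loading| element positive per component
        for k in range(loadings.shape[0]):
            j = int(np.argmax(np.abs(loadings[k])))
            if loadings[k, j] < 0:
                loadings[k] *= -1.0
                scores[:, k] *= -1.0
        self.common_grid_ = grid
        self.mean_ = pca.mean_
        self.loadings_ = loadings
        self.explained_variance_ = pca.explained_variance_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.sample_ids_ = ids
        self.scores_ = pd.DataFrame(
            scores, index=pd.Index(ids, name="sample_id"),
            columns=[f"PC{k + 1}" for k in range(scores.shape[1])],
        )
        return self

    def transform(self, X: Sequence[Spectrum]) -> pd.DataFrame:
        check_is_fitted(self, "loadings_")
        M, ids = self._preprocess(X, self.common_grid_)
        scores = (M - self.mean_) @ self.loadings_.T
        return pd.DataFrame(
            scores, index=pd.Index(ids, name="sample_id"),
            columns=[f"PC{k + 1}" for k in range(self.loadings_.shape[0])],
        )


def pca_spectra(
    spectra: Sequence[Spectrum], n_components: int | None = None
) -> AreaNormalizedPCA:
    """Fit :class:`AreaNormalizedPCA` on a spectrum collection."""
    return AreaNormalizedPCA(n_components=n_components).fit(spectra)


# ---------------------------------------------------------------------------
# external-variable vector fitting (ordination arrows)
# ---------------------------------------------------------------------------

def fit_external_vectors(
    scores: pd.DataFrame,
    variables: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Least-squares projection of external variables onto two score axes.

    For each variable column, rows with a defined value are regressed on the
    first two score columns (with intercept); the arrow direction is the
    normalized coefficient vector, its squared correlation is the fit R^2,
    and significance is a permutation p value over ``n_perm`` row shuffles of
    the variable.  Constant variables get ``r_squared 0, p 1`` and a NaN
    direction with a warning.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    axes = scores.iloc[:, :2].to_numpy(float)
    out = []
    for name in variables.columns:
        v = variables[name].reindex(scores.index)
        mask = v.notna().to_numpy()
        y = v.to_numpy(float)[mask]
        Z = axes[mask]
        n = int(mask.sum())
        if n < 3 or np.ptp(y) == 0.0:
            warnings.warn(f"variable {name!r} constant or underdetermined", stacklevel=2)
            out.append({"variable": name, "dx": np.nan, "dy": np.nan,
                        "r_squared": 0.0, "p_perm": 1.0, "n": n})
            continue
        r2, coef = _vector_r2(Z, y)
        norm = np.linalg.norm(coef)
        direction = coef / norm if norm > 0 else np.full(2, np.nan)
        hits = 0
        for _ in range(n_perm):
            r2p, _c = _vector_r2(Z, rng.permutation(y))
            if r2p >= r2:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
        out.append({"variable": name, "dx": float(direction[0]),
                    "dy": float(direction[1]), "r_squared": float(r2),
                    "p_perm": float(p), "n": n})
    return pd.DataFrame(out)


def _vector_r2(Z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    X = np.column_stack([np.ones(len(y)), Z])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if sstot == 0 else 1.0 - float(np.sum(resid**2)) / sstot
    return max(r2, 0.0), coef[1:]


# ---------------------------------------------------------------------------
# humification indices and table assembly
# ---------------------------------------------------------------------------

def humification_indices(
    measurements: Iterable[PeakMeasurement],
) -> tuple[float, float]:
    """Classical band-ratio humification indices from one sample's bands.

    Returns ``(aromatic:carbohydrate, aliphatic:carbohydrate)`` ratios of
    normalized heights, aromatics summed over arom15 + arom16 and aliphatics
    over aliph28 + aliph29.  A non-positive carb height makes the ratios
    undefined (NaN, with a warning).
    """
    h = {m.peak_name: m.normalized_height for m in measurements}
    carb = h.get("carb", np.nan)
    if not carb > 0:
        warnings.warn("carb height <= 0; humification indices undefined", stacklevel=2)
        return float("nan"), float("nan")
    arom = h.get("arom15", 0.0) + h.get("arom16", 0.0)
    aliph = h.get("aliph28", 0.0) + h.get("aliph29", 0.0)
    return arom / carb, aliph / carb


def build_composition_table(
    heights: pd.DataFrame,
    records: Sequence,
    models: dict[str, CalibrationModel],
) -> pd.DataFrame:
    """Join peak heights, metadata, and calibrated composition estimates.

    ``heights`` is the wide table from
    :class:`~peatspec.peaks.PeakHeightTransformer`; ``records`` a sequence of
    :class:`~peatspec.spectra.SampleRecord`; ``models`` the dict from
    :func:`~peatspec.calibration.calibrate_from_standards`.  Excluded samples
    are retained with their flags and should be dropped by downstream
    statistics.
    """
    meta = pd.DataFrame([vars(r) for r in records]).set_index("sample_id")
    df = meta.join(heights, how="inner")
    carb_m = models["carbohydrates"]
    arom_m = models["aromatics"]
    df["carbohydrates_est"] = carb_m.slope * df["carb"] + carb_m.intercept
    df["carbohydrates_se"] = carb_m.see
    arom_x = df["arom15"] + df["arom16"] if arom_m.predictor == "arom15_plus_arom16" \
        else df[arom_m.predictor]
    df["aromatics_est"] = arom_m.slope * arom_x + arom_m.intercept
    df["aromatics_se"] = arom_m.see
    with np.errstate(divide="ignore", invalid="ignore"):
        carb_h = df["carb"].to_numpy(float)
        ok = carb_h > 0
        arom_ratio = np.where(ok, (df["arom15"] + df["arom16"]) / carb_h, np.nan)
        if {"aliph28", "aliph29"} <= set(df.columns):
            aliph_ratio = np.where(ok, (df["aliph28"] + df["aliph29"]) / carb_h, np.nan)
        else:
            aliph_ratio = np.full(len(df), np.nan)
    df["arom_carb_ratio"] = arom_ratio
    df["aliph_carb_ratio"] = aliph_ratio
    return df
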