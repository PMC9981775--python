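"""Continent-scale spatial genetic structure statistics.

Covers the downstream stages run on the QC'd, hybrid/inbred-excluded,
per-location-downsampled panel: isolation by distance (Mantel test of
genetic vs. great-circle geographic distance, by default at population
level to damp spatial autocorrelation), Spearman correlations of
ordination axes with longitude/latitude, multilocus observed
heterozygosity (MLH) and its linear model on longitude, F_hybrid and
F_ROH, selection of region-typical alleles and ordinary-kriging
interpolation of their mean frequencies over a geographic grid.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .io import MISSING, GenotypeMatrix, SampleTable, ValidationError
from .qc import allele_frequency

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# Sample selection
# ---------------------------------------------------------------------------


def downsample_per_location(
    samples: SampleTable, max_n: int = 5, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Randomly keep at most ``max_n`` samples per sampling location.

    Seeded and reproducible: locations are visited in sorted order and
    candidates sorted by sample id before drawing.
    """
    rng = rng or np.random.default_rng()
    tab = samples.table
    keep: list[str] = []
    for loc in sorted(pd.unique(tab["location_id"])):
        ids = sorted(tab.loc[tab["location_id"] == loc, "sample_id"])
        if len(ids) <= max_n:
            keep.extend(ids)
        else:
            chosen = rng.choice(len(ids), size=max_n, replace=False)
            keep.extend(ids[i] for i in sorted(chosen))
    return np.array(keep)


def exclude_inbred_and_hybrid(
    hybrid: pd.DataFrame, inbreeding: pd.DataFrame, threshold: float = 0.0625
) -> np.ndarray:
    """Sample ids with F_hybrid <= threshold and F_ROH <= threshold."""
    fh = hybrid.set_index("sample_id")["f_hybrid"]
    fr = inbreeding.set_index("sample_id")["f_roh"]
    ids = fh.index.intersection(fr.index)
    ok = (fh.loc[ids] <= threshold) & (fr.loc[ids] <= threshold)
    return ids[ok].to_numpy()


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def geographic_distance_matrix(samples: SampleTable) -> np.ndarray:
    """Great-circle distances (km) between all samples."""
    lon = samples.table["longitude"].to_numpy(dtype=float)
    lat = samples.table["latitude"].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(lon) | ~np.isfinite(lat))
    if len(bad):
        raise ValidationError(
            f"missing coordinates for samples: {list(samples.sample_ids[bad][:5])}"
        )
    d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def project_equirectangular_km(lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Planar km coordinates about the mean latitude (for variogram/kriging)."""
    lat0 = np.deg2rad(np.nanmean(lat))
    x = np.deg2rad(lon) * EARTH_RADIUS_KM * math.cos(lat0)
    y = np.deg2rad(lat) * EARTH_RADIUS_KM
    return x, y


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    method: str = "permutation"


def population_distance_matrix(
    d_individual: np.ndarray, location_ids: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean between-location distance matrix from an individual-level one."""
    locs = np.asarray(location_ids)
    uniq = np.array(sorted(pd.unique(locs)))
    k = len(uniq)
    out = np.zeros((k, k))
    idx = {l: np.flatnonzero(locs == l) for l in uniq}
    for a in range(k):
        for b in range(a + 1, k):
            block = d_individual[np.ix_(idx[uniq[a]], idx[uniq[b]])]
            out[a, b] = out[b, a] = block.mean()
    return out, uniq


def mantel_test(
    d_gen: np.ndarray,
    d_geo: np.ndarray,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
    exact: bool = False,
    two_sided: bool = True,
) -> MantelResult:
    """Mantel correlation of two distance matrices.

    r is the Pearson correlation of the strict upper triangles; the null
    distribution permutes rows and columns of one matrix jointly.  The
    permutation p-value uses the add-one estimator
    (1 + #{|r*| >= |r|}) / (1 + n_perm); with ``exact=True`` all n!
    relabelings are enumerated and p = #{|r*| >= |r|} / n! (identity
    included).
    """
    d_gen, d_geo = np.asarray(d_gen, float), np.asarray(d_geo, float)
    if d_gen.shape != d_geo.shape or d_gen.shape[0] != d_gen.shape[1]:
        raise ValidationError("distance matrices must be square and congruent")
    n = d_gen.shape[0]
    if n < 3:
        raise ValidationError("Mantel test needs at least 3 units")
    iu = np.triu_indices(n, k=1)

    def corr(perm: np.ndarray) -> float:
        x = d_gen[np.ix_(perm, perm)][iu]
        y = d_geo[iu]
        xc, yc = x - x.mean(), y - y.mean()
        denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
        return float(xc @ yc) / denom if denom > 0 else 0.0

    ident = np.arange(n)
    r_obs = corr(ident)
    stat = abs if two_sided else (lambda v: v)

    if exact:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if stat(corr(np.array(perm))) >= stat(r_obs) - 1e-12:
                count += 1
        return MantelResult(r=r_obs, p_value=count / total, n_permutations=total, method="exact")

    rng = rng or np.random.default_rng()
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if stat(corr(perm)) >= stat(r_obs) - 1e-12:
            exceed += 1
    return MantelResult(
        r=r_obs, p_value=(1 + exceed) / (1 + n_perm), n_permutations=n_perm
    )


# ---------------------------------------------------------------------------
# Axis-geography correlation
# ---------------------------------------------------------------------------


def axis_geography_correlation(
    coordinates: np.ndarray, samples: SampleTable, n_axes: int = 2
) -> pd.DataFrame:
    """Spearman correlation of per-location mean ordination scores with
    longitude and latitude (population level, reducing autocorrelation)."""
    tab = samples.table
    locs = sorted(pd.unique(tab["location_id"]))
    if len(locs) < 3:
        raise ValidationError("need at least 3 locations")
    means, lons, lats = [], [], []
    for loc in locs:
        sel = (tab["location_id"] == loc).to_numpy()
        means.append(coordinates[sel, :n_axes].mean(axis=0))
        lons.append(float(tab.loc[sel, "longitude"].mean()))
        lats.append(float(tab.loc[sel, "latitude"].mean()))
    means = np.asarray(means)
    rows = []
    for axis in range(min(n_axes, means.shape[1])):
        for geo_name, geo in (("longitude", lons), ("latitude", lats)):
            score = means[:, axis]
            if np.ptp(score) == 0 or np.ptp(geo) == 0:
                rho, p = float("nan"), float("nan")
            else:
                rho, p = stats.spearmanr(score, geo)
            rows.append((axis + 1, geo_name, float(rho), float(p)))
    return pd.DataFrame(rows, columns=["axis", "geo_variable", "spearman_rho", "p_value"])


# ---------------------------------------------------------------------------
# Multilocus heterozygosity
# ---------------------------------------------------------------------------


def mlh(g: GenotypeMatrix) -> pd.DataFrame:
    """Multilocus observed heterozygosity: heterozygous / non-missing loci.

    Adds decile class labels (1..10, equal observation counts) for mapping;
    all-missing samples are flagged with NaN.
    """
    het = (g.dosage == 1).sum(axis=1)
    typed = (g.dosage != MISSING).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(typed > 0, het / np.maximum(typed, 1), np.nan)
    out = pd.DataFrame({"sample_id": g.samples.sample_ids, "mlh": values})
    finite = out["mlh"].notna()
    if finite.sum() >= 10 and out.loc[finite, "mlh"].nunique() >= 10:
        out.loc[finite, "decile"] = (
            pd.qcut(out.loc[finite, "mlh"], 10, labels=False, duplicates="drop") + 1
        )
    else:
        out["decile"] = np.nan
    return out


def mlh_linear_model(
    mlh_values: np.ndarray,
    longitude: np.ndarray,
    f_hybrid: np.ndarray,
    f_roh: np.ndarray,
    latitude: np.ndarray | None = None,
) -> dict:
    """OLS of MLH on longitude, F_hybrid and F_ROH.

    Latitude, when given, is screened in a separate univariate model (it is
    not part of the main design).  Returns the coefficient table, overall
    F statistic, adjusted R-squared and residual degrees of freedom.
    """
    y = np.asarray(mlh_values, float)
    X = np.column_stack([longitude, f_hybrid, f_roh]).astype(float)
    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[ok], X[ok]
    design = sm.add_constant(X)
    if np.linalg.cond(design) > 1e10:
        raise ValidationError("collinear design matrix in MLH linear model")
    fit = sm.OLS(y, design).fit()
    names = ["const", "longitude", "f_hybrid", "f_roh"]
    coef = pd.DataFrame(
        {
            "term": names,
            "estimate": fit.params,
            "t_value": fit.tvalues,
            "p_value": fit.pvalues,
        }
    )
    out = {
        "coefficients": coef,
        "f_statistic": float(fit.fvalue),
        "f_pvalue": float(fit.f_pvalue),
        "r2_adj": float(fit.rsquared_adj),
        "df_resid": int(fit.df_resid),
    }
    if latitude is not None:
        lat = np.asarray(latitude, float)[ok]
        lat_fit = sm.OLS(y, sm.add_constant(lat)).fit()
        out["latitude_screen"] = {
            "estimate": float(lat_fit.params[1]),
            "t_value": float(lat_fit.tvalues[1]),
            "p_value": float(lat_fit.pvalues[1]),
        }
    return out


# ---------------------------------------------------------------------------
# Regional alleles and clines
# ---------------------------------------------------------------------------


def select_regional_alleles(
    g: GenotypeMatrix,
    samples: SampleTable,
    focal_locations: set[str],
    focal_min_freq: float = 0.5,
) -> pd.DataFrame:
    """Loci whose panel-scale minor allele is locally major in the focal
    region (within-region frequency above ``focal_min_freq``).

    Monomorphic panel loci are skipped.  Returns locus_id, which map allele
    ('a'/'b') is region-typical, its panel and focal frequencies.
    """
    if not focal_locations:
        raise ValidationError("focal location set is empty")
    locs = samples.table["location_id"].to_numpy()
    focal_idx = np.flatnonzero(np.isin(locs, list(focal_locations)))
    if len(focal_idx) == 0:
        raise ValidationError("no samples in the focal region")
    p_panel = allele_frequency(g)
    p_focal = allele_frequency(g, focal_idx)
    rows = []
    for j, locus in enumerate(g.markers.locus_ids):
        pp, pf = p_panel[j], p_focal[j]
        if np.isnan(pp) or np.isnan(pf) or pp in (0.0, 1.0):
            continue  # monomorphic or untyped
        if pp <= 0.5:
            which, panel_freq, focal_freq = "b", pp, pf
        else:
            which, panel_freq, focal_freq = "a", 1.0 - pp, 1.0 - pf
        if focal_freq > focal_min_freq:
            rows.append((locus, which, float(panel_freq), float(focal_freq)))
    return pd.DataFrame(
        rows, columns=["locus_id", "allele", "panel_freq", "focal_freq"]
    )


def mean_regional_frequency(
    g: GenotypeMatrix, samples: SampleTable, selection: pd.DataFrame
) -> pd.DataFrame:
    """Per location: mean frequency of the region-typical alleles."""
    if len(selection) == 0:
        raise ValidationError("empty allele selection")
    lookup = {l: i for i, l in enumerate(g.markers.locus_ids)}
    idx = np.array([lookup[l] for l in selection["locus_id"]], dtype=np.intp)
    flip = (selection["allele"] == "a").to_numpy()
    locs = samples.table["location_id"].to_numpy()
    rows = []
    for loc in sorted(pd.unique(locs)):
        sub = np.flatnonzero(locs == loc)
        p = allele_frequency(g, sub)[idx]
        p = np.where(flip, 1.0 - p, p)
        typed = np.isfinite(p)
        lon = float(samples.table.loc[sub, "longitude"].mean())
        lat = float(samples.table.loc[sub, "latitude"].mean())
        if typed.any():
            rows.append((loc, lon, lat, float(np.nanmean(p)), int(typed.sum())))
        else:
            warnings.warn(f"location {loc!r} has no typed selected loci", stacklevel=2)
            rows.append((loc, lon, lat, float("nan"), 0))
    return pd.DataFrame(
        rows, columns=["location_id", "longitude", "latitude", "mean_freq", "n_loci"]
    )


# ---------------------------------------------------------------------------
# Variogram + ordinary kriging
# ---------------------------------------------------------------------------


@dataclass
class VariogramModel:
    model_family: str  # spherical | exponential | gaussian
    nugget: float
    sill: float        # total sill (nugget + partial sill)
    range_: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate:
            if self.nugget < 0 or self.sill < self.nugget or self.range_ <= 0:
                raise ValidationError("invalid variogram parameters")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        if self.degenerate:
            return np.zeros_like(h)
        psill = self.sill - self.nugget
        r = self.range_
        if self.model_family == "spherical":
            hr = np.minimum(h / r, 1.0)
            structure = 1.5 * hr - 0.5 * hr**3
        elif self.model_family == "exponential":
            structure = 1.0 - np.exp(-3.0 * h / r)  # r = practical range
        elif self.model_family == "gaussian":
            structure = 1.0 - np.exp(-3.0 * (h / r) ** 2)
        else:
            raise ValidationError(f"unknown model family {self.model_family!r}")
        gamma = self.nugget + psill * structure
        return np.where(h == 0, 0.0, gamma)


def empirical_variogram(
    x: np.ndarray, y: np.ndarray, values: np.ndarray, n_bins: int = 12
) -> pd.DataFrame:
    """Binned semivariance 0.5 * mean (v_i - v_j)^2 up to half the max
    pairwise distance."""
    pts = np.column_stack([x, y]).astype(float)
    v = np.asarray(values, float)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    iu = np.triu_indices(len(v), k=1)
    h = d[iu]
    sq = 0.5 * (v[iu[0]] - v[iu[1]]) ** 2
    hmax = h.max() / 2.0
    edges = np.linspace(0, hmax, n_bins + 1)
    rows = []
    for k in range(n_bins):
        sel = (h > edges[k]) & (h <= edges[k + 1])
        if sel.sum() > 0:
            rows.append((float(h[sel].mean()), float(sq[sel].mean()), int(sel.sum())))
    return pd.DataFrame(rows, columns=["distance", "gamma", "n_pairs"])


def fit_variogram(
    x: np.ndarray, y: np.ndarray, values: np.ndarray, n_bins: int = 12
) -> VariogramModel:
    """Auto-fit a variogram: weighted least squares over spherical,
    exponential and gaussian families; best weighted SSE wins."""
    if len(np.asarray(values)) < 5:
        raise ValidationError("need at least 5 points to fit a variogram")
    v = np.asarray(values, float)
    if np.allclose(v, v[0]):
        return VariogramModel("spherical", 0.0, 0.0, 1.0, degenerate=True)
    emp = empirical_variogram(x, y, v, n_bins=n_bins)
    h, gamma, npairs = (emp[c].to_numpy() for c in ("distance", "gamma", "n_pairs"))
    var_v = float(np.var(v))
    hmax = float(h.max())

    best: VariogramModel | None = None
    best_sse = np.inf
    for family in ("spherical", "exponential", "gaussian"):

        def residuals(theta, family=family):
            nugget, psill, rng_ = theta
            model = VariogramModel(family, nugget, nugget + psill, rng_)
            return np.sqrt(npairs) * (model(h) - gamma)

        x0 = np.array([gamma[0] / 2.0, max(var_v - gamma[0] / 2.0, 1e-6), hmax / 2.0])
        try:
            res = optimize.least_squares(
                residuals,
                x0,
                bounds=([0.0, 1e-9, 1e-6], [np.inf, np.inf, 10.0 * hmax]),
            )
        except Exception:  # pragma: no cover - optimizer failure
            continue
        sse = float(np.sum(res.fun**2))
        if sse < best_sse:
            nugget, psill, rng_ = res.x
            best = VariogramModel(family, float(nugget), float(nugget + psill), float(rng_))
            best_sse = sse
    if best is None:  # pragma: no cover - defensive
        raise ValidationError("variogram fitting failed for all families")
    return best


class OrdinaryKriging(BaseEstimator):
    """Ordinary kriging with a fitted (or supplied) variogram.

    ``fit(X, y)`` takes planar coordinates (n x 2, km) and values;
    duplicate locations are averaged with a warning.  ``predict(X0)``
    solves the ordinary-kriging system (variogram form, Lagrange
    multiplier) per node and returns predictions; ``predict_var`` also
    returns kriging variances.  Weights sum to one by construction; the
    solved weights for the last prediction are kept in ``last_weights_``.
    """

    def __init__(self, variogram: VariogramModel | None = None, n_bins: int = 12):
        self.variogram = variogram
        self.n_bins = n_bins

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OrdinaryKriging":
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        # average duplicate points to keep the system nonsingular
        key = pd.DataFrame({"x": X[:, 0], "y": X[:, 1], "v": y})
        grouped = key.groupby(["x", "y"], as_index=False, sort=False)["v"].mean()
        if len(grouped) < len(key):
            warnings.warn("duplicate locations averaged before kriging", stacklevel=2)
        self.X_ = grouped[["x", "y"]].to_numpy()
        self.y_ = grouped["v"].to_numpy()
        self.model_ = self.variogram or fit_variogram(
            self.X_[:, 0], self.X_[:, 1], self.y_, n_bins=self.n_bins
        )
        n = len(self.y_)
        d = np.sqrt(((self.X_[:, None, :] - self.X_[None, :, :]) ** 2).sum(axis=2))
        A = np.empty((n + 1, n + 1))
        A[:n, :n] = self.model_(d)
        A[n, :n] = 1.0
        A[:n, n] = 1.0
        A[n, n] = 0.0
        if self.model_.degenerate or np.linalg.matrix_rank(A) < n + 1:
            # pure-nugget / constant field: fall back to the mean predictor
            self._lu = None
        else:
            self._lu = np.linalg.inv(A)
        return self

    def predict(self, X0: np.ndarray, return_var: bool = False):
        X0 = np.asarray(X0, float)
        n = len(self.y_)
        if self._lu is None:
            pred = np.full(len(X0), float(self.y_.mean()))
            var = np.zeros(len(X0))
            self.last_weights_ = np.full((len(X0), n), 1.0 / n)
            return (pred, var) if return_var else pred
        d0 = np.sqrt(((X0[:, None, :] - self.X_[None, :, :]) ** 2).sum(axis=2))
        b = np.empty((len(X0), n + 1))
        b[:, :n] = self.model_(d0)
        b[:, n] = 1.0
        sol = b @ self._lu.T
        w = sol[:, :n]
        mu = sol[:, n]
        pred = w @ self.y_
        var = np.einsum("ij,ij->i", w, b[:, :n]) + mu
        self.last_weights_ = w
        return (pred, np.maximum(var, 0.0)) if return_var else pred


@dataclass
class GridSpec:
    step_deg: float = 0.5
    margin_frac: float = 0.10


def krige_surface(
    location_freqs: pd.DataFrame,
    model: VariogramModel | None = None,
    grid: GridSpec | None = None,
) -> pd.DataFrame:
    """Interpolate per-location mean allele frequencies over a lon/lat grid.

    Locations are projected to planar km about their mean latitude; the
    grid covers the bounding box of the locations with a proportional
    margin.  Returns columns longitude, latitude, prediction, variance.
    """
    grid = grid or GridSpec()
    df = location_freqs.dropna(subset=["mean_freq"])
    lon = df["longitude"].to_numpy(float)
    lat = df["latitude"].to_numpy(float)
    vals = df["mean_freq"].to_numpy(float)
    x, y = project_equirectangular_km(lon, lat)
    krig = OrdinaryKriging(variogram=model).fit(np.column_stack([x, y]), vals)

    mlon = (lon.max() - lon.min()) * grid.margin_frac
    mlat = (lat.max() - lat.min()) * grid.margin_frac
    glon = np.arange(lon.min() - mlon, lon.max() + mlon + grid.step_deg, grid.step_deg)
    glat = np.arange(lat.min() - mlat, lat.max() + mlat + grid.step_deg, grid.step_deg)
    gx, gy = np.meshgrid(glon, glat)
    lat0 = np.deg2rad(np.nanmean(lat))
    px = np.deg2rad(gx.ravel()) * EARTH_RADIUS_KM * math.cos(lat0)
    py = np.deg2rad(gy.ravel()) * EARTH_RADIUS_KM
    pred, var = krig.predict(np.column_stack([px, py]), return_var=True)
    return pd.DataFrame(
        {
            "longitude": gx.ravel(),
            "latitude": gy.ravel(),
            "prediction": pred,
            "variance": var,
        }
    )
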