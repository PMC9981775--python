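"""Spatial structure: Mantel, geography, MLH model, clines, kriging."""

import itertools

import numpy as np
import pandas as pd
import pytest

from boarpop.io import MISSING, SampleTable, ValidationError
from boarpop.spatial import (
    GridSpec,
    OrdinaryKriging,
    VariogramModel,
    axis_geography_correlation,
    downsample_per_location,
    exclude_inbred_and_hybrid,
    fit_variogram,
    geographic_distance_matrix,
    haversine_km,
    krige_surface,
    mantel_test,
    mean_regional_frequency,
    mlh,
    mlh_linear_model,
    population_distance_matrix,
    select_regional_alleles,
)
from helpers import build_genotypes, build_markers


def make_samples(n, locations=None, lon=None, lat=None, groups="wild"):
    tab = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(n)],
         "group": [groups] * n if isinstance(groups, str) else groups}
    )
    if locations is not None:
        tab["location_id"] = locations
    if lon is not None:
        tab["longitude"] = lon
        tab["latitude"] = lat
    return SampleTable(tab)


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------


def test_downsample_keeps_small_locations_whole(rng):
    s = make_samples(8, locations=["A"] * 3 + ["B"] * 5)
    kept = downsample_per_location(s, 5, rng)
    assert len(kept) == 8


def test_downsample_caps_large_location(rng):
    s = make_samples(30, locations=["A"] * 26 + ["B"] * 4)
    kept = downsample_per_location(s, 5, rng)
    locs = s.table.set_index("sample_id").loc[kept, "location_id"]
    assert (locs == "A").sum() == 5 and (locs == "B").sum() == 4


def test_downsample_deterministic_under_seed():
    s = make_samples(40, locations=["A"] * 20 + ["B"] * 20)
    a = downsample_per_location(s, 5, np.random.default_rng(7))
    b = downsample_per_location(s, 5, np.random.default_rng(7))
    np.testing.assert_array_equal(a, b)


def test_exclusion_threshold_oracle(rng):
    n = 30
    fh = rng.uniform(0, 0.15, n)
    fr = rng.uniform(0, 0.15, n)
    hyb = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)], "f_hybrid": fh})
    inb = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)], "f_roh": fr})
    kept = set(exclude_inbred_and_hybrid(hyb, inb, 0.0625))
    expected = {f"s{i}" for i in range(n) if fh[i] <= 0.0625 and fr[i] <= 0.0625}
    assert kept == expected


def test_exclusion_removes_marginal_hybrid():
    hyb = pd.DataFrame({"sample_id": ["a", "b"], "f_hybrid": [0.07, 0.0]})
    inb = pd.DataFrame({"sample_id": ["a", "b"], "f_roh": [0.0, 0.0]})
    assert list(exclude_inbred_and_hybrid(hyb, inb)) == ["b"]


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------


def test_haversine_closed_forms():
    assert haversine_km(0.0, 0.0, 0.0, 0.0) == 0.0
    half = np.pi * 6371.0
    assert haversine_km(0.0, 0.0, 180.0, 0.0) == pytest.approx(half, rel=1e-6)


def test_geographic_distance_matrix_symmetric(rng):
    lon = rng.uniform(-10, 30, 8)
    lat = rng.uniform(35, 60, 8)
    s = make_samples(8, lon=lon, lat=lat)
    d = geographic_distance_matrix(s)
    np.testing.assert_allclose(d, d.T)
    assert (np.diag(d) == 0).all()


def test_geographic_distance_requires_coordinates():
    s = make_samples(3, lon=[1.0, np.nan, 2.0], lat=[1.0, 2.0, 3.0])
    with pytest.raises(ValidationError, match="s1"):
        geographic_distance_matrix(s)


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------


def test_mantel_perfect_correlation(rng):
    x = rng.uniform(0, 10, (6, 1))
    d = np.abs(x - x.T)
    res = mantel_test(d, 3.0 * d, n_perm=99, rng=rng)
    assert res.r == pytest.approx(1.0)
    assert res.p_value <= 0.05


def test_mantel_exact_matches_enumeration_oracle(rng):
    d1 = np.abs(rng.normal(size=(4, 1)) - rng.normal(size=(4, 1)).T)
    d2 = np.abs(rng.normal(size=(4, 1)) - rng.normal(size=(4, 1)).T)
    np.fill_diagonal(d1, 0)
    np.fill_diagonal(d2, 0)
    res = mantel_test(d1, d2, exact=True)
    iu = np.triu_indices(4, 1)

    def corr(perm):
        a = d1[np.ix_(perm, perm)][iu]
        b = d2[iu]
        return np.corrcoef(a, b)[0, 1]

    r_obs = corr(list(range(4)))
    count = sum(
        abs(corr(list(p))) >= abs(r_obs) - 1e-12
        for p in itertools.permutations(range(4))
    )
    assert res.n_permutations == 24
    assert res.p_value == pytest.approx(count / 24)
    assert res.r == pytest.approx(r_obs)


def test_mantel_rejects_too_few_units():
    d = np.zeros((2, 2))
    with pytest.raises(ValidationError):
        mantel_test(d, d)


def test_mantel_agrees_with_skbio(rng):
    skbio = pytest.importorskip("skbio")
    x = rng.uniform(0, 1, (7, 2))
    y = x + rng.normal(0, 0.2, (7, 2))
    dx = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
    dy = np.sqrt(((y[:, None] - y[None, :]) ** 2).sum(-1))
    ours = mantel_test(dx, dy, n_perm=999, rng=rng)
    r_skbio, _, _ = skbio.stats.distance.mantel(dx, dy, permutations=0)
    assert ours.r == pytest.approx(r_skbio, abs=1e-10)


def test_population_distance_matrix_means():
    d = np.array(
        [[0.0, 1.0, 4.0, 6.0],
         [1.0, 0.0, 2.0, 8.0],
         [4.0, 2.0, 0.0, 3.0],
         [6.0, 8.0, 3.0, 0.0]]
    )
    pop, labels = population_distance_matrix(d, np.array(["A", "A", "B", "B"]))
    assert list(labels) == ["A", "B"]
    assert pop[0, 1] == pytest.approx(np.mean([4.0, 6.0, 2.0, 8.0]))


# ---------------------------------------------------------------------------
# Axis-geography correlation
# ---------------------------------------------------------------------------


def test_axis_scores_equal_longitude_give_rho_one():
    lon = np.array([0.0, 5.0, 10.0, 15.0, 20.0, 25.0])
    s = make_samples(6, locations=[f"L{i}" for i in range(6)], lon=lon, lat=lon * 0 + 45)
    coords = np.column_stack([lon, lon[::-1]])
    out = axis_geography_correlation(coords, s)
    row = out[(out.axis == 1) & (out.geo_variable == "longitude")].iloc[0]
    assert row.spearman_rho == pytest.approx(1.0)


def test_axis_constant_scores_flagged_nan():
    s = make_samples(5, locations=[f"L{i}" for i in range(5)],
                     lon=np.arange(5.0), lat=np.arange(5.0) + 40)
    coords = np.column_stack([np.ones(5), np.arange(5.0)])
    out = axis_geography_correlation(coords, s)
    row = out[(out.axis == 1) & (out.geo_variable == "longitude")].iloc[0]
    assert np.isnan(row.spearman_rho)


def test_axis_correlation_hand_computed_ranks():
    """6 locations with one rank swap: rho = 1 - 6*sum(d^2)/(n(n^2-1))."""
    lon = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
    score = np.array([0.0, 1.0, 3.0, 2.0, 4.0, 5.0])  # swap ranks 3/4
    s = make_samples(6, locations=[f"L{i}" for i in range(6)], lon=lon, lat=lon + 40)
    out = axis_geography_correlation(np.column_stack([score, score]), s)
    row = out[(out.axis == 1) & (out.geo_variable == "longitude")].iloc[0]
    expected = 1 - 6 * 2 / (6 * 35)
    assert row.spearman_rho == pytest.approx(expected)


# ---------------------------------------------------------------------------
# MLH and linear model
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "dosage,expected",
    [(np.ones((1, 10)), 1.0), (np.full((1, 10), 2), 0.0)],
)
def test_mlh_extremes(dosage, expected):
    out = mlh(build_genotypes(dosage.astype(np.int8)))
    assert out.loc[0, "mlh"] == expected


def test_mlh_counts_only_typed_loci():
    dosage = np.array([[1, 1, 1, 0, 0, 0, 0, 2, 2, 2] + [MISSING] * 2])
    out = mlh(build_genotypes(dosage.astype(np.int8)))
    assert out.loc[0, "mlh"] == pytest.approx(0.3)


def test_mlh_invariant_under_flip(rng):
    g = build_genotypes(rng.choice([0, 1, 2, MISSING], size=(10, 50)))
    np.testing.assert_allclose(mlh(g)["mlh"], mlh(g.flip_alleles())["mlh"])


def test_mlh_linear_model_noiseless_recovery(rng):
    n = 80
    lon = rng.uniform(-10, 30, n)
    fh = rng.uniform(0, 0.1, n)
    fr = rng.uniform(0, 0.1, n)
    y = 0.1 + 0.004 * lon  # response exactly linear in longitude alone
    out = mlh_linear_model(y, lon, fh, fr)
    coef = out["coefficients"].set_index("term")["estimate"]
    assert coef["longitude"] == pytest.approx(0.004, abs=1e-8)
    assert out["r2_adj"] == pytest.approx(1.0, abs=1e-6)


def test_mlh_linear_model_recovers_negative_roh_effect(rng):
    n = 200
    lon = rng.uniform(-10, 30, n)
    fh = rng.uniform(0, 0.3, n)
    fr = rng.uniform(0, 0.3, n)
    y = 0.3 + 0.002 * lon + 0.2 * fh - 0.56 * fr + rng.normal(0, 0.01, n)
    out = mlh_linear_model(y, lon, fh, fr)
    coef = out["coefficients"].set_index("term")["estimate"]
    assert coef["f_roh"] < 0
    assert coef["f_hybrid"] > 0
    assert out["f_statistic"] > 10


def test_mlh_linear_model_rejects_collinear_design(rng):
    n = 50
    lon = rng.uniform(0, 1, n)
    with pytest.raises(ValidationError, match="collinear"):
        mlh_linear_model(rng.uniform(0, 1, n), lon, lon, lon)


# ---------------------------------------------------------------------------
# Regional alleles
# ---------------------------------------------------------------------------


def _cline_panel(rng):
    """3 locations; locus 0 engineered region-typical for A; locus 1 common
    everywhere; locus 2 rare everywhere."""
    n_per = 30
    freqs = {
        "A": [0.65, 0.60, 0.05],
        "B": [0.05, 0.60, 0.05],
        "C": [0.02, 0.60, 0.05],
    }
    blocks, locs = [], []
    for loc, f in freqs.items():
        blocks.append(rng.binomial(2, f, size=(n_per, 3)))
        locs += [loc] * n_per
    g = build_genotypes(np.vstack(blocks).astype(np.int8), location_ids=locs)
    return g


def test_select_regional_alleles_rule(rng):
    g = _cline_panel(rng)
    sel = select_regional_alleles(g, g.samples, {"A"})
    # locus 0: panel freq ~0.24 (minor=b), focal freq ~0.65 -> selected
    # locus 1: ~0.60 everywhere -> minor allele is a, focal freq ~0.4 -> not
    # locus 2: rare everywhere -> focal freq ~0.05 -> not
    assert list(sel["locus_id"]) == ["snp0"]
    assert sel.iloc[0]["allele"] == "b"
    assert sel.iloc[0]["focal_freq"] > 0.5


def test_mean_regional_frequency_gradient(rng):
    g = _cline_panel(rng)
    sel = select_regional_alleles(g, g.samples, {"A"})
    freqs = mean_regional_frequency(g, g.samples, sel).set_index("location_id")
    assert freqs.loc["A", "mean_freq"] > 0.5
    # focal region dominates both non-focal regions (whose true freq is ~0.05)
    assert freqs.loc["A", "mean_freq"] > freqs.loc["B", "mean_freq"]
    assert freqs.loc["A", "mean_freq"] > freqs.loc["C", "mean_freq"]


def test_mean_regional_frequency_direct_computation(rng):
    g = _cline_panel(rng)
    sel = select_regional_alleles(g, g.samples, {"A"})
    out = mean_regional_frequency(g, g.samples, sel).set_index("location_id")
    locs = g.samples.table["location_id"].to_numpy()
    sub = g.dosage[locs == "B", 0]
    assert out.loc["B", "mean_freq"] == pytest.approx(sub.mean() / 2.0)


# ---------------------------------------------------------------------------
# Variogram + kriging
# ---------------------------------------------------------------------------


def test_variogram_constant_field_degenerate():
    model = fit_variogram(np.arange(10.0), np.zeros(10), np.full(10, 0.7))
    assert model.degenerate and model.sill == 0.0


def test_variogram_white_noise_nugget(rng):
    x = rng.uniform(0, 100, 150)
    y = rng.uniform(0, 100, 150)
    v = rng.normal(0, 1, 150)
    model = fit_variogram(x, y, v)
    assert model.sill == pytest.approx(np.var(v), rel=0.5)


def test_variogram_parameter_recovery_exponential(rng):
    """Field simulated from a known exponential covariance: sill and range
    recovered within 25%."""
    n = 200
    pts = rng.uniform(0, 100, (n, 2))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    true = VariogramModel("exponential", 0.0, 1.0, 40.0)
    cov = true.sill - true(d)
    L = np.linalg.cholesky(cov + 1e-8 * np.eye(n))
    v = L @ rng.normal(size=n)
    model = fit_variogram(pts[:, 0], pts[:, 1], v)
    assert model.sill == pytest.approx(true.sill, rel=0.4)
    assert model.range_ == pytest.approx(true.range_, rel=0.6)


def test_kriging_exact_interpolation_zero_nugget(rng):
    X = rng.uniform(0, 50, (12, 2))
    y = rng.uniform(0, 1, 12)
    ok = OrdinaryKriging(VariogramModel("spherical", 0.0, 0.2, 30.0)).fit(X, y)
    pred = ok.predict(X)
    np.testing.assert_allclose(pred, y, atol=1e-8)
    np.testing.assert_allclose(ok.last_weights_.sum(axis=1), 1.0, atol=1e-9)


def test_kriging_constant_field_constant_surface(rng):
    X = rng.uniform(0, 50, (8, 2))
    y = np.full(8, 0.4)
    ok = OrdinaryKriging().fit(X, y)
    pred = ok.predict(rng.uniform(0, 50, (20, 2)))
    np.testing.assert_allclose(pred, 0.4, atol=1e-9)


def test_kriging_two_point_weights_match_hand_solution():
    """1-D two-point system solved by hand from the kriging equations."""
    model = VariogramModel("exponential", 0.1, 1.0, 30.0)
    X = np.array([[0.0, 0.0], [10.0, 0.0]])
    y = np.array([1.0, 2.0])
    x0 = np.array([[3.0, 0.0]])
    ok = OrdinaryKriging(model).fit(X, y)
    pred = ok.predict(x0)
    g01 = model(np.array([10.0]))[0]
    g0a = model(np.array([3.0]))[0]
    g0b = model(np.array([7.0]))[0]
    A = np.array([[0.0, g01, 1.0], [g01, 0.0, 1.0], [1.0, 1.0, 0.0]])
    w = np.linalg.solve(A, np.array([g0a, g0b, 1.0]))
    assert pred[0] == pytest.approx(w[0] * 1.0 + w[1] * 2.0, abs=1e-10)
    np.testing.assert_allclose(ok.last_weights_[0], w[:2], atol=1e-10)


def test_kriging_averages_duplicate_points(rng):
    X = np.array([[0.0, 0.0], [0.0, 0.0], [10.0, 0.0], [5.0, 5.0], [2.0, 8.0]])
    y = np.array([1.0, 3.0, 2.0, 1.5, 1.0])
    with pytest.warns(UserWarning, match="duplicate"):
        ok = OrdinaryKriging(VariogramModel("spherical", 0.0, 1.0, 20.0)).fit(X, y)
    pred = ok.predict(np.array([[0.0, 0.0]]))
    assert pred[0] == pytest.approx(2.0, abs=1e-8)  # mean of the duplicates


def test_krige_surface_covers_bounding_box(rng):
    df = pd.DataFrame(
        {
            "location_id": [f"L{i}" for i in range(8)],
            "longitude": rng.uniform(0, 10, 8),
            "latitude": rng.uniform(40, 50, 8),
            "mean_freq": rng.uniform(0.2, 0.8, 8),
            "n_loci": 5,
        }
    )
    surface = krige_surface(df, model=VariogramModel("spherical", 0.01, 0.1, 500.0),
                            grid=GridSpec(step_deg=1.0))
    assert surface["longitude"].min() <= df["longitude"].min()
    assert surface["longitude"].max() >= df["longitude"].max()
    assert surface["latitude"].min() <= df["latitude"].min()
    assert (surface["variance"] >= 0).all()
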