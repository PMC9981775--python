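"""Synthetic-data generator: divergence model, clines, HWE, gene dropping
with pedigree ground truth, benchmark suite determinism."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from boarpop.io import MISSING, ValidationError
from boarpop.qc import QCConfig, filter_call_rate, filter_maf
from boarpop.simulate import (
    GeneticMap,
    Pedigree,
    PopulationModel,
    SuiteConfig,
    apply_cline,
    balding_nichols_freqs,
    gene_drop,
    make_benchmark_suite,
    sample_genotypes,
)


# ---------------------------------------------------------------------------
# Independent pedigree oracle: recursive kinship / path counting
# ---------------------------------------------------------------------------


def kinship(ped):
    """Recursive kinship coefficients phi(i, j) for all pedigree members.
    Inbreeding of an individual = phi(sire, dam)."""
    order = [m.id for m in ped.members]
    parents = {m.id: (m.sire, m.dam) for m in ped.members}
    phi = {}

    def get(a, b):
        key = (a, b) if a <= b else (b, a)
        if key in phi:
            return phi[key]
        ia, ib = order.index(a), order.index(b)
        if ia > ib:  # recurse on the later-born individual
            a, b, ia, ib = b, a, ib, ia
        if a == b:
            sa, da = parents[a]
            val = 0.5 * (1 + (get(sa, da) if sa else 0.0))
        else:
            sb, db = parents[b]
            if sb is None:
                val = 0.0
            else:
                val = 0.5 * (get(a, sb) + get(a, db))
        phi[key] = val
        return val

    return {m.id: (get(*parents[m.id]) if parents[m.id][0] else 0.0) for m in ped.members}


@pytest.mark.parametrize(
    "builder,expected_f",
    [
        (Pedigree.half_sib_offspring, 1 / 8),
        (Pedigree.full_sib_offspring, 1 / 4),
        (Pedigree.full_cousin_offspring, 1 / 16),
        (Pedigree.half_cousin_offspring, 1 / 32),
    ],
)
def test_pedigree_builders_match_path_counting_oracle(builder, expected_f):
    ped = builder()
    assert kinship(ped)[ped.proband] == pytest.approx(expected_f)


# ---------------------------------------------------------------------------
# Balding-Nichols
# ---------------------------------------------------------------------------


def test_bn_fst_zero_copies_ancestral(rng):
    model = PopulationModel(n_populations=2, n_loci=100, fst=0.0)
    freqs = balding_nichols_freqs(model, rng)
    np.testing.assert_array_equal(freqs[0], freqs[1])


def test_bn_variance_matches_beta_moments(rng):
    """At fixed ancestral p = 0.5, Var(freq) across loci ~ F * p * (1-p)."""
    model = PopulationModel(
        n_populations=1, n_loci=10_000, fst=0.2, ancestral_low=0.5, ancestral_high=0.5
    )
    freqs = balding_nichols_freqs(model, rng)[0]
    target = 0.2 * 0.25
    se = np.sqrt(2.0 / 10_000) * target  # rough SE of a variance estimate
    assert freqs.var() == pytest.approx(target, abs=5 * se + 0.003)


def weir_cockerham_fst(dosage, pops):
    """Independent two-population Weir-Cockerham theta estimator (loci
    averaged), written from the standard variance-component formulas."""
    thetas_num, thetas_den = [], []
    r = 2
    for j in range(dosage.shape[1]):
        ns, ps, hs = [], [], []
        for pop in (0, 1):
            d = dosage[pops == pop, j]
            d = d[d != MISSING]
            if len(d) == 0:
                break
            ns.append(len(d))
            ps.append(d.mean() / 2.0)
            hs.append((d == 1).mean())
        else:
            n1, n2 = ns
            nbar = (n1 + n2) / 2
            nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
            pbar = (n1 * ps[0] + n2 * ps[1]) / (r * nbar)
            s2 = (n1 * (ps[0] - pbar) ** 2 + n2 * (ps[1] - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n1 * hs[0] + n2 * hs[1]) / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            thetas_num.append(a)
            thetas_den.append(a + b + c)
    return np.sum(thetas_num) / np.sum(thetas_den)


def test_bn_generated_fst_matches_model(rng):
    model = PopulationModel(n_populations=2, n_loci=5000, fst=0.10)
    freqs = balding_nichols_freqs(model, rng)
    g = sample_genotypes(freqs, 100, GeneticMap.pig_like(2).marker_map(n_loci=5000), rng)
    pops = np.repeat([0, 1], 100)
    theta = weir_cockerham_fst(g.dosage, pops)
    assert theta == pytest.approx(0.10, abs=0.03)


# ---------------------------------------------------------------------------
# Cline
# ---------------------------------------------------------------------------


def test_cline_strength_zero_is_identity(rng):
    model = PopulationModel(
        n_populations=3, n_loci=50, locations=np.array([[0, 0], [1, 0], [2, 0.0]]),
        cline_strength=0.0,
    )
    freqs = balding_nichols_freqs(model, rng)
    np.testing.assert_array_equal(apply_cline(freqs, model), freqs)


def test_cline_differentiation_monotone_in_strength(rng):
    locations = np.array([[0.0, 0.0], [10.0, 0.0]])
    base_model = PopulationModel(n_populations=2, n_loci=2000, fst=0.0,
                                 locations=locations)
    freqs = balding_nichols_freqs(base_model, rng)
    diffs = []
    for strength in (0.0, 0.5, 1.0, 2.0):
        model = PopulationModel(
            n_populations=2, n_loci=2000, fst=0.0, locations=locations,
            cline_strength=strength,
        )
        shifted = apply_cline(freqs, model)
        diffs.append(np.abs(shifted[0] - shifted[1]).mean())
    assert all(b > a for a, b in zip(diffs, diffs[1:]))


# ---------------------------------------------------------------------------
# Genotype sampling
# ---------------------------------------------------------------------------


def test_sample_genotypes_extremes_and_missingness(rng):
    markers = GeneticMap.pig_like(1).marker_map(n_loci=500)
    g0 = sample_genotypes(np.zeros((1, markers.n_loci)), 10, markers, rng)
    assert (g0.dosage == 0).all()
    g = sample_genotypes(
        np.full((1, markers.n_loci), 0.5), 200, markers, rng, missing_rate=0.05
    )
    typed = g.dosage != MISSING
    assert typed.mean() == pytest.approx(0.95, abs=0.01)
    het = (g.dosage == 1)[typed].mean() if typed.any() else 0
    assert (g.dosage[typed] == 1).mean() == pytest.approx(0.5, abs=0.02)


def test_generated_genotypes_satisfy_hwe(rng):
    """Chi-square HWE screen within a population: ~1% of loci flagged at
    alpha = 0.01, never a gross excess."""
    markers = GeneticMap.pig_like(1).marker_map(n_loci=1000)
    freqs = rng.uniform(0.1, 0.9, (1, markers.n_loci))
    g = sample_genotypes(freqs, 300, markers, rng)
    flagged = 0
    for j in range(markers.n_loci):
        d = g.dosage[:, j]
        n = len(d)
        p = d.mean() / 2.0
        exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        obs = np.array([(d == 0).sum(), (d == 1).sum(), (d == 2).sum()])
        if (exp > 0).all():
            chi2 = ((obs - exp) ** 2 / exp).sum()
            if stats.chi2.sf(chi2, 1) < 0.01:
                flagged += 1
    assert flagged / markers.n_loci < 0.03


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------


def test_offspring_of_unrelated_founders_has_zero_autozygosity(rng):
    gmap = GeneticMap.pig_like(4)
    ped = Pedigree(
        [
            type(Pedigree.half_sib_offspring().members[0])("f1", population="wild"),
            type(Pedigree.half_sib_offspring().members[0])("f2", population="wild"),
            type(Pedigree.half_sib_offspring().members[0])("kid", sire="f1", dam="f2"),
        ],
        proband="kid",
    )
    res = gene_drop(ped, gmap, None, rng, n_replicates=20)
    assert (res.truth["ibd_fraction"] == 0.0).all()
    assert len(res.ibd_tracts) == 0


@pytest.mark.parametrize("depth,expected", [(1, 0.5), (2, 0.25), (3, 0.125)])
def test_backcross_ancestry_expectation(rng, depth, expected):
    gmap = GeneticMap.pig_like(18)
    res = gene_drop(Pedigree.backcross(depth), gmap, None, rng, n_replicates=120)
    anc = res.truth["pig_ancestry"]
    se = anc.std() / np.sqrt(len(anc))
    assert anc.mean() == pytest.approx(expected, abs=max(3 * se, 0.01))


def test_full_sib_offspring_ibd_quarter(rng):
    gmap = GeneticMap.pig_like(18)
    res = gene_drop(Pedigree.full_sib_offspring(), gmap, None, rng, n_replicates=200)
    ibd = res.truth["ibd_fraction"]
    se = ibd.std() / np.sqrt(len(ibd))
    assert ibd.mean() == pytest.approx(0.25, abs=3 * se)


def test_gene_drop_ibd_matches_path_counting_over_pedigrees(rng):
    """Mean simulated genome-IBD fraction converges to the pedigree
    inbreeding coefficient from the independent kinship oracle."""
    gmap = GeneticMap.pig_like(18)
    for builder in (Pedigree.half_sib_offspring, Pedigree.full_cousin_offspring):
        ped = builder()
        expected = kinship(ped)[ped.proband]
        res = gene_drop(ped, gmap, None, rng, n_replicates=150)
        ibd = res.truth["ibd_fraction"]
        se = ibd.std() / np.sqrt(len(ibd))
        assert ibd.mean() == pytest.approx(expected, abs=max(3 * se, 0.01))


def test_gene_drop_genotypes_match_truth_alignment(rng):
    """Marker genotypes of an autozygous tract are homozygous."""
    gmap = GeneticMap.pig_like(2)
    markers = gmap.marker_map(spacing_bp=200_000)
    freqs = rng.uniform(0.2, 0.8, markers.n_loci)
    res = gene_drop(
        Pedigree.full_sib_offspring(), gmap, {"wild": freqs}, rng,
        markers=markers, n_replicates=5,
    )
    for row in res.ibd_tracts.itertuples():
        i = list(res.genotypes.samples.sample_ids).index(row.sample_id)
        sel = (
            (res.genotypes.markers.chromosomes == row.chromosome)
            & (res.genotypes.markers.positions >= row.start_bp)
            & (res.genotypes.markers.positions <= row.end_bp)
        )
        dos = res.genotypes.dosage[i, sel]
        assert not np.any(dos == 1)


def test_gene_drop_rejects_disordered_pedigree():
    Individual = type(Pedigree.half_sib_offspring().members[0])
    with pytest.raises(ValidationError, match="precede"):
        Pedigree(
            [Individual("kid", sire="f1", dam="f2"),
             Individual("f1", population="wild"),
             Individual("f2", population="wild")],
            proband="kid",
        )


# ---------------------------------------------------------------------------
# Benchmark suite
# ---------------------------------------------------------------------------

SMALL_SUITE = SuiteConfig(
    n_chromosomes=3,
    marker_spacing_bp=150_000,
    n_wild_populations=6,
    samples_per_population=6,
    n_pigs=10,
    n_hybrids_per_depth=5,
    hybrid_depths=(2, 3),
    n_inbred_per_class=5,
)


def _hash_dir(path):
    out = {}
    for f in sorted(Path(path).iterdir()):
        out[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    return out


def test_benchmark_suite_deterministic_and_truthful(tmp_path):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    make_benchmark_suite(99, d1, SMALL_SUITE)
    make_benchmark_suite(99, d2, SMALL_SUITE)
    assert _hash_dir(d1) == _hash_dir(d2)

    truth = pd.read_csv(d1 / "truth.tsv", sep="\t")
    d3 = truth[truth["cohort"] == "hybrid_depth3"]["pig_ancestry"]
    assert d3.mean() == pytest.approx(0.125, abs=0.06)  # n = 5: loose band
    hs = truth[truth["cohort"] == "inbred_half_sib"]["ibd_fraction"]
    assert hs.mean() == pytest.approx(0.125, abs=0.08)


def test_benchmark_panel_passes_qc_thresholds(tmp_path):
    """Generator calibration: the continental panel retains > 90% of loci
    under the standard call-rate and MAF thresholds."""
    from boarpop.io import read_ped_map

    # default panel size (12 locations x 8 samples); short genome for speed
    cfg_suite = SuiteConfig(
        n_chromosomes=2, marker_spacing_bp=150_000,
        n_pigs=5, n_hybrids_per_depth=2, hybrid_depths=(2,), n_inbred_per_class=2,
    )
    make_benchmark_suite(5, tmp_path, cfg_suite)
    g = read_ped_map(tmp_path / "panel.ped", tmp_path / "panel.map")
    cfg = QCConfig()
    g1, _ = filter_call_rate(g, cfg)
    g2, _ = filter_maf(g1, cfg)
    assert g2.n_loci / g.n_loci > 0.90
    assert g2.n_samples == g.n_samples
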