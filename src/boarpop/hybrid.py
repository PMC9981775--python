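"""PCoA-projection estimate of domestic-pig ancestry (F_hybrid).

The hybrid index follows the projection idea of McVean's PCA/admixture
theory: samples are ordinated by classical principal coordinates of
pairwise Hamming genetic distances together with (i) a domestic-pig
reference pool and (ii) "pure" wild genotypes simulated binomially from
per-cluster wild allele frequencies.  Each focal sample's ordination
position is projected orthogonally onto the axis joining the pure-wild and
pig centroids and rescaled so that the pure centroid maps to 0 and the pig
centroid to 1.  The projected score is taken as the fraction of the genome
of domestic-pig origin; under this construction its expectation is linear
in the true admixture proportion, so first/second/third/fourth-generation
hybrids are expected near 0.5 / 0.25 / 0.125 / 0.0625.

Also implements the complementary diagnostic-allele analysis: alleles rare
in wild boar (MAF < 0.025) but common in pigs (frequency > 0.225), and a
permutation test for their genomic clustering within a sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import MISSING, GenotypeMatrix, MarkerMap, SampleTable, ValidationError
from .qc import allele_frequency

#: F_hybrid class boundaries: below 0.0625 no hybrid call, then expected
#: values for 4th / 3rd / (2nd-or-closer) generation hybrids.
HYBRID_CLASS_BOUNDS = (0.0625, 0.125, 0.250)
HYBRID_CLASS_LABELS = ("none", "gen4", "gen3", "gen2_or_more")


def classify_f_hybrid(f: np.ndarray) -> np.ndarray:
    """Map raw (unclamped) scores to hybrid-generation classes:
    none < 0.0625 <= gen4 < 0.125 <= gen3 <= 0.250 < gen2_or_more."""
    f = np.asarray(f, dtype=float)
    b4, b3, b2 = HYBRID_CLASS_BOUNDS
    return np.select(
        [f < b4, f < b3, f <= b2],
        [HYBRID_CLASS_LABELS[0], HYBRID_CLASS_LABELS[1], HYBRID_CLASS_LABELS[2]],
        default=HYBRID_CLASS_LABELS[3],
    ).astype(object)


# ---------------------------------------------------------------------------
# Pure-genotype simulation
# ---------------------------------------------------------------------------


def simulate_pure_genotypes(
    freq_by_locus: np.ndarray,
    n: int,
    rng: np.random.Generator,
    markers: MarkerMap,
    sample_prefix: str = "pure",
) -> GenotypeMatrix:
    """Simulate unadmixed genotypes: dosage ~ Binomial(2, freq) per locus.

    ``freq_by_locus`` is the frequency of the counted allele in the
    (cluster-specific) wild pool; drawing from it reproduces the wild
    signature under Hardy-Weinberg, which is what the projection needs as
    its zero anchor.
    """
    freq = np.asarray(freq_by_locus, dtype=float)
    if freq.shape != (markers.n_loci,):
        raise ValidationError("freq_by_locus length must match marker count")
    if np.any((freq < 0) | (freq > 1) | ~np.isfinite(freq)):
        raise ValidationError("frequencies must lie in [0, 1]")
    dosage = rng.binomial(2, freq, size=(n, markers.n_loci)).astype(np.int8)
    samples = SampleTable(
        pd.DataFrame(
            {
                "sample_id": [f"{sample_prefix}_{i}" for i in range(n)],
                "group": "simulated_pure",
            }
        )
    )
    return GenotypeMatrix(markers, samples, dosage)


# ---------------------------------------------------------------------------
# Hamming distances
# ---------------------------------------------------------------------------


def hamming_distance_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Pairwise allele-mismatch distance.

    d(i,j) = sum over pairwise-non-missing loci of |dosage_i - dosage_j|,
    normalised by twice the number of such loci, so opposite homozygotes
    contribute 2 and the distance lies in [0, 1].
    """
    if g.n_samples < 2:
        raise ValidationError("need at least two samples")
    dos = g.dosage
    called = (dos != MISSING).astype(np.float64)
    ind = [(dos == k).astype(np.float64) for k in (0, 1, 2)]
    # |di-dj| decomposes over the dosage-class indicator cross-products
    mism1 = ind[0] @ ind[1].T + ind[1] @ ind[0].T + ind[1] @ ind[2].T + ind[2] @ ind[1].T
    mism2 = ind[0] @ ind[2].T + ind[2] @ ind[0].T
    shared = called @ called.T
    if np.any(shared + np.eye(g.n_samples) * 1e9 == 0):
        i, j = np.argwhere(shared == 0)[0]
        ids = g.samples.sample_ids
        raise ValidationError(
            f"samples {ids[i]!r} and {ids[j]!r} share no non-missing locus"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (mism1 + 2.0 * mism2) / (2.0 * shared)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0  # symmetrise away float round-off


# ---------------------------------------------------------------------------
# Principal coordinates
# ---------------------------------------------------------------------------


@dataclass
class PCoAResult:
    """Classical (metric) principal-coordinates ordination."""

    coordinates: np.ndarray          # samples x retained axes
    eigenvalues: np.ndarray          # positive eigenvalues, decreasing
    axis_count: int
    negative_eigenvalue_mass: float  # |sum of negative eigenvalues| / sum |eigenvalues|
    sample_ids: np.ndarray | None = None


def pcoa(d: np.ndarray, max_axes: int | None = None) -> PCoAResult:
    """Classical PCoA: double-centre -0.5 * J D^2 J and eigendecompose.

    Coordinates are eigenvectors scaled by the square root of their
    eigenvalues; axes with non-positive eigenvalues are dropped and their
    absolute eigenvalue mass reported.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValidationError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-12
    pos = eigval > tol
    neg_mass = float(np.abs(eigval[eigval < -tol]).sum())
    total_mass = float(np.abs(eigval).sum())
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    if max_axes is not None:
        coords = coords[:, :max_axes]
    return PCoAResult(
        coordinates=coords,
        eigenvalues=eigval[pos][: coords.shape[1]],
        axis_count=coords.shape[1],
        negative_eigenvalue_mass=neg_mass / total_mass if total_mass > 0 else 0.0,
    )


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------


def _pig_contrast_axes(
    coords: np.ndarray, groups: np.ndarray, max_candidates: int = 10, t_min: float = 6.0
) -> np.ndarray:
    """Ordination axes carrying the pig-vs-wild contrast.

    An axis qualifies when the pig-reference vs observed-wild centroid
    separation is large relative to its standard error.  This rejects both
    wild-structure axes (clines, cluster splits: wild spread inflates the
    SE) and the nuisance axis that can separate the simulated-pure anchor
    from every observed sample.  At least one axis (the best) is always
    returned.
    """
    pig = coords[groups == "pig_reference"]
    wild = coords[groups == "wild"]
    if len(wild) == 0:  # references-only ordination: fall back to pure anchor
        wild = coords[groups == "simulated_pure"]
    if len(pig) < 2 or len(wild) < 2:  # degenerate groups: leading axis
        return np.array([0])
    k = min(max_candidates, coords.shape[1])
    sep = np.abs(pig[:, :k].mean(axis=0) - wild[:, :k].mean(axis=0))
    se = np.sqrt(
        pig[:, :k].var(axis=0, ddof=1) / len(pig)
        + wild[:, :k].var(axis=0, ddof=1) / len(wild)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, sep / se, 0.0)
    chosen = np.flatnonzero(t >= t_min)
    if len(chosen) == 0:
        chosen = np.array([int(np.argmax(t))])
    return chosen


def project_f_hybrid(
    ordination: PCoAResult,
    samples: SampleTable,
    axes_used: int | str = "auto",
    clamp: bool = False,
) -> pd.DataFrame:
    """Project ordination positions onto the pure-wild -> pig polar axis.

    The axis runs from the centroid of the ``simulated_pure`` samples to the
    centroid of the ``pig_reference`` samples; scores are affinely rescaled
    so the pure centroid maps to 0 and the pig centroid to 1.  With
    ``axes_used='auto'`` (default) the projection uses the ordination axes
    on which the pig pool separates from the observed wild samples; an
    integer selects the leading ``axes_used`` axes instead.  Scores are not
    clamped by default (over/undershoot is informative); classes use the
    raw score.
    """
    groups = samples.groups
    if ordination.coordinates.shape[0] != samples.n_samples:
        raise ValidationError("ordination and sample table sizes differ")
    if axes_used == "auto":
        axes = _pig_contrast_axes(ordination.coordinates, groups)
    else:
        axes = np.arange(min(int(axes_used), ordination.coordinates.shape[1]))
    coords = ordination.coordinates[:, axes]
    pure = coords[groups == "simulated_pure"]
    pig = coords[groups == "pig_reference"]
    if len(pure) == 0 or len(pig) == 0:
        raise ValidationError("need both simulated_pure and pig_reference samples")
    c_pure, c_pig = pure.mean(axis=0), pig.mean(axis=0)
    axis = c_pig - c_pure
    norm2 = float(axis @ axis)
    if norm2 < 1e-20:
        raise ValidationError("pure and pig centroids coincide; no polar axis")
    f = (coords - c_pure) @ axis / norm2
    if clamp:
        f = np.clip(f, 0.0, 1.0)
    return pd.DataFrame(
        {
            "sample_id": samples.sample_ids,
            "group": groups,
            "f_hybrid": f,
            "hybrid_class": classify_f_hybrid(f),
        }
    )


class HybridIndexEstimator(BaseEstimator):
    """Full hybrid-index stage as a transductive estimator.

    ``fit`` takes a genotype matrix containing wild samples and a
    ``pig_reference`` pool; it estimates wild allele frequencies per
    genetic cluster (``cluster_id`` in the sample table; one pooled cluster
    if absent), simulates ``n_pure`` pure wild genotypes per cluster,
    builds the Hamming distance matrix and PCoA, and projects every sample
    on the pure->pig axis.

    Fitted attributes: ``results_`` (per input sample: f_hybrid and class),
    ``ordination_``, ``distance_``, ``combined_samples_``.
    """

    def __init__(self, n_axes: int | str = "auto", n_pure: int = 20, clamp: bool = False,
                 random_state: int | None = None):
        self.n_axes = n_axes
        self.n_pure = n_pure
        self.clamp = clamp
        self.random_state = random_state

    def fit(self, g: GenotypeMatrix) -> "HybridIndexEstimator":
        rng = np.random.default_rng(self.random_state)
        groups = g.samples.groups
        wild_idx = np.flatnonzero(groups == "wild")
        if len(wild_idx) == 0 or not np.any(groups == "pig_reference"):
            raise ValidationError("fit requires wild and pig_reference samples")

        clusters = g.samples.table["cluster_id"].to_numpy()
        wild_clusters = pd.unique(clusters[wild_idx])
        pure_blocks = []
        for ci, cl in enumerate(wild_clusters):
            idx = wild_idx[clusters[wild_idx] == cl]
            freqs = np.nan_to_num(allele_frequency(g, idx), nan=0.0)
            pure_blocks.append(
                simulate_pure_genotypes(
                    freqs, self.n_pure, rng, g.markers, sample_prefix=f"pure_c{ci}"
                )
            )
        dosage = np.vstack([g.dosage] + [b.dosage for b in pure_blocks])
        sample_tab = pd.concat(
            [g.samples.table] + [b.samples.table for b in pure_blocks], ignore_index=True
        )
        combined = GenotypeMatrix(g.markers, SampleTable(sample_tab), dosage)

        self.distance_ = hamming_distance_matrix(combined)
        self.ordination_ = pcoa(self.distance_)
        self.ordination_.sample_ids = combined.samples.sample_ids
        self.combined_samples_ = combined.samples
        all_results = project_f_hybrid(
            self.ordination_, combined.samples, axes_used=self.n_axes, clamp=self.clamp
        )
        self.results_ = all_results.iloc[: g.n_samples].reset_index(drop=True)
        self.pure_results_ = all_results.iloc[g.n_samples :].reset_index(drop=True)
        return self

    def fit_predict(self, g: GenotypeMatrix) -> np.ndarray:
        """F_hybrid scores for the input samples (wild + references)."""
        self.fit(g)
        return self.results_["f_hybrid"].to_numpy()


# ---------------------------------------------------------------------------
# Diagnostic alleles
# ---------------------------------------------------------------------------


def diagnostic_alleles(
    wild: GenotypeMatrix,
    pigs: GenotypeMatrix,
    wild_max_freq: float = 0.025,
    pig_min_freq: float = 0.225,
) -> pd.DataFrame:
    """Loci carrying an allele rare in wild boar but common in pigs.

    At each shared locus the candidate allele is the one with wild-pool
    frequency below ``wild_max_freq``; the locus is diagnostic iff that
    same allele's pig-pool frequency exceeds ``pig_min_freq``.

    Returns columns: locus_id, diagnostic_allele ('a' or 'b', i.e. which
    map allele), wild_freq, pig_freq.
    """
    if not np.array_equal(wild.markers.locus_ids, pigs.markers.locus_ids):
        shared = set(wild.markers.locus_ids) & set(pigs.markers.locus_ids)
        if not shared:
            raise ValidationError("wild and pig panels share no loci")
        order = [l for l in wild.markers.locus_ids if l in shared]
        wild = wild.select_loci_by_id(order)
        pigs = pigs.select_loci_by_id(order)
    pw = allele_frequency(wild)   # counted-allele freq in wild
    pp = allele_frequency(pigs)
    rows = []
    for j, locus in enumerate(wild.markers.locus_ids):
        if np.isnan(pw[j]) or np.isnan(pp[j]):
            continue
        if pw[j] < wild_max_freq:
            which, wfreq, pfreq = "b", pw[j], pp[j]
        elif 1.0 - pw[j] < wild_max_freq:
            which, wfreq, pfreq = "a", 1.0 - pw[j], 1.0 - pp[j]
        else:
            continue
        if pfreq > pig_min_freq:
            rows.append((locus, which, float(wfreq), float(pfreq)))
    return pd.DataFrame(rows, columns=["locus_id", "diagnostic_allele", "wild_freq", "pig_freq"])


def _carries(dosage: np.ndarray, which: np.ndarray) -> np.ndarray:
    """Whether a sample carries >= 1 copy of the diagnostic allele."""
    carry_b = dosage >= 1
    carry_a = (dosage <= 1) & (dosage != MISSING)
    return np.where(which == "b", carry_b, carry_a) & (dosage != MISSING)


def _max_window_count(positions: np.ndarray, chroms: np.ndarray, carried: np.ndarray,
                      window_bp: int) -> int:
    """Max number of carried diagnostic loci in any window of window_bp."""
    best = 0
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        pos = positions[sel]
        car = carried[sel]
        order = np.argsort(pos)
        pos, car = pos[order], car[order]
        csum = np.concatenate([[0], np.cumsum(car)])
        right = np.searchsorted(pos, pos + window_bp, side="left")
        counts = csum[right] - csum[np.arange(len(pos))]
        if len(counts):
            best = max(best, int(counts.max()))
    return best


def diagnostic_allele_profile(
    sample_dosage: np.ndarray,
    das: pd.DataFrame,
    markers: MarkerMap,
    window_mb: float = 10.0,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Carrier load and genomic clustering of diagnostic alleles in one sample.

    carrier_fraction: share of typed diagnostic loci where the sample
    carries the diagnostic allele.  cluster_score: maximum carried count in
    any ``window_mb`` sliding window.  The p-value permutes which
    diagnostic loci are carried (carrier count fixed), with add-one
    correction; it tests spatial arrangement, not load.
    """
    if len(das) == 0:
        raise ValidationError("empty diagnostic allele set")
    if n_perm < 100:
        warnings.warn("n_perm < 100: clustering p-value will be coarse", stacklevel=2)
    rng = rng or np.random.default_rng()
    lookup = {l: i for i, l in enumerate(markers.locus_ids)}
    idx = np.array([lookup[l] for l in das["locus_id"]], dtype=np.intp)
    dos = np.asarray(sample_dosage)[idx]
    which = das["diagnostic_allele"].to_numpy()
    typed = dos != MISSING
    carried = _carries(dos, which) & typed
    n_typed = int(typed.sum())
    carrier_fraction = float(carried.sum() / n_typed) if n_typed else float("nan")

    positions = markers.positions[idx][typed]
    chroms = markers.chromosomes[idx][typed]
    car = carried[typed]
    window_bp = int(window_mb * 1e6)
    obs = _max_window_count(positions, chroms, car, window_bp)

    k = int(car.sum())
    exceed = 0
    perm = np.zeros(len(car), dtype=bool)
    for _ in range(n_perm):
        perm[:] = False
        perm[rng.choice(len(car), size=k, replace=False)] = True
        if _max_window_count(positions, chroms, perm, window_bp) >= obs:
            exceed += 1
    p_value = (1 + exceed) / (1 + n_perm)
    return {
        "carrier_fraction": carrier_fraction,
        "cluster_score": obs,
        "p_value": float(p_value),
        "n_carried": k,
        "n_typed": n_typed,
    }
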