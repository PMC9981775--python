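"""Quality control for SNP-array genotype panels.

Implements the standard beadchip QC chain: call-rate filters (loci before
samples), minor-allele-frequency filter, windowed LD pruning
(indep-pairwise semantics: 50-SNP window, 5-SNP step, r-squared ceiling),
method-of-moments identity-by-descent relatedness with iterative removal of
related individuals, and exclusion of intragenic SNPs.

Defaults follow the thresholds used for PorcineSNP60 wild-boar panels:
call rates above 0.95, MAF above 0.025, relatedness estimated within
sampling location on SNPs with MAF > 0.10, and a pi-hat cutoff of 0.183.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GeneIntervalSet, GenotypeMatrix, ValidationError


@dataclass
class QCConfig:
    min_sample_call_rate: float = 0.95
    min_locus_call_rate: float = 0.95
    min_maf: float = 0.025
    ld_window_snps: int = 50
    ld_step_snps: int = 5
    ld_r2_max: float = 0.5       # relaxed (ROH panel); 0.2 for structure panel
    relatedness_maf_min: float = 0.10
    relatedness_max: float = 0.183
    exclude_intragenic: bool = True

    def __post_init__(self) -> None:
        for name in (
            "min_sample_call_rate",
            "min_locus_call_rate",
            "min_maf",
            "ld_r2_max",
            "relatedness_maf_min",
            "relatedness_max",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if not (self.ld_window_snps > self.ld_step_snps >= 1):
            raise ValidationError("need ld_window_snps > ld_step_snps >= 1")


class QCError(ValueError):
    """Raised when a QC step would produce an unusable dataset."""


def _removal_log(entities, kind: str, reason: str, stats) -> pd.DataFrame:
    entities = list(entities)
    if np.isscalar(stats) or stats is None:
        stats = [stats] * len(entities)
    return pd.DataFrame(
        {"entity": entities, "kind": kind, "reason": reason, "statistic": list(stats)}
    )


# ---------------------------------------------------------------------------
# Call rate and MAF
# ---------------------------------------------------------------------------


def filter_call_rate(
    g: GenotypeMatrix, cfg: QCConfig
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove loci, then samples, below their call-rate thresholds."""
    locus_cr = g.locus_call_rate()
    keep_loci = locus_cr >= cfg.min_locus_call_rate
    log = _removal_log(
        g.markers.locus_ids[~keep_loci], "locus", "call_rate", locus_cr[~keep_loci]
    )
    g = g.subset_loci(keep_loci)

    sample_cr = g.sample_call_rate()
    keep_samples = sample_cr >= cfg.min_sample_call_rate
    log = pd.concat(
        [
            log,
            _removal_log(
                g.samples.sample_ids[~keep_samples],
                "sample",
                "call_rate",
                sample_cr[~keep_samples],
            ),
        ],
        ignore_index=True,
    )
    if not bool(keep_samples.any()):
        raise QCError("call-rate filter removed every sample")
    return g.subset_samples(keep_samples), log


def allele_frequency(
    g: GenotypeMatrix, sample_idx: np.ndarray | None = None
) -> np.ndarray:
    """Frequency of the counted allele (allele_b) per locus, ignoring
    missing calls.  NaN where a locus has no non-missing genotype."""
    dos = g.dosage if sample_idx is None else g.dosage[np.asarray(sample_idx)]
    if dos.shape[0] == 0:
        raise QCError("empty sample subset for allele frequency")
    called = dos != MISSING
    n_called = called.sum(axis=0)
    total = np.where(called, dos, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, total / (2.0 * n_called), np.nan)
    return p


def minor_allele_frequency(
    g: GenotypeMatrix, sample_idx: np.ndarray | None = None
) -> np.ndarray:
    """Folded MAF = min(p, 1-p); invariant to allele orientation.
    NaN flags loci with no called genotype in the subset."""
    p = allele_frequency(g, sample_idx)
    return np.minimum(p, 1.0 - p)


def filter_maf(g: GenotypeMatrix, cfg: QCConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Keep loci with MAF above the threshold (and at least one call)."""
    maf = minor_allele_frequency(g)
    keep = np.nan_to_num(maf, nan=-1.0) > cfg.min_maf
    log = _removal_log(g.markers.locus_ids[~keep], "locus", "maf", maf[~keep])
    return g.subset_loci(keep), log


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _pairwise_r2(dos: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns, pairwise-complete
    over non-missing entries."""
    m = dos != MISSING
    x = np.where(m, dos, 0).astype(float)
    mf = m.astype(float)
    n = mf.T @ mf
    sx = x.T @ mf
    sxy = x.T @ x
    sxx = (x * x).T @ mf
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        var_i = sxx - sx**2 / n
        denom = var_i * var_i.T
        r2 = np.where(denom > 0, cov**2 / denom, 0.0)
    r2 = np.nan_to_num(r2, nan=0.0)
    np.fill_diagonal(r2, 1.0)
    return r2


def ld_prune(g: GenotypeMatrix, cfg: QCConfig) -> np.ndarray:
    """Greedy windowed LD pruning; returns retained locus ids.

    Within each sliding window (per chromosome), while any retained pair
    exceeds the r-squared ceiling, the pair with the largest r-squared is
    resolved by dropping the member with the lower MAF (ties: the later map
    position).  Deterministic for a given input order.
    """
    if cfg.ld_window_snps < 2:
        raise QCError("LD window must cover at least 2 SNPs")
    g = g.sort_loci()
    maf = np.nan_to_num(minor_allele_frequency(g), nan=0.0)
    pos = g.markers.positions
    removed = np.zeros(g.n_loci, dtype=bool)

    for _, cols in g.markers.chromosome_slices().items():
        n = len(cols)
        starts = range(0, max(n - 1, 1), cfg.ld_step_snps)
        for s in starts:
            win = cols[s : s + cfg.ld_window_snps]
            active = win[~removed[win]]
            if len(active) < 2:
                continue
            r2 = _pairwise_r2(g.dosage[:, active])
            np.fill_diagonal(r2, 0.0)
            while True:
                i, j = np.unravel_index(np.argmax(r2), r2.shape)
                if r2[i, j] <= cfg.ld_r2_max:
                    break
                gi, gj = active[i], active[j]
                # drop the lower-MAF member; ties -> later map position
                if (maf[gi], -pos[gi]) <= (maf[gj], -pos[gj]):
                    drop_local, drop_global = i, gi
                else:
                    drop_local, drop_global = j, gj
                removed[drop_global] = True
                r2[drop_local, :] = 0.0
                r2[:, drop_local] = 0.0
    return g.markers.locus_ids[~removed]


# ---------------------------------------------------------------------------
# Relatedness (identity by descent)
# ---------------------------------------------------------------------------


def _ibd_for_pairs(
    dos: np.ndarray, freqs: np.ndarray, pairs: list[tuple[int, int]]
) -> list[tuple[int, int, float]]:
    """PLINK-style method-of-moments pi-hat for the given index pairs.

    IBS counts over pairwise non-missing loci are equated to their
    expectations under IBD state 0/1/2 given the sample allele
    frequencies; negative state estimates are truncated to zero and the
    vector renormalised.  pi-hat = P(IBD=2) + P(IBD=1)/2, clamped to [0,1].
    """
    p = freqs
    q = 1.0 - p
    # per-locus IBS-class probabilities conditional on IBD state
    e0_ibs0 = 2.0 * p**2 * q**2
    e0_ibs1 = 4.0 * p**3 * q + 4.0 * p * q**3
    e1_ibs1 = 2.0 * p**2 * q + 2.0 * p * q**2
    e0_ibs2 = p**4 + q**4 + 4.0 * p**2 * q**2
    e1_ibs2 = p**3 + q**3 + p**2 * q + p * q**2

    out = []
    miss = dos == MISSING
    for i, j in pairs:
        shared = ~(miss[i] | miss[j])
        L = int(shared.sum())
        if L == 0:
            out.append((i, j, np.nan))
            continue
        di, dj = dos[i, shared], dos[j, shared]
        diff = np.abs(di - dj)
        n_ibs0 = int((diff == 2).sum())
        n_ibs1 = int((diff == 1).sum())
        n_ibs2 = L - n_ibs0 - n_ibs1
        s0_0, s0_1, s0_2 = e0_ibs0[shared].sum(), e0_ibs1[shared].sum(), e0_ibs2[shared].sum()
        s1_1, s1_2 = e1_ibs1[shared].sum(), e1_ibs2[shared].sum()
        p0 = n_ibs0 / s0_0 if s0_0 > 0 else 0.0
        p1 = (n_ibs1 - p0 * s0_1) / s1_1 if s1_1 > 0 else 0.0
        p2 = (n_ibs2 - p0 * s0_2 - p1 * s1_2) / L
        probs = np.clip([p0, p1, p2], 0.0, None)
        total = probs.sum()
        if total > 0:
            probs = probs / total
        pihat = float(np.clip(probs[2] + 0.5 * probs[1], 0.0, 1.0))
        out.append((i, j, pihat))
    return out


def estimate_ibd(
    g: GenotypeMatrix, cfg: QCConfig, scope: str = "location"
) -> pd.DataFrame:
    """Pairwise pi-hat relatedness.

    With ``scope='location'`` (default) pairs are formed within each
    sampling location and allele frequencies are estimated from that
    location's samples, on loci with within-scope MAF above
    ``relatedness_maf_min``.  ``scope='all'`` uses every pair and
    panel-wide frequencies.

    Returns a DataFrame (sample_i, sample_j, location_id, ibd_score).
    """
    ids = g.samples.sample_ids
    if scope == "all":
        groups = {"": np.arange(g.n_samples)}
    elif scope == "location":
        loc = g.samples.table["location_id"].to_numpy()
        groups = {l: np.flatnonzero(loc == l) for l in pd.unique(loc)}
    else:
        raise ValueError(f"unknown scope {scope!r}")

    rows = []
    for loc_id, idx in groups.items():
        if len(idx) < 2:
            continue
        p = allele_frequency(g, idx)
        maf = np.minimum(p, 1.0 - p)
        informative = np.nan_to_num(maf, nan=-1.0) > cfg.relatedness_maf_min
        if informative.sum() < 100:
            warnings.warn(
                f"location {loc_id!r}: only {int(informative.sum())} loci with "
                f"MAF > {cfg.relatedness_maf_min}; IBD estimates unstable",
                stacklevel=2,
            )
        dos = g.dosage[np.ix_(idx, np.flatnonzero(informative))]
        freqs = p[informative]
        pairs = [(a, b) for a in range(len(idx)) for b in range(a + 1, len(idx))]
        for a, b, pihat in _ibd_for_pairs(dos, freqs, pairs):
            rows.append((ids[idx[a]], ids[idx[b]], loc_id, pihat))
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "location_id", "ibd_score"])


def drop_related(
    g: GenotypeMatrix, scores: pd.DataFrame, cfg: QCConfig
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Iteratively remove the individual participating in the most pairs at
    or above the relatedness cutoff until no such pair remains.

    Ties are broken by lower call rate, then sample-id order.
    """
    ids = list(g.samples.sample_ids)
    call_rate = dict(zip(ids, g.sample_call_rate()))
    hot = scores[scores["ibd_score"] >= cfg.relatedness_max]
    edges = {(str(r.sample_i), str(r.sample_j)) for r in hot.itertuples()}
    removed: list[tuple[str, float]] = []
    while edges:
        degree: dict[str, int] = {}
        for a, b in edges:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        worst = min(degree, key=lambda s: (-degree[s], call_rate.get(s, 1.0), s))
        removed.append((worst, degree[worst]))
        edges = {e for e in edges if worst not in e}
    removed_ids = {s for s, _ in removed}
    keep = np.array([s not in removed_ids for s in ids])
    log = _removal_log(
        [s for s, _ in removed], "sample", "relatedness", [d for _, d in removed]
    )
    return g.subset_samples(keep), log


# ---------------------------------------------------------------------------
# Intragenic exclusion
# ---------------------------------------------------------------------------


def exclude_intragenic(g: GenotypeMatrix, genes: GeneIntervalSet) -> np.ndarray:
    """Locus ids outside every gene interval.  Errors if the interval set is
    non-empty yet shares no chromosome name with the marker map."""
    if len(genes) == 0:
        return g.markers.locus_ids.copy()
    marker_chroms = set(map(str, pd.unique(g.markers.chromosomes)))
    if not marker_chroms & genes.chromosomes:
        raise QCError(
            "no chromosome shared between marker map and gene intervals "
            "(naming convention clash?)"
        )
    inside = np.zeros(g.n_loci, dtype=bool)
    for chrom, cols in g.markers.chromosome_slices().items():
        inside[cols] = genes.contains(chrom, g.markers.positions[cols])
    return g.markers.locus_ids[~inside]


# ---------------------------------------------------------------------------
# sklearn-style QC chain
# ---------------------------------------------------------------------------


class QCPipeline:
    """Full QC chain as a transform-style estimator.

    Order: locus call rate -> sample call rate -> MAF -> intragenic
    exclusion (optional) -> LD pruning -> within-location relatedness
    removal.  ``fit_transform`` returns the filtered matrix; removal logs
    and the relatedness table are exposed as fitted attributes.
    """

    def __init__(
        self,
        config: QCConfig | None = None,
        gene_intervals: GeneIntervalSet | None = None,
        relatedness_scope: str = "location",
    ):
        self.config = config
        self.gene_intervals = gene_intervals
        self.relatedness_scope = relatedness_scope

    # minimal get/set_params so the class composes with sklearn utilities
    def get_params(self, deep: bool = True) -> dict:
        return {
            "config": self.config,
            "gene_intervals": self.gene_intervals,
            "relatedness_scope": self.relatedness_scope,
        }

    def set_params(self, **params) -> "QCPipeline":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit_transform(self, g: GenotypeMatrix) -> GenotypeMatrix:
        cfg = self.config or QCConfig()
        logs = []
        g1, log = filter_call_rate(g, cfg)
        logs.append(log)
        g2, log = filter_maf(g1, cfg)
        logs.append(log)
        if cfg.exclude_intragenic and self.gene_intervals is not None and len(self.gene_intervals):
            keep_ids = exclude_intragenic(g2, self.gene_intervals)
            dropped = set(g2.markers.locus_ids) - set(keep_ids)
            logs.append(_removal_log(sorted(dropped), "locus", "intragenic", np.nan))
            g2 = g2.select_loci_by_id(keep_ids)
        retained = ld_prune(g2, cfg)
        dropped = set(g2.markers.locus_ids) - set(retained)
        logs.append(_removal_log(sorted(dropped), "locus", "ld_prune", np.nan))
        g3 = g2.select_loci_by_id(retained).sort_loci()
        self.relatedness_ = estimate_ibd(g3, cfg, scope=self.relatedness_scope)
        g4, log = drop_related(g3, self.relatedness_, cfg)
        logs.append(log)
        self.removal_log_ = pd.concat(logs, ignore_index=True)
        self.n_samples_, self.n_loci_ = g4.n_samples, g4.n_loci
        return g4

    def fit(self, g: GenotypeMatrix) -> "QCPipeline":
        self.fit_transform(g)
        return self
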