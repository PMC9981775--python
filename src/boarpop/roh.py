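"""Runs of homozygosity and the genomic inbreeding coefficient F_ROH.

Detection mirrors the PLINK ``--homozyg`` sliding-window semantics: a
70-SNP window passes if it contains no heterozygote (and a bounded number
of missing calls); a SNP joins a candidate run when the proportion of
passing windows covering it reaches the hit threshold; candidate runs are
trimmed to homozygous end-SNPs, split at large inter-SNP gaps and filtered
by physical length, SNP count and marker density.  With the default >5 Mb
length cutoff a detected run indicates a common ancestor roughly within
the last ten generations, so F_ROH(>5Mb) — the summed run length divided
by the scanned genome — estimates recent autozygosity: expected values are
0.125, 0.0625 and 0.03125 for offspring of half siblings, full cousins and
half cousins.

The F_ROH denominator is the total length of *scanned regions*: the parts
of the marker map dense enough that a qualifying run could be detected at
all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import MISSING, GeneIntervalSet, GenotypeMatrix, MarkerMap, ValidationError

#: F_ROH class boundaries; expected autozygosity of offspring of
#: half cousins / full cousins / half siblings.
INBRED_CLASS_BOUNDS = (0.03125, 0.0625, 0.125)
INBRED_CLASS_LABELS = ("<0.03125", "0.03125-0.0625", "0.0625-0.125", ">0.125")


@dataclass
class ROHConfig:
    window_snps: int = 70
    window_max_het: int = 0
    window_max_missing: int = 5
    window_hit_threshold: float = 0.05
    min_length_bp: int = 5_000_000
    min_snps: int = 50
    min_density_bp_per_snp: int = 150_000
    max_gap_bp: int = 500_000

    def __post_init__(self) -> None:
        if min(self.window_snps, self.window_max_het, self.window_max_missing,
               self.min_snps) < 0 or self.min_length_bp <= 0:
            raise ValidationError("invalid ROH configuration")


def classify_f_roh(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    idx = np.searchsorted(np.array(INBRED_CLASS_BOUNDS), f, side="right")
    return np.array(INBRED_CLASS_LABELS, dtype=object)[idx]


# ---------------------------------------------------------------------------
# Scanned regions (the F_ROH denominator)
# ---------------------------------------------------------------------------


def scanned_regions(m: MarkerMap, cfg: ROHConfig) -> tuple[GeneIntervalSet, int]:
    """Marker-map regions where a qualifying run is detectable in principle.

    Per chromosome, markers are split at gaps above ``max_gap_bp``; within
    each dense stretch the union of spans of all marker intervals [i..j]
    satisfying the segment criteria (length >= min_length_bp, count >=
    min_snps, mean density <= min_density_bp_per_snp) is reported.
    Intervals are returned in BED convention; the total is in bp.
    """
    order = m.sort_order()
    chroms = m.chromosomes[order]
    positions = m.positions[order]
    rows: list[tuple[str, int, int]] = []
    total = 0
    for chrom in pd.unique(chroms):
        pos = positions[chroms == chrom]
        gaps = np.diff(pos)
        breaks = np.flatnonzero(gaps > cfg.max_gap_bp)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for s, e in zip(starts, ends):
            sub = pos[s : e + 1]
            merged: list[list[int]] = []
            for i in range(len(sub)):
                span = sub[i:] - sub[i] + 1
                count = np.arange(1, len(span) + 1)
                ok = (
                    (span >= cfg.min_length_bp)
                    & (count >= cfg.min_snps)
                    & (span <= cfg.min_density_bp_per_snp * count)
                )
                if not ok.any():
                    continue
                j = int(np.flatnonzero(ok)[-1])
                lo, hi = int(sub[i]), int(sub[i] + span[j] - 1)
                if merged and lo <= merged[-1][1] + 1:
                    merged[-1][1] = max(merged[-1][1], hi)
                else:
                    merged.append([lo, hi])
            for lo, hi in merged:
                rows.append((str(chrom), lo - 1, hi))  # 1-based inclusive -> BED
                total += hi - lo + 1
    regions = GeneIntervalSet(pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp"]))
    return regions, total


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def _moving_sum(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0], np.cumsum(x)])
    return c[w:] - c[:-w]


def _candidate_runs(flag: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] index runs of True."""
    if not flag.any():
        return []
    padded = np.concatenate([[False], flag, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts, ends))


def detect_roh(g: GenotypeMatrix, cfg: ROHConfig | None = None) -> pd.DataFrame:
    """Detect ROH segments for every sample.

    Returns a DataFrame (sample_id, chromosome, start_bp, end_bp, n_snps,
    length_bp) where length_bp = end_bp - start_bp + 1; segment boundaries
    are the outermost homozygous SNP positions.
    """
    cfg = cfg or ROHConfig()
    g = g.sort_loci()
    w = cfg.window_snps
    chrom_slices = g.markers.chromosome_slices()
    skipped = [c for c, cols in chrom_slices.items() if len(cols) < w]
    if skipped:
        warnings.warn(
            f"chromosomes with fewer than {w} markers skipped: {skipped}", stacklevel=2
        )
    rows = []
    for chrom, cols in chrom_slices.items():
        n = len(cols)
        if n < w:
            continue
        pos = g.markers.positions[cols]
        dos_chrom = g.dosage[:, cols]
        for si, sid in enumerate(g.samples.sample_ids):
            dos = dos_chrom[si]
            het = (dos == 1).astype(np.int64)
            mis = (dos == MISSING).astype(np.int64)
            win_ok = (_moving_sum(het, w) <= cfg.window_max_het) & (
                _moving_sum(mis, w) <= cfg.window_max_missing
            )
            # per-SNP: passing windows covering / windows covering
            win_ok_f = win_ok.astype(np.float64)
            cum = np.concatenate([[0.0], np.cumsum(win_ok_f)])
            k = np.arange(n)
            lo = np.maximum(k - w + 1, 0)
            hi = np.minimum(k, n - w)
            covering = hi - lo + 1
            hits = cum[hi + 1] - cum[lo]
            prop = hits / covering
            candidate = prop >= cfg.window_hit_threshold
            hom = (dos != 1) & (dos != MISSING)
            for a, b in _candidate_runs(candidate):
                # trim to homozygous end-SNPs
                idxs = np.arange(a, b + 1)
                hom_in = hom[idxs]
                if not hom_in.any():
                    continue
                a2 = idxs[hom_in][0]
                b2 = idxs[hom_in][-1]
                # split at oversized gaps, then filter
                seg_pos = pos[a2 : b2 + 1]
                gap_breaks = np.flatnonzero(np.diff(seg_pos) > cfg.max_gap_bp)
                seg_starts = np.concatenate([[a2], a2 + gap_breaks + 1])
                seg_ends = np.concatenate([a2 + gap_breaks, [b2]])
                for s0, e0 in zip(seg_starts, seg_ends):
                    # re-trim split pieces to homozygous ends
                    piece = np.arange(s0, e0 + 1)
                    hp = hom[piece]
                    if not hp.any():
                        continue
                    s1, e1 = piece[hp][0], piece[hp][-1]
                    length = int(pos[e1] - pos[s1] + 1)
                    n_snps = int(e1 - s1 + 1)
                    if length < cfg.min_length_bp or n_snps < cfg.min_snps:
                        continue
                    if length > cfg.min_density_bp_per_snp * n_snps:
                        continue
                    rows.append((sid, str(chrom), int(pos[s1]), int(pos[e1]), n_snps, length))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chromosome", "start_bp", "end_bp", "n_snps", "length_bp"],
    )


# ---------------------------------------------------------------------------
# F_ROH
# ---------------------------------------------------------------------------


def f_roh(
    segments: pd.DataFrame,
    scanned_total_bp: int,
    sample_ids: np.ndarray,
    min_length_bp: int | None = None,
) -> pd.DataFrame:
    """Per-sample F_ROH = summed segment length / scanned genome length.

    Segments shorter than ``min_length_bp`` (if given) are excluded first;
    raising the cutoff can only lower F_ROH.
    """
    if scanned_total_bp <= 0:
        raise ValidationError("scanned_total_bp must be positive")
    segs = segments
    if min_length_bp is not None:
        segs = segs[segs["length_bp"] >= min_length_bp]
    sums = segs.groupby("sample_id")["length_bp"].sum()
    f = np.array([sums.get(s, 0) / scanned_total_bp for s in sample_ids], dtype=float)
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "f_roh": f,
            "scanned_genome_bp": scanned_total_bp,
            "inbred_class": classify_f_roh(f),
        }
    )


class ROHDetector(BaseEstimator):
    """ROH stage as an estimator: ``fit`` detects segments and computes
    per-sample F_ROH over the scanned genome.

    Fitted attributes: ``segments_``, ``scanned_regions_``, ``scanned_bp_``,
    ``f_roh_``.
    """

    def __init__(
        self,
        window_snps: int = 70,
        window_max_het: int = 0,
        window_max_missing: int = 5,
        window_hit_threshold: float = 0.05,
        min_length_bp: int = 5_000_000,
        min_snps: int = 50,
        min_density_bp_per_snp: int = 150_000,
        max_gap_bp: int = 500_000,
    ):
        self.window_snps = window_snps
        self.window_max_het = window_max_het
        self.window_max_missing = window_max_missing
        self.window_hit_threshold = window_hit_threshold
        self.min_length_bp = min_length_bp
        self.min_snps = min_snps
        self.min_density_bp_per_snp = min_density_bp_per_snp
        self.max_gap_bp = max_gap_bp

    def _config(self) -> ROHConfig:
        return ROHConfig(
            window_snps=self.window_snps,
            window_max_het=self.window_max_het,
            window_max_missing=self.window_max_missing,
            window_hit_threshold=self.window_hit_threshold,
            min_length_bp=self.min_length_bp,
            min_snps=self.min_snps,
            min_density_bp_per_snp=self.min_density_bp_per_snp,
            max_gap_bp=self.max_gap_bp,
        )

    def fit(self, g: GenotypeMatrix) -> "ROHDetector":
        cfg = self._config()
        self.scanned_regions_, self.scanned_bp_ = scanned_regions(g.markers, cfg)
        self.segments_ = detect_roh(g, cfg)
        self.f_roh_ = f_roh(self.segments_, self.scanned_bp_, g.samples.sample_ids)
        return self

    def fit_predict(self, g: GenotypeMatrix) -> np.ndarray:
        self.fit(g)
        return self.f_roh_["f_roh"].to_numpy()
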