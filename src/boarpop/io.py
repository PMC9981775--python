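"""Genotype data model and text-format I/O.

The shared in-memory container is :class:`GenotypeMatrix`: an
``individuals x loci`` dosage matrix coding each biallelic genotype as the
number of copies (0/1/2) of the *counted* allele (``allele_b`` in the
marker map), with a reserved sentinel for missing calls.  Genotypes are read
and written as PLINK PED/MAP text, sample metadata as CSV, and gene
intervals as BED3.

Coordinate conventions: marker positions are 1-based base pairs; BED
intervals are kept native (0-based, half-open) and converted only at the
membership boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel dosage for a missing genotype call.  All operations treat it
#: explicitly; it never silently participates in arithmetic.
MISSING: int = -1

#: Sample group labels understood by the pipeline.
SAMPLE_GROUPS = ("wild", "pig_reference", "simulated_pure", "synthetic")

_VALID_ALLELES = frozenset("ACGT12")


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


class MarkerMap:
    """Per-locus chromosome, position and allele labels.

    Parameters
    ----------
    table
        DataFrame with columns ``locus_id``, ``chromosome``, ``position_bp``,
        ``allele_a``, ``allele_b``.  ``allele_b`` is the allele whose copies
        the dosage matrix counts.
    """

    REQUIRED = ("locus_id", "chromosome", "position_bp", "allele_a", "allele_b")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValidationError(f"marker map missing columns: {missing}")
        table = table.reset_index(drop=True).copy()
        table["locus_id"] = table["locus_id"].astype(str)
        table["chromosome"] = table["chromosome"].astype(str)
        table["position_bp"] = table["position_bp"].astype(np.int64)
        if table["locus_id"].duplicated().any():
            dups = table.loc[table["locus_id"].duplicated(), "locus_id"].tolist()
            raise ValidationError(f"duplicate locus ids: {dups[:5]}")
        same = table["allele_a"].astype(str) == table["allele_b"].astype(str)
        if bool(same.any()):
            raise ValidationError("allele_a equals allele_b at some loci")
        for chrom, grp in table.groupby("chromosome", sort=False):
            pos = grp["position_bp"].to_numpy()
            srt = np.sort(pos)
            if np.any(np.diff(srt) == 0):
                raise ValidationError(
                    f"duplicate positions on chromosome {chrom}"
                )
        self.table = table

    @property
    def n_loci(self) -> int:
        return len(self.table)

    @property
    def locus_ids(self) -> np.ndarray:
        return self.table["locus_id"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.table["position_bp"].to_numpy()

    def is_sorted(self) -> bool:
        order = self.sort_order()
        return bool(np.array_equal(order, np.arange(self.n_loci)))

    def sort_order(self) -> np.ndarray:
        """Stable order sorting by chromosome (file order of first
        appearance) then position."""
        chroms = self.table["chromosome"]
        first_seen = {c: i for i, c in enumerate(pd.unique(chroms))}
        key = chroms.map(first_seen).to_numpy()
        return np.lexsort((self.table["position_bp"].to_numpy(), key))

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.table.iloc[np.asarray(idx)])

    def chromosome_slices(self) -> dict[str, np.ndarray]:
        """Column indices per chromosome, in map order."""
        out: dict[str, np.ndarray] = {}
        for chrom in pd.unique(self.table["chromosome"]):
            out[str(chrom)] = np.flatnonzero(
                (self.table["chromosome"] == chrom).to_numpy()
            )
        return out

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_loci


class SampleTable:
    """Sample ids, group labels and (optional) geographic metadata."""

    def __init__(self, table: pd.DataFrame):
        if "sample_id" not in table.columns or "group" not in table.columns:
            raise ValidationError("sample table requires sample_id and group")
        table = table.reset_index(drop=True).copy()
        table["sample_id"] = table["sample_id"].astype(str)
        if table["sample_id"].duplicated().any():
            dups = table.loc[table["sample_id"].duplicated(), "sample_id"]
            raise ValidationError(f"duplicate sample ids: {dups.tolist()[:5]}")
        bad = ~table["group"].astype(str).isin(SAMPLE_GROUPS)
        if bool(bad.any()):
            raise ValidationError(
                f"unknown group labels: {sorted(set(table.loc[bad, 'group']))}"
            )
        for col, lo, hi in (("latitude", -90.0, 90.0), ("longitude", -180.0, 180.0)):
            if col in table.columns:
                vals = pd.to_numeric(table[col], errors="coerce")
                out_of_range = vals.notna() & ((vals < lo) | (vals > hi))
                if bool(out_of_range.any()):
                    raise ValidationError(f"{col} outside [{lo}, {hi}]")
                table[col] = vals
            else:
                table[col] = np.nan
        if "location_id" not in table.columns:
            table["location_id"] = ""
        table["location_id"] = table["location_id"].fillna("").astype(str)
        if "cluster_id" not in table.columns:
            table["cluster_id"] = ""
        table["cluster_id"] = table["cluster_id"].fillna("").astype(str)
        self.table = table

    @property
    def n_samples(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.table["sample_id"].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self.table["group"].to_numpy()

    def subset(self, idx: np.ndarray) -> "SampleTable":
        return SampleTable(self.table.iloc[np.asarray(idx)])

    def index_of(self, sample_ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[str(s)] for s in sample_ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample id {exc}") from exc

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_samples


@dataclass
class GenotypeMatrix:
    """Dosage matrix bound to its marker map and sample table."""

    markers: MarkerMap
    samples: SampleTable
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (self.samples.n_samples, self.markers.n_loci):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{self.samples.n_samples} samples x {self.markers.n_loci} loci"
            )
        valid = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not bool(valid.all()):
            raise ValidationError("dosage entries must be 0/1/2 or missing")

    # -- shape ----------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.samples.n_samples

    @property
    def n_loci(self) -> int:
        return self.markers.n_loci

    # -- masks and rates -------------------------------------------------
    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def sample_call_rate(self) -> np.ndarray:
        if self.n_loci == 0:
            return np.ones(self.n_samples)
        return 1.0 - self.missing_mask().mean(axis=1)

    def locus_call_rate(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.ones(self.n_loci)
        return 1.0 - self.missing_mask().mean(axis=0)

    # -- subsetting ------------------------------------------------------
    def subset_samples(self, idx) -> "GenotypeMatrix":
        idx = self._as_index(idx, self.n_samples)
        return GenotypeMatrix(self.markers, self.samples.subset(idx), self.dosage[idx])

    def subset_loci(self, idx) -> "GenotypeMatrix":
        idx = self._as_index(idx, self.n_loci)
        return GenotypeMatrix(self.markers.subset(idx), self.samples, self.dosage[:, idx])

    def select_samples_by_id(self, sample_ids: Iterable[str]) -> "GenotypeMatrix":
        return self.subset_samples(self.samples.index_of(sample_ids))

    def select_loci_by_id(self, locus_ids: Iterable[str]) -> "GenotypeMatrix":
        lookup = {l: i for i, l in enumerate(self.markers.locus_ids)}
        return self.subset_loci(np.array([lookup[str(l)] for l in locus_ids], dtype=np.intp))

    def sort_loci(self) -> "GenotypeMatrix":
        return self.subset_loci(self.markers.sort_order())

    @staticmethod
    def _as_index(idx, n: int) -> np.ndarray:
        idx = np.asarray(idx)
        if idx.dtype == bool:
            if idx.shape != (n,):
                raise ValidationError("boolean index has wrong length")
            idx = np.flatnonzero(idx)
        return idx.astype(np.intp)

    # -- allele orientation ---------------------------------------------
    def flip_alleles(self, loci_idx: np.ndarray | None = None) -> "GenotypeMatrix":
        """Swap counted/other allele at the given loci; dosage d -> 2 - d,
        missing fixed.  Flipping twice is the identity."""
        if loci_idx is None:
            loci_idx = np.arange(self.n_loci)
        loci_idx = np.asarray(loci_idx, dtype=np.intp)
        dosage = self.dosage.copy()
        block = dosage[:, loci_idx]
        observed = block != MISSING
        block[observed] = 2 - block[observed]
        dosage[:, loci_idx] = block
        tab = self.markers.table.copy()
        a = tab.loc[loci_idx, "allele_a"].copy()
        tab.loc[loci_idx, "allele_a"] = tab.loc[loci_idx, "allele_b"]
        tab.loc[loci_idx, "allele_b"] = a
        return GenotypeMatrix(MarkerMap(tab), self.samples, dosage)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            MarkerMap(self.markers.table), SampleTable(self.samples.table), self.dosage.copy()
        )


@dataclass
class GeneIntervalSet:
    """Genomic intervals in BED convention (0-based, half-open).

    Membership of 1-based marker positions is tested against the union of
    intervals; overlaps are retained as given.
    """

    intervals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chromosome", "start_bp", "end_bp"])
    )

    def __post_init__(self) -> None:
        df = self.intervals.reset_index(drop=True).copy()
        if len(df):
            df["chromosome"] = df["chromosome"].astype(str)
            df["start_bp"] = df["start_bp"].astype(np.int64)
            df["end_bp"] = df["end_bp"].astype(np.int64)
            if bool((df["start_bp"] >= df["end_bp"]).any()):
                raise ValidationError("interval start_bp must be < end_bp")
        self.intervals = df
        # merged, per-chromosome interval bounds for fast membership
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, grp in df.groupby("chromosome", sort=False) if len(df) else []:
            ivals = grp.sort_values("start_bp")[["start_bp", "end_bp"]].to_numpy()
            starts, ends = [], []
            for s, e in ivals:
                if ends and s <= ends[-1]:
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            self._merged[str(chrom)] = (np.array(starts), np.array(ends))

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def chromosomes(self) -> set[str]:
        return set(self._merged)

    def contains(self, chromosome: str, positions_1based: np.ndarray) -> np.ndarray:
        """Vectorised membership of 1-based positions in the interval union."""
        positions_1based = np.asarray(positions_1based, dtype=np.int64)
        if str(chromosome) not in self._merged:
            return np.zeros(positions_1based.shape, dtype=bool)
        starts, ends = self._merged[str(chromosome)]
        pos0 = positions_1based - 1  # to BED coordinates
        k = np.searchsorted(starts, pos0, side="right") - 1
        inside = k >= 0
        inside[inside] = pos0[inside] < ends[k[inside]]
        return inside


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------


def read_ped_map(
    ped_path: str | Path,
    map_path: str | Path,
    *,
    reference_alleles: dict[str, str] | None = None,
    permissive: bool = False,
) -> GenotypeMatrix:
    """Read PLINK text PED/MAP into a :class:`GenotypeMatrix`.

    The counted allele (``allele_b``) at each locus is the
    lexicographically-second observed allele, unless `reference_alleles`
    maps the locus id to an explicit counted allele.  ``0 0`` allele pairs
    become missing.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, locus_id, _cm, pos = parts
            map_rows.append((locus_id, chrom, int(pos)))
    n_loci = len(map_rows)

    sample_rows = []
    allele_pairs: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_loci:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_loci} columns, got {len(parts)}"
                )
            sample_rows.append(parts[1])
            alleles = np.array(parts[6:], dtype="U8")
            if not permissive:
                bad = ~np.isin(alleles, list(_VALID_ALLELES | {"0"}))
                if bool(bad.any()):
                    sym = sorted(set(alleles[bad]))
                    raise ParseError(
                        f"{ped_path}:{lineno}: unexpected allele symbols {sym[:5]} "
                        "(set permissive=True to accept)"
                    )
            allele_pairs.append(alleles)

    n_samples = len(sample_rows)
    a1 = (
        np.stack(allele_pairs)[:, 0::2]
        if n_samples
        else np.empty((0, n_loci), dtype="U8")
    )
    a2 = np.stack(allele_pairs)[:, 1::2] if n_samples else a1.copy()

    dosage = np.full((n_samples, n_loci), MISSING, dtype=np.int8)
    allele_a_col, allele_b_col = [], []
    reference_alleles = reference_alleles or {}
    for j, (locus_id, _chrom, _pos) in enumerate(map_rows):
        col1, col2 = a1[:, j], a2[:, j]
        called = (col1 != "0") & (col2 != "0")
        half_called = (col1 != "0") != (col2 != "0")
        if bool(half_called.any()):
            raise ParseError(f"locus {locus_id}: half-missing genotype (one allele '0')")
        observed = sorted(set(col1[called]) | set(col2[called]))
        if locus_id in reference_alleles:
            allele_b = str(reference_alleles[locus_id])
            others = [x for x in observed if x != allele_b]
            allele_a = others[0] if others else "N"
        elif len(observed) >= 2:
            if len(observed) > 2:
                raise ParseError(f"locus {locus_id}: more than two alleles {observed}")
            allele_a, allele_b = observed[0], observed[1]
        elif len(observed) == 1:
            allele_a, allele_b = "N", observed[0]
        else:  # fully missing locus
            allele_a, allele_b = "N", "M"
        allele_a_col.append(allele_a)
        allele_b_col.append(allele_b)
        dosage[called, j] = (col1[called] == allele_b).astype(np.int8) + (
            col2[called] == allele_b
        ).astype(np.int8)

    markers = MarkerMap(
        pd.DataFrame(
            {
                "locus_id": [r[0] for r in map_rows],
                "chromosome": [r[1] for r in map_rows],
                "position_bp": [r[2] for r in map_rows],
                "allele_a": allele_a_col,
                "allele_b": allele_b_col,
            }
        )
    )
    samples = SampleTable(pd.DataFrame({"sample_id": sample_rows, "group": "wild"}))
    return GenotypeMatrix(markers, samples, dosage)


def write_ped_map(g: GenotypeMatrix, ped_path: str | Path, map_path: str | Path) -> None:
    """Write PED/MAP text re-readable by :func:`read_ped_map` with identical
    dosage, marker order and missingness."""
    tab = g.markers.table
    with open(map_path, "w") as fh:
        for _, row in tab.iterrows():
            fh.write(f"{row.chromosome}\t{row.locus_id}\t0\t{row.position_bp}\n")

    allele_a = tab["allele_a"].to_numpy(dtype="U8")
    allele_b = tab["allele_b"].to_numpy(dtype="U8")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(g.samples.sample_ids):
            dos = g.dosage[i]
            first = np.where(dos >= 1, allele_b, allele_a)
            second = np.where(dos == 2, allele_b, allele_a)
            first = np.where(dos == MISSING, "0", first)
            second = np.where(dos == MISSING, "0", second)
            fields = np.empty(2 * g.n_loci, dtype="U8")
            fields[0::2] = first
            fields[1::2] = second
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\t" + "\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Metadata and intervals
# ---------------------------------------------------------------------------


def read_sample_metadata(
    csv_path: str | Path, genotype_sample_ids: Sequence[str] | None = None
) -> SampleTable:
    """Read the sample metadata CSV (sample_id, group, location_id,
    longitude, latitude, cluster_id).  When genotype ids are supplied,
    warn about metadata rows that match no genotyped sample."""
    df = pd.read_csv(csv_path, dtype={"sample_id": str})
    table = SampleTable(df)
    if genotype_sample_ids is not None:
        known = set(map(str, genotype_sample_ids))
        unmatched = [s for s in table.sample_ids if s not in known]
        if unmatched:
            warnings.warn(
                f"{len(unmatched)} metadata ids match no genotyped sample: {unmatched}",
                stacklevel=2,
            )
    return table


def attach_metadata(g: GenotypeMatrix, meta: SampleTable) -> GenotypeMatrix:
    """Replace the genotype matrix's sample table with metadata rows matched
    by sample id (genotype order preserved)."""
    meta_df = meta.table.set_index("sample_id")
    missing = [s for s in g.samples.sample_ids if s not in meta_df.index]
    if missing:
        raise ValidationError(f"metadata missing for samples: {missing[:5]}")
    aligned = meta_df.loc[list(g.samples.sample_ids)].reset_index()
    return GenotypeMatrix(g.markers, SampleTable(aligned), g.dosage)


def read_gene_intervals(bed_path: str | Path) -> GeneIntervalSet:
    """Read a BED3+ file of gene intervals (0-based half-open, kept native)."""
    rows = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith(("#", "track", "browser")):
                continue
            if len(parts) < 3:
                raise ParseError(f"{bed_path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValidationError(f"{bed_path}:{lineno}: start >= end")
            rows.append((chrom, start, end))
    return GeneIntervalSet(pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp"]))
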