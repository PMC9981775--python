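"""Synthetic genotype data with the structure the analysis assumes.

The generator emulates, at desk scale, the statistical features of a
continental SNP-array panel: multiple populations diverged under the
Balding-Nichols model, a spatial allele-frequency cline across populations
placed on a geographic grid (producing isolation by distance), a domestic
pig reference pool, pig x wild hybrid pedigrees of known backcross depth,
and inbred pedigrees (half-sib, full-cousin and half-cousin matings) whose
offspring carry long autozygous tracts.  Gene dropping transmits founder
haplotypes down a pedigree with Haldane (no-interference) recombination
and records, besides the marker genotypes, the *true* pig-ancestry
fraction and the true identity-by-descent tracts of each simulated
individual — the ground truth the estimators are scored against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import (
    MISSING,
    GenotypeMatrix,
    MarkerMap,
    SampleTable,
    ValidationError,
    write_ped_map,
)

# ---------------------------------------------------------------------------
# Genome model
# ---------------------------------------------------------------------------

#: Pig-like autosome lengths (Mb), 18 autosomes totalling ~2.26 Gb.
_PIG_AUTOSOME_MB = (274, 151, 132, 130, 104, 170, 121, 138, 139, 69, 79, 61,
                    208, 141, 140, 79, 63, 55)


@dataclass
class GeneticMap:
    """Chromosome names, physical lengths and genetic lengths.

    The default emulates the 18 pig autosomes at 1 cM/Mb (about 2.3 Gb and
    23 Morgans in total).
    """

    chromosomes: list[tuple[str, int, float]]  # (name, length_bp, length_morgans)

    def __post_init__(self) -> None:
        if any(l <= 0 or m <= 0 for _, l, m in self.chromosomes):
            raise ValidationError("chromosome lengths must be positive")

    @classmethod
    def pig_like(cls, n_chromosomes: int = 18, cm_per_mb: float = 1.0) -> "GeneticMap":
        mb = _PIG_AUTOSOME_MB[:n_chromosomes]
        return cls(
            [(f"chr{i + 1}", int(m * 1e6), m * 1e6 * cm_per_mb / 1e8) for i, m in enumerate(mb)]
        )

    @property
    def total_bp(self) -> int:
        return sum(l for _, l, _ in self.chromosomes)

    @property
    def total_morgans(self) -> float:
        return sum(m for _, _, m in self.chromosomes)

    def marker_map(self, spacing_bp: int | None = None, n_loci: int | None = None) -> MarkerMap:
        """Evenly spaced biallelic markers (default 1 per 100 kb)."""
        if spacing_bp is None and n_loci is None:
            spacing_bp = 100_000
        if spacing_bp is None:
            spacing_bp = max(self.total_bp // int(n_loci), 1)
        rows = []
        for name, length, _ in self.chromosomes:
            positions = np.arange(spacing_bp // 2, length, spacing_bp, dtype=np.int64)
            for pos in positions:
                rows.append((f"{name}_{pos}", name, int(pos)))
        df = pd.DataFrame(rows, columns=["locus_id", "chromosome", "position_bp"])
        df["allele_a"] = "A"
        df["allele_b"] = "G"
        return MarkerMap(df)


# ---------------------------------------------------------------------------
# Population model
# ---------------------------------------------------------------------------


@dataclass
class PopulationModel:
    """Diverged populations on a geographic grid, optionally with a cline."""

    n_populations: int
    n_loci: int
    fst: float | np.ndarray = 0.05
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    locations: np.ndarray | None = None          # (n_pops, 2) lon/lat
    cline_direction: tuple[float, float] = (1.0, 0.0)
    cline_strength: float = 0.0

    def __post_init__(self) -> None:
        fst = np.broadcast_to(np.asarray(self.fst, float), (self.n_populations,))
        if np.any((fst < 0) | (fst >= 1)):
            raise ValidationError("fst must lie in [0, 1)")
        self.fst = fst
        if self.n_loci < 1:
            raise ValidationError("n_loci must be >= 1")
        if self.locations is not None:
            self.locations = np.asarray(self.locations, float)


def balding_nichols_freqs(model: PopulationModel, rng: np.random.Generator) -> np.ndarray:
    """Per-population, per-locus frequencies under the Balding-Nichols model.

    Ancestral p ~ Uniform(low, high); each population draws
    Beta(p (1-F)/F, (1-p)(1-F)/F), whose variance is F p (1-p).  F = 0
    copies the ancestral frequency exactly.
    """
    p = rng.uniform(model.ancestral_low, model.ancestral_high, size=model.n_loci)
    out = np.empty((model.n_populations, model.n_loci))
    for k in range(model.n_populations):
        F = float(model.fst[k])
        if F == 0.0:
            out[k] = p
        else:
            a = p * (1.0 - F) / F
            b = (1.0 - p) * (1.0 - F) / F
            out[k] = rng.beta(a, b)
    return out


def apply_cline(freqs: np.ndarray, model: PopulationModel) -> np.ndarray:
    """Shift population frequencies along a geographic cline.

    Each population's location is projected on the cline direction; the
    centred, rescaled projection shifts every locus on the logit scale by
    ``strength`` times the projection.  The shift sign alternates with
    locus parity so the spatial signal does not move all frequencies the
    same way.  Strength 0 returns the input unchanged.
    """
    if model.cline_strength == 0.0:
        return freqs
    if model.locations is None:
        raise ValidationError("cline requires population locations")
    u = np.asarray(model.cline_direction, float)
    u = u / np.linalg.norm(u)
    z = model.locations @ u
    z = z - z.mean()
    span = np.abs(z).max()
    if span > 0:
        z = z / span  # in [-1, 1]
    eps = 1e-6
    f = np.clip(freqs, eps, 1 - eps)
    sign = np.where(np.arange(freqs.shape[1]) % 2 == 0, 1.0, -1.0)
    shifted = expit(logit(f) + model.cline_strength * z[:, None] * sign[None, :])
    return shifted


def sample_genotypes(
    freqs: np.ndarray,
    n_per_pop: int | list[int],
    markers: MarkerMap,
    rng: np.random.Generator,
    missing_rate: float = 0.0,
    pop_names: list[str] | None = None,
    locations: np.ndarray | None = None,
    group: str = "wild",
    cluster_ids: list[str] | None = None,
    id_prefix: str = "ind",
) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes: dosage ~ Binomial(2, freq), then missingness."""
    freqs = np.atleast_2d(np.asarray(freqs, float))
    n_pops, n_loci = freqs.shape
    if n_loci != markers.n_loci:
        raise ValidationError("frequency matrix does not match marker count")
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValidationError("frequencies must lie in [0, 1]")
    counts = [n_per_pop] * n_pops if np.isscalar(n_per_pop) else list(n_per_pop)
    pop_names = pop_names or [f"pop{k}" for k in range(n_pops)]
    blocks, meta = [], []
    for k in range(n_pops):
        dos = rng.binomial(2, freqs[k], size=(counts[k], n_loci)).astype(np.int8)
        if missing_rate > 0:
            dos[rng.random(dos.shape) < missing_rate] = MISSING
        blocks.append(dos)
        for i in range(counts[k]):
            lon, lat = (
                (float(locations[k][0]), float(locations[k][1]))
                if locations is not None
                else (np.nan, np.nan)
            )
            meta.append(
                (
                    f"{id_prefix}_{pop_names[k]}_{i}",
                    group,
                    pop_names[k],
                    lon,
                    lat,
                    cluster_ids[k] if cluster_ids else "",
                )
            )
    samples = SampleTable(
        pd.DataFrame(
            meta,
            columns=["sample_id", "group", "location_id", "longitude", "latitude", "cluster_id"],
        )
    )
    return GenotypeMatrix(markers, samples, np.vstack(blocks))


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------


@dataclass
class Individual:
    id: str
    sire: str | None = None
    dam: str | None = None
    population: str | None = None  # founders only

    @property
    def is_founder(self) -> bool:
        return self.sire is None and self.dam is None


@dataclass
class Pedigree:
    """Ordered pedigree; parents must precede offspring.  ``proband`` is the
    individual whose genotype/ancestry the simulation reports by default."""

    members: list[Individual]
    proband: str

    def __post_init__(self) -> None:
        seen: set[str] = set()
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate pedigree ids")
        for m in self.members:
            if m.is_founder:
                if m.population is None:
                    raise ValidationError(f"founder {m.id} needs a population")
            else:
                if m.sire not in seen or m.dam not in seen:
                    raise ValidationError(
                        f"{m.id}: parents must precede offspring (cycle or ordering error)"
                    )
            seen.add(m.id)
        if self.proband not in seen:
            raise ValidationError("proband not in pedigree")

    # -- builders -------------------------------------------------------
    @classmethod
    def backcross(cls, depth: int, wild_population: str = "wild",
                  pig_population: str = "pig") -> "Pedigree":
        """Hybrid of generation ``depth``: an F1 (depth 1) backcrossed to
        wild ``depth - 1`` times; expected pig ancestry 2**-depth."""
        if depth < 1:
            raise ValidationError("depth must be >= 1")
        members = [
            Individual("pig0", population=pig_population),
            Individual("wild1", population=wild_population),
            Individual("hyb1", sire="pig0", dam="wild1"),
        ]
        for g in range(2, depth + 1):
            members.append(Individual(f"wild{g}", population=wild_population))
            members.append(Individual(f"hyb{g}", sire=f"hyb{g - 1}", dam=f"wild{g}"))
        return cls(members, proband=f"hyb{depth}")

    @classmethod
    def half_sib_offspring(cls, population: str = "wild") -> "Pedigree":
        """Offspring of half siblings: expected F = 1/8."""
        p = population
        return cls(
            [
                Individual("sire", population=p),
                Individual("dam1", population=p),
                Individual("dam2", population=p),
                Individual("hs1", sire="sire", dam="dam1"),
                Individual("hs2", sire="sire", dam="dam2"),
                Individual("proband", sire="hs1", dam="hs2"),
            ],
            proband="proband",
        )

    @classmethod
    def full_sib_offspring(cls, population: str = "wild") -> "Pedigree":
        """Offspring of full siblings: expected F = 1/4."""
        p = population
        return cls(
            [
                Individual("sire", population=p),
                Individual("dam", population=p),
                Individual("fs1", sire="sire", dam="dam"),
                Individual("fs2", sire="sire", dam="dam"),
                Individual("proband", sire="fs1", dam="fs2"),
            ],
            proband="proband",
        )

    @classmethod
    def full_cousin_offspring(cls, population: str = "wild") -> "Pedigree":
        """Offspring of full first cousins: expected F = 1/16."""
        p = population
        return cls(
            [
                Individual("g1", population=p),
                Individual("g2", population=p),
                Individual("u1", population=p),
                Individual("u2", population=p),
                Individual("s1", sire="g1", dam="g2"),
                Individual("s2", sire="g1", dam="g2"),
                Individual("c1", sire="s1", dam="u1"),
                Individual("c2", sire="s2", dam="u2"),
                Individual("proband", sire="c1", dam="c2"),
            ],
            proband="proband",
        )

    @classmethod
    def half_cousin_offspring(cls, population: str = "wild") -> "Pedigree":
        """Offspring of half first cousins: expected F = 1/32."""
        p = population
        return cls(
            [
                Individual("g", population=p),
                Individual("a", population=p),
                Individual("b", population=p),
                Individual("u1", population=p),
                Individual("u2", population=p),
                Individual("p1", sire="g", dam="a"),
                Individual("p2", sire="g", dam="b"),
                Individual("c1", sire="p1", dam="u1"),
                Individual("c2", sire="p2", dam="u2"),
                Individual("proband", sire="c1", dam="c2"),
            ],
            proband="proband",
        )


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

# A haplotype along one chromosome is piecewise constant in the founder-hap
# label: (breaks, ids) with breaks[0] == 0; segment i spans
# [breaks[i], breaks[i+1]) (bp), the last one ending at chromosome length.
_Hap = tuple[np.ndarray, np.ndarray]


def _meiosis_chrom(
    hap_a: _Hap, hap_b: _Hap, length_bp: int, morgans: float, rng: np.random.Generator
) -> _Hap:
    """One gamete: Poisson(morgans) crossovers, positions uniform (Haldane)."""
    k = int(rng.poisson(morgans))
    xovers = np.sort(rng.uniform(0.0, length_bp, size=k))
    phase = int(rng.integers(2))
    bounds = np.concatenate([[0.0], xovers, [float(length_bp)]])
    out_breaks: list[float] = []
    out_ids: list[int] = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e <= s:
            continue
        bks, ids = (hap_a, hap_b)[phase]
        i0 = int(np.searchsorted(bks, s, side="right") - 1)
        i1 = int(np.searchsorted(bks, e, side="left"))
        for i in range(i0, i1):
            seg_start = max(float(bks[i]), s)
            if out_ids and out_ids[-1] == int(ids[i]):
                continue  # merge with previous segment
            out_breaks.append(seg_start)
            out_ids.append(int(ids[i]))
        phase ^= 1
    return np.array(out_breaks), np.array(out_ids, dtype=np.int64)


def _hap_fraction(hap: _Hap, length_bp: int, target_ids: set[int]) -> float:
    breaks, ids = hap
    ends = np.concatenate([breaks[1:], [float(length_bp)]])
    mask = np.isin(ids, list(target_ids)) if target_ids else np.zeros(len(ids), bool)
    return float(np.sum((ends - breaks)[mask]))


def _ibd_tracts_chrom(hap_a: _Hap, hap_b: _Hap, length_bp: int) -> list[tuple[float, float]]:
    """Intervals where both haplotypes carry the same founder-hap label."""
    all_breaks = np.unique(np.concatenate([hap_a[0], hap_b[0], [0.0]]))
    ends = np.concatenate([all_breaks[1:], [float(length_bp)]])
    ia = np.searchsorted(hap_a[0], all_breaks, side="right") - 1
    ib = np.searchsorted(hap_b[0], all_breaks, side="right") - 1
    same = hap_a[1][ia] == hap_b[1][ib]
    tracts: list[tuple[float, float]] = []
    for s, e, eq in zip(all_breaks, ends, same):
        if not eq or e <= s:
            continue
        if tracts and tracts[-1][1] == s:
            tracts[-1] = (tracts[-1][0], e)
        else:
            tracts.append((float(s), float(e)))
    return tracts


@dataclass
class GeneDropResult:
    genotypes: GenotypeMatrix | None
    truth: pd.DataFrame       # sample_id, replicate, pig_ancestry, ibd_fraction
    ibd_tracts: pd.DataFrame  # sample_id, chromosome, start_bp, end_bp


def gene_drop(
    ped: Pedigree,
    gmap: GeneticMap,
    founder_freqs: dict[str, np.ndarray] | None,
    rng: np.random.Generator,
    markers: MarkerMap | None = None,
    n_replicates: int = 1,
    pig_population: str = "pig",
    group: str = "synthetic",
    id_prefix: str = "gd",
) -> GeneDropResult:
    """Drop founder haplotypes down the pedigree ``n_replicates`` times.

    Founders are redrawn each replicate.  When ``markers`` is given (its
    chromosome names must match the genetic map), founder haplotype
    alleles are drawn Bernoulli(freq) from ``founder_freqs[population]``
    and the proband's marker genotypes are emitted alongside the truth
    table (true pig-ancestry fraction of the genome, true autozygous
    fraction, and the autozygous tract list).
    """
    chrom_names = [c[0] for c in gmap.chromosomes]
    if markers is not None:
        unknown = set(map(str, pd.unique(markers.chromosomes))) - set(chrom_names)
        if unknown:
            raise ValidationError(f"marker chromosomes not in genetic map: {unknown}")
        if founder_freqs is None:
            raise ValidationError("founder_freqs required when markers are given")
        for pop, f in founder_freqs.items():
            if np.asarray(f).shape != (markers.n_loci,):
                raise ValidationError(f"founder_freqs[{pop!r}] length mismatch")
        marker_cols = {
            c: np.flatnonzero(markers.chromosomes == c) for c in chrom_names
        }

    total_bp = gmap.total_bp
    truth_rows = []
    tract_rows = []
    dosages = []
    sample_ids = []

    for rep in range(n_replicates):
        haps: dict[str, list[_Hap]] = {}
        hap_pop: dict[int, str] = {}
        next_hap = 0
        founder_hap_rows: dict[int, int] = {}
        founder_allele_blocks: list[np.ndarray] = []

        for m in ped.members:
            if m.is_founder:
                h1, h2 = next_hap, next_hap + 1
                next_hap += 2
                hap_pop[h1] = hap_pop[h2] = m.population
                # two single-segment haplotypes per chromosome
                haps[m.id] = [
                    [(np.array([0.0]), np.array([h1], dtype=np.int64)) for _ in chrom_names],
                    [(np.array([0.0]), np.array([h2], dtype=np.int64)) for _ in chrom_names],
                ]
                if markers is not None:
                    freq = np.asarray(founder_freqs[m.population], float)
                    for h in (h1, h2):
                        founder_hap_rows[h] = len(founder_allele_blocks)
                        founder_allele_blocks.append(
                            (rng.random(markers.n_loci) < freq).astype(np.int8)
                        )
            else:
                gametes = []
                for parent in (m.sire, m.dam):
                    pa, pb = haps[parent]
                    gametes.append(
                        [
                            _meiosis_chrom(pa[ci], pb[ci], length, morg, rng)
                            for ci, (_, length, morg) in enumerate(gmap.chromosomes)
                        ]
                    )
                haps[m.id] = gametes

        pig_haps = {h for h, pop in hap_pop.items() if pop == pig_population}
        hap_a, hap_b = haps[ped.proband]
        pig_bp = sum(
            _hap_fraction(hap_a[ci], length, pig_haps)
            + _hap_fraction(hap_b[ci], length, pig_haps)
            for ci, (_, length, _) in enumerate(gmap.chromosomes)
        )
        ibd_bp = 0.0
        sid = f"{id_prefix}_{rep}"
        for ci, (cname, length, _) in enumerate(gmap.chromosomes):
            for s, e in _ibd_tracts_chrom(hap_a[ci], hap_b[ci], length):
                ibd_bp += e - s
                tract_rows.append((sid, cname, int(round(s)), int(round(e))))
        truth_rows.append((sid, rep, pig_bp / (2.0 * total_bp), ibd_bp / total_bp))
        sample_ids.append(sid)

        if markers is not None:
            allele_mat = np.vstack(founder_allele_blocks)
            dos = np.empty(markers.n_loci, dtype=np.int8)
            for ci, (cname, _, _) in enumerate(gmap.chromosomes):
                cols = marker_cols[cname]
                if len(cols) == 0:
                    continue
                pos = markers.positions[cols].astype(float)
                alleles = np.zeros(len(cols), dtype=np.int8)
                for hap in (hap_a[ci], hap_b[ci]):
                    breaks, ids = hap
                    seg = np.searchsorted(breaks, pos, side="right") - 1
                    rows = np.array([founder_hap_rows[int(i)] for i in ids], dtype=np.intp)
                    alleles += allele_mat[rows[seg], cols]
                dos[cols] = alleles
            dosages.append(dos)

    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "replicate", "pig_ancestry", "ibd_fraction"]
    )
    tracts = pd.DataFrame(
        tract_rows, columns=["sample_id", "chromosome", "start_bp", "end_bp"]
    )
    genotypes = None
    if markers is not None:
        samples = SampleTable(
            pd.DataFrame({"sample_id": sample_ids, "group": group})
        )
        genotypes = GenotypeMatrix(markers, samples, np.vstack(dosages))
    return GeneDropResult(genotypes=genotypes, truth=truth, ibd_tracts=tracts)


# ---------------------------------------------------------------------------
# Benchmark suite
# ---------------------------------------------------------------------------


@dataclass
class SuiteConfig:
    """Defaults are the study conditions the fixture suite emulates:
    clustered continental wild populations with a longitudinal cline,
    a strongly diverged pig pool (FST ~ 0.15 against wild), hybrid
    cohorts of backcross depth 1-4 and the three inbred relationship
    classes, at a marker density (1 per ~120 kb) that keeps >5 Mb ROH
    detectable."""

    n_chromosomes: int = 6
    marker_spacing_bp: int = 120_000
    n_wild_populations: int = 12
    samples_per_population: int = 8
    wild_fst: float = 0.05
    pig_fst: float = 0.15
    cline_strength: float = 1.5
    missing_rate: float = 0.01  # typical post-genotyping beadchip missingness
    n_pigs: int = 30
    n_hybrids_per_depth: int = 20
    hybrid_depths: tuple[int, ...] = (1, 2, 3, 4)
    n_inbred_per_class: int = 20
    diag_fraction: float = 0.02  # loci made wild-rare / pig-common (breed variants)


def _plant_diagnostic_loci(
    wild_freqs: np.ndarray, pig_freqs: np.ndarray, cfg: SuiteConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Make a small, evenly spread locus subset wild-rare but pig-common,
    emulating breed-derived variants that diagnose introgression."""
    n_loci = wild_freqs.shape[1]
    n_diag = int(round(cfg.diag_fraction * n_loci))
    if n_diag == 0:
        return wild_freqs, pig_freqs
    idx = np.linspace(0, n_loci - 1, n_diag).astype(int)
    wild_freqs = wild_freqs.copy()
    pig_freqs = pig_freqs.copy()
    wild_freqs[:, idx] = 0.005
    pig_freqs[idx] = 0.40
    return wild_freqs, pig_freqs


def _wild_grid(n_pops: int) -> tuple[np.ndarray, list[str]]:
    """Population coordinates on a rough European lon/lat grid with four
    named clusters (Iberia, southern France, Italy, rest of Europe)."""
    lons = np.linspace(-8.0, 28.0, n_pops)
    lats = 40.0 + 12.0 * (np.arange(n_pops) % 3) / 2.0
    locations = np.column_stack([lons, lats])
    clusters = []
    for lon, lat in locations:
        if lon < -2.0:
            clusters.append("iberia")
        elif lon < 4.0:
            clusters.append("france_s")
        elif lon < 12.0 and lat < 44.0:
            clusters.append("italy")
        else:
            clusters.append("europe")
    return locations, clusters


def make_benchmark_suite(
    seed: int, outdir: str | Path, config: SuiteConfig | None = None
) -> dict[str, Path]:
    """Write the fixture suite: continental panel, pig pool, hybrid and
    inbred cohorts, plus truth tables.  Byte-identical for a given seed."""
    cfg = config or SuiteConfig()
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gmap = GeneticMap.pig_like(cfg.n_chromosomes)
    markers = gmap.marker_map(spacing_bp=cfg.marker_spacing_bp)
    paths: dict[str, Path] = {}

    # (a) continental wild panel with cline
    locations, clusters = _wild_grid(cfg.n_wild_populations)
    model = PopulationModel(
        n_populations=cfg.n_wild_populations,
        n_loci=markers.n_loci,
        fst=cfg.wild_fst,
        locations=locations,
        cline_strength=cfg.cline_strength,
    )
    wild_freqs = apply_cline(balding_nichols_freqs(model, rng), model)
    # (b) pig reference pool diverged from the wild ancestral pool, plus a
    # small set of planted breed-diagnostic loci (wild-rare, pig-common)
    mean_wild = wild_freqs.mean(axis=0)
    F = cfg.pig_fst
    pig_freqs = rng.beta(
        np.clip(mean_wild, 1e-3, None) * (1 - F) / F,
        np.clip(1 - mean_wild, 1e-3, None) * (1 - F) / F,
    )
    wild_freqs, pig_freqs = _plant_diagnostic_loci(wild_freqs, pig_freqs, cfg)
    mean_wild = wild_freqs.mean(axis=0)

    panel = sample_genotypes(
        wild_freqs,
        cfg.samples_per_population,
        markers,
        rng,
        missing_rate=cfg.missing_rate,
        pop_names=[f"loc{k:02d}" for k in range(cfg.n_wild_populations)],
        locations=locations,
        cluster_ids=clusters,
        group="wild",
        id_prefix="wb",
    )
    _write_dataset(panel, outdir, "panel", paths)
    pigs = sample_genotypes(
        pig_freqs[None, :],
        cfg.n_pigs,
        markers,
        rng,
        missing_rate=cfg.missing_rate,
        pop_names=["pig_pool"],
        group="pig_reference",
        id_prefix="pig",
    )
    _write_dataset(pigs, outdir, "pigs", paths)

    # (c) hybrid cohorts at backcross depths
    truth_frames = []
    for depth in cfg.hybrid_depths:
        ped = Pedigree.backcross(depth)
        res = gene_drop(
            ped,
            gmap,
            {"wild": mean_wild, "pig": pig_freqs},
            rng,
            markers=markers,
            n_replicates=cfg.n_hybrids_per_depth,
            id_prefix=f"hyb{depth}",
        )
        _write_dataset(res.genotypes, outdir, f"hybrid_depth{depth}", paths)
        t = res.truth.copy()
        t["cohort"] = f"hybrid_depth{depth}"
        truth_frames.append(t)

    # (d) inbred cohorts for the three relationship classes
    for name, builder in (
        ("half_sib", Pedigree.half_sib_offspring),
        ("full_cousin", Pedigree.full_cousin_offspring),
        ("half_cousin", Pedigree.half_cousin_offspring),
    ):
        res = gene_drop(
            builder(),
            gmap,
            {"wild": mean_wild},
            rng,
            markers=markers,
            n_replicates=cfg.n_inbred_per_class,
            id_prefix=f"inb_{name}",
        )
        _write_dataset(res.genotypes, outdir, f"inbred_{name}", paths)
        t = res.truth.copy()
        t["cohort"] = f"inbred_{name}"
        truth_frames.append(t)
        tr = res.ibd_tracts.copy()
        tr.to_csv(outdir / f"truth_tracts_{name}.tsv", sep="\t", index=False)
        paths[f"truth_tracts_{name}"] = outdir / f"truth_tracts_{name}.tsv"

    # (e) combined truth table
    truth = pd.concat(truth_frames, ignore_index=True)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format="%.8f")
    paths["truth"] = outdir / "truth.tsv"
    return paths


def make_pipeline_input(
    seed: int,
    outdir: str | Path,
    config: SuiteConfig | None = None,
    n_hybrids: int = 8,
    n_inbred: int = 8,
) -> dict[str, Path]:
    """One combined dataset for end-to-end pipeline runs.

    Wild panel samples, the pig reference pool, plus gene-dropped
    second-generation hybrids and half-sib-mating offspring planted into
    two host locations *labelled wild* (as they would appear in field
    samples).  Writes combined PED/MAP, metadata CSV, a small BED of
    synthetic gene intervals, and the truth table.
    """
    cfg = config or SuiteConfig()
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gmap = GeneticMap.pig_like(cfg.n_chromosomes)
    markers = gmap.marker_map(spacing_bp=cfg.marker_spacing_bp)

    locations, clusters = _wild_grid(cfg.n_wild_populations)
    model = PopulationModel(
        n_populations=cfg.n_wild_populations,
        n_loci=markers.n_loci,
        fst=cfg.wild_fst,
        locations=locations,
        cline_strength=cfg.cline_strength,
    )
    wild_freqs = apply_cline(balding_nichols_freqs(model, rng), model)
    mean_wild = wild_freqs.mean(axis=0)
    F = cfg.pig_fst
    pig_freqs = rng.beta(
        np.clip(mean_wild, 1e-3, None) * (1 - F) / F,
        np.clip(1 - mean_wild, 1e-3, None) * (1 - F) / F,
    )
    wild_freqs, pig_freqs = _plant_diagnostic_loci(wild_freqs, pig_freqs, cfg)
    panel = sample_genotypes(
        wild_freqs,
        cfg.samples_per_population,
        markers,
        rng,
        missing_rate=cfg.missing_rate,
        pop_names=[f"loc{k:02d}" for k in range(cfg.n_wild_populations)],
        locations=locations,
        cluster_ids=clusters,
        group="wild",
        id_prefix="wb",
    )
    pigs = sample_genotypes(
        pig_freqs[None, :],
        cfg.n_pigs,
        markers,
        rng,
        missing_rate=cfg.missing_rate,
        pop_names=["pig_pool"],
        group="pig_reference",
        id_prefix="pig",
    )

    hyb = gene_drop(
        Pedigree.backcross(2),
        gmap,
        {"wild": wild_freqs[0], "pig": pig_freqs},
        rng,
        markers=markers,
        n_replicates=n_hybrids,
        id_prefix="field_hyb",
    )
    inb = gene_drop(
        Pedigree.half_sib_offspring(),
        gmap,
        {"wild": wild_freqs[1]},
        rng,
        markers=markers,
        n_replicates=n_inbred,
        id_prefix="field_inb",
    )
    # planted samples present as ordinary wild animals at host locations
    for res, host in ((hyb, 0), (inb, 1)):
        tab = res.genotypes.samples.table
        tab["group"] = "wild"
        tab["location_id"] = f"loc{host:02d}"
        tab["longitude"] = locations[host][0]
        tab["latitude"] = locations[host][1]
        tab["cluster_id"] = clusters[host]

    dosage = np.vstack(
        [panel.dosage, pigs.dosage, hyb.genotypes.dosage, inb.genotypes.dosage]
    )
    tab = pd.concat(
        [
            panel.samples.table,
            pigs.samples.table,
            hyb.genotypes.samples.table,
            inb.genotypes.samples.table,
        ],
        ignore_index=True,
    )
    combined = GenotypeMatrix(markers, SampleTable(tab), dosage)

    paths: dict[str, Path] = {}
    _write_dataset(combined, outdir, "combined", paths)
    truth = pd.concat([hyb.truth, inb.truth], ignore_index=True)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format="%.8f")
    paths["truth"] = outdir / "truth.tsv"

    # synthetic gene intervals: every 4th 400-kb tile is "genic"
    rows = []
    for name, length, _ in gmap.chromosomes:
        for start in range(0, length - 400_000, 1_600_000):
            rows.append((name, start, start + 400_000))
    bed = outdir / "genes_synthetic.bed"
    with open(bed, "w") as fh:
        for chrom, s, e in rows:
            fh.write(f"{chrom}\t{s}\t{e}\n")
    paths["gene_intervals"] = bed
    return paths


def _write_dataset(g: GenotypeMatrix, outdir: Path, stem: str, paths: dict[str, Path]) -> None:
    ped, mp = outdir / f"{stem}.ped", outdir / f"{stem}.map"
    write_ped_map(g, ped, mp)
    meta = outdir / f"{stem}_metadata.csv"
    g.samples.table.to_csv(meta, index=False, float_format="%.6f")
    paths[stem] = ped
    paths[f"{stem}_map"] = mp
    paths[f"{stem}_metadata"] = meta
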