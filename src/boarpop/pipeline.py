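"""End-to-end pipeline: QC -> hybrid index -> ROH -> spatial structure.

A single YAML config drives the run.  Every stochastic stage has an
explicit named seed; identical config + inputs produce byte-identical
output tables (floats are written with a fixed format).

Stage order follows the analysis narrative: call-rate and MAF filters,
then two LD-pruned panels (relaxed r-squared including intragenic SNPs
for ROH; stringent r-squared on intergenic SNPs for structure),
within-location relatedness removal, the PCoA-projection hybrid index
against the pig reference pool, ROH/F_ROH, exclusion of inbred and hybrid
samples (both at 0.0625), per-location downsampling, and the spatial
statistics (PCoA + geography correlations, population-level Mantel, MLH
and its linear model, regional allele clines with kriging).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hybrid as hy
from . import qc as qcmod
from . import roh as rohmod
from . import spatial as sp
from .io import (
    GenotypeMatrix,
    ValidationError,
    attach_metadata,
    read_gene_intervals,
    read_ped_map,
    read_sample_metadata,
)

log = logging.getLogger("boarpop")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    ped: str
    map: str
    metadata: str
    output_dir: str
    gene_intervals: str | None = None
    qc: dict = field(default_factory=dict)
    roh: dict = field(default_factory=dict)
    hybrid: dict = field(default_factory=dict)   # n_pure, axes, clamp
    spatial: dict = field(default_factory=dict)  # n_perm, grid_step, focal_regions,
                                                 # exclusion_threshold, max_per_location
    seeds: dict = field(default_factory=dict)    # hybrid, downsample, mantel, profile

    REQUIRED_SEEDS = ("hybrid", "downsample", "mantel", "profile")

    def validate(self) -> None:
        for attr in ("ped", "map", "metadata"):
            p = Path(getattr(self, attr))
            if not p.exists():
                raise ValidationError(f"{attr} file not found: {p}")
        if self.gene_intervals and not Path(self.gene_intervals).exists():
            raise ValidationError(f"gene_intervals file not found: {self.gene_intervals}")
        missing = [s for s in self.REQUIRED_SEEDS if s not in self.seeds]
        if missing:
            raise ValidationError(f"missing stage seeds: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns the report dict (also written as JSON)."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    def stage(name):
        log.info("stage: %s", name)
        report["stages"][name] = {}
        return report["stages"][name]

    # ------------------------------------------------------------------ input
    st = stage("input")
    g = read_ped_map(cfg.ped, cfg.map)
    meta = read_sample_metadata(cfg.metadata, genotype_sample_ids=g.samples.sample_ids)
    g = attach_metadata(g, meta).sort_loci()
    genes = read_gene_intervals(cfg.gene_intervals) if cfg.gene_intervals else None
    st["n_samples"], st["n_loci"] = g.n_samples, g.n_loci

    # --------------------------------------------------------------------- qc
    st = stage("qc")
    qc_cfg = qcmod.QCConfig(**cfg.qc)
    g1, log_cr = qcmod.filter_call_rate(g, qc_cfg)
    g1, log_maf = qcmod.filter_maf(g1, qc_cfg)
    st["after_call_rate_maf"] = [g1.n_samples, g1.n_loci]

    # relaxed LD panel (intragenic kept) for ROH
    relaxed_cfg = dataclasses.replace(qc_cfg, ld_r2_max=max(qc_cfg.ld_r2_max, 0.5))
    roh_loci = qcmod.ld_prune(g1, relaxed_cfg)
    g_roh_panel = g1.select_loci_by_id(roh_loci).sort_loci()
    st["roh_panel_loci"] = int(g_roh_panel.n_loci)

    # stringent LD panel on intergenic SNPs for structure
    g_struct = g1
    if genes is not None and qc_cfg.exclude_intragenic:
        keep = qcmod.exclude_intragenic(g_struct, genes)
        g_struct = g_struct.select_loci_by_id(keep)
    stringent_cfg = dataclasses.replace(qc_cfg, ld_r2_max=min(qc_cfg.ld_r2_max, 0.2))
    struct_loci = qcmod.ld_prune(g_struct, stringent_cfg)
    g_struct = g_struct.select_loci_by_id(struct_loci).sort_loci()
    st["structure_panel_loci"] = int(g_struct.n_loci)

    # relatedness among wild samples, within location
    wild_mask = g_struct.samples.groups == "wild"
    g_wild = g_struct.subset_samples(wild_mask)
    rel = qcmod.estimate_ibd(g_wild, qc_cfg, scope="location")
    g_wild_unrel, log_rel = qcmod.drop_related(g_wild, rel, qc_cfg)
    unrelated_ids = set(g_wild_unrel.samples.sample_ids)
    st["wild_unrelated"] = len(unrelated_ids)
    removal_log = pd.concat([log_cr, log_maf, log_rel], ignore_index=True)
    _write(removal_log, outdir / "qc_removals.tsv")
    _write(rel, outdir / "relatedness.tsv")

    keep_mask = np.array(
        [
            (grp != "wild") or (sid in unrelated_ids)
            for sid, grp in zip(g_struct.samples.sample_ids, g_struct.samples.groups)
        ]
    )
    g_struct = g_struct.subset_samples(keep_mask)
    g_roh_panel = g_roh_panel.subset_samples(
        np.isin(g_roh_panel.samples.sample_ids, g_struct.samples.sample_ids)
    )

    # ------------------------------------------------------------- hybrid index
    st = stage("hybrid")
    hyb_opts = dict(cfg.hybrid)
    axes = hyb_opts.get("axes", "auto")
    est = hy.HybridIndexEstimator(
        n_axes=axes if axes == "auto" else int(axes),
        n_pure=int(hyb_opts.get("n_pure", 20)),
        clamp=bool(hyb_opts.get("clamp", False)),
        random_state=int(cfg.seeds["hybrid"]),
    )
    est.fit(g_struct)
    fhyb = est.results_
    _write(fhyb, outdir / "f_hybrid.tsv")
    wild_fhyb = fhyb[fhyb["group"] == "wild"]
    st["class_counts"] = wild_fhyb["hybrid_class"].value_counts().to_dict()

    wild_g = g_struct.subset_samples(g_struct.samples.groups == "wild")
    pig_g = g_struct.subset_samples(g_struct.samples.groups == "pig_reference")
    das = hy.diagnostic_alleles(wild_g, pig_g)
    _write(das, outdir / "diagnostic_alleles.tsv")
    st["n_diagnostic_loci"] = int(len(das))
    profiles = []
    if len(das):
        prof_rng = np.random.default_rng(int(cfg.seeds["profile"]))
        flagged = wild_fhyb[wild_fhyb["hybrid_class"] != "none"]["sample_id"]
        for sid in list(flagged)[:50]:
            i = int(np.flatnonzero(g_struct.samples.sample_ids == sid)[0])
            prof = hy.diagnostic_allele_profile(
                g_struct.dosage[i], das, g_struct.markers, rng=prof_rng,
                n_perm=int(hyb_opts.get("n_perm", 200)),
            )
            profiles.append({"sample_id": sid, **prof})
    _write(pd.DataFrame(profiles), outdir / "diagnostic_profiles.tsv")

    # --------------------------------------------------------------------- roh
    st = stage("roh")
    detector = rohmod.ROHDetector(**{k: v for k, v in cfg.roh.items()})
    wild_roh = g_roh_panel.subset_samples(g_roh_panel.samples.groups == "wild")
    detector.fit(wild_roh)
    _write(detector.segments_, outdir / "roh_segments.tsv")
    _write(detector.f_roh_, outdir / "f_roh.tsv")
    st["scanned_mb"] = round(detector.scanned_bp_ / 1e6, 3)
    st["n_segments"] = int(len(detector.segments_))
    st["n_inbred_gt_0125"] = int((detector.f_roh_["f_roh"] > 0.125).sum())

    # ------------------------------------------------------------------ spatial
    st = stage("spatial")
    sp_opts = dict(cfg.spatial)
    threshold = float(sp_opts.get("exclusion_threshold", 0.0625))
    keep_ids = sp.exclude_inbred_and_hybrid(wild_fhyb, detector.f_roh_, threshold)
    wild_kept = wild_g.select_samples_by_id(
        [s for s in wild_g.samples.sample_ids if s in set(keep_ids)]
    )
    st["after_exclusion"] = wild_kept.n_samples

    ds_rng = np.random.default_rng(int(cfg.seeds["downsample"]))
    ds_ids = sp.downsample_per_location(
        wild_kept.samples, int(sp_opts.get("max_per_location", 5)), ds_rng
    )
    g_sp = wild_kept.select_samples_by_id(ds_ids)
    st["after_downsampling"] = g_sp.n_samples

    d_gen = hy.hamming_distance_matrix(g_sp)
    ordination = hy.pcoa(d_gen)
    coords_df = pd.DataFrame(
        {
            "sample_id": g_sp.samples.sample_ids,
            "axis1": ordination.coordinates[:, 0],
            "axis2": ordination.coordinates[:, 1]
            if ordination.coordinates.shape[1] > 1
            else np.nan,
        }
    )
    _write(coords_df, outdir / "pcoa_scores.tsv")

    axis_geo = sp.axis_geography_correlation(ordination.coordinates, g_sp.samples)
    _write(axis_geo, outdir / "axis_geography.tsv")

    d_geo = sp.geographic_distance_matrix(g_sp.samples)
    loc_ids = g_sp.samples.table["location_id"].to_numpy()
    d_gen_pop, _ = sp.population_distance_matrix(d_gen, loc_ids)
    d_geo_pop, _ = sp.population_distance_matrix(d_geo, loc_ids)
    mantel = sp.mantel_test(
        d_gen_pop,
        d_geo_pop,
        n_perm=int(sp_opts.get("n_perm", 999)),
        rng=np.random.default_rng(int(cfg.seeds["mantel"])),
    )
    st["mantel_r"] = round(mantel.r, 6)
    st["mantel_p"] = round(mantel.p_value, 6)

    mlh_df = sp.mlh(wild_g)
    _write(mlh_df, outdir / "mlh.tsv")
    merged = (
        mlh_df.merge(wild_fhyb[["sample_id", "f_hybrid"]], on="sample_id")
        .merge(detector.f_roh_[["sample_id", "f_roh"]], on="sample_id")
        .merge(
            wild_g.samples.table[["sample_id", "longitude", "latitude"]], on="sample_id"
        )
    )
    try:
        glm = sp.mlh_linear_model(
            merged["mlh"].to_numpy(),
            merged["longitude"].to_numpy(),
            merged["f_hybrid"].to_numpy(),
            merged["f_roh"].to_numpy(),
            latitude=merged["latitude"].to_numpy(),
        )
        _write(glm["coefficients"], outdir / "mlh_glm_coefficients.tsv")
        st["mlh_glm"] = {
            "F": round(glm["f_statistic"], 4),
            "r2_adj": round(glm["r2_adj"], 4),
            "df_resid": glm["df_resid"],
        }
    except ValidationError as exc:
        st["mlh_glm"] = {"error": str(exc)}

    for region in sp_opts.get("focal_regions", []):
        name, locs = region["name"], set(region["locations"])
        sel = sp.select_regional_alleles(g_sp, g_sp.samples, locs)
        if len(sel) == 0:
            st[f"cline_{name}"] = {"n_loci": 0}
            continue
        freqs = sp.mean_regional_frequency(g_sp, g_sp.samples, sel)
        _write(freqs, outdir / f"cline_{name}_frequencies.tsv")
        surface = sp.krige_surface(
            freqs, grid=sp.GridSpec(step_deg=float(sp_opts.get("grid_step", 0.5)))
        )
        surface.to_csv(
            outdir / f"cline_{name}_surface.csv", index=False, float_format=_FLOAT_FMT
        )
        st[f"cline_{name}"] = {"n_loci": int(len(sel))}

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
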