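"""Top-level orchestration: simulate -> preprocess -> gFCD -> group stats.

``analyze_cohort`` runs the full analysis on an in-memory cohort and returns
an :class:`AnalysisResults` bundle; ``run_pipeline`` wraps it with disk IO
(reads a simulated cohort directory, writes maps, tables and a structured
log in which every applied threshold is recorded)."""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import yaml

from . import io as fio
from .fcd import FcdParams, SmoothingSpec, compute_gfcd, group_hub_map, rescale_map, smooth_map
from .preprocess import BandpassSpec, PreprocessConfig, run_preprocess
from .stats import (
    correlation_table,
    dissociation_report,
    extract_clusters,
    glm_group_contrast,
    roi_group_compare,
    roi_means,
)
from .types import ConfigurationError, GMVMap

logger = logging.getLogger("fcdtools")


@dataclasses.dataclass
class RunConfig:
    """Every stage's tunables in one place (paper-anchored defaults)."""

    n_discard: int = 10
    fd_thresh_mm: float = 0.5
    band: tuple = (0.01, 0.08)
    detrend: bool = True
    r_threshold: float = 0.6
    chunk_size: int = 1024
    fwhm_mm: float = 6.0
    alpha: float = 0.05
    min_extent: int = 10
    seed: int = 0

    def validate(self, tr_s: float):
        BandpassSpec(*self.band).validate(tr_s)
        FcdParams(self.r_threshold, self.chunk_size).validate()
        SmoothingSpec(self.fwhm_mm)
        if not (0 < self.alpha < 1):
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_extent < 1:
            raise ConfigurationError("min_extent must be >= 1")
        if self.n_discard < 0:
            raise ConfigurationError("n_discard must be nonnegative")
        return self

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(
            n_discard=self.n_discard,
            fd_thresh_mm=self.fd_thresh_mm,
            band=BandpassSpec(*self.band),
            detrend=self.detrend,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class AnalysisResults:
    config: RunConfig
    gfcd_maps: list          # per-subject smoothed gFCD maps
    gmv_maps: list           # per-subject smoothed GMV maps
    hub_maps: dict           # group label -> averaged rescaled gFCD map
    gfcd_result: object      # GroupStatResult
    gmv_result: object       # GroupStatResult
    clusters: object         # ClusterTable from the gFCD contrast
    roi_gfcd: object         # per-subject x ROI means (DataFrame)
    roi_gmv: object
    roi_gmv_tests: object    # per-ROI confound-adjusted group tests
    correlations: object     # Table-3-shaped correlation table
    dissociation: object     # DissociationReport
    subject_logs: list


def analyze_cohort(cohort, config: RunConfig | None = None) -> AnalysisResults:
    """The in-scope analysis chain on a simulated (or loaded) cohort."""
    config = (config or RunConfig()).validate(cohort.spec.tr_s)
    gm = cohort.gm_mask
    smoothing = SmoothingSpec(config.fwhm_mm)
    fcd_params = FcdParams(config.r_threshold, config.chunk_size)
    pp_config = config.preprocess_config()

    gfcd_maps, gmv_maps, raw_for_hub = [], [], []
    subject_logs = []
    for subj in cohort.subjects:
        try:
            clean, log = run_preprocess(
                subj.bold, subj.motion, cohort.wm_mask, cohort.csf_mask, pp_config
            )
            fcd = compute_gfcd(clean, gm, fcd_params)
        except Exception as exc:
            raise type(exc)(f"[subject {subj.subject_id}] {exc}") from exc
        log["subject_id"] = subj.subject_id
        subject_logs.append(log)
        raw_for_hub.append(fcd)
        gfcd_maps.append(smooth_map(fcd, smoothing, mask=gm))
        gmv_maps.append(smooth_map(GMVMap(subj.gmv.data, subj.gmv.affine),
                                   smoothing, mask=gm))
        logger.info("subject %s: %d spike regressors, FD max %.3f mm",
                    subj.subject_id, log["n_spikes"], log["fd_max_mm"])

    groups = [s.group for s in cohort.subjects]
    hub_maps = {
        g: group_hub_map([m for m, gg in zip(raw_for_hub, groups) if gg == g], gm)
        for g in sorted(set(groups))
    }

    gfcd_result = glm_group_contrast(gfcd_maps, cohort.records, mask=gm,
                                     alpha=config.alpha)
    gmv_result = glm_group_contrast(gmv_maps, cohort.records, mask=gm,
                                    alpha=config.alpha)
    clusters = extract_clusters(gfcd_result.sig_mask, gfcd_result.t_map,
                                gfcd_result.affine, config.min_extent)

    roi_gfcd = roi_gmv = roi_tests = corr = None
    ids = [s.subject_id for s in cohort.subjects]
    if len(clusters) > 0:
        roi_gfcd = roi_means(gfcd_maps, clusters.label_map, ids)
        roi_gmv = roi_means(gmv_maps, clusters.label_map, ids)
        roi_tests = roi_group_compare(roi_gmv, cohort.records)
        corr = correlation_table(roi_gfcd, roi_gmv, cohort.records)
    dis = dissociation_report(gfcd_result, gmv_result, config.min_extent)

    return AnalysisResults(
        config=config,
        gfcd_maps=gfcd_maps,
        gmv_maps=gmv_maps,
        hub_maps=hub_maps,
        gfcd_result=gfcd_result,
        gmv_result=gmv_result,
        clusters=clusters,
        roi_gfcd=roi_gfcd,
        roi_gmv=roi_gmv,
        roi_gmv_tests=roi_tests,
        correlations=corr,
        dissociation=dis,
        subject_logs=subject_logs,
    )


def write_results(results: AnalysisResults, cohort, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for subj, fcd, gmv in zip(cohort.subjects, results.gfcd_maps, results.gmv_maps):
        sdir = outdir / "maps" / subj.subject_id
        fio.write_map(fcd, sdir / "gfcd_smoothed.nii.gz")
        fio.write_map(rescale_map(fcd, cohort.gm_mask), sdir / "gfcd_rescaled.nii.gz")
        fio.write_map(gmv, sdir / "gmv_smoothed.nii.gz")
    for g, hub in results.hub_maps.items():
        fio.write_map(hub, outdir / f"hub_map_{g}.nii.gz")
    for name, res in (("gfcd", results.gfcd_result), ("gmv", results.gmv_result)):
        fio.write_volume(res.t_map, res.affine, outdir / f"{name}_tmap.nii.gz")
        fio.write_volume(res.p_map, res.affine, outdir / f"{name}_pmap.nii.gz")
        fio.write_volume(res.q_map, res.affine, outdir / f"{name}_qmap.nii.gz")
        fio.write_volume(res.sig_mask, res.affine, outdir / f"{name}_sigmask.nii.gz")
    results.clusters.to_frame().to_csv(outdir / "cluster_table.tsv", sep="\t", index=False)
    if results.correlations is not None:
        results.correlations.to_csv(outdir / "correlation_table.tsv", sep="\t", index=False)
    if results.roi_gmv_tests is not None:
        results.roi_gmv_tests.to_csv(outdir / "roi_gmv_tests.tsv", sep="\t")
    results.dissociation.table.to_csv(outdir / "dissociation_report.tsv", sep="\t", index=False)
    log = {
        "config": results.config.to_dict(),
        "applied_thresholds": {
            "n_discard": results.config.n_discard,
            "fd_thresh_mm": results.config.fd_thresh_mm,
            "r_threshold": results.config.r_threshold,
            "fwhm_mm": results.config.fwhm_mm,
            "alpha": results.config.alpha,
            "min_extent": results.config.min_extent,
            "band_hz": list(results.config.band),
        },
        "subjects": results.subject_logs,
        "n_clusters": len(results.clusters),
        "dissociation": {
            "n_concordant": results.dissociation.n_concordant,
            "n_discordant": results.dissociation.n_discordant,
        },
    }
    (outdir / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=False))
    return outdir


def run_pipeline(data_dir, out_dir, config: RunConfig | None = None) -> AnalysisResults:
    """Load a simulated cohort directory, run the analysis, write outputs."""
    cohort = fio.read_cohort(data_dir)
    config = (config or RunConfig()).validate(cohort.spec.tr_s)
    results = analyze_cohort(cohort, config)
    write_results(results, cohort, out_dir)
    return results
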