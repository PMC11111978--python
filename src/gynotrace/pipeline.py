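"""End-to-end cohort analysis: filter -> DSV -> MSSV -> common MSSV -> annotation.

The in-memory entry point is :func:`run_cohort`, which takes callsets that
are already loaded (e.g. straight from the simulator); :func:`run_full`
wraps it with file IO driven by a :class:`PipelineConfig` manifest.

Role semantics follow the gynogenetic study design: one maternal sample
whose composite callset is the subtraction reference (never record-
filtered itself), one male per cohort, and offspring compared only
against their assigned male.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .annotate import (
    AnnotateParams,
    GeneModel,
    classify_region,
    load_gene_model,
    tally_annotations,
    write_annotation_tsv,
)
from .coverage import CoverageTrack, read_coverage
from .dsv import DSVParams, DSVResult, detect_dsv
from .filters import FilterParams, filter_callset
from .io import read_sv_vcf, write_summary_tsv, write_sv_vcf
from .match import MergeCluster
from .models import SVCallset, summarize_callset
from .mssv import MSSVParams, MSSVResult, common_mssv, detect_mssv, per_chromosome_tally

log = logging.getLogger(__name__)

ROLES = ("maternal", "male_hom", "male_het", "offspring_hom", "offspring_het")


@dataclass
class SampleSpec:
    sample_id: str
    role: str
    path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")


@dataclass
class PipelineConfig:
    samples: List[SampleSpec]
    coverage_path: str
    gene_model_path: Optional[str] = None
    outdir: str = "gynotrace_out"
    filter_params: FilterParams = field(
        default_factory=lambda: FilterParams(strict_support=True)
    )
    dsv_params: DSVParams = field(default_factory=DSVParams)
    mssv_params: MSSVParams = field(default_factory=MSSVParams)
    annotate_params: AnnotateParams = field(default_factory=AnnotateParams)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        by_role: Dict[str, List[SampleSpec]] = {r: [] for r in ROLES}
        for s in self.samples:
            by_role[s.role].append(s)
        if len(by_role["maternal"]) != 1:
            raise ValueError(
                f"manifest must name exactly one maternal sample, "
                f"got {len(by_role['maternal'])}"
            )
        for cohort in ("hom", "het"):
            males = by_role[f"male_{cohort}"]
            kids = by_role[f"offspring_{cohort}"]
            if kids and len(males) != 1:
                raise ValueError(
                    f"offspring_{cohort} samples need exactly one male_{cohort}"
                )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in manifest")

    def of_role(self, role: str) -> List[SampleSpec]:
        return [s for s in self.samples if s.role == role]


@dataclass
class CohortReport:
    """All per-sample and per-cohort results of one pipeline run."""

    filtered: Dict[str, SVCallset]
    dsv: Dict[str, DSVResult]
    mssv: Dict[str, MSSVResult]
    common: Dict[str, List[MergeCluster]]  # cohort -> qualifying clusters
    common_by_chrom: Dict[str, Dict[str, int]]
    annotation: Dict[str, list]  # sample -> RegionCalls
    annotation_tallies: Dict[str, object]
    run_log: List[str] = field(default_factory=list)

    def mssv_table(self) -> pd.DataFrame:
        rows = []
        for sid, res in self.mssv.items():
            d = self.dsv[sid]
            rows.append(
                {
                    "sample_id": sid,
                    "n_filtered": d.n_input,
                    "n_dsv": d.n_dsv,
                    "dsv_fraction_of_filtered": d.fraction_of_filtered,
                    "n_mssv": res.n_mssv,
                    "mssv_fraction_of_dsv": res.fraction_of_dsv,
                    "mssv_fraction_of_filtered": res.fraction_of_filtered,
                }
            )
        return pd.DataFrame(rows)


def run_cohort(
    maternal: SVCallset,
    males: Dict[str, SVCallset],
    offspring: Dict[str, Dict[str, SVCallset]],
    coverage: CoverageTrack,
    gene_model: Optional[GeneModel] = None,
    filter_params: FilterParams = FilterParams(strict_support=True),
    dsv_params: DSVParams = DSVParams(),
    mssv_params: MSSVParams = MSSVParams(),
    annotate_params: AnnotateParams = AnnotateParams(),
    prefiltered: bool = False,
) -> CohortReport:
    """Run the full analysis on in-memory callsets.

    ``males`` maps cohort name ("hom"/"het") to the male callset;
    ``offspring`` maps cohort name to {sample_id: callset}. Set
    ``prefiltered=True`` when the inputs already passed record filtering.
    """
    run_log = [
        f"filter: {filter_params}",
        f"dsv merge: {dsv_params.merge.as_string()} "
        f"(min maternal depth {dsv_params.min_maternal_depth})",
        f"mssv merge: {mssv_params.merge.as_string()} "
        f"(max span {mssv_params.max_sv_span})",
        f"common-mssv merge: {mssv_params.common_merge.as_string()}",
    ]
    filtered: Dict[str, SVCallset] = {}
    dsv_res: Dict[str, DSVResult] = {}
    mssv_res: Dict[str, MSSVResult] = {}
    common: Dict[str, List[MergeCluster]] = {}
    common_chrom: Dict[str, Dict[str, int]] = {}
    annotation: Dict[str, list] = {}
    ann_tallies: Dict[str, object] = {}

    def prepare(cs: SVCallset) -> SVCallset:
        return cs if prefiltered else filter_callset(cs, filter_params)

    male_dsv: Dict[str, DSVResult] = {}
    for cohort, male_cs in males.items():
        f = prepare(male_cs)
        filtered[male_cs.sample_id] = f
        res = detect_dsv(f, maternal, coverage, dsv_params)
        dsv_res[male_cs.sample_id] = res
        male_dsv[cohort] = res
        run_log.append(
            f"{male_cs.sample_id}: {len(male_cs)} raw, {len(f)} filtered, "
            f"{res.n_dsv} DSV ({res.iterations_run} subtraction iterations)"
        )

    for cohort, kids in offspring.items():
        cohort_mssv: List[MSSVResult] = []
        for sid in sorted(kids):
            f = prepare(kids[sid])
            filtered[sid] = f
            res = detect_dsv(f, maternal, coverage, dsv_params)
            dsv_res[sid] = res
            m = detect_mssv(
                res.dsv, male_dsv[cohort].dsv, mssv_params, n_filtered=res.n_input
            )
            mssv_res[sid] = m
            cohort_mssv.append(m)
            run_log.append(
                f"{sid}: {len(f)} filtered, {res.n_dsv} DSV, {m.n_mssv} MSSV"
            )
            if gene_model is not None:
                calls = [
                    classify_region(r, gene_model, annotate_params) for r in m.mssv
                ]
                annotation[sid] = calls
                ann_tallies[sid] = tally_annotations(calls, gene_model)
        if len(cohort_mssv) >= mssv_params.common_min_samples:
            clusters = common_mssv(cohort_mssv, mssv_params)
            common[cohort] = clusters
            common_chrom[cohort] = per_chromosome_tally(clusters)
            run_log.append(f"{cohort}: {len(clusters)} common MSSV clusters")
        elif cohort_mssv:
            log.info(
                "cohort %s smaller than common_min_samples=%d; "
                "skipping common-MSSV stage",
                cohort,
                mssv_params.common_min_samples,
            )
    return CohortReport(
        filtered=filtered,
        dsv=dsv_res,
        mssv=mssv_res,
        common=common,
        common_by_chrom=common_chrom,
        annotation=annotation,
        annotation_tallies=ann_tallies,
        run_log=run_log,
    )


def run_full(config: PipelineConfig) -> CohortReport:
    """File-driven pipeline: read inputs per the manifest, run, write reports."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat_spec = config.of_role("maternal")[0]
    maternal = read_sv_vcf(mat_spec.path, mat_spec.sample_id)
    coverage = read_coverage(config.coverage_path, mat_spec.sample_id)
    gene_model = (
        load_gene_model(config.gene_model_path) if config.gene_model_path else None
    )
    males = {}
    offspring: Dict[str, Dict[str, SVCallset]] = {"hom": {}, "het": {}}
    for cohort in ("hom", "het"):
        specs = config.of_role(f"male_{cohort}")
        if specs:
            males[cohort] = read_sv_vcf(specs[0].path, specs[0].sample_id)
        for s in config.of_role(f"offspring_{cohort}"):
            offspring[cohort][s.sample_id] = read_sv_vcf(s.path, s.sample_id)
    offspring = {k: v for k, v in offspring.items() if v}
    males = {k: v for k, v in males.items() if k in offspring or k in males}
    report = run_cohort(
        maternal,
        males,
        offspring,
        coverage,
        gene_model,
        config.filter_params,
        config.dsv_params,
        config.mssv_params,
        config.annotate_params,
    )
    _write_report(report, outdir, gene_model)
    return report


def _write_report(report: CohortReport, outdir: Path, gene_model) -> None:
    write_summary_tsv(
        [summarize_callset(cs) for cs in report.filtered.values()],
        outdir / "filtered_summary.tsv",
    )
    for sid, res in report.dsv.items():
        write_sv_vcf(res.dsv, outdir / f"{sid}.dsv.vcf")
    for sid, res in report.mssv.items():
        write_sv_vcf(res.mssv, outdir / f"{sid}.mssv.vcf")
    report.mssv_table().to_csv(outdir / "mssv_report.tsv", sep="\t", index=False)
    dsv_rows = [
        {
            "sample_id": sid,
            "n_filtered": r.n_input,
            "n_dsv": r.n_dsv,
            "fraction_of_filtered": r.fraction_of_filtered,
            "iterations_run": r.iterations_run,
            "n_removed_by_coverage": r.n_removed_by_coverage,
        }
        for sid, r in report.dsv.items()
    ]
    pd.DataFrame(dsv_rows).to_csv(outdir / "dsv_report.tsv", sep="\t", index=False)
    common_rows = []
    for cohort, clusters in report.common.items():
        for i, c in enumerate(clusters):
            rep = c.representative
            common_rows.append(
                {
                    "cohort": cohort,
                    "cluster": i,
                    "chrom": rep.chrom,
                    "pos": rep.pos,
                    "end": rep.end,
                    "svtype": rep.svtype.value,
                    "n_samples": c.n_samples,
                    "samples": ",".join(sorted(c.samples)),
                }
            )
    pd.DataFrame(
        common_rows,
        columns=[
            "cohort", "cluster", "chrom", "pos", "end",
            "svtype", "n_samples", "samples",
        ],
    ).to_csv(outdir / "common_mssv.tsv", sep="\t", index=False)
    if gene_model is not None:
        for sid, calls in report.annotation.items():
            write_annotation_tsv(calls, gene_model, outdir / f"{sid}.annotation.tsv")
    (outdir / "run_log.txt").write_text("\n".join(report.run_log) + "\n")
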