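"""End-to-end orchestration: validated YAML config, logging, run-all.

A run takes exactly one entry point — raw FASTQ files, a prebuilt count
matrix, or the synthetic-data generator — then normalizes, filters, tests the
two differentiation contrasts, classifies trajectories and computes
cluster/family contributions, writing every stage's table plus a
human-readable report under the output directory.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import __version__
from .annotation import (
    derive_clusters,
    assign_families,
    load_contaminants,
    load_packaged_reference,
    load_reference,
    ClusterTable,
)
from .clusterseed import (
    cluster_contributions,
    cluster_seed_report,
    diversity_summary,
    family_contributions,
)
from .diffexpr import CountMatrix, DifferentialExpressionModel
from .preprocess import FilterParams, build_count_matrix
from .simulate import SimulationSpec, simulate_counts
from .trajectory import export_tables, load_group_mapping

log = logging.getLogger("mirflow")


class FastqInput(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fastqs: dict[str, str]  # sample_id -> path
    sample_sheet: str


class CountsInput(BaseModel):
    model_config = ConfigDict(extra="forbid")
    counts_tsv: str
    samples_tsv: str


class SimulateInput(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_mirnas: int = 347
    baseline_mean: float = Field(500.0, gt=0)
    dispersion: float = Field(0.05, ge=0)
    planted_per_group: int = Field(0, ge=0)
    effect_size: float = Field(2.0, ge=0)


class ReferenceConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mature_fasta: Optional[str] = None
    genomic_gff: Optional[str] = None
    contaminants_fasta: Optional[str] = None
    clusters_tsv: Optional[str] = None  # bypasses distance-based derivation


class Thresholds(BaseModel):
    model_config = ConfigDict(extra="forbid")
    adapter: str = "AGATCGGAAGAGCACACGTCT"
    end_trim_phred: int = Field(5, ge=0)
    min_phred: int = Field(10, ge=0)
    min_fraction_at_min_phred: float = Field(0.85, gt=0, le=1)
    min_len: int = Field(16, ge=1)
    max_len: int = Field(27, ge=1)
    max_mismatches: int = Field(1, ge=0)
    filter_threshold: float = Field(50.0, ge=0)
    filter_min_samples: int = Field(2, ge=1)
    p_thresh: float = Field(0.05, gt=0, le=1)
    fc_thresh: float = Field(0.6, ge=0)
    cluster_gap_bp: int = Field(10_000, ge=0)

    @model_validator(mode="after")
    def _length_window(self):
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        return self


class RunConfig(BaseModel):
    """Validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    fastq: Optional[FastqInput] = None
    counts: Optional[CountsInput] = None
    simulate: Optional[SimulateInput] = None
    reference: ReferenceConfig = ReferenceConfig()
    thresholds: Thresholds = Thresholds()
    design: tuple[str, str, str] = ("hESC", "NSC", "DiffNSC")
    group_mapping_tsv: Optional[str] = None
    seed: int = 0
    outdir: str = "mirflow_out"

    @model_validator(mode="after")
    def _one_entry_point(self):
        set_inputs = [k for k in ("fastq", "counts", "simulate") if getattr(self, k) is not None]
        if len(set_inputs) != 1:
            raise ValueError(
                f"exactly one of fastq/counts/simulate must be set (got {set_inputs or 'none'})"
            )
        return self


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; all errors are reported together."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        msgs = [f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()]
        raise ValueError("invalid config:\n  " + "\n  ".join(msgs)) from exc


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s [%(stage)s] %(message)s", "%H:%M:%S")
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(outdir / "run.log")):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def _stage(name: str, msg: str) -> None:
    log.info(msg, extra={"stage": name})


def run_all(config: RunConfig) -> dict:
    """Execute every stage in fixed order; returns the run report dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    report: dict = {"version": __version__, "parameters": config.model_dump(), "stages": {}}
    thr = config.thresholds

    # references
    ref = config.reference
    if ref.mature_fasta:
        mirnas = load_reference(ref.mature_fasta, ref.genomic_gff)
        contaminants = load_contaminants(ref.contaminants_fasta) if ref.contaminants_fasta else []
    else:
        mirnas, contaminants = load_packaged_reference()
    _stage("reference", f"{len(mirnas)} mature records, {len(contaminants)} contaminants")
    report["stages"]["reference"] = {"mirnas": len(mirnas), "contaminants": len(contaminants)}

    # count matrix entry point
    filter_report = None
    if config.fastq is not None:
        sheet = pd.read_csv(config.fastq.sample_sheet, sep="\t", index_col="sample_id")
        params = FilterParams(
            adapter=thr.adapter,
            end_trim_phred=thr.end_trim_phred,
            min_phred=thr.min_phred,
            min_fraction_at_min_phred=thr.min_fraction_at_min_phred,
            min_len=thr.min_len,
            max_len=thr.max_len,
            max_mismatches=thr.max_mismatches,
        )
        cm, filter_report = build_count_matrix(
            config.fastq.fastqs, sheet, mirnas, contaminants, params
        )
        filter_report.to_csv(outdir / "filter_report.tsv", sep="\t")
        _stage("preprocess", f"{filter_report['total'].sum()} reads -> "
               f"{int(cm.counts.to_numpy().sum())} counted")
    elif config.counts is not None:
        cm = CountMatrix.from_tsv(config.counts.counts_tsv, config.counts.samples_tsv)
        _stage("counts", f"loaded {len(cm.mirna_ids)} miRNAs x {len(cm.sample_ids)} samples")
    else:
        sim = config.simulate
        groups = {}
        if sim.planted_per_group:
            from .simulate import GROUP_EFFECTS

            groups = {
                g: (sim.planted_per_group, (e1 * sim.effect_size / 2, e2 * sim.effect_size / 2))
                for g, (e1, e2) in GROUP_EFFECTS.items()
            }
        spec = SimulationSpec(
            n_mirnas=sim.n_mirnas,
            cell_types=config.design,
            baseline_mean=sim.baseline_mean,
            dispersion=sim.dispersion,
            planted_groups=groups,
            seed=config.seed,
        )
        cm, truth = simulate_counts(spec)
        truth.to_tsv(outdir / "ground_truth.tsv")
        _stage("simulate", f"simulated {len(cm.mirna_ids)} miRNAs x {len(cm.sample_ids)} samples")
    cm.to_tsv(outdir / "counts.tsv", outdir / "samples.tsv")
    report["stages"]["counts"] = {
        "mirnas": len(cm.mirna_ids),
        "samples": len(cm.sample_ids),
        "total_counts": int(cm.counts.to_numpy().sum()),
    }
    if filter_report is not None:
        report["stages"]["preprocess"] = filter_report.sum().to_dict()

    # differential expression + trajectory groups
    model = DifferentialExpressionModel(
        cm,
        design=config.design,
        filter_threshold=thr.filter_threshold,
        min_samples=thr.filter_min_samples,
    )
    res = model.fit()
    res.de1.to_csv(outdir / "de_contrast1.tsv", sep="\t", index=False)
    res.de2.to_csv(outdir / "de_contrast2.tsv", sep="\t", index=False)
    _stage("diffexpr", f"{len(res.retained)} retained; "
           f"{res.n_significant(1)}/{res.n_significant(2)} significant per contrast")
    report["stages"]["diffexpr"] = {
        "retained": len(res.retained),
        "significant_contrast1": res.n_significant(1),
        "significant_contrast2": res.n_significant(2),
    }

    mapping = load_group_mapping(config.group_mapping_tsv) if config.group_mapping_tsv else None
    calls = res.classify(thr.p_thresh, thr.fc_thresh, mapping)
    export_tables(calls, res.de1, res.de2, res.normalized_retained, outdir)
    group_counts = calls["group"].value_counts().to_dict()
    _stage("trajectory", f"group sizes: {group_counts}")
    report["stages"]["trajectory"] = {"calls": len(calls), "groups": group_counts}

    # clusters and families
    if ref.clusters_tsv:
        clusters = ClusterTable.from_tsv(ref.clusters_tsv)
    else:
        clusters = derive_clusters(mirnas, max_gap_bp=thr.cluster_gap_bp)
    overlap = set(clusters.cluster_of()) & set(res.retained)
    if overlap:
        contrib = cluster_contributions(res.normalized_retained, clusters)
        contrib.to_csv(outdir / "cluster_contributions.tsv", sep="\t", index=False)
        diversity_summary(contrib).to_csv(outdir / "cluster_diversity.tsv", sep="\t", index=False)
        seed_rep = cluster_seed_report(clusters, mirnas)
        seed_rep.to_csv(outdir / "seed_similarity.tsv", sep="\t", index=False)
        fams = assign_families(mirnas)
        fam_members = {f for members in fams.values() for f in members}
        if fam_members & set(res.retained):
            fam_contrib = family_contributions(res.normalized_retained, fams)
            fam_contrib.to_csv(outdir / "family_contributions.tsv", sep="\t", index=False)
        report["stages"]["clusterseed"] = {
            "clusters": len(clusters.members),
            "contribution_rows": len(contrib),
        }
        _stage("clusterseed", f"{len(clusters.members)} clusters")
    else:
        _stage("clusterseed", "no cluster members present in the count matrix; skipped")
        report["stages"]["clusterseed"] = {"clusters": 0, "contribution_rows": 0}

    with open(outdir / "report.txt", "w") as fh:
        fh.write(res.summary() + "\n\nStage record counts\n")
        for stage, info in report["stages"].items():
            fh.write(f"  {stage}: {info}\n")
    _stage("report", f"written to {outdir}")
    return report
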