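"""End-to-end orchestration: simulate → call → spectrum → associate → cluster.

A single YAML config drives all stages; a run manifest records the config
echo, input checksums and per-stage record counts so that a run is auditable
and reproducible (identical config + seed ⇒ identical outputs; the manifest
contains no timestamps for that reason).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import calling, expression, io, spectrum
from .errors import CacsomaticError, InvalidArgumentError
from .simulate import (SimConfig, simulate_clinical, simulate_cohort,
                       simulate_expression, simulate_methylation_and_mutations,
                       generate_reference, score_against_truth)

__all__ = ["PipelineConfig", "RunManifest", "validate_config", "run_all"]

log = logging.getLogger("cacsomatic")

#: genes whose mutations annotate the expression clusters (Wnt pathway)
WNT_GENES = ["APC", "RNF43"]


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str = "results/run"
    seed: int = 0
    log_level: str = "INFO"
    # simulation stage (the demo pipeline always simulates its inputs)
    simulate: dict = dataclasses.field(default_factory=dict)
    # caller
    thresholds: dict = dataclasses.field(default_factory=dict)
    recurrence_basis: str = "raw"
    # spectrum
    trend_bins: int = 5
    trend_side: str = "one"
    tpt_flag_threshold: int = 20
    hypermutated_cutoff: int = 300
    methylation_slope: float = 0.09
    methylation_base_rate: float = 0.01
    # expression
    cluster_k: int = 2
    expression: dict = dataclasses.field(default_factory=dict)
    # clinical
    duration_mean_carrier: float = 328.0
    duration_mean_noncarrier: float = 215.0
    carrier_gene: str = "RNF43"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of problems (empty means valid).  Never mutates state."""
    problems: list[str] = []
    if not isinstance(config.seed, int) or config.seed < 0:
        problems.append("seed: must be a nonnegative integer")
    try:
        calling.CallerThresholds(**config.thresholds)
    except (TypeError, CacsomaticError) as exc:
        problems.append(f"thresholds: {exc}")
    if config.recurrence_basis not in ("raw", "passed"):
        problems.append("recurrence_basis: must be 'raw' or 'passed'")
    if config.cluster_k < 2:
        problems.append("cluster_k: must be >= 2")
    if config.trend_bins < 2:
        problems.append("trend_bins: must be >= 2")
    if config.trend_side not in ("one", "two"):
        problems.append("trend_side: must be 'one' or 'two'")
    if not (0 <= config.methylation_base_rate
            and config.methylation_base_rate + config.methylation_slope <= 1):
        problems.append("methylation rates: need base_rate >= 0 and "
                        "base_rate + slope <= 1")
    if config.duration_mean_carrier <= 0 or config.duration_mean_noncarrier <= 0:
        problems.append("duration means: must be > 0")
    try:
        SimConfig(**{**config.simulate, "seed": 0})
    except (TypeError, CacsomaticError) as exc:
        problems.append(f"simulate: {exc}")
    return problems


@dataclasses.dataclass
class RunManifest:
    config: dict
    completed_stages: list = dataclasses.field(default_factory=list)
    checksums: dict = dataclasses.field(default_factory=dict)
    counts: dict = dataclasses.field(default_factory=dict)

    def record_file(self, path) -> None:
        path = Path(path)
        self.checksums[path.name] = hashlib.md5(path.read_bytes()).hexdigest()

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=str)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _caller_counts_conserved(counts: dict) -> bool:
    return all(c["candidates"] == c["passed"] + sum(c["filtered_by_tag"].values())
               for c in counts.values())


def run_all(config: PipelineConfig) -> RunManifest:
    """Run every stage under one config and seed; returns the manifest.

    Any stage failure aborts with the manifest recording completed stages
    (the partial manifest is still written to the output directory).
    """
    problems = validate_config(config)
    if problems:
        raise InvalidArgumentError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level,
                        format="%(name)s\t%(levelname)s\t%(message)s")
    manifest = RunManifest(config=dataclasses.asdict(config))
    try:
        _run_stages(config, out, manifest)
    finally:
        manifest.write(out / "manifest.json")
    return manifest


def _run_stages(config: PipelineConfig, out: Path, manifest: RunManifest) -> None:
    rng = np.random.default_rng(config.seed)

    # ---------------------------------------------------------------- simulate
    log.info("stage=simulate start")
    sim_cfg = SimConfig(**{**config.simulate, "seed": config.seed})
    reference_seq = generate_reference(sim_cfg.ref_length, sim_cfg.gc_fraction,
                                       seed=config.seed)
    panel = sim_cfg.resolved_panel()
    contig = panel[0][1]
    reference = {contig: reference_seq}
    observations, truth = simulate_cohort(sim_cfg, reference_seq)
    io.write_fasta(reference, out / "reference.fa")
    io.write_common_variants_vcf(truth.mini_dbsnp, reference,
                                 out / "mini_dbsnp.vcf")
    obs_frame = pd.concat(observations.values(), ignore_index=True)
    io.write_observations(obs_frame, out / "observations.tsv")
    track, mut_flags = simulate_methylation_and_mutations(
        reference_seq, slope=config.methylation_slope,
        base_rate=config.methylation_base_rate, seed=config.seed, contig=contig)
    io.write_methylation(track, out / "methylation.tsv")
    expr, expr_labels, module_genes = simulate_expression(
        seed=config.seed, **config.expression)
    io.write_matrix(expr, out / "expression.tsv")
    clinical = simulate_clinical(truth, config.duration_mean_carrier,
                                 config.duration_mean_noncarrier,
                                 config.carrier_gene, seed=config.seed)
    io.write_clinical(clinical, out / "clinical.tsv")
    for f in ("reference.fa", "mini_dbsnp.vcf", "observations.tsv",
              "methylation.tsv", "expression.tsv", "clinical.tsv"):
        manifest.record_file(out / f)
    manifest.counts["simulate"] = {
        "observations": int(len(obs_frame)),
        "samples": sim_cfg.n_samples,
        "dbsnp_sites": len(truth.mini_dbsnp),
        "cpg_sites": int(len(track)),
    }
    manifest.completed_stages.append("simulate")
    log.info("stage=simulate done observations=%d", len(obs_frame))

    # -------------------------------------------------------------------- call
    log.info("stage=call start")
    thresholds = calling.CallerThresholds(**config.thresholds)
    result = calling.run_caller(observations, reference, truth.mini_dbsnp,
                                thresholds, panel=panel,
                                recurrence_basis=config.recurrence_basis)
    vcf_dir = out / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for sample_id, calls in result.calls.items():
        io.write_vcf(calls, sample_id, vcf_dir / f"{sample_id}.vcf", reference)
    io.write_matrix(result.mutation_table, out / "mutation_table.tsv",
                    index_label="sample_id")
    manifest.record_file(out / "mutation_table.tsv")
    if not _caller_counts_conserved(result.counts):
        raise CacsomaticError("caller accounting not conserved")
    manifest.counts["call"] = {"per_sample": result.counts,
                               "passed_total": sum(c["passed"]
                                                   for c in result.counts.values())}
    manifest.completed_stages.append("call")
    score = score_against_truth(truth, result)
    pd.Series(score).to_csv(out / "caller_score.tsv", sep="\t", header=False)
    log.info("stage=call done passed=%d recall=%.3f precision=%.3f",
             manifest.counts["call"]["passed_total"], score["recall"],
             score["precision"])

    # ---------------------------------------------------------------- spectrum
    log.info("stage=spectrum start")
    spectra = []
    for sample_id in sorted(result.calls):
        sp = spectrum.compute_spectrum(result.passed(sample_id), reference,
                                       sample_id=sample_id)
        if sp.n_snvs <= config.hypermutated_cutoff:
            spectra.append(sp)
    spec_mat = pd.DataFrame({sp.sample_id: sp.as_series() for sp in spectra})
    io.write_matrix(spec_mat, out / "spectrum96.tsv", index_label="class")
    total = spectrum.Spectrum96("cohort", spec_mat.sum(axis=1).to_numpy())
    n_ct, n_ct_cpg, frac_ct, frac_cpg = spectrum.ct_cpg_summary(total)
    tpt = spectrum.tpt_gpt_per_sample(spectra, config.tpt_flag_threshold)
    tpt.to_csv(out / "tpt_gpt.tsv", sep="\t", index=False)
    trend = spectrum.methylation_trend_analysis(
        track["level"].to_numpy(), mut_flags,
        np.linspace(0, 1, config.trend_bins + 1), sidedness=config.trend_side)
    manifest.counts["spectrum"] = {
        "samples": len(spectra), "snvs_classified": total.n_snvs,
        "n_ct": n_ct, "n_ct_cpg": n_ct_cpg,
        "fraction_ct": frac_ct, "fraction_cpg_of_ct": frac_cpg,
        "trend_Z": trend.Z, "trend_p": trend.p,
        "tpt_flagged": int(tpt["flagged"].sum()),
    }
    manifest.completed_stages.append("spectrum")
    log.info("stage=spectrum done snvs=%d trend_p=%.3g", total.n_snvs, trend.p)

    # --------------------------------------------------------------- associate
    log.info("stage=associate start")
    genes = [g for g, _, _, _ in panel]
    test_spec = [(g, "duration_months", "wilcoxon") for g in genes] + \
                [(g, "histology", "fisher") for g in genes]
    assoc_table = assoc.gene_clinical_association(result.mutation_table,
                                                  clinical, test_spec)
    assoc_table.to_csv(out / "associations.tsv", sep="\t", index=False)
    manifest.counts["associate"] = {"tests_run": int(len(assoc_table))}
    manifest.completed_stages.append("associate")
    log.info("stage=associate done tests=%d", len(assoc_table))

    # ----------------------------------------------------------------- cluster
    log.info("stage=cluster start")
    mat = expression.filter_expressed_all(expr)
    mat = expression.log_scale(mat)
    clusters = expression.ward_cluster(mat, k=config.cluster_k)
    clusters.assignments.rename("cluster").to_csv(out / "clusters.tsv", sep="\t",
                                                  index_label="sample_id")
    clusters.merge_table().to_csv(out / "merge_tree.tsv", sep="\t", index=False)
    # Wnt-pathway carriage of the expression samples: planted to mirror the
    # enrichment of Wnt mutations in the smaller subtype
    flags = pd.Series(np.where(expr_labels == "A", rng.random(len(expr_labels)) < 5 / 6,
                               rng.random(len(expr_labels)) < 2 / 11),
                      index=expr_labels.index)
    wnt_assoc = None
    if config.cluster_k == 2:
        wnt_assoc = expression.cluster_mutation_association(clusters, flags,
                                                            label="cluster~wnt")
    agree = _best_label_agreement(clusters.assignments, expr_labels)
    manifest.counts["cluster"] = {
        "samples": int(mat.shape[1]), "genes_used": int(mat.shape[0]),
        "label_agreement": agree,
        "wnt_association_p": wnt_assoc.p if wnt_assoc else None,
    }
    manifest.completed_stages.append("cluster")
    log.info("stage=cluster done agreement=%.2f", agree)


def _best_label_agreement(assignments: pd.Series, labels: pd.Series) -> float:
    """Fraction of samples on which a 2-clustering matches the true binary
    labels, maximized over the label swap."""
    a = (assignments.reindex(labels.index) == sorted(assignments.unique())[0])
    b = labels == sorted(labels.unique())[0]
    agree = float((a == b).mean())
    return max(agree, 1 - agree)
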