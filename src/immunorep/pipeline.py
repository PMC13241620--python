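"""End-to-end orchestration: read -> filter -> clonotype -> metrics ->
compare/correlate -> survival, with a manifest of hashed outputs and a
cohort-level detection summary."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import airr_io, clonotyping, metrics as metrics_mod, stats as stats_mod, survival as survival_mod
from .models import BCR_LOCI, LOCI

logger = logging.getLogger(__name__)

TCR_LOCI = tuple(l for l in LOCI if l not in BCR_LOCI)


@dataclass
class CohortSummary:
    n_cases: int
    n_with_bcr_only: int
    n_with_tcr_only: int
    n_with_both: int
    n_with_neither: int

    def __post_init__(self) -> None:
        parts = (
            self.n_with_bcr_only + self.n_with_tcr_only
            + self.n_with_both + self.n_with_neither
        )
        if parts != self.n_cases:
            raise ValueError(
                f"detection categories ({parts}) do not partition n_cases ({self.n_cases})"
            )

    @property
    def n_detectable(self) -> int:
        return self.n_with_bcr_only + self.n_with_tcr_only + self.n_with_both

    @property
    def pct_detectable(self) -> float:
        return round(100.0 * self.n_detectable / self.n_cases, 1)

    @property
    def pct_neither(self) -> float:
        return round(100.0 * self.n_with_neither / self.n_cases, 1)

    def as_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "n_with_bcr_only": self.n_with_bcr_only,
            "n_with_tcr_only": self.n_with_tcr_only,
            "n_with_both": self.n_with_both,
            "n_with_neither": self.n_with_neither,
            "n_detectable": self.n_detectable,
            "pct_detectable": self.pct_detectable,
            "pct_neither": self.pct_neither,
        }


def summarize_detection(metrics: pd.DataFrame) -> CohortSummary:
    """Classify each case by presence of BCR and/or TCR receptor reads."""
    bcr_only = tcr_only = both = neither = 0
    for _, sub in metrics.groupby("sample_id"):
        has_bcr = bool((sub.loc[sub["locus"].isin(BCR_LOCI), "abundance"] > 0).any())
        has_tcr = bool((sub.loc[sub["locus"].isin(TCR_LOCI), "abundance"] > 0).any())
        if has_bcr and has_tcr:
            both += 1
        elif has_bcr:
            bcr_only += 1
        elif has_tcr:
            tcr_only += 1
        else:
            neither += 1
    return CohortSummary(
        n_cases=bcr_only + tcr_only + both + neither,
        n_with_bcr_only=bcr_only,
        n_with_tcr_only=tcr_only,
        n_with_both=both,
        n_with_neither=neither,
    )


@dataclass
class PipelineConfig:
    repertoire_dir: str
    clinical_path: str
    output_dir: str
    expression_path: str | None = None
    gene_set_path: str | None = None
    library_reads_path: str | None = None
    bcr_identity_threshold: float = 0.90
    tcr_identity_threshold: float = 0.95
    gene_match_level: str = "gene"
    cpk_mode: str = "per_kiloread"
    entropy_base: str = "nats"
    min_samples: int = 3
    stage_coding: str = "ordinal"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for attr in ("repertoire_dir", "clinical_path"):
            path = getattr(self, attr)
            if not Path(path).exists():
                raise FileNotFoundError(f"{attr}: {path} does not exist")
        for attr in ("expression_path", "gene_set_path", "library_reads_path"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{attr}: {path} does not exist")
        for attr in ("bcr_identity_threshold", "tcr_identity_threshold"):
            value = getattr(self, attr)
            if not 0 < value <= 1:
                raise ValueError(f"{attr} must be in (0, 1], got {value}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log_settings(config: PipelineConfig) -> None:
    for key, value in dataclasses.asdict(config).items():
        logger.info("setting %s=%r", key, value)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the artifact manifest (path -> sha256)."""
    config.validate()
    _log_settings(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        # resolved config for provenance
        stage = "config"
        config_path = outdir / "resolved_config.yaml"
        config_path.write_text(yaml.safe_dump(dataclasses.asdict(config)))
        written.append(config_path)

        stage = "read"
        clinical = airr_io.read_clinical_table(config.clinical_path)
        library = {}
        if config.library_reads_path:
            lib_df = pd.read_csv(config.library_reads_path, sep="\t", dtype={"sample_id": str})
            library = dict(zip(lib_df["sample_id"], lib_df["library_reads"]))
        rep_paths = sorted(Path(config.repertoire_dir).glob("*.tsv"))
        repertoires = []
        for path in rep_paths:
            sid = path.name.split(".")[0]
            lib = int(library.get(sid, 10**9))
            repertoires.append(airr_io.read_airr_table(path, sid, lib))

        stage = "clonotype"
        cfg = clonotyping.ClonotypingConfig(
            bcr_identity_threshold=config.bcr_identity_threshold,
            tcr_identity_threshold=config.tcr_identity_threshold,
            gene_match_level=config.gene_match_level,
        )
        clone_sets = [
            clonotyping.assign_clones(airr_io.filter_productive(rep), cfg)
            for rep in repertoires
        ]
        clones_path = outdir / "clones.tsv"
        pd.concat(
            [clonotyping.clone_table(cs) for cs in clone_sets], ignore_index=True
        ).to_csv(clones_path, sep="\t", index=False)
        written.append(clones_path)

        stage = "metrics"
        lib_by_sample = {rep.sample_id: rep.library_reads for rep in repertoires}
        metrics = metrics_mod.metrics_table(
            clone_sets, lib_by_sample,
            cpk_mode=config.cpk_mode, entropy_base=config.entropy_base,
        )
        metrics_path = outdir / "metrics.tsv"
        metrics_mod.write_metrics(metrics, metrics_path)
        written.append(metrics_path)

        stage = "summary"
        summary = summarize_detection(metrics)
        summary_path = outdir / "summary.json"
        summary_path.write_text(json.dumps(summary.as_dict(), indent=1))
        written.append(summary_path)

        stage = "compare"
        comparisons = compare_phenotypes(metrics, clinical, min_samples=config.min_samples)
        comparisons_path = outdir / "comparisons.tsv"
        stats_mod.comparison_table(comparisons).to_csv(comparisons_path, sep="\t", index=False)
        written.append(comparisons_path)

        stage = "correlate"
        if config.expression_path:
            expr = pd.read_csv(config.expression_path, sep="\t", index_col=0)
            covariates = expr.T
            if config.gene_set_path:
                gene_sets = stats_mod.read_gene_sets(config.gene_set_path)
                for name, genes in gene_sets.items():
                    scores = stats_mod.signature_score(expr, genes, name=name)
                    covariates[name] = pd.Series(
                        {s.sample_id: s.score for s in scores}
                    )
            strata = clinical.set_index("sample_id")["phenotype"]
            correlations = stats_mod.spearman_matrix(metrics, covariates, strata)
            correlations_path = outdir / "correlations.tsv"
            stats_mod.correlation_table(correlations).to_csv(
                correlations_path, sep="\t", index=False
            )
            written.append(correlations_path)

        stage = "survival"
        surv = survival_summary(metrics, clinical, stage_coding=config.stage_coding)
        surv_path = outdir / "survival.json"
        surv_path.write_text(json.dumps(surv, indent=1, default=float))
        written.append(surv_path)
    except Exception as exc:
        partial = {str(p): _sha256(p) for p in written if p.exists()}
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    stage = "manifest"
    manifest = {str(p.relative_to(outdir)): _sha256(p) for p in written}
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest


def compare_phenotypes(
    metrics: pd.DataFrame, clinical: pd.DataFrame, min_samples: int = 3
) -> list:
    """LSP-vs-HSP Mann-Whitney per (metric, locus), BH within each metric family."""
    phenotype = clinical.set_index("sample_id")["phenotype"]
    merged = metrics.merge(
        phenotype.rename("phenotype"), left_on="sample_id", right_index=True
    )
    results = []
    for metric in ("abundance", "cpk", "entropy", "clonality"):
        family = f"LSP-vs-HSP:{metric}"
        family_results = []
        for locus in LOCI:
            sub = merged[merged["locus"] == locus]
            res = stats_mod.mann_whitney(
                sub.loc[sub["phenotype"] == "LSP", metric],
                sub.loc[sub["phenotype"] == "HSP", metric],
                metric=metric, locus=locus, grouping="LSP-vs-HSP",
                labels=("LSP", "HSP"), min_samples=min_samples,
            )
            res.family = family
            family_results.append(res)
        testable = [r for r in family_results if r.testable]
        if testable:
            import numpy as np

            adj = stats_mod.bh_adjust(
                [max(r.p_raw, np.nextafter(0, 1)) for r in testable]
            )
            for r, p in zip(testable, adj):
                r.p_adj = float(p)
        results.extend(family_results)
    return results


def survival_summary(
    metrics: pd.DataFrame, clinical: pd.DataFrame, stage_coding: str = "ordinal"
) -> dict:
    """KM curves (phenotype; median-dichotomized metrics within phenotype)
    and Cox batteries for abundance and entropy with chain interactions."""
    clin = clinical.copy()
    if "event" not in clin.columns:
        clin["event"] = clin["vital_status"].astype(int)
    out: dict = {"metadata": {
        "tie_handling": "efron",
        "stage_coding": stage_coding,
        "metric_scale": "log2(value+1)",
        "median_ties": "Low",
        "time_unit": "days",
    }}

    km = survival_mod.km_logrank(clin["os_days"], clin["event"], clin["phenotype"])
    out["km_phenotype"] = survival_mod.km_summary(km)

    wide = metrics.pivot_table(index="sample_id", columns="locus", values=["abundance", "entropy"])
    out["km_dichotomized"] = {}
    for metric in ("abundance", "entropy"):
        for locus in ("IGH", "TRB"):
            if (metric, locus) not in wide.columns:
                continue
            for phenotype in ("LSP", "HSP"):
                rows = clin[clin["phenotype"] == phenotype].set_index("sample_id")
                values = wide[(metric, locus)].reindex(rows.index)
                try:
                    labels = survival_mod.dichotomize_by_median(values.to_numpy())
                except (survival_mod.NotDichotomizableError, ValueError) as exc:
                    out["km_dichotomized"][f"{phenotype}:{locus}:{metric}"] = {
                        "not_dichotomizable": str(exc)
                    }
                    continue
                km = survival_mod.km_logrank(
                    rows["os_days"].to_numpy(), rows["event"].to_numpy(), labels
                )
                out["km_dichotomized"][f"{phenotype}:{locus}:{metric}"] = (
                    survival_mod.km_summary(km)
                )

    out["cox"] = {}
    interactions = [("IGH", "IGK"), ("IGH", "IGL"), ("TRA", "TRB")]
    for metric in ("abundance", "entropy"):
        cov = wide[metric][["IGH", "IGK", "IGL", "TRA", "TRB"]]
        try:
            results = survival_mod.cox_multivariate(
                clin, covariates=cov, interactions=interactions,
                stage_coding=stage_coding,
            )
            out["cox"][metric] = survival_mod.cox_table(results).to_dict(orient="records")
        except ValueError as exc:
            out["cox"][metric] = {"error": str(exc)}
    return out
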