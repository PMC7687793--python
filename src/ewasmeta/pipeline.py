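"""Configuration-driven orchestration of the full analysis:
QC -> per-cohort EWAS -> meta-analysis -> prior comparison -> annotation,
with provenance headers and a machine-readable exclusion log.

The pipeline can start either from simulated cohorts (a
:class:`~ewasmeta.simulate.SimulationConfig` block) or from cohort
directories written in the package's file formats, mirroring consortium
practice where cohorts run the EWAS stage locally and a coordinating
center runs the meta-analysis onward.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ewas import MODEL_SPECS, genomic_lambda, run_cohort_ewas
from .meta import manhattan_table, run_meta, volcano_table, write_metal
from .phenotypes import overweight_fraction
from .priors import PriorCpGSet, effect_correlation, enrichment_report
from .qc import filter_probes, validate_betas
from .references import IOTFCutoffs, LMSReference, load_synthetic_iotf, load_synthetic_lms
from .simulate import SimulationConfig, generate_consortium, generate_manifest, read_cohort
from .windows import nominal_neighbor_summary

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "Thresholds", "run_pipeline",
           "write_ewas_result", "read_ewas_result"]


@dataclass
class Thresholds:
    bonferroni_alpha: float = 0.05
    fdr_q: float = 0.05
    top_cutoffs: tuple = (1e-5, 0.05)
    i2_flag: float = 50.0
    overweight_flag: float = 0.30

    def validate(self):
        for name in ("bonferroni_alpha", "fdr_q"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"threshold {name}={v} outside (0, 1)")
        if not all(0 < c < 1 for c in self.top_cutoffs):
            raise ValueError("top_cutoffs must lie in (0, 1)")


@dataclass
class PipelineConfig:
    output_dir: str = "ewasmeta_output"
    models: list = field(default_factory=lambda: ["C"])
    subset_rules: list = field(default_factory=list)
    master_seed: int = 0
    simulation: SimulationConfig | None = None
    cohort_dirs: list | None = None
    manifest_path: str | None = None
    lms_path: str | None = None
    iotf_path: str | None = None
    prior_paths: list = field(default_factory=list)
    thresholds: Thresholds = field(default_factory=Thresholds)

    def validate(self):
        self.thresholds.validate()
        if self.simulation is None and not self.cohort_dirs:
            raise ValueError("config must provide either a simulation block or cohort_dirs")
        if self.cohort_dirs and self.manifest_path is None:
            raise ValueError("manifest_path is required when reading cohorts from files")
        for p in list(self.prior_paths) + (
            [self.manifest_path] if self.cohort_dirs else []
        ) + [self.lms_path, self.iotf_path]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        unknown = [m for m in self.models if m not in MODEL_SPECS]
        if unknown:
            raise ValueError(f"unknown model ids {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if d.get("simulation") is not None:
            sim = dict(d["simulation"])
            if "age_window" in sim:
                sim["age_window"] = tuple(sim["age_window"])
            d["simulation"] = SimulationConfig(**sim)
        if d.get("thresholds") is not None:
            th = dict(d["thresholds"])
            if "top_cutoffs" in th:
                th["top_cutoffs"] = tuple(th["top_cutoffs"])
            d["thresholds"] = Thresholds(**th)
        return cls(**d)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _header_lines(config: PipelineConfig, extra=()):
    return [
        f"ewasmeta {__version__}",
        f"config_digest {config.digest()}",
        f"timestamp {time.strftime('%Y-%m-%dT%H:%M:%S')}",
        *extra,
    ]


def write_ewas_result(df: pd.DataFrame, path, header_lines=()):
    """Cohort result file: tab-separated (cpg_id, beta, se, n, converged, p),
    effects on the native unit-beta scale."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("# encoding: beta and se per unit methylation beta (0-1); "
                 "robust=Huber t=1.345, MAD scale, asymptotic SE\n")
        df.to_csv(fh, sep="\t", index=False)


def read_ewas_result(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _log_record(log_fh, **record):
    log_fh.write(json.dumps(record, default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage for each selected model; returns a bundle dict.

    Outputs are written under ``config.output_dir``; rerunning with an
    identical config and inputs reproduces identical result tables
    (headers carry a timestamp, tables do not).  On failure a
    ``FAILED`` marker file is left next to any partial outputs.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    marker = out_dir / "FAILED"
    try:
        bundle = _run(config, out_dir)
        if marker.exists():
            marker.unlink()
        return bundle
    except Exception as exc:
        marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise


def _run(config: PipelineConfig, out_dir: Path) -> dict:
    lms = LMSReference.from_csv(config.lms_path) if config.lms_path else load_synthetic_lms()
    iotf = IOTFCutoffs.from_csv(config.iotf_path) if config.iotf_path else load_synthetic_iotf()

    if config.simulation is not None:
        sim = config.simulation
        cohorts = generate_consortium(sim, lms_ref=lms, iotf=iotf)
        manifest = (
            pd.read_csv(config.manifest_path)
            if config.manifest_path
            else generate_manifest(sim.n_probes, sim.master_seed)
        )
    else:
        cohorts = [read_cohort(d) for d in config.cohort_dirs]
        manifest = pd.read_csv(config.manifest_path)

    log_path = out_dir / "exclusions.log"
    bundle = {"models": {}, "lambdas": {}, "cohort_info": None}
    with open(log_path, "w") as log_fh:
        for ds in cohorts:
            validate_betas(ds.betas)

        # cohort-level characteristics for subsetting decisions
        info_rows = []
        for ds in cohorts:
            frac, flagged = overweight_fraction(ds.samples, iotf,
                                                config.thresholds.overweight_flag)
            info_rows.append(
                {
                    "cohort_id": ds.cohort_id,
                    "n": len(ds.samples),
                    "ancestry_label": ds.ancestry_label,
                    "selection_flag": ds.selection_flag,
                    "overweight_fraction": frac,
                    "overweight_flagged": flagged,
                }
            )
        cohort_info = pd.DataFrame(info_rows)
        cohort_info.to_csv(out_dir / "cohort_info.tsv", sep="\t", index=False)
        bundle["cohort_info"] = cohort_info

        presence = sum(
            (~ds.betas.isna()).any(axis=1).astype(int).reindex(manifest["cpg_id"], fill_value=0)
            for ds in cohorts
        )
        presence.index.name = "cpg_id"
        probe_table = filter_probes(manifest, presence)
        probe_table.to_csv(out_dir / "probe_filter.tsv", sep="\t")
        for cpg, row in probe_table[~probe_table["retained"]].iterrows():
            _log_record(log_fh, kind="probe_excluded", cpg_id=cpg,
                        reason=row["exclusion_reason"])
        retained = probe_table.index[probe_table["retained"]]

        priors = [PriorCpGSet.from_csv(p) for p in config.prior_paths]

        for model_id in config.models:
            spec = MODEL_SPECS[model_id]
            model_dir = out_dir / f"model_{model_id}"
            model_dir.mkdir(exist_ok=True)
            cohort_results = {}
            for ds in cohorts:
                res = run_cohort_ewas(
                    ds, spec, probes=retained, lms_ref=lms, iotf_cutoffs=iotf
                )
                if res.empty:
                    _log_record(log_fh, kind="cohort_excluded", model=model_id,
                                cohort_id=ds.cohort_id, reason="no_analyzable_probes")
                    continue
                cohort_results[ds.cohort_id] = res
                write_ewas_result(
                    res, model_dir / f"ewas_{ds.cohort_id}.tsv",
                    _header_lines(config, [f"model {model_id}", f"cohort {ds.cohort_id}"]),
                )
            if not cohort_results:
                raise RuntimeError(f"model {model_id}: no cohort produced results")

            min_studies = 2 if len(cohort_results) > 1 else 1
            variants = {"main": None}
            for rule in config.subset_rules:
                variants[rule] = rule
            for variant, rule in variants.items():
                try:
                    meta = run_meta(
                        cohort_results,
                        retained_probes=retained,
                        subset_rule=rule,
                        cohort_info=cohort_info,
                        min_studies=min_studies,
                        fdr_q=config.thresholds.fdr_q,
                        alpha=config.thresholds.bonferroni_alpha,
                    )
                except ValueError as exc:
                    _log_record(log_fh, kind="subset_skipped", model=model_id,
                                rule=rule, reason=str(exc))
                    continue
                meta = meta.join(probe_table["flags"], on="cpg_id")
                tag = f"{model_id}_{variant}"
                write_metal(meta, model_dir / f"meta_{tag}.tsv",
                            _header_lines(config, [f"model {model_id}", f"variant {variant}"]))
                if variant == "main":
                    bundle["models"][model_id] = meta
                    bundle["lambdas"][model_id] = genomic_lambda(meta["p"])
                    manhattan_table(meta, manifest).to_csv(
                        model_dir / f"manhattan_{model_id}.tsv", sep="\t", index=False)
                    volcano_table(meta).to_csv(
                        model_dir / f"volcano_{model_id}.tsv", sep="\t", index=False)
                    if priors:
                        rep = enrichment_report(meta, priors, config.thresholds.top_cutoffs)
                        rep.to_csv(model_dir / f"enrichment_{model_id}.tsv",
                                   sep="\t", index=False)
                        bundle.setdefault("enrichment", {})[model_id] = rep
                        _prior_correlations(meta, priors, model_dir, model_id, bundle)
                    _neighborhoods(meta, manifest, model_dir, model_id, bundle)

        with open(out_dir / "run_info.yaml", "w") as fh:
            yaml.safe_dump(
                {"version": __version__, "config_digest": config.digest(),
                 "master_seed": config.master_seed,
                 "lambdas": {k: float(v) for k, v in bundle["lambdas"].items()}},
                fh,
            )
    return bundle


def _prior_correlations(meta, priors, model_dir, model_id, bundle):
    by_cpg = meta.set_index("cpg_id")["pooled_beta_per10pct"]
    rows = []
    for prior in priors:
        if prior.effects is None:
            continue
        matched = [
            (e, by_cpg[c]) for c, e in zip(prior.cpg_ids, prior.effects) if c in by_cpg.index
        ]
        if len(matched) < 4:
            continue
        r, n, p = effect_correlation([m[0] for m in matched], [m[1] for m in matched])
        rows.append({"source": prior.source_label, "r": r, "n_pairs": n, "p": p})
    if rows:
        df = pd.DataFrame(rows)
        df.to_csv(model_dir / f"prior_correlation_{model_id}.tsv", sep="\t", index=False)
        bundle.setdefault("prior_correlation", {})[model_id] = df


def _neighborhoods(meta, manifest, model_dir, model_id, bundle):
    hits = meta.loc[meta["bonferroni_significant"] | meta["fdr_significant"], "cpg_id"]
    rows = []
    for cpg in hits:
        try:
            rows.append(nominal_neighbor_summary(cpg, meta, manifest))
        except KeyError:
            continue
    if rows:
        df = pd.DataFrame(rows)
        df.to_csv(model_dir / f"neighbors_{model_id}.tsv", sep="\t", index=False)
        bundle.setdefault("neighbors", {})[model_id] = df
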