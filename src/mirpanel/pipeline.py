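"""End-to-end orchestration: simulate → discover → validate → compare.

Mirrors the two-phase study design: a sequencing Discovery phase (count
filter, size factors, surrogate variables, per-subtype NB Wald DE and
predictive power, panel selection, endogenous-control screen) followed by
a qPCR Replica/Validation phase (ΔCt, ΔΔCt fold changes, adjusted
association and trend tests, Model 0/1 ROC comparison).  Every run writes
TSV/JSON outputs plus a manifest (config hash, seed) sufficient to
reproduce it exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import batch, counts, de, normsel, panel, pp, qpcr, roc, simulate

log = logging.getLogger("mirpanel")

SUBTYPES = ("NMIBC_G1G2", "NMIBC_G3", "MIBC")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All file paths and stage thresholds of a pipeline run."""

    counts_path: str = "counts.tsv"
    metadata_path: str = "metadata.tsv"
    ct_path: str = "ct.tsv"
    outdir: str = "results"
    seed: int = 0
    # discovery thresholds
    min_total: int = 20
    fdr_max: float = 0.05
    min_mean: float = 300.0
    pp_min: float = 0.70
    pp_scheme: str = "loocv"
    use_sv: bool = True
    max_sv: int = 5
    n_perm: int = 100
    # normalizer thresholds
    norm_min_reads: int = 2
    norm_max_log2_sd: float = 12.0
    norm_fc_low: float = -4.0
    norm_fc_high: float = 7.0
    norm_top_k: int = 2
    # validation
    trend_cases_only: bool = False
    subtypes: tuple[str, ...] = SUBTYPES
    manual_candidates: dict = field(default_factory=dict)
    # simulation (used by run_simulate)
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0.0 <= self.fdr_max <= 1.0:
            raise ConfigError("fdr_max must lie in [0, 1]")
        if not 0.0 <= self.pp_min <= 1.0:
            raise ConfigError("pp_min must lie in [0, 1]")
        if self.min_total < 0 or self.min_mean < 0:
            raise ConfigError("count thresholds must be non-negative")
        if self.pp_scheme not in ("loocv", "apparent"):
            raise ConfigError(f"unknown pp_scheme {self.pp_scheme!r}")
        bad = [s for s in self.subtypes if s not in SUBTYPES]
        if bad:
            raise ConfigError(f"unknown subtype(s) {bad}")

    def manifest(self) -> dict:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return {
            "config": dataclasses.asdict(self),
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "seed": self.seed,
        }


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_simulate(config: PipelineConfig) -> simulate.SimulationConfig:
    """Generate a synthetic cohort and write counts/metadata/Ct tables."""
    sim_kwargs = dict(config.simulation)
    sim_kwargs.setdefault("seed", config.seed)
    planted = [tuple(t) for t in sim_kwargs.pop("planted_de", [])]
    stable = list(sim_kwargs.pop("planted_stable", []))
    sim = simulate.SimulationConfig(
        planted_de=planted, planted_stable=stable, **sim_kwargs
    )
    cm, meta = simulate.generate_counts(sim)
    assays = sorted({mid for mid, _, _ in planted})
    controls = stable[: config.norm_top_k] if stable else []
    out = _outdir(config)
    counts.write_counts(cm, Path(config.counts_path))
    counts.write_metadata(meta, Path(config.metadata_path))
    if assays and controls:
        ct = simulate.generate_ct(sim, cm, meta, assays, controls)
        simulate.write_ct(ct, Path(config.ct_path))
    log.info(
        "simulate: %d miRNAs x %d samples (%d planted DE, %d stable)",
        cm.shape[0], cm.shape[1], len(planted), len(stable),
    )
    (out / "manifest.json").write_text(json.dumps(config.manifest(), indent=2))
    return sim


def run_discovery(config: PipelineConfig) -> dict:
    """Low-count filter, SV estimation, per-subtype DE+PP, panels, normalizers."""
    out = _outdir(config)
    cm = counts.read_counts(config.counts_path)
    meta = counts.read_metadata(config.metadata_path).aligned_to(cm)

    filtered = counts.filter_low_counts(cm, config.min_total)
    log.info("filter: %d/%d miRNAs with >= %d total reads",
             filtered.shape[0], cm.shape[0], config.min_total)
    sf = de.size_factors(filtered)

    sv = None
    if config.use_sv:
        sv = batch.estimate_sv(
            filtered, meta, max_sv=config.max_sv, n_perm=config.n_perm,
            seed=config.seed, sf=sf,
        )
        log.info("batch: %d surrogate variable(s)", sv.n_sv)

    panels: dict[str, panel.CandidatePanel] = {}
    for subtype in config.subtypes:
        if not (meta.classes == subtype).any():
            log.info("de/pp: no %s samples; skipped", subtype)
            continue
        de_res = de.nb_wald_test(filtered, meta, subtype, sv=sv)
        pp_res = pp.predictive_power(
            filtered, meta, subtype, scheme=config.pp_scheme
        )
        cp = panel.build_panel(
            de_res, pp_res, subtype=subtype,
            fdr_max=config.fdr_max, min_mean=config.min_mean,
            pp_min=config.pp_min,
            manual=list(config.manual_candidates.get(subtype, [])),
        )
        panels[subtype] = cp
        de.write_de(de_res, out / f"de_{subtype}.tsv")
        pp.write_pp(pp_res, out / f"pp_{subtype}.tsv")
        panel.write_panel(cp, out / f"panel_{subtype}.tsv")
        log.info(
            "%s vs control: |DE|=%d |PP|=%d |DE∩PP|=%d",
            subtype, cp.track_sizes["n_de"], cp.track_sizes["n_pp"],
            cp.track_sizes["n_intersection"],
        )

    if len(panels) >= 2:
        overlap = panel.cross_subtype_overlap(list(panels.values()))
        overlap.to_csv(out / "panel_overlap.tsv", sep="\t", index=False)

    ns = normsel.select_normalizers(
        filtered, sf,
        min_reads=config.norm_min_reads, max_log2_sd=config.norm_max_log2_sd,
        fc_low=config.norm_fc_low, fc_high=config.norm_fc_high,
        top_k=config.norm_top_k,
    )
    normsel.write_normalizers(ns, out / "normalizers.tsv")
    log.info("normalizers: %s", ns.selected)
    (out / "manifest.json").write_text(json.dumps(config.manifest(), indent=2))
    return {"panels": panels, "normalizers": ns, "sv": sv, "size_factors": sf}


def run_validation(
    config: PipelineConfig,
    panels: dict[str, panel.CandidatePanel],
    normalizers,
) -> dict:
    """ΔCt statistics, trend tests and the Model 0/1 ROC comparison."""
    out = _outdir(config)
    controls = list(normalizers)
    if not controls:
        raise ConfigError("no endogenous controls; provide an explicit list")
    meta = counts.read_metadata(config.metadata_path)
    ct = qpcr.read_ct(config.ct_path, controls=controls, spike_in="UniSp6")
    d = qpcr.delta_ct(ct)
    if d.excluded_samples:
        log.info("qpcr: %d sample(s) excluded (missing control Ct)",
                 len(d.excluded_samples))

    results = {}
    for subtype, cp in panels.items():
        assays = [a for a in cp.mirna_ids if a in d.values.columns]
        if not assays:
            continue
        sub = d.values[assays]
        lfc = qpcr.log2_fold_change(sub, meta, subtype)
        assoc = qpcr.association_test(sub, meta, subtype)
        table = assoc.copy()
        table.insert(0, "log2FC", lfc)
        qpcr.write_qpcr(table, out / f"qpcr_{subtype}.tsv")
        results[subtype] = table
        log.info("qpcr %s: %d assay(s), %d with p<0.05",
                 subtype, len(assays), int((assoc["p"] < 0.05).sum()))

    trend = qpcr.trend_test(d, meta, cases_only=config.trend_cases_only)
    qpcr.write_qpcr(trend, out / "trend.tsv")

    shared = sorted(
        set.intersection(*(set(p.mirna_ids) for p in panels.values()))
        & set(d.values.columns)
    ) if panels else []
    comparison = None
    if shared:
        comparison = roc.compare_models(d, meta, shared)
        (out / "model_comparison.json").write_text(
            json.dumps(comparison.as_dict(), indent=2)
        )
        log.info("models: AUC0=%.3f AUC1=%.3f DeLong p=%.4g",
                 comparison.auc0, comparison.auc1, comparison.delong_p)
    (out / "manifest.json").write_text(json.dumps(config.manifest(), indent=2))
    return {"qpcr": results, "trend": trend, "comparison": comparison}


def run_all(config: PipelineConfig) -> dict:
    """simulate (if configured) → discover → validate; returns the full report."""
    if config.simulation:
        run_simulate(config)
    disc = run_discovery(config)
    report: dict = {"discovery": disc}
    if Path(config.ct_path).exists() and disc["panels"]:
        controls = list(disc["normalizers"])
        if controls:
            report["validation"] = run_validation(
                config, disc["panels"], disc["normalizers"]
            )
    return report
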