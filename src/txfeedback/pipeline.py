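"""End-to-end orchestration: simulate -> preprocess -> factorize -> enrich -> signature -> survey.

A single master seed deterministically spawns per-stage seeds (SeedSequence
of ``[master, stage_index]``), so any stage can be re-run in isolation with
identical results.  Every stage writes its tables under the run directory;
the run report (JSON) records per-stage status and headline statistics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alterations as alt
from . import enrich, factorization, io, preprocess, signature, synthetic
from .errors import TxFeedbackError

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "factorize", "enrich", "signature", "survey")

#: Default gene families for the synthetic alteration survey, mirroring an
#: EGFR-network node list.
DEFAULT_FAMILIES = {
    "EGFR": ["EGFR"],
    "RAS": ["HRAS", "KRAS", "NRAS"],
    "PI3K": ["PIK3CA", "PIK3CB", "PIK3CG", "PIK3CD"],
    "AKT": ["AKT1", "AKT2", "AKT3"],
    "RAF": ["BRAF", "ARAF"],
    "NF-KB": ["NFKB1", "NFKB2", "RELA", "RELB"],
}

DEFAULT_EVENT_RATES = {
    "EGFR": {"mutation": 0.04, "amplification": 0.08},
    "HRAS": {"mutation": 0.03}, "KRAS": {"mutation": 0.15}, "NRAS": {"mutation": 0.02},
    "PIK3CA": {"mutation": 0.18, "amplification": 0.05}, "PIK3CB": {"mutation": 0.01},
    "PIK3CG": {"mutation": 0.02}, "PIK3CD": {"mutation": 0.01},
    "AKT1": {"mutation": 0.02}, "AKT2": {"amplification": 0.03}, "AKT3": {"mutation": 0.01},
    "BRAF": {"mutation": 0.05}, "ARAF": {"mutation": 0.01},
    "NFKB1": {"mutation": 0.02}, "NFKB2": {"mutation": 0.01},
    "RELA": {"mutation": 0.02}, "RELB": {"mutation": 0.01},
}


@dataclass
class PipelineConfig:
    """Resolved parameters for a full pipeline run."""

    outdir: str = "results/run"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    sim: dict = field(default_factory=dict)          # SimConfig overrides
    floor_fraction: float = 0.05
    logfc_min: float = 0.5
    k: int | None = None                             # fixed k; None => scan
    k_range: tuple[int, int] = (2, 6)
    n_runs: int = 3
    n_iter: int = 50_000
    n_draws: int = 50
    scan_sweeps: int = 300
    robustness_threshold: float = 0.9
    n_perm: int = 10_000
    clustering: dict = field(default_factory=lambda: {"method": "average",
                                                      "metric": "euclidean"})
    survey_n_samples: int = 200
    survey_tumor_types: tuple[str, ...] = ("TYPE_A", "TYPE_B")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise TxFeedbackError(f"unknown config keys: {sorted(unknown)}")
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        if "survey_tumor_types" in raw:
            raw["survey_tumor_types"] = tuple(raw["survey_tumor_types"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        d["survey_tumor_types"] = list(self.survey_tumor_types)
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(config: PipelineConfig) -> list[str]:
    """Human-readable list of content problems; empty when valid."""
    issues = []
    if config.floor_fraction <= 0:
        issues.append(f"floor_fraction must be > 0 (got {config.floor_fraction})")
    if config.logfc_min < 0:
        issues.append(f"logfc_min must be >= 0 (got {config.logfc_min})")
    lo, hi = config.k_range
    if lo > hi:
        issues.append(f"k_range {lo}:{hi} is empty")
    if lo < 1:
        issues.append("k_range lower bound must be >= 1")
    if config.k is not None and config.k < 1:
        issues.append(f"k must be >= 1 (got {config.k})")
    if config.n_runs < 2:
        issues.append(f"n_runs must be >= 2 (got {config.n_runs})")
    if config.n_draws < 2:
        issues.append(f"n_draws must be >= 2 (got {config.n_draws})")
    if config.n_perm < 1:
        issues.append(f"n_perm must be >= 1 (got {config.n_perm})")
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        issues.append(f"unknown stages: {sorted(unknown)}")
    try:
        synthetic.SimConfig(**dict(config.sim, seed=0))
    except Exception as exc:  # content problem, not I/O
        issues.append(f"sim config invalid: {exc}")
    return issues


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return int(np.random.SeedSequence([master, STAGES.index(stage)])
               .generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute enabled stages in dependency order; returns the run report.

    A failed stage is recorded in the report and its dependents are skipped;
    the report's ``ok`` flag turns false.
    """
    issues = validate_config(config)
    if issues:
        raise TxFeedbackError("invalid config: " + "; ".join(issues))
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "config_hash": config.content_hash(),
                    "master_seed": config.seed, "stages": {}, "ok": True}
    enabled = {s for s in STAGES if config.stages.get(s, False)}
    state: dict = {}

    def run_stage(name, deps, fn):
        entry = {"status": "disabled"}
        if name in enabled:
            missing = [d for d in deps if d not in state]
            if missing:
                entry = {"status": "skipped", "missing_dependencies": missing}
                report["ok"] = False
            else:
                try:
                    entry = {"status": "ok", **(fn() or {})}
                except Exception as exc:
                    logger.exception("stage %s failed", name)
                    entry = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
                    report["ok"] = False
        report["stages"][name] = entry

    def do_simulate():
        sim_cfg = synthetic.SimConfig(**dict(config.sim, seed=stage_seed(config.seed, "simulate")))
        truth = synthetic.generate_truth(sim_cfg)
        bundle = synthetic.simulate_expression(truth, sim_cfg)
        state.update(sim_cfg=sim_cfg, truth=truth, bundle=bundle)
        data_dir = outdir / "data"
        io.write_bundle(bundle, data_dir)
        io.write_gmt(truth.tf_targets, data_dir / "tf_targets.gmt")
        io.write_survival(truth.survival_true, data_dir / "survival.tsv")
        io.write_json({"reference": truth.signature_truth["reference"],
                       "up": truth.signature_truth["up"],
                       "down": truth.signature_truth["down"]},
                      data_dir / "signature_truth.json")
        truth.P_true.rename_axis("pattern").to_csv(data_dir / "P_true.tsv", sep="\t")
        truth.A_true.rename_axis("gene").to_csv(data_dir / "A_true.tsv", sep="\t")
        return {"n_genes": sim_cfg.n_genes, "n_samples": bundle.values.shape[1]}

    def do_preprocess():
        bundle = state["bundle"]
        collapsed = preprocess.collapse_probes(bundle) if bundle.probe_map is not None else bundle
        fi = preprocess.condition_stats(collapsed)
        fi = preprocess.apply_uncertainty_floor(fi, fraction=config.floor_fraction)
        fi = preprocess.filter_genes(fi, state["truth"].tf_targets, logfc_min=config.logfc_min)
        state.update(collapsed=collapsed, fi=fi)
        io.write_factor_input(fi, outdir / "factor_input")
        return {"filter_report": fi.meta.get("filter_report", {})}

    def do_factorize():
        fi = state["fi"]
        seed = stage_seed(config.seed, "factorize")
        info: dict = {}
        k = config.k
        if k is None:
            lo, hi = config.k_range
            sel = factorization.select_dimension(
                fi, k_range=range(lo, hi + 1), n_runs=config.n_runs, seed=seed,
                threshold=config.robustness_threshold, n_iter=config.scan_sweeps)
            k = sel.k
            info["selected_k"] = sel.k
            info["robustness"] = {str(kk): v for kk, v in sel.robustness.items()}
            info["robustness_warning"] = sel.warning
        result = factorization.factorize(fi, k, n_iter=config.n_iter, seed=seed,
                                     n_draws=config.n_draws)
        state["result"] = result
        fac_dir = outdir / "factorization"
        fac_dir.mkdir(parents=True, exist_ok=True)
        result.A.rename_axis("gene").to_csv(fac_dir / "A.tsv", sep="\t")
        result.P.rename_axis("pattern").to_csv(fac_dir / "P.tsv", sep="\t")
        info.update(k=k, chi2=result.chi2, n_sweeps=result.n_sweeps,
                    converged=result.converged)
        matching = factorization.match_patterns(state["truth"].P_true, result.P)
        info["match_to_planted"] = {
            state["truth"].P_true.index[i]: {"pattern": result.P.index[j], "r": r}
            for (i, j), r in zip(matching.pairs, matching.correlations)}
        state["matching"] = matching
        return info

    def do_enrich():
        result = state["result"]
        truth = state["truth"]
        Z = enrich.compute_zscores(result)
        Z.rename_axis("gene").to_csv(outdir / "factorization" / "zscores.tsv", sep="\t")
        state["Z"] = Z
        seed = stage_seed(config.seed, "enrich")
        sets = enrich.resolve_gene_sets(truth.tf_targets, Z.index)
        table = []
        for i, (tf, members) in enumerate(sorted(sets.items())):
            for pattern in Z.columns:
                res = enrich.gene_set_statistic(Z, members, pattern,
                                                n_perm=config.n_perm,
                                                seed=seed + i)
                table.append({"tf": tf, "pattern": pattern,
                              "statistic": res.statistic, "p_value": res.p_value})
        set_table = pd.DataFrame(table)
        set_table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        reference = truth.signature_truth["reference"]
        assoc = pd.DataFrame()
        if reference in Z.index:
            corr = enrich.gene_correlation_profile(Z, reference)
            assoc = enrich.tf_association(corr, sets, reference)
            assoc.to_csv(outdir / "tf_association.tsv", sep="\t", index=False)
        state.update(set_table=set_table, assoc=assoc)
        return {"top_associations": assoc.head(5).to_dict(orient="records")}

    def do_signature():
        truth = state["truth"]
        changes = signature.treatment_changes(state["collapsed"],
                                              control_treatment=state["sim_cfg"].control)
        reference = truth.signature_truth["reference"]
        targets = sorted(truth.tf_targets.get("AP2A", set()) & set(changes.index))
        sig = signature.build_signature(changes, targets, reference,
                                        **config.clustering)
        res, ranked = signature.signature_enrichment(changes, sig)
        io.write_signature(sig, outdir / "signature.json")
        ranked.rename_axis("gene").to_csv(outdir / "signature_ranking.tsv", sep="\t")
        feedback = _feedback_pattern(state["result"], state["sim_cfg"])
        r, p = signature.pattern_delta_survival(state["result"], truth.survival_true,
                                                feedback,
                                                control_treatment=state["sim_cfg"].control)
        state.update(sig=sig, changes=changes)
        return {"n_up": len(sig.up), "n_down": len(sig.down),
                "enrichment_p": res.p_value, "feedback_pattern": feedback,
                "delta_survival_r": r, "delta_survival_p": p}

    def do_survey():
        seed = stage_seed(config.seed, "survey")
        tables = []
        for i, tt in enumerate(config.survey_tumor_types):
            tables.append(synthetic.simulate_alterations(
                config.survey_n_samples, DEFAULT_EVENT_RATES, seed=seed + i,
                tumor_type=tt))
        table = pd.concat(tables, ignore_index=True)
        io.write_alterations(table, outdir / "alterations.tsv")
        nodes = alt.collapse_families(table, DEFAULT_FAMILIES)
        freqs = alt.alteration_frequency(nodes)
        summary = pd.DataFrame({"mean_pct_across_types": alt.average_across_types(freqs),
                                "pooled_pct": alt.pooled_frequency(nodes)})
        freqs.rename_axis("tumor_type").to_csv(outdir / "alteration_frequencies.tsv", sep="\t")
        summary.rename_axis("node").to_csv(outdir / "alteration_summary.tsv", sep="\t")
        return {"mean_pct_across_types": summary["mean_pct_across_types"].round(2).to_dict()}

    run_stage("simulate", [], do_simulate)
    run_stage("preprocess", ["bundle", "truth"], do_preprocess)
    run_stage("factorize", ["fi"], do_factorize)
    run_stage("enrich", ["result", "truth"], do_enrich)
    run_stage("signature", ["collapsed", "result", "truth"], do_signature)
    run_stage("survey", [], do_survey)

    io.write_json(report, outdir / "run_report.json")
    return report


def _feedback_pattern(result, sim_cfg) -> str:
    """Pick the treatment-induced pattern: largest mean treated-minus-control delta."""
    P = result.P
    deltas = {}
    for name in P.index:
        row = P.loc[name]
        vals = []
        for bg in sim_cfg.backgrounds:
            ctrl = row[preprocess.condition_label(bg, sim_cfg.control)]
            for drug in sim_cfg.drugs:
                vals.append(row[preprocess.condition_label(bg, drug)] - ctrl)
        deltas[name] = float(np.mean(vals))
    return max(deltas, key=deltas.get)
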