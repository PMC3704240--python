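"""End-to-end analysis pipeline: normalize -> summarize/test -> classify ->
Bateman-Mukai -> (optional) ML -> pleiotropy, emitting structured JSON
reports per stage plus a combined human-readable summary."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bateman_mukai import bm_table
from .data import FitnessTable, read_fitness_table, relative_fitness, summarize
from .groupstats import classify_lines, count_calls, trait_comparison_battery
from .ml_effects import LikelihoodSettings, MutationEffectsModel
from .pleiotropy import pleiotropy_analysis

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Configuration for a full pipeline run."""

    table_path: str | None = None
    out_dir: str = "ma_results"
    G: int = 994
    alpha: float = 0.05
    family_size: int | None = None  # None -> all tested lines
    n_sims: int = 1000
    seed: int = 1
    run_ml: bool = False  # the slow stage, off unless asked
    ml_settings: LikelihoodSettings = field(default_factory=LikelihoodSettings)

    def digest(self) -> str:
        """Hash of the analysis-relevant settings (paths excluded, so the
        same analysis written to two directories hashes identically)."""
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if k not in ("table_path", "out_dir")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def _write_json(path: Path, payload: dict, meta: dict) -> None:
    out = {"meta": meta}
    out.update(_jsonable(payload))
    path.write_text(json.dumps(out, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: AnalysisConfig, table: FitnessTable | None = None) -> dict:
    """Run all stages in order; stage outputs are written under
    ``config.out_dir`` and also returned.  Deterministic given the seed."""
    if table is None:
        if config.table_path is None:
            raise ValueError("config.table_path or an in-memory table is required")
        table = read_fitness_table(config.table_path, schema={"G": config.G})
    table.validate_ancestry()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"version": __version__, "seed": config.seed,
            "config_hash": config.digest(), "G": config.G}
    logger.info("pipeline start (hash %s, seed %d)", meta["config_hash"], config.seed)

    rel = relative_fitness(table)
    report: dict = {"meta": meta}

    # stage 1: group summaries + nonparametric test battery (means/variances)
    stage = "group_summary"
    try:
        summaries = {}
        for trait in rel.traits:
            s = summarize(rel, trait)
            tests = trait_comparison_battery(rel, trait)
            summaries[trait] = {
                "summaries": {g: dataclasses.asdict(v) for g, v in s.items()},
                "tests": {name: dataclasses.asdict(t) for name, t in tests.items()},
            }
        report["group_summary"] = summaries
        _write_json(out_dir / "group_summary.json", {"traits": summaries}, meta)
    except Exception:
        logger.exception("stage %s failed", stage)
        raise RuntimeError(f"pipeline stage failed: {stage}")

    # stage 2: per-line classification (confidence band, low/high counts)
    stage = "classification"
    try:
        classification = {}
        all_calls = []
        for trait in rel.traits:
            calls, bounds = classify_lines(rel, trait, alpha=config.alpha,
                                           family_size=config.family_size)
            all_calls.extend(calls)
            low, high = count_calls(calls)
            classification[trait] = {
                "lower_bound": bounds[0], "upper_bound": bounds[1],
                "low": low, "high": high,
                "calls": [dataclasses.asdict(c) for c in calls],
            }
        report["classification"] = classification
        _write_json(out_dir / "classification.json", {"traits": classification}, meta)
    except Exception:
        logger.exception("stage %s failed", stage)
        raise RuntimeError(f"pipeline stage failed: {stage}")

    # stage 3: Bateman-Mukai estimates
    stage = "bateman_mukai"
    try:
        bm = bm_table(table, G=config.G)
        report["bateman_mukai"] = {e.trait: dataclasses.asdict(e) for e in bm}
        _write_json(out_dir / "bateman_mukai.json", report["bateman_mukai"], meta)
    except Exception:
        logger.exception("stage %s failed", stage)
        raise RuntimeError(f"pipeline stage failed: {stage}")

    # stage 4 (optional): ML mutation-parameter fits
    if config.run_ml:
        stage = "ml_fit"
        try:
            ml = {}
            for trait in rel.traits:
                model = MutationEffectsModel(
                    rel.ancestor_values(trait),
                    rel.line_means(trait, "MA").to_numpy(float),
                    G=config.G, settings=config.ml_settings)
                res = model.fit()
                ml[trait] = {
                    "U": res.U, "E_a": res.mean_effect,
                    "P": res.params_hat.P, "beta": res.params_hat.beta,
                    "sigma_env": res.params_hat.sigma_env,
                    "loglik": res.loglik, "ridge": res.ridge,
                    "flat_surface": res.flat_surface,
                    "support_intervals": {
                        k: dataclasses.asdict(v)
                        for k, v in res.support_intervals.items()},
                }
            report["ml_fit"] = ml
            _write_json(out_dir / "ml_fit.json", ml, meta)
        except Exception:
            logger.exception("stage %s failed", stage)
            raise RuntimeError(f"pipeline stage failed: {stage}")

    # stage 5: pleiotropy (needs at least two traits to correlate)
    stage = "pleiotropy"
    try:
        if len(rel.traits) < 2:
            report["pleiotropy"] = {"skipped": "fewer than two traits"}
            _write_json(out_dir / "pleiotropy.json", report["pleiotropy"], meta)
            (out_dir / "summary.txt").write_text(render_summary(report))
            _write_json(out_dir / "report.json", report, meta)
            return report
        line_means = pd.DataFrame({
            t: rel.line_means(t, "MA") for t in rel.traits}).dropna()
        calls = []
        for trait in rel.traits:
            c, _ = classify_lines(rel, trait, alpha=config.alpha,
                                  family_size=config.family_size)
            calls.extend(c)
        pleio = pleiotropy_analysis(line_means, calls, n_lines=rel.n_ma,
                                    G=config.G, n_sims=config.n_sims,
                                    seed=config.seed)
        payload = {
            "n_eff": pleio.n_eff, "var_lambda": pleio.var_lambda,
            "eigenvalues": pleio.eigenvalues,
            "spearman": pleio.spearman,
            "observed_counts": pleio.observed_counts,
            "expected_counts": pleio.expected_counts,
            "chi2": pleio.chi2, "df": pleio.df, "p_value": pleio.p_value,
            "test_a_significant": pleio.test_a.n_significant_sims,
            "test_b_significant": pleio.n_significant_sims,
            "n_sims": pleio.n_sims,
        }
        report["pleiotropy"] = _jsonable(payload)
        _write_json(out_dir / "pleiotropy.json", payload, meta)
    except Exception:
        logger.exception("stage %s failed", stage)
        raise RuntimeError(f"pipeline stage failed: {stage}")

    (out_dir / "summary.txt").write_text(render_summary(report))
    _write_json(out_dir / "report.json", report, meta)
    return report


def render_summary(report: dict) -> str:
    """Human-readable digest of a pipeline report."""
    lines = ["MA fitness analysis summary",
             f"(version {report['meta']['version']}, seed {report['meta']['seed']}, "
             f"config {report['meta']['config_hash']})", ""]
    lines.append(f"{'trait':<22}{'anc mean':>9}{'MA mean':>9}{'MA var':>9}"
                 f"{'low':>5}{'high':>5}{'BM E(a)':>9}{'BM U':>9}")
    gs = report.get("group_summary", {})
    cls = report.get("classification", {})
    bm = report.get("bateman_mukai", {})
    for trait in gs:
        s = gs[trait]["summaries"]
        anc = s.get("ancestor", {})
        ma = s.get("MA", {})
        c = cls.get(trait, {})
        b = bm.get(trait, {})
        ea = b.get("E_a")
        u = b.get("U_per_gen")
        lines.append(
            f"{trait:<22}{anc.get('mean', float('nan')):>9.3f}"
            f"{ma.get('mean', float('nan')):>9.3f}"
            f"{(ma.get('variance') or float('nan')):>9.4f}"
            f"{c.get('low', 0):>5d}{c.get('high', 0):>5d}"
            f"{(ea if ea is not None else float('nan')):>9.3f}"
            f"{(u if u is not None else float('nan')):>9.4f}")
    pl = report.get("pleiotropy", {})
    if pl and "n_eff" in pl:
        lines += ["", f"effective number of traits N_eff = {pl['n_eff']:.2f}",
                  f"randomization A: {pl['test_a_significant']}/{pl['n_sims']} "
                  "simulations significant",
                  f"randomization B: {pl['test_b_significant']}/{pl['n_sims']} "
                  "simulations significant"]
    return "\n".join(lines) + "\n"
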