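"""End-to-end orchestration: simulate -> structure -> kinship -> association
scans (4 models) -> random forest -> network -> method comparison.

Every stage writes its outputs under the run directory, a manifest records a
content hash for each artifact, and per-stage seeds are derived from the
global seed by stable hashing of stage names so adding a stage never perturbs
another stage's random stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, kinship, netstats, popstruct, rf_assoc, simdata

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ComparisonReport", "run", "report_table", "stage_seed"]


@dataclass
class PipelineConfig:
    sim: simdata.SimConfig | None = None
    marker_path: str | None = None
    phenotype_path: str | None = None
    outdir: str = "qkforest_run"
    seed: int = 0
    min_freq: float = 0.10
    structure_k: int = 4
    structure_iters: int = 2000
    structure_burnin: int = 500
    kinship_estimator: str = "freqcorr"
    alpha: float = 0.05
    correction: str = "bh"  # or "maxt"
    n_perm: int = 500
    rf_trees: int = 500
    rf_perm: int = 200
    rf_perm_trees: int | None = None
    run_rf: bool = True
    run_network: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_paths = self.marker_path is not None and self.phenotype_path is not None
        if (self.sim is None) == (not has_paths):
            raise ValueError("provide exactly one of a SimConfig or input paths")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.correction not in ("bh", "maxt"):
            raise ValueError("correction must be 'bh' or 'maxt'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        sim = None
        if sim_raw is not None:
            if "causal_effects" in sim_raw:
                sim_raw["causal_effects"] = {
                    int(k): float(v) for k, v in sim_raw["causal_effects"].items()}
            sim = simdata.SimConfig(**sim_raw)
        return cls(sim=sim, **raw)


@dataclass
class ComparisonReport:
    """Per trait x method significant-marker counts and RF/model overlaps."""

    counts: pd.DataFrame          # rows: method, cols: traits
    overlaps: pd.DataFrame        # long-format per trait RF-vs-model overlaps
    marker_table: pd.DataFrame    # marker-level long table
    sets: dict = field(default_factory=dict)  # (trait, method) -> set of markers


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: blake2 hash of the stage name mixed with the
    global seed."""
    h = hashlib.blake2b(f"{stage}".encode(), digest_size=4).hexdigest()
    return (int(h, 16) ^ (global_seed * 2654435761)) % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline halted at stage {stage!r}: {cause}")
        self.stage = stage


def run(config: PipelineConfig) -> ComparisonReport:
    """Execute the full pipeline; artifacts land under ``config.outdir``.

    Reruns with the same config are bitwise identical.  A stage failure halts
    the pipeline with the failing stage named; earlier outputs are preserved.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def _save(obj, name: str):
        path = out / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, sep="\t")
        else:
            simdata.write_matrix(obj, path)
        artifacts.append(path)
        return path

    # --- stage: input / simulate
    stage = "simulate"
    try:
        if config.sim is not None:
            markers, pheno, truth = simdata.simulate_dataset(config.sim)
            simdata.write_truth(truth, out / "truth", config.sim)
            _save(markers, "markers.tsv")
            _save(pheno, "phenotypes.tsv")
        else:
            markers = simdata.read_marker_matrix(config.marker_path)
            pheno = simdata.read_phenotype_table(config.phenotype_path)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stage: preprocess
    stage = "filter"
    try:
        structure_markers = simdata.most_frequent_allele_subset(markers)
        assoc_markers = simdata.filter_markers(markers, min_freq=config.min_freq)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stage: structure
    stage = "structure"
    try:
        Q = popstruct.estimate_admixture(
            structure_markers, K=config.structure_k,
            n_iter=config.structure_iters, burnin=config.structure_burnin,
            seed=stage_seed(config.seed, stage))
        _save(Q.to_frame(), "Q.tsv")
        labels = popstruct.assign_members(Q)
        labels.to_csv(out / "labels.tsv", sep="\t", index=False)
        artifacts.append(out / "labels.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stage: kinship
    stage = "kinship"
    try:
        if config.kinship_estimator == "jaccard":
            K = kinship.kinship_jaccard(structure_markers)
        else:
            K = kinship.kinship_freq_corrected(assoc_markers)
        _save(K.to_frame(), "kinship.tsv")
        kinship.kinship_histogram(K).to_csv(out / "kinship_hist.tsv", sep="\t",
                                            index=False)
        artifacts.append(out / "kinship_hist.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # mixed models need a PSD covariance; truncation can break that mildly
    from .simdata import _psd_sqrt
    L, _ = _psd_sqrt(K.values)
    Kpsd = L @ L.T

    # --- stage: association scans
    stage = "assoc"
    counts: dict[str, dict[str, int]] = {}
    sets: dict[tuple[str, str], set[str]] = {}
    scan_rows = []
    model4_scans = []
    try:
        for t, trait in enumerate(pheno.trait_names):
            yv = pheno.values[:, t]
            scans = {
                "model1": assoc.scan_naive(assoc_markers, yv, trait=trait),
                "model2": assoc.scan_q(assoc_markers, yv, Q, trait=trait),
                "model3": assoc.scan_mixed(assoc_markers, yv, Kpsd, trait=trait),
                "model4": assoc.scan_mixed(assoc_markers, yv, Kpsd, Q=Q, trait=trait),
            }
            for name, scan in scans.items():
                if config.correction == "bh":
                    scan.p_adj = assoc.adjust_fdr(scan.p_raw)
                    scan.adjust_method = "bh"
                else:
                    res = assoc.adjust_resampling(
                        assoc_markers, yv, scan.model, n_perm=config.n_perm,
                        seed=stage_seed(config.seed, f"maxt:{trait}:{name}"),
                        Q=Q if scan.model.uses_Q else None,
                        K=Kpsd if scan.model.uses_K else None)
                    scan.p_adj = res.p_adj
                    scan.adjust_method = "maxT"
                sets[(trait, name)] = scan.significant(config.alpha)
                counts.setdefault(name, {})[trait] = len(sets[(trait, name)])
                scan_rows.append(scan.to_frame())
            model4_scans.append(scans["model4"])
        marker_table = pd.concat(scan_rows, ignore_index=True)
        marker_table.to_csv(out / "scans.tsv", sep="\t", index=False)
        artifacts.append(out / "scans.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stage: random forest
    stage = "rf"
    rf_results = {}
    try:
        if config.run_rf:
            for t, trait in enumerate(pheno.trait_names):
                cfg = rf_assoc.RFConfig(
                    n_trees=config.rf_trees, n_perm=config.rf_perm,
                    perm_trees=config.rf_perm_trees or config.rf_trees,
                    alpha=config.alpha,
                    seed=stage_seed(config.seed, f"rf:{trait}"))
                res = rf_assoc.rf_permutation_scan(assoc_markers,
                                                   pheno.values[:, t], cfg,
                                                   trait=trait)
                rf_results[trait] = res
                sets[(trait, "RF")] = res.significant_set()
                counts.setdefault("RF", {})[trait] = len(sets[(trait, "RF")])
                res.to_frame().to_csv(out / f"rf_{trait}.tsv", sep="\t", index=False)
                artifacts.append(out / f"rf_{trait}.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stage: network
    stage = "network"
    try:
        if config.run_network and pheno.values.shape[1] >= 2:
            method = ("inverse" if pheno.values.shape[0] > pheno.values.shape[1] + 2
                      else "shrinkage")
            pc = netstats.partial_correlation(pheno, method=method)
            G = netstats.build_network(pc, model4_scans, alpha=config.alpha)
            netstats.write_pajek(G, out / "network.net")
            netstats.write_edgelist(G, out / "network_edges.tsv")
            netstats.write_vertex_table(G, out / "network_vertices.tsv")
            artifacts += [out / "network.net", out / "network_edges.tsv",
                          out / "network_vertices.tsv"]
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stage: compare/report
    stage = "report"
    try:
        overlap_rows = []
        for trait in pheno.trait_names:
            rf_set = sets.get((trait, "RF"), set())
            for name in ("model1", "model3", "model4"):
                mset = sets.get((trait, name), set())
                overlap_rows.append({
                    "trait": trait, "method": f"RF-{name}",
                    "overlap": len(rf_set & mset),
                })
        overlaps = pd.DataFrame(overlap_rows)
        count_df = pd.DataFrame(counts).T.reindex(
            [m for m in ("model1", "model2", "model3", "model4", "RF")
             if m in counts])
        count_df = count_df[pheno.trait_names].fillna(0).astype(int)
        report = ComparisonReport(counts=count_df, overlaps=overlaps,
                                  marker_table=marker_table, sets=sets)
        grid = report_table(report)
        grid.to_csv(out / "report.tsv", sep="\t")
        (out / "report.txt").write_text(grid.to_string() + "\n")
        artifacts += [out / "report.tsv", out / "report.txt"]

        manifest = {
            "seed": config.seed,
            "alpha": config.alpha,
            "correction": config.correction,
            "artifacts": {str(p.relative_to(out)): _sha256(p)
                          for p in sorted(set(artifacts))},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True) + "\n")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    return report


def report_table(report: ComparisonReport) -> pd.DataFrame:
    """Comparison grid: methods (and RF-model overlaps) x traits."""
    traits = list(report.counts.columns)
    rows = {}
    for method in report.counts.index:
        rows[method] = report.counts.loc[method]
    for name in ("RF-model1", "RF-model3", "RF-model4"):
        sub = report.overlaps[report.overlaps["method"] == name]
        if not sub.empty:
            rows[name] = sub.set_index("trait")["overlap"].reindex(traits).fillna(0).astype(int)
    return pd.DataFrame(rows).T[traits]
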