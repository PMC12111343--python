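"""Config-driven orchestration: simulate -> preprocess -> DE (all
comparisons) -> pairs -> enrichment -> clustering -> concordance.

Every stage logs the feature counts entering and surviving its filters
(console + ``run.log``), writes TSV/JSON artifacts into one results
directory, and the whole run is reproducible: a single config seed feeds a
named substream per stage, and re-running with the same config and seed
produces byte-identical outputs (``run.log`` carries wall-clock timestamps
and is the one exception).
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_data import (
    Comparison,
    ExpressionMatrix,
    SampleDesign,
    read_design,
    read_expression_matrix,
    read_gene_sets,
    read_target_table,
    write_design,
    write_expression_matrix,
    write_gene_sets,
    write_target_table,
)
from .coexpression import (
    choose_k_elbow,
    extract_core,
    group_mean_profile,
    heatmap_export,
    kmeans_cluster,
    pca_scores,
    select_clustering_features,
    sse_curve,
    zscore_rows,
)
from .concordance import direction_concordance
from .diffexp import call_differential, moderated_t_test, volcano_table
from .enrichment import bubble_export, hypergeometric_enrichment
from .preprocess import filter_low_variance, log2_transform, quantile_normalize
from .synthetic import SimulationParams, default_comparisons, simulate_dataset, write_truth
from .target_pairing import aggregate_targets, call_pairs, pair_gene_set

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; see ``PipelineConfig.from_yaml``."""

    seed: int = 0
    simulate: bool = True
    sim_params: dict[str, Any] = field(default_factory=dict)
    # input paths (ignored when simulate=True)
    mirna_path: str | None = None
    mrna_path: str | None = None
    design_path: str | None = None
    targets_path: str | None = None
    gene_sets_path: str | None = None
    other_de_paths: dict[str, str] = field(default_factory=dict)  # comparison -> TSV
    input_scale: str = "log2"
    # preprocessing
    quantile_normalize: bool = False
    variance_quantile: float = 0.25
    log2_offset: float = 1.0
    # thresholds
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    fdr_level: float = 0.20
    min_sources: int = 3
    core_corr: float = 0.8
    alpha: float = 0.05
    # clustering
    k: int | str = "auto"
    k_max: int = 8
    n_init: int = 25
    scale_rows: bool = True
    # comparisons: list of {name, group_a, group_b}; empty -> the seven defaults
    comparisons: list[dict[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, v in (
            ("fc_threshold", self.fc_threshold),
            ("p_threshold", self.p_threshold),
            ("fdr_level", self.fdr_level),
            ("core_corr", self.core_corr),
            ("alpha", self.alpha),
        ):
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.min_sources < 1:
            raise ValueError("min_sources must be >= 1")

    def comparison_list(self, design: SampleDesign) -> list[Comparison]:
        if not self.comparisons:
            cmps = default_comparisons(design.group_order)
        else:
            cmps = [
                Comparison(c.get("name") or f"{c['group_a']}_vs_{c['group_b']}", c["group_a"], c["group_b"])
                for c in self.comparisons
            ]
        for c in cmps:
            for g in (c.group_a, c.group_b):
                if g not in design.group_order:
                    raise ValueError(f"comparison {c.name!r} references unknown group {g!r}")
        return cmps

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        from dataclasses import asdict

        return asdict(self)


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic named substream, independent of stage order."""
    h = 0
    for ch in stage:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return (seed * 2654435761 + h) % (2**31 - 1)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every stage and return the results directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("mirpair")
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(fmt)
    sh = logging.StreamHandler()
    sh.setFormatter(fmt)
    log.addHandler(fh)
    log.addHandler(sh)
    outputs: list[str] = []

    def record(path: Path) -> Path:
        outputs.append(str(path.relative_to(out)))
        return path

    try:
        # ---------------- inputs ------------------------------------------
        stage = "simulate" if config.simulate else "load"
        try:
            if config.simulate:
                params = SimulationParams(**{**config.sim_params, "seed": _stage_seed(config.seed, "simulate")})
                mirna, mrna, design, targets, gene_sets, truth = simulate_dataset(params)
                sim_dir = out / "simulated"
                sim_dir.mkdir(exist_ok=True)
                write_expression_matrix(mirna, record(sim_dir / "mirna.tsv"))
                write_expression_matrix(mrna, record(sim_dir / "mrna.tsv"))
                write_design(design, record(sim_dir / "design.tsv"))
                write_target_table(targets, record(sim_dir / "targets.tsv"))
                write_gene_sets(gene_sets, record(sim_dir / "gene_sets.gmt"))
                write_truth(truth, record(sim_dir / "truth.json"))
                log.info("simulate: %d miRNAs x %d samples, %d mRNAs, %d target rows",
                         mirna.n_features, mirna.n_samples, mrna.n_features, len(targets))
            else:
                for name, p in (("mirna", config.mirna_path), ("mrna", config.mrna_path),
                                ("design", config.design_path), ("targets", config.targets_path),
                                ("gene_sets", config.gene_sets_path)):
                    if p is None:
                        raise ValueError(f"{name} input path missing (simulate=false)")
                mirna = read_expression_matrix(config.mirna_path, config.input_scale)
                mrna = read_expression_matrix(config.mrna_path, config.input_scale)
                design = read_design(config.design_path)
                targets = None  # consumed lazily by the pairs stage
                gene_sets = read_gene_sets(config.gene_sets_path)
                log.info("load: %d miRNAs, %d mRNAs, %d samples", mirna.n_features,
                         mrna.n_features, mirna.n_samples)
        except Exception as e:
            raise PipelineError(f"stage {stage}: {e}") from e

        comparisons = config.comparison_list(design)

        # ---------------- preprocess --------------------------------------
        try:
            def prep(m: ExpressionMatrix, label: str) -> ExpressionMatrix:
                n_in = m.n_features
                if m.scale == "linear":
                    m = log2_transform(m, config.log2_offset)
                if config.quantile_normalize:
                    m = quantile_normalize(m)
                m = filter_low_variance(m, config.variance_quantile)
                log.info("preprocess %s: %d features in, %d survive variance filter (q=%.2f)",
                         label, n_in, m.n_features, config.variance_quantile)
                return m

            mirna = prep(mirna, "miRNA")
            mrna = prep(mrna, "mRNA")
        except Exception as e:
            raise PipelineError(f"stage preprocess: {e}") from e

        # ---------------- differential expression -------------------------
        de_dir = out / "de"
        de_dir.mkdir(exist_ok=True)
        de_mirna: dict[str, pd.DataFrame] = {}
        de_mrna: dict[str, pd.DataFrame] = {}
        try:
            for cmp in comparisons:
                for label, mat, store in (("mirna", mirna, de_mirna), ("mrna", mrna, de_mrna)):
                    res = moderated_t_test(mat, design, cmp)
                    res, (n_down, n_up) = call_differential(
                        res, config.fc_threshold, config.p_threshold, config.fdr_level
                    )
                    store[cmp.name] = res
                    _write_tsv(res, record(de_dir / f"{cmp.name}_{label}.tsv"))
                    _write_tsv(volcano_table(res), record(de_dir / f"{cmp.name}_{label}_volcano.tsv"))
                    with open(record(de_dir / f"{cmp.name}_{label}_summary.json"), "wt") as jf:
                        json.dump({"comparison": cmp.name, "n_down": n_down, "n_up": n_up}, jf)
                    log.info("de %s %s: %d down, %d up", cmp.name, label, n_down, n_up)
        except Exception as e:
            raise PipelineError(f"stage de: {e}") from e

        # ---------------- target pairing ----------------------------------
        pairs_dir = out / "pairs"
        pairs_dir.mkdir(exist_ok=True)
        pairs_by_cmp: dict[str, pd.DataFrame] = {}
        try:
            if targets is None:
                targets = read_target_table(config.targets_path)
            agg = aggregate_targets(targets, config.min_sources)
            log.info("pairs: %d target rows -> %d aggregated pairs (>=%d sources)",
                     len(targets), len(agg), config.min_sources)
            for cmp in comparisons:
                pairs = call_pairs(de_mirna[cmp.name], de_mrna[cmp.name], agg, cmp)
                pairs_by_cmp[cmp.name] = pairs
                _write_tsv(pairs, record(pairs_dir / f"{cmp.name}_pairs.tsv"), index=False)
                log.info("pairs %s: %d anti-correlated pairs", cmp.name, len(pairs))
        except Exception as e:
            raise PipelineError(f"stage pairs: {e}") from e

        # ---------------- enrichment --------------------------------------
        enrich_dir = out / "enrich"
        enrich_dir.mkdir(exist_ok=True)
        try:
            assayed = set(mrna.feature_ids)
            background = gene_sets.restrict_universe(assayed) if assayed else gene_sets
            for cmp in comparisons:
                genes = pair_gene_set(pairs_by_cmp[cmp.name])
                if not genes:
                    log.info("enrich %s: no pair genes, skipped", cmp.name)
                    continue
                res = hypergeometric_enrichment(genes, background)
                _write_tsv(res, record(enrich_dir / f"{cmp.name}_enrichment.tsv"), index=False)
                _write_tsv(bubble_export(res, config.alpha),
                           record(enrich_dir / f"{cmp.name}_bubble.tsv"), index=False)
                n_sig = int((res["p_adj"] < config.alpha).sum())
                log.info("enrich %s: %d genes tested, %d significant terms", cmp.name, len(genes), n_sig)
        except Exception as e:
            raise PipelineError(f"stage enrich: {e}") from e

        # ---------------- co-expression clustering ------------------------
        cluster_dir = out / "cluster"
        cluster_dir.mkdir(exist_ok=True)
        try:
            features = select_clustering_features(de_mirna)
            log.info("cluster: %d miRNAs significant in >= 1 comparison", len(features))
            if len(features) >= 3:
                profiles = group_mean_profile(mirna, design, features)
                if config.scale_rows:
                    profiles = zscore_rows(profiles)
                km_seed = _stage_seed(config.seed, "kmeans")
                k_max = min(config.k_max, len(features))
                curve = sse_curve(profiles, k_max, km_seed, config.n_init)
                _write_tsv(pd.DataFrame(curve, columns=["k", "sse"]),
                           record(cluster_dir / "sse_curve.tsv"), index=False)
                if config.k == "auto":
                    k, diag = choose_k_elbow(curve)
                    _write_tsv(diag, record(cluster_dir / "elbow_diagnostics.tsv"), index=False)
                else:
                    k = int(config.k)
                model = kmeans_cluster(profiles, k, km_seed, config.n_init)
                model = extract_core(model, profiles, config.core_corr)
                log.info("cluster: k=%d, sse=%.4f, core sizes=%s", k, model.sse,
                         {c: len(v) for c, v in model.core.items()})
                assign = pd.DataFrame(
                    {"feature": list(model.assignments), "cluster": list(model.assignments.values())}
                )
                _write_tsv(assign, record(cluster_dir / "clusters.tsv"), index=False)
                core_rows = [(c, f, r) for c, members in model.core.items() for f, r in members]
                _write_tsv(pd.DataFrame(core_rows, columns=["cluster", "feature", "r"]),
                           record(cluster_dir / "core.tsv"), index=False)
                mean_p, sample_p, fc_p = heatmap_export(mirna, design, model, de_mirna)
                _write_tsv(mean_p, record(cluster_dir / "heatmap_means.tsv"))
                _write_tsv(sample_p, record(cluster_dir / "heatmap_samples.tsv"))
                _write_tsv(fc_p, record(cluster_dir / "heatmap_foldchanges.tsv"))
            else:
                log.info("cluster: skipped (fewer than 3 significant miRNAs)")
            scores, explained = pca_scores(mirna)
            scores["group"] = [design.assignments[s] for s in scores.index]
            _write_tsv(scores, record(cluster_dir / "pca_scores.tsv"))
            with open(record(cluster_dir / "pca_explained.json"), "wt") as jf:
                json.dump({"explained_fraction": [float(x) for x in explained]}, jf)
        except Exception as e:
            raise PipelineError(f"stage cluster: {e}") from e

        # ---------------- concordance (optional) --------------------------
        if config.other_de_paths:
            concord_dir = out / "concord"
            concord_dir.mkdir(exist_ok=True)
            try:
                for cmp_name, path in config.other_de_paths.items():
                    if cmp_name not in de_mirna:
                        raise ValueError(f"external table for unknown comparison {cmp_name!r}")
                    other = pd.read_csv(path, sep="\t")
                    outcome = direction_concordance(de_mirna[cmp_name], other, config.alpha)
                    _write_tsv(outcome.per_feature, record(concord_dir / f"{cmp_name}_concordance.tsv"))
                    with open(record(concord_dir / f"{cmp_name}_summary.json"), "wt") as jf:
                        json.dump({"n_common": outcome.n_common,
                                   "concordant_fraction": outcome.concordant_fraction}, jf)
                    log.info("concord %s: %d common, fraction %.3f", cmp_name,
                             outcome.n_common, outcome.concordant_fraction)
            except Exception as e:
                raise PipelineError(f"stage concord: {e}") from e

        # ---------------- manifest ----------------------------------------
        manifest = {
            "config": config.to_dict(),
            "seed": config.seed,
            "versions": {
                "mirpair": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "outputs": sorted(outputs),
        }
        with open(out / "manifest.json", "wt") as jf:
            json.dump(manifest, jf, indent=1, sort_keys=True)
        log.info("done: %d output files in %s", len(outputs), out)
        return out
    finally:
        log.removeHandler(fh)
        log.removeHandler(sh)
        fh.close()
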