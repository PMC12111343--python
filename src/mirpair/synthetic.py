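"""Synthetic coupled miRNA/mRNA data with planted, machine-readable truth.

The generator emulates the statistical structure of a six-group gonadectomy /
hormone-replacement adrenal study (Male C, Female C, ORX, OVX, ORX+T, OVX+E;
three replicates per group) on the log2 scale:

* per-feature baselines drawn from N(baseline_mean, baseline_sd);
* i.i.d. Gaussian noise whose per-feature variance follows a scaled
  inverse-chi-square prior (d0 = 4, s0^2 = noise_sd^2), so the
  empirical-Bayes variance moderation used downstream is well specified;
* two planted co-expression archetypes implemented as additive group-effect
  patterns — cluster 1 peaks in ORX+T (male groups above female groups),
  cluster 2 is minimal in ORX+T and maximal in OVX+E;
* repressive miRNA -> mRNA edges: every planted DE miRNA represses
  ``targets_per_de_mirna`` dedicated genes, each receiving the exact
  opposite-sign group-effect vector;
* a multi-source target table where planted edges are supported by at least
  ``min_planted_sources`` databases at top ranks, alongside under-supported
  edges (< 3 sources) and well-supported decoy edges between non-DE features;
* gene-set annotations with one planted enriched term per archetype.

Archetype group weights are integers, so every pairwise group difference of
a planted feature is either exactly zero or at least ``effect_low`` in
magnitude — the planted truth contains no sub-threshold effects that would
blur sensitivity/FDR bookkeeping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import (
    Comparison,
    ExpressionMatrix,
    GeneSetCollection,
    SampleDesign,
    TargetTable,
)

__all__ = [
    "DEFAULT_GROUPS",
    "DEFAULT_COMPARISONS",
    "SimulationParams",
    "SyntheticTruth",
    "simulate_dataset",
    "write_truth",
    "read_truth",
]

DEFAULT_GROUPS = ["Male C", "Female C", "ORX", "OVX", "ORX+T", "OVX+E"]


def _cmp_name(a: str, b: str) -> str:
    clean = lambda g: g.replace(" ", "").replace("+", "")
    return f"{clean(a)}_vs_{clean(b)}"


def default_comparisons(groups: list[str] = DEFAULT_GROUPS) -> list[Comparison]:
    """The study's seven contrasts (treated-vs-control and cross-group)."""
    pairs = [
        ("ORX", "Male C"),
        ("ORX+T", "Male C"),
        ("OVX", "Female C"),
        ("OVX+E", "Female C"),
        ("Male C", "Female C"),
        ("ORX", "OVX"),
        ("ORX+T", "OVX+E"),
    ]
    return [Comparison(_cmp_name(a, b), a, b) for a, b in pairs if a in groups and b in groups]


DEFAULT_COMPARISONS = default_comparisons()

# group-effect archetypes, in units of the per-miRNA effect magnitude;
# order matches DEFAULT_GROUPS
_ARCHETYPES = {
    1: np.array([1.0, 0.0, 1.0, 0.0, 2.0, 0.0]),   # peak in ORX+T, males above females
    2: np.array([0.0, 1.0, 0.0, 1.0, -1.0, 2.0]),  # trough in ORX+T, peak in OVX+E
}


@dataclass
class SimulationParams:
    """Knobs of the generator; defaults mirror the study's design scale."""

    n_mirna: int = 700
    n_mrna: int = 5000
    groups: list[str] = field(default_factory=lambda: list(DEFAULT_GROUPS))
    reps_per_group: int = 3
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.25
    n_de_mirna_per_comparison: int = 30
    effect_low: float = 1.2
    effect_high: float = 2.5
    targets_per_de_mirna: int = 5
    n_sources: int = 5
    min_planted_sources: int = 3
    n_terms: int = 40
    enriched_term_fraction: float = 0.75
    seed: int = 0

    def validate(self) -> None:
        if self.effect_low < 1:
            raise ValueError("effect_low must be >= 1 so planted effects clear the |FC|>2 gate")
        if self.effect_high < self.effect_low:
            raise ValueError("effect_high must be >= effect_low")
        if self.reps_per_group < 2:
            raise ValueError("reps_per_group must be >= 2")
        if self.min_planted_sources > self.n_sources:
            raise ValueError("min_planted_sources must be <= n_sources")
        if self.min_planted_sources < 1 or self.n_sources < 1:
            raise ValueError("source counts must be >= 1")
        if self.groups != list(DEFAULT_GROUPS):
            raise ValueError("the archetype patterns are defined over the six default groups")
        n_planted = 2 * self.n_de_mirna_per_comparison
        if n_planted > self.n_mirna:
            raise ValueError("more planted DE miRNAs than miRNAs")
        if n_planted * self.targets_per_de_mirna > self.n_mrna:
            raise ValueError("more planted target genes than mRNAs")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not (0 < self.enriched_term_fraction <= 1):
            raise ValueError("enriched_term_fraction must be in (0, 1]")
        if self.n_terms < 2:
            raise ValueError("need at least 2 terms (one enriched per archetype)")


@dataclass
class SyntheticTruth:
    """Planted ground truth: DE sets, repressive edges, expected pairs,
    cluster labels and enriched terms."""

    de_sets: dict[str, dict[str, float]]          # comparison -> miRNA -> planted log2FC
    mrna_de_sets: dict[str, dict[str, float]]     # comparison -> gene -> planted log2FC
    edges: list[tuple[str, str, int]]             # (mirna, gene, sign=-1)
    pairs: dict[str, list[tuple[str, str]]]       # comparison -> expected (mirna, gene)
    cluster_labels: dict[str, int]                # planted miRNA -> {1, 2}; absent = none
    enriched_terms: set[str]
    decoy_edges: list[tuple[str, str]] = field(default_factory=list)  # well-supported non-DE decoys

    def label_of(self, mirna: str) -> int | str:
        return self.cluster_labels.get(mirna, "none")


def _noise_variances(rng: np.random.Generator, n: int, d0: float, s0_sq: float) -> np.ndarray:
    """Per-feature variances from a scaled inverse-chi-square(d0, s0^2)."""
    if s0_sq == 0:
        return np.zeros(n)
    return d0 * s0_sq / rng.chisquare(d0, size=n)


def simulate_dataset(
    params: SimulationParams,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SampleDesign, TargetTable, GeneSetCollection, SyntheticTruth]:
    """Generate coupled miRNA/mRNA matrices, design, target table, gene sets
    and the planted truth.  Deterministic given ``params`` (incl. seed)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    groups = params.groups
    n_g = len(groups)
    reps = params.reps_per_group

    sample_ids = [f"{g.replace(' ', '').replace('+', '')}_{r + 1}" for g in groups for r in range(reps)]
    group_of = [g for g in groups for _ in range(reps)]
    design = SampleDesign(dict(zip(sample_ids, group_of)), list(groups))

    mirna_ids = [f"miR-{i:04d}" for i in range(1, params.n_mirna + 1)]
    gene_ids = [f"G{i:05d}" for i in range(1, params.n_mrna + 1)]

    # --- plant archetype effects -------------------------------------------
    n_per = params.n_de_mirna_per_comparison
    planted_idx = rng.choice(params.n_mirna, size=2 * n_per, replace=False)
    cluster_of_idx = {int(i): (1 if pos < n_per else 2) for pos, i in enumerate(planted_idx)}
    magnitudes = rng.uniform(params.effect_low, params.effect_high, size=2 * n_per)

    effect_mirna = np.zeros((params.n_mirna, n_g))
    for pos, i in enumerate(planted_idx):
        effect_mirna[i] = magnitudes[pos] * _ARCHETYPES[cluster_of_idx[int(i)]]

    # each planted miRNA represses a dedicated block of genes with the exact
    # opposite-sign group-effect vector
    n_targets = params.targets_per_de_mirna
    target_gene_idx = rng.choice(params.n_mrna, size=2 * n_per * n_targets, replace=False)
    effect_mrna = np.zeros((params.n_mrna, n_g))
    edges: list[tuple[str, str, int]] = []
    targets_of: dict[str, list[str]] = {}
    for pos, i in enumerate(planted_idx):
        block = target_gene_idx[pos * n_targets : (pos + 1) * n_targets]
        m_id = mirna_ids[i]
        targets_of[m_id] = []
        for gi in block:
            effect_mrna[gi] = -effect_mirna[i]
            g_id = gene_ids[gi]
            edges.append((m_id, g_id, -1))
            targets_of[m_id].append(g_id)

    # --- sample expression values ------------------------------------------
    def _matrix(ids: list[str], effects: np.ndarray) -> ExpressionMatrix:
        n = len(ids)
        baseline = rng.normal(params.baseline_mean, params.baseline_sd, size=n)
        sigma2 = _noise_variances(rng, n, d0=4.0, s0_sq=params.noise_sd**2)
        group_index = np.array([groups.index(g) for g in group_of])
        mean = baseline[:, None] + effects[:, group_index]
        noise = rng.standard_normal((n, len(sample_ids))) * np.sqrt(sigma2)[:, None]
        return ExpressionMatrix(ids, list(sample_ids), mean + noise, "log2")

    mirna = _matrix(mirna_ids, effect_mirna)
    mrna = _matrix(gene_ids, effect_mrna)

    # --- planted truth per comparison --------------------------------------
    comparisons = default_comparisons(groups)
    de_sets: dict[str, dict[str, float]] = {}
    mrna_de_sets: dict[str, dict[str, float]] = {}
    pairs: dict[str, list[tuple[str, str]]] = {}
    for cmp in comparisons:
        ia, ib = groups.index(cmp.group_a), groups.index(cmp.group_b)
        mir_de: dict[str, float] = {}
        gene_de: dict[str, float] = {}
        cmp_pairs: list[tuple[str, str]] = []
        for i in planted_idx:
            delta = effect_mirna[i, ia] - effect_mirna[i, ib]
            if delta != 0.0:
                m_id = mirna_ids[i]
                mir_de[m_id] = float(delta)
                for g_id in targets_of[m_id]:
                    gene_de[g_id] = float(-delta)
                    cmp_pairs.append((m_id, g_id))
        de_sets[cmp.name] = mir_de
        mrna_de_sets[cmp.name] = gene_de
        pairs[cmp.name] = cmp_pairs

    cluster_labels = {mirna_ids[i]: c for i, c in cluster_of_idx.items()}

    # --- multi-source target table -----------------------------------------
    sources = [f"db{s + 1}" for s in range(params.n_sources)]
    # support[(source, mirna)] -> list of genes; planted genes go first (top ranks)
    support: dict[tuple[str, str], list[str]] = {}

    def _add(src: str, m_id: str, g_id: str) -> None:
        support.setdefault((src, m_id), []).append(g_id)

    for m_id, g_id, _sign in edges:
        k = int(rng.integers(params.min_planted_sources, params.n_sources + 1))
        for s in rng.choice(params.n_sources, size=k, replace=False):
            _add(sources[s], m_id, g_id)

    non_de_mirna = [m for m in mirna_ids if m not in cluster_labels]
    planted_gene_set = {g for _m, g, _s in edges}
    non_de_gene = [g for g in gene_ids if g not in planted_gene_set]
    decoy_records: list[tuple[str, str]] = []
    if edges:
        # well-supported decoys between non-DE features (~10% of edges), plus
        # under-supported edges that must fall below the >=3-source gate
        n_decoy = max(1, round(0.1 * len(edges) / 0.9))
        n_under = n_decoy if params.min_planted_sources > 1 else 0
        # disjoint gene pools so no (mirna, gene, source) triple can repeat
        gi_all = rng.choice(len(non_de_gene), size=n_decoy + n_under, replace=False)
        dm = rng.choice(len(non_de_mirna), size=n_decoy, replace=False)
        for mi, gi in zip(dm, gi_all[:n_decoy]):
            m_id, g_id = non_de_mirna[mi], non_de_gene[gi]
            decoy_records.append((m_id, g_id))
            k = int(rng.integers(params.min_planted_sources, params.n_sources + 1))
            for s in rng.choice(params.n_sources, size=k, replace=False):
                _add(sources[s], m_id, g_id)
        um = rng.choice(len(mirna_ids), size=n_under, replace=True)
        for mi, gi in zip(um, gi_all[n_decoy:]):
            m_id, g_id = mirna_ids[mi], non_de_gene[gi]
            k = int(rng.integers(1, params.min_planted_sources))
            for s in rng.choice(params.n_sources, size=k, replace=False):
                _add(sources[s], m_id, g_id)

    records = []
    for (src, m_id), genes in support.items():
        for rank, g_id in enumerate(genes, start=1):
            records.append((m_id, g_id, src, rank))
    targets = TargetTable(pd.DataFrame(records, columns=["mirna", "gene", "source", "rank"]))

    # --- gene sets with one enriched term per archetype --------------------
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    enriched: set[str] = set()
    genes_by_cluster = {
        c: [g for m, gs in targets_of.items() if cluster_labels[m] == c for g in gs]
        for c in (1, 2)
    }
    term_counter = 0
    for c in (1, 2):
        pool = genes_by_cluster[c]
        if not pool:
            continue
        term_counter += 1
        tid = f"GO:SYN{term_counter:04d}"
        n_core = max(1, round(params.enriched_term_fraction * len(pool)))
        core = list(rng.choice(pool, size=n_core, replace=False))
        n_pad = max(0, round(len(pool) * (1 - params.enriched_term_fraction)))
        pad = list(rng.choice(non_de_gene, size=n_pad, replace=False)) if n_pad else []
        terms[tid] = (f"planted archetype {c} response", frozenset(core + pad))
        enriched.add(tid)
    while term_counter < params.n_terms:
        term_counter += 1
        tid = f"GO:SYN{term_counter:04d}"
        size = int(rng.integers(20, 201))
        members = rng.choice(params.n_mrna, size=size, replace=False)
        terms[tid] = (f"background term {term_counter}", frozenset(gene_ids[i] for i in members))
    gene_sets = GeneSetCollection(terms, frozenset(gene_ids))

    truth = SyntheticTruth(
        de_sets=de_sets,
        mrna_de_sets=mrna_de_sets,
        edges=edges,
        pairs=pairs,
        cluster_labels=cluster_labels,
        enriched_terms=enriched,
        decoy_edges=decoy_records,
    )
    return mirna, mrna, design, targets, gene_sets, truth


# ---------------------------------------------------------------------------
# truth serialization (JSON; lossless for the float payloads via repr round-trip)

_SCHEMA = "mirpair-truth-v1"


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "schema": _SCHEMA,
        "de_sets": truth.de_sets,
        "mrna_de_sets": truth.mrna_de_sets,
        "edges": [list(e) for e in truth.edges],
        "pairs": {c: [list(p) for p in ps] for c, ps in truth.pairs.items()},
        "cluster_labels": truth.cluster_labels,
        "enriched_terms": sorted(truth.enriched_terms),
        "decoy_edges": [list(e) for e in truth.decoy_edges],
    }
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_truth(path: str | Path) -> SyntheticTruth:
    with open(path, "rt", encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("schema") != _SCHEMA:
        raise ValueError(f"{path}: not a truth file (schema={payload.get('schema')!r})")
    return SyntheticTruth(
        de_sets={c: dict(d) for c, d in payload["de_sets"].items()},
        mrna_de_sets={c: dict(d) for c, d in payload["mrna_de_sets"].items()},
        edges=[(m, g, int(s)) for m, g, s in payload["edges"]],
        pairs={c: [(m, g) for m, g in ps] for c, ps in payload["pairs"].items()},
        cluster_labels={m: int(c) for m, c in payload["cluster_labels"].items()},
        enriched_terms=set(payload["enriched_terms"]),
        decoy_edges=[(m, g) for m, g in payload.get("decoy_edges", [])],
    )
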