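"""Domain types and delimited-text readers/writers for the pipeline.

All tabular formats are TAB-delimited with a mandatory header row; gene sets
use the standard GMT dialect.  Feature and gene identifiers are case-sensitive
opaque strings; harmonization between naming schemes (e.g. mature-miRNA vs
precursor names) is the caller's job via an optional alias map.  Readers
validate invariants and reject malformed input rather than silently repairing
it; missing values in expression matrices are an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleDesign",
    "Comparison",
    "TargetTable",
    "GeneSetCollection",
    "CtTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_design",
    "write_design",
    "read_target_table",
    "write_target_table",
    "read_gene_sets",
    "write_gene_sets",
    "read_ct_table",
    "write_ct_table",
    "read_alias_map",
    "apply_alias_map",
]

SCALES = ("linear", "log2")


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Features-by-samples real matrix with a scale tag.

    ``scale`` is ``"log2"`` (all values finite) or ``"linear"`` (all
    values >= 0).  Row order is meaningful and preserved by every
    operation that does not explicitly drop features.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        _check_unique(self.feature_ids, "feature id")
        _check_unique(self.sample_ids, "sample id")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        if self.scale == "linear" and np.any(self.values < 0):
            raise ValueError("linear-scale expression values must be >= 0")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def subset_features(self, features: list[str]) -> "ExpressionMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in features if f not in idx]
        if missing:
            raise KeyError(f"unknown feature(s): {missing[:5]}")
        rows = [idx[f] for f in features]
        return ExpressionMatrix(list(features), list(self.sample_ids), self.values[rows], self.scale)


@dataclass
class SampleDesign:
    """Mapping of samples to experimental groups with a fixed group order."""

    assignments: dict[str, str]
    group_order: list[str]

    def __post_init__(self) -> None:
        _check_unique(self.group_order, "group label")
        groups_used = set(self.assignments.values())
        for g in self.group_order:
            if g not in groups_used:
                raise ValueError(f"group {g!r} has no samples")
        unknown = groups_used - set(self.group_order)
        if unknown:
            raise ValueError(f"samples assigned to groups missing from group_order: {sorted(unknown)}")

    def samples_of(self, group: str) -> list[str]:
        if group not in self.group_order:
            raise KeyError(f"unknown group {group!r}")
        return [s for s, g in self.assignments.items() if g == group]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignments)


@dataclass(frozen=True)
class Comparison:
    """A two-group contrast; positive log2FC means higher in ``group_a``."""

    name: str
    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError(f"comparison {self.name!r}: group_a == group_b ({self.group_a!r})")


@dataclass
class TargetTable:
    """Ranked miRNA-target predictions from multiple source databases.

    ``records`` has columns mirna, gene, source, rank.  Within one
    (source, mirna) prediction list, ranks are unique positive integers
    (lower = stronger prediction).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["mirna", "gene", "source", "rank"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise ValueError(f"target table missing column(s) {missing}")
        rec = self.records.reset_index(drop=True)[required].copy()
        ranks = rec["rank"]
        if not np.all(ranks == ranks.astype(int)):
            raise ValueError("target ranks must be integers")
        rec["rank"] = ranks.astype(int)
        if (rec["rank"] < 1).any():
            bad = rec.loc[rec["rank"] < 1].iloc[0]
            raise ValueError(f"rank must be >= 1, got {bad['rank']} for ({bad['mirna']}, {bad['gene']}, {bad['source']})")
        dup = rec.duplicated(subset=["mirna", "gene", "source"])
        if dup.any():
            bad = rec.loc[dup].iloc[0]
            raise ValueError(f"duplicate (mirna, gene, source) triple ({bad['mirna']}, {bad['gene']}, {bad['source']})")
        dupr = rec.duplicated(subset=["source", "mirna", "rank"])
        if dupr.any():
            bad = rec.loc[dupr].iloc[0]
            raise ValueError(
                f"duplicate rank {bad['rank']} within source {bad['source']!r} for miRNA {bad['mirna']!r}"
            )
        self.records = rec

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GeneSetCollection:
    """Gene-set annotations: term_id -> (term_name, gene set), plus a universe."""

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, frozenset[str]]] = {}
        for tid, (name, genes) in self.terms.items():
            genes = frozenset(genes) & self.universe
            if not genes:
                raise ValueError(f"term {tid!r} has no genes in the universe")
            clean[tid] = (name, genes)
        self.terms = clean
        self.universe = frozenset(self.universe)

    def restrict_universe(self, assayed: Iterable[str]) -> "GeneSetCollection":
        """Intersect the universe (and every term) with an assayed-gene list."""
        new_universe = self.universe & frozenset(assayed)
        terms = {
            tid: (name, genes)
            for tid, (name, genes) in self.terms.items()
            if genes & new_universe
        }
        return GeneSetCollection(terms, new_universe)


@dataclass
class CtTable:
    """qPCR Ct cycles: samples x genes matrix with one designated reference gene."""

    samples: list[str]
    genes: list[str]
    ct: np.ndarray
    design: SampleDesign

    def __post_init__(self) -> None:
        self.ct = np.asarray(self.ct, dtype=float)
        _check_unique(self.samples, "sample id")
        _check_unique(self.genes, "gene id")
        if self.ct.shape != (len(self.samples), len(self.genes)):
            raise ValueError("Ct matrix shape does not match samples x genes")
        if not np.all(np.isfinite(self.ct)) or np.any(self.ct <= 0):
            raise ValueError("Ct values must be finite and > 0")
        for s in self.samples:
            if s not in self.design.assignments:
                raise ValueError(f"sample {s!r} missing from design")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ct, index=self.samples, columns=self.genes)


# ---------------------------------------------------------------------------
# readers / writers


def _read_table_rows(path: str | Path) -> list[list[str]]:
    rows: list[list[str]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line == "":
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise ValueError(f"{path}: empty file")
    return rows


def read_expression_matrix(path: str | Path, scale: str) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column feature ids, header = sample ids)."""
    rows = _read_table_rows(path)
    header = rows[0]
    if len(header) < 2:
        raise ValueError(f"{path}: header must contain at least one sample column")
    sample_ids = header[1:]
    ncol = len(header)
    feature_ids: list[str] = []
    data: list[list[str]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != ncol:
            raise ValueError(f"{path}: ragged row at line {lineno} ({len(row)} fields, expected {ncol})")
        feature_ids.append(row[0])
        data.append(row[1:])
    try:
        values = np.array(data, dtype=float)
    except ValueError:
        for i, row in enumerate(data):
            for j, cell in enumerate(row):
                try:
                    float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {cell!r} at feature {feature_ids[i]!r}, "
                        f"sample {sample_ids[j]!r}"
                    ) from None
        raise
    return ExpressionMatrix(feature_ids, sample_ids, values, scale)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    df = m.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_design(path: str | Path) -> SampleDesign:
    rows = _read_table_rows(path)
    if [c.lower() for c in rows[0][:2]] != ["sample_id", "group"]:
        raise ValueError(f"{path}: expected header 'sample_id\\tgroup'")
    assignments: dict[str, str] = {}
    order: list[str] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != 2:
            raise ValueError(f"{path}: expected 2 fields at line {lineno}, got {len(row)}")
        sample, group = row
        if sample in assignments:
            raise ValueError(f"{path}: sample {sample!r} listed twice")
        assignments[sample] = group
        if group not in order:
            order.append(group)
    return SampleDesign(assignments, order)


def write_design(design: SampleDesign, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in design.assignments.items():
            fh.write(f"{sample}\t{group}\n")


def read_target_table(path: str | Path) -> TargetTable:
    rows = _read_table_rows(path)
    if [c.lower() for c in rows[0][:4]] != ["mirna", "gene", "source", "rank"]:
        raise ValueError(f"{path}: expected header 'mirna\\tgene\\tsource\\trank'")
    recs = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != 4:
            raise ValueError(f"{path}: expected 4 fields at line {lineno}, got {len(row)}")
        mirna, gene, source, rank_s = row
        try:
            rank_f = float(rank_s)
        except ValueError:
            raise ValueError(f"{path}: non-numeric rank {rank_s!r} at line {lineno}") from None
        if not rank_f.is_integer():
            raise ValueError(f"{path}: non-integer rank {rank_s!r} at line {lineno}")
        recs.append((mirna, gene, source, int(rank_f)))
    return TargetTable(pd.DataFrame(recs, columns=["mirna", "gene", "source", "rank"]))


def write_target_table(t: TargetTable, path: str | Path) -> None:
    t.records.to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file: term_id TAB description TAB gene TAB gene...

    The universe defaults to the union of all term genes; pass ``universe``
    to use an explicit background population instead.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    union: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has {len(fields)} fields, need >= 3")
            tid, name, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}: line {lineno}: term {tid!r} has an empty gene list")
            if tid in terms:
                raise ValueError(f"{path}: duplicate term id {tid!r} at line {lineno}")
            terms[tid] = (name, frozenset(genes))
            union.update(genes)
    if not terms:
        raise ValueError(f"{path}: no terms parsed")
    uni = frozenset(universe) if universe is not None else frozenset(union)
    return GeneSetCollection(terms, uni)


def write_gene_sets(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for tid, (name, genes) in sets.terms.items():
            fh.write("\t".join([tid, name, *sorted(genes)]) + "\n")


def read_ct_table(path: str | Path, design: SampleDesign) -> CtTable:
    """Read a long-format Ct TSV (sample_id, gene, ct) and pivot to samples x genes."""
    rows = _read_table_rows(path)
    if [c.lower() for c in rows[0][:3]] != ["sample_id", "gene", "ct"]:
        raise ValueError(f"{path}: expected header 'sample_id\\tgene\\tct'")
    recs = []
    seen: set[tuple[str, str]] = set()
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != 3:
            raise ValueError(f"{path}: expected 3 fields at line {lineno}, got {len(row)}")
        sample, gene, ct_s = row
        if (sample, gene) in seen:
            raise ValueError(f"{path}: duplicate (sample, gene) pair ({sample!r}, {gene!r})")
        seen.add((sample, gene))
        try:
            ct = float(ct_s)
        except ValueError:
            raise ValueError(f"{path}: non-numeric Ct {ct_s!r} at line {lineno}") from None
        recs.append((sample, gene, ct))
    df = pd.DataFrame(recs, columns=["sample_id", "gene", "ct"])
    wide = df.pivot(index="sample_id", columns="gene", values="ct")
    if wide.isna().any().any():
        missing = [(s, g) for (s, g) in zip(*np.where(wide.isna().values))]
        raise ValueError(f"{path}: incomplete Ct table ({len(missing)} missing sample/gene cells)")
    samples = list(wide.index)
    genes = list(wide.columns)
    return CtTable(samples, genes, wide.values, design)


def write_ct_table(ct: CtTable, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("sample_id\tgene\tct\n")
        for i, s in enumerate(ct.samples):
            for j, g in enumerate(ct.genes):
                fh.write(f"{s}\t{g}\t{ct.ct[i, j]:.10g}\n")


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (alias, canonical) identifier harmonization map."""
    rows = _read_table_rows(path)
    if [c.lower() for c in rows[0][:2]] != ["alias", "canonical"]:
        raise ValueError(f"{path}: expected header 'alias\\tcanonical'")
    out: dict[str, str] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != 2:
            raise ValueError(f"{path}: expected 2 fields at line {lineno}")
        alias, canonical = row
        if alias in out:
            raise ValueError(f"{path}: alias {alias!r} mapped twice")
        out[alias] = canonical
    return out


def apply_alias_map(ids: Iterable[str], alias_map: Mapping[str, str]) -> list[str]:
    """Map identifiers through an alias map; unmapped ids pass through unchanged."""
    return [alias_map.get(i, i) for i in ids]
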