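"""Multi-source target aggregation and anti-correlated miRNA-mRNA pair calling.

A predicted (miRNA, gene) interaction is retained only when supported by at
least ``min_sources`` distinct databases; its aggregate score is the
geometric mean of the within-source ranks over the sources where the pair
occurs (lower = stronger).  A pair is *called* in a comparison when both
members pass the compound DE gates and their log2 fold changes have strictly
opposite signs — with n = 3 per group, sign opposition of the point
estimates is the operative reading of "inversely correlated"; a sample-level
Pearson rule is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import Comparison, ExpressionMatrix, SampleDesign, TargetTable

__all__ = ["AggregatedTargets", "aggregate_targets", "call_pairs", "pair_gene_set"]


@dataclass
class AggregatedTargets:
    """One record per (mirna, gene) with source support count and rank score."""

    records: pd.DataFrame  # columns: mirna, gene, n_sources, agg_score
    min_sources: int

    def __len__(self) -> int:
        return len(self.records)

    def key_set(self) -> set[tuple[str, str]]:
        return set(zip(self.records["mirna"], self.records["gene"]))


def aggregate_targets(t: TargetTable, min_sources: int = 3) -> AggregatedTargets:
    """Collapse the target table to pairs supported by >= min_sources databases.

    agg_score = geometric mean of the ranks over the sources where the pair
    is present (no penalty padding for absent sources); output sorted by
    (mirna, agg_score, gene).
    """
    if min_sources < 1:
        raise ValueError(f"min_sources must be >= 1, got {min_sources}")
    if len(t.records) == 0:
        empty = pd.DataFrame(columns=["mirna", "gene", "n_sources", "agg_score"])
        return AggregatedTargets(empty, min_sources)
    grp = t.records.groupby(["mirna", "gene"], sort=False)
    agg = grp.agg(
        n_sources=("source", "nunique"),
        agg_score=("rank", lambda r: float(stats.gmean(r))),
    ).reset_index()
    agg = agg[agg["n_sources"] >= min_sources]
    agg = agg.sort_values(["mirna", "agg_score", "gene"], kind="stable").reset_index(drop=True)
    return AggregatedTargets(agg, min_sources)


def _pearson_sign_opposed(
    mirna_row: np.ndarray, gene_row: np.ndarray
) -> bool:
    """Sample-level alternative rule: negative Pearson correlation."""
    if np.std(mirna_row) == 0 or np.std(gene_row) == 0:
        return False
    return float(np.corrcoef(mirna_row, gene_row)[0, 1]) < 0


def call_pairs(
    de_mirna: pd.DataFrame,
    de_mrna: pd.DataFrame,
    agg: AggregatedTargets,
    cmp: Comparison,
    sign_rule: str = "point",
    mirna_matrix: ExpressionMatrix | None = None,
    mrna_matrix: ExpressionMatrix | None = None,
) -> pd.DataFrame:
    """Emit anti-correlated DE miRNA-target pairs for one comparison.

    A pair (m, g) is emitted iff m and g are both called (status up/down),
    (m, g) is in the aggregated targets, and sign(m.log2fc) != sign(g.log2fc)
    (strict; log2fc = 0 never passes).  Output is deterministic: sorted by
    (mirna, agg_score, gene).  ``sign_rule="pearson"`` replaces the sign test
    by negative sample-level Pearson correlation (requires both matrices).
    """
    for tbl, which in ((de_mirna, "miRNA"), (de_mrna, "mRNA")):
        if tbl.attrs.get("comparison") != cmp.name:
            raise ValueError(
                f"{which} DE table was computed for comparison "
                f"{tbl.attrs.get('comparison')!r}, not {cmp.name!r}"
            )
    if sign_rule not in ("point", "pearson"):
        raise ValueError(f"sign_rule must be 'point' or 'pearson', got {sign_rule!r}")
    if sign_rule == "pearson" and (mirna_matrix is None or mrna_matrix is None):
        raise ValueError("pearson sign rule needs both expression matrices")

    sig_m = de_mirna[de_mirna["status"].isin(["up", "down"])]
    sig_g = de_mrna[de_mrna["status"].isin(["up", "down"])]
    lfc_m = sig_m["log2fc"]
    lfc_g = sig_g["log2fc"]

    rows = []
    for rec in agg.records.itertuples(index=False):
        if rec.mirna not in lfc_m.index or rec.gene not in lfc_g.index:
            continue
        fm = float(lfc_m[rec.mirna])
        fg = float(lfc_g[rec.gene])
        if sign_rule == "point":
            opposed = fm * fg < 0
        else:
            mi = mirna_matrix.to_frame().loc[rec.mirna].to_numpy()
            gi = mrna_matrix.to_frame().loc[rec.gene].to_numpy()
            opposed = _pearson_sign_opposed(mi, gi)
        if opposed:
            rows.append((cmp.name, rec.mirna, fm, rec.gene, fg, rec.n_sources, rec.agg_score))
    out = pd.DataFrame(
        rows,
        columns=["comparison", "mirna", "mirna_log2fc", "gene", "gene_log2fc", "n_sources", "agg_score"],
    )
    out = out.sort_values(["mirna", "agg_score", "gene"], kind="stable").reset_index(drop=True)
    # hard invariant: no emitted pair may have concordant point fold-change signs
    if sign_rule == "point" and len(out):
        assert (out["mirna_log2fc"] * out["gene_log2fc"] < 0).all(), "sign-opposition invariant violated"
    return out


def pair_gene_set(pairs: pd.DataFrame) -> list[str]:
    """Deduplicated, order-stable gene list of the emitted pairs."""
    seen: set[str] = set()
    out: list[str] = []
    for g in pairs["gene"] if "gene" in pairs else []:
        if g not in seen:
            seen.add(g)
            out.append(g)
    return out
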