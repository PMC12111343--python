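"""Hypergeometric over-representation analysis of paired target genes.

The background universe is the gene-set collection's universe (by default
the union of all annotated genes), optionally intersected with the assayed
mRNA features — the defensible background when annotations cover genes the
platform never measured.  p-values use the inclusive upper tail
P[X >= k] and are Benjamini-Hochberg adjusted across tested terms.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import GeneSetCollection
from .diffexp import benjamini_hochberg

__all__ = ["hypergeometric_enrichment", "bubble_export"]


def hypergeometric_enrichment(
    query: list[str], sets: GeneSetCollection
) -> pd.DataFrame:
    """Test every term for over-representation in ``query``.

    Query genes outside the universe are dropped with a warning and do not
    count toward the draw size n.  Returns a DataFrame with one row per
    term: k (overlap), n (retained query size), K (term size), N (universe
    size), fold_enrichment = (k/n)/(K/N), p_raw = P[X >= k] for
    X ~ Hypergeom(N, K, n), and BH-adjusted p_adj; sorted by (p_adj, p_raw,
    term_id).
    """
    universe = sets.universe
    if not universe:
        raise ValueError("empty annotation universe")
    retained = [g for g in dict.fromkeys(query) if g in universe]
    dropped = len(set(query)) - len(retained)
    if dropped:
        warnings.warn(f"{dropped} query gene(s) outside the universe were dropped")
    if not retained:
        raise ValueError("no query genes remain after intersecting with the universe")
    n = len(retained)
    N = len(universe)
    qset = set(retained)
    rows = []
    for tid, (name, genes) in sets.terms.items():
        K = len(genes)
        k = len(qset & genes)
        # inclusive upper tail: P[X >= k] = sf(k - 1)
        p_raw = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if K else 0.0
        rows.append((tid, name, k, n, K, N, fold, p_raw))
    res = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "k", "n", "K", "N", "fold_enrichment", "p_raw"],
    )
    res["p_adj"] = benjamini_hochberg(res["p_raw"].to_numpy())
    res = res.sort_values(["p_adj", "p_raw", "term_id"], kind="stable").reset_index(drop=True)
    return res


def bubble_export(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Bubble-plot rows for terms with p_adj < alpha, sorted by p_adj."""
    keep = results[results["p_adj"] < alpha].copy()
    keep = keep.sort_values(["p_adj", "p_raw", "term_id"], kind="stable")
    with np.errstate(divide="ignore"):
        neg = -np.log10(keep["p_adj"].to_numpy(dtype=float))
    return pd.DataFrame(
        {
            "term_id": keep["term_id"].to_numpy(),
            "term_name": keep["term_name"].to_numpy(),
            "fold_enrichment": keep["fold_enrichment"].to_numpy(),
            "neg_log10_p_adj": neg,
            "k": keep["k"].to_numpy(),
        }
    )
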