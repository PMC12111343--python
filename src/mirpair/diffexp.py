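"""Moderated-t differential expression, compound DE calling, and qPCR stats.

The variance moderation follows the standard empirical-Bayes hierarchical
model for gene-wise variances: the observed pooled variance of feature g is
s_g^2 ~ s0^2 * F(d_g, d0), i.e. the true residual variances are drawn from a
scaled inverse-chi-square prior with d0 degrees of freedom and location s0^2.
The prior is fit by moment matching on z = log(s_g^2):

    var(z)  = trigamma(d_g/2) + trigamma(d0/2)
    mean(z) = log(s0^2) + digamma(d_g/2) - log(d_g/2) - digamma(d0/2) + log(d0/2)

The moderated statistic replaces s_g^2 by the posterior variance
s~^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g) and gains d0 degrees of freedom:
t_mod is referred to a t distribution on d0 + d_g df.  With d0 = 0 this is
the ordinary pooled two-sample t; d0 = +inf is full shrinkage to s0^2 and is
handled as a t with df = 1e6 (normal limit).

A feature is called differentially expressed under the study's compound
cut-off: |fold change| > 2 (|log2FC| > 1) AND raw p < 0.05 AND
Benjamini-Hochberg adjusted p < 0.20.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .core_data import Comparison, CtTable, ExpressionMatrix, SampleDesign

__all__ = [
    "VariancePrior",
    "fit_variance_prior",
    "moderated_t_test",
    "benjamini_hochberg",
    "call_differential",
    "qpcr_ddct",
    "volcano_table",
]

_DF_NORMAL_LIMIT = 1e6


class VariancePrior:
    """Scaled inverse-chi-square prior on residual variances.

    ``d0`` may be ``np.inf`` (full shrinkage to ``s0_sq``); ``s0_sq`` must be
    finite and positive.
    """

    def __init__(self, d0: float, s0_sq: float):
        if not (d0 >= 0):
            raise ValueError(f"d0 must be >= 0, got {d0}")
        if not (np.isfinite(s0_sq) and s0_sq > 0):
            raise ValueError(f"s0_sq must be finite and > 0, got {s0_sq}")
        self.d0 = float(d0)
        self.s0_sq = float(s0_sq)

    def __repr__(self) -> str:
        return f"VariancePrior(d0={self.d0:g}, s0_sq={self.s0_sq:g})"


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        step = tri * (1 - tri / y) / polygamma(2, x)
        x += step
        if abs(step) < tol * x:
            break
    return float(x)


def fit_variance_prior(s_sq: np.ndarray, d_g: float) -> VariancePrior:
    """Moment-matching fit of (d0, s0^2) from per-feature sample variances.

    Features with zero variance are excluded with a warning.  If the spread
    of log variances does not exceed what d_g residual df alone explains,
    the prior degrees of freedom are infinite (full shrinkage).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    if np.any(s_sq == 0):
        warnings.warn(f"excluding {int(np.sum(s_sq == 0))} zero-variance feature(s) from prior fit")
        s_sq = s_sq[s_sq > 0]
    if s_sq.size < 2:
        raise ValueError("need at least 2 positive variances to estimate the prior")
    if d_g < 1:
        raise ValueError(f"residual degrees of freedom must be >= 1, got {d_g}")
    z = np.log(s_sq)
    mean_z = float(np.mean(z))
    var_z = float(np.var(z, ddof=1))
    excess = var_z - polygamma(1, d_g / 2.0)
    if excess <= 0:
        s0_sq = float(np.exp(mean_z - digamma(d_g / 2.0) + np.log(d_g / 2.0)))
        return VariancePrior(np.inf, s0_sq)
    x = _trigamma_inverse(excess)  # x = d0/2
    d0 = 2.0 * x
    log_s0 = mean_z - digamma(d_g / 2.0) + np.log(d_g / 2.0) + digamma(x) - np.log(x)
    return VariancePrior(d0, float(np.exp(log_s0)))


def moderated_t_test(
    m: ExpressionMatrix,
    design: SampleDesign,
    cmp: Comparison,
    prior: VariancePrior | str = "estimate",
) -> pd.DataFrame:
    """Per-feature moderated two-sample t statistics for one comparison.

    Returns a DataFrame indexed by feature with columns mean_a, mean_b,
    log2fc, signed_fc, t_mod, df_total, p_raw, p_adj and a placeholder
    status ('ns' until :func:`call_differential`).  ``prior`` may be a
    fitted :class:`VariancePrior` or ``"estimate"`` to fit one from this
    matrix's pooled variances.
    """
    if m.scale != "log2":
        raise ValueError("differential expression requires a log2-scale matrix")
    for g in (cmp.group_a, cmp.group_b):
        if g not in design.group_order:
            raise ValueError(f"group {g!r} missing from design")
    a_samples = design.samples_of(cmp.group_a)
    b_samples = design.samples_of(cmp.group_b)
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError(f"comparison {cmp.name!r}: both groups need >= 2 samples")
    col = {s: j for j, s in enumerate(m.sample_ids)}
    missing = [s for s in a_samples + b_samples if s not in col]
    if missing:
        raise ValueError(f"design sample(s) absent from matrix: {missing[:5]}")
    xa = m.values[:, [col[s] for s in a_samples]]
    xb = m.values[:, [col[s] for s in b_samples]]
    na, nb = xa.shape[1], xb.shape[1]
    d_g = na + nb - 2

    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    log2fc = mean_a - mean_b
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)
    s_g_sq = ((na - 1) * va + (nb - 1) * vb) / d_g

    if isinstance(prior, str):
        if prior != "estimate":
            raise ValueError(f"prior must be a VariancePrior or 'estimate', got {prior!r}")
        prior = fit_variance_prior(s_g_sq, d_g)

    if np.isinf(prior.d0):
        s_tilde_sq = np.full_like(s_g_sq, prior.s0_sq)
        df_total = _DF_NORMAL_LIMIT
    else:
        s_tilde_sq = (prior.d0 * prior.s0_sq + d_g * s_g_sq) / (prior.d0 + d_g)
        df_total = min(prior.d0 + d_g, _DF_NORMAL_LIMIT)

    se = np.sqrt(s_tilde_sq * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
        # zero posterior variance: t=0, p=1 when the means agree; +-inf otherwise
        degenerate = (se == 0) & (log2fc != 0)
        t_mod = np.where(degenerate, np.sign(log2fc) * np.inf, t_mod)
    p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p_raw = np.where(np.isinf(t_mod), 0.0, p_raw)
    p_adj = benjamini_hochberg(p_raw)

    signed_fc = np.where(log2fc >= 0, np.exp2(log2fc), -np.exp2(-log2fc))
    res = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "signed_fc": signed_fc,
            "t_mod": t_mod,
            "df_total": df_total,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "status": "ns",
        },
        index=pd.Index(m.feature_ids, name="feature"),
    )
    res.attrs["comparison"] = cmp.name
    res.attrs["prior"] = (prior.d0, prior.s0_sq)
    return res


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up FDR adjustment (returns adjusted p-values in input order)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    res: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    fdr_level: float = 0.20,
) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Fill DE status under the compound cut-off; returns (table, (n_down, n_up)).

    up:   log2fc >  log2(fc_threshold) and p_raw < p_threshold and p_adj < fdr_level
    down: log2fc < -log2(fc_threshold) and the same p gates; otherwise ns.
    """
    if fc_threshold <= 0 or p_threshold <= 0 or fdr_level <= 0:
        raise ValueError("thresholds must be positive")
    lfc_gate = np.log2(fc_threshold)
    out = res.copy()
    out.attrs = dict(res.attrs)
    p_ok = (out["p_raw"] < p_threshold) & (out["p_adj"] < fdr_level)
    up = (out["log2fc"] > lfc_gate) & p_ok
    down = (out["log2fc"] < -lfc_gate) & p_ok
    out["status"] = np.where(up, "up", np.where(down, "down", "ns"))
    return out, (int(down.sum()), int(up.sum()))


def qpcr_ddct(
    ct: CtTable, reference_gene: str, ref_group: str, cmp_group: str
) -> pd.DataFrame:
    """Delta-delta-Ct relative quantification against a reference gene.

    Per gene: dCt_s = Ct_s(gene) - Ct_s(reference); ddCt = mean dCt(cmp_group)
    - mean dCt(ref_group); fold = 2^(-ddCt); two-sided equal-variance Student
    t on the dCt values (p is NaN when a group has < 2 samples).
    """
    if reference_gene not in ct.genes:
        raise ValueError(f"reference gene {reference_gene!r} not measured")
    for g in (ref_group, cmp_group):
        if g not in ct.design.group_order:
            raise ValueError(f"group {g!r} missing from design")
    frame = ct.to_frame()
    dct = frame.sub(frame[reference_gene], axis=0)
    ref_samples = [s for s in ct.samples if ct.design.assignments[s] == ref_group]
    cmp_samples = [s for s in ct.samples if ct.design.assignments[s] == cmp_group]
    if not ref_samples or not cmp_samples:
        raise ValueError("both groups must have measured samples")
    rows = []
    for gene in ct.genes:
        if gene == reference_gene:
            continue
        d_ref = dct.loc[ref_samples, gene].to_numpy()
        d_cmp = dct.loc[cmp_samples, gene].to_numpy()
        ddct = d_cmp.mean() - d_ref.mean()
        fold = float(2.0 ** (-ddct))
        if len(d_ref) >= 2 and len(d_cmp) >= 2:
            if np.allclose(d_ref, d_ref[0]) and np.allclose(d_cmp, d_cmp[0]) and ddct == 0:
                p = 1.0
            else:
                p = float(stats.ttest_ind(d_cmp, d_ref, equal_var=True).pvalue)
        else:
            p = float("nan")
        rows.append((gene, fold, p))
    return pd.DataFrame(rows, columns=["gene", "fold_change", "p"]).set_index("gene")


def volcano_table(res: pd.DataFrame) -> pd.DataFrame:
    """Lossless volcano-plot projection: feature, log2fc, -log10 p_raw, status."""
    with np.errstate(divide="ignore"):
        neg_log10_p = -np.log10(res["p_raw"].to_numpy(dtype=float))
    out = pd.DataFrame(
        {
            "log2fc": res["log2fc"],
            "neg_log10_p": neg_log10_p,
            "status": res["status"],
        },
        index=res.index,
    )
    out.attrs = dict(res.attrs)
    return out
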