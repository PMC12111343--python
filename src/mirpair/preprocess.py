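"""Normalization, probe summarization and variance filtering.

The pipeline's contract starts at intensity matrices: exact reproduction of
array-platform background correction (normexp) is out of scope, but the two
RMA workhorses — quantile normalization across samples and Tukey median
polish for probe-to-feature summarization — are implemented here, together
with a low-variance feature filter and a guarded log2 transform.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core_data import ExpressionMatrix

__all__ = [
    "quantile_normalize",
    "median_polish_summarize",
    "filter_low_variance",
    "log2_transform",
    "background_floor",
]


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to share the mean-of-order-statistics distribution.

    Ties within a column receive the mean of the reference values at their
    tied rank positions, so the operation is permutation-equivariant and
    idempotent.
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    x = m.values
    order = np.argsort(x, axis=0, kind="stable")
    ref = np.mean(np.take_along_axis(x, order, axis=0), axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col_sorted = x[order[:, j], j]
        mapped = ref.copy()
        # average the reference over each tie block of the sorted column
        start = 0
        for i in range(1, len(col_sorted) + 1):
            if i == len(col_sorted) or col_sorted[i] != col_sorted[start]:
                if i - start > 1:
                    mapped[start:i] = ref[start:i].mean()
                start = i
        out[order[:, j], j] = mapped
    return ExpressionMatrix(list(m.feature_ids), list(m.sample_ids), out, m.scale)


def _median_polish(x: np.ndarray, tol: float = 1e-6, max_iter: int = 10) -> tuple[float, np.ndarray, np.ndarray]:
    """Tukey median polish of a probes-x-samples submatrix.

    Returns (overall, row_effects, col_effects); sweeps alternate row and
    column medians until the largest sweep adjustment falls below ``tol``
    or ``max_iter`` iterations.
    """
    z = x.astype(float).copy()
    overall = 0.0
    row = np.zeros(z.shape[0])
    col = np.zeros(z.shape[1])
    for _ in range(max_iter):
        rdelta = np.median(z, axis=1)
        z -= rdelta[:, None]
        row += rdelta
        cmed = np.median(col)
        col -= cmed
        overall += cmed
        cdelta = np.median(z, axis=0)
        z -= cdelta[None, :]
        col += cdelta
        rmed = np.median(row)
        row -= rmed
        overall += rmed
        change = max(np.max(np.abs(rdelta)), np.max(np.abs(cdelta)))
        if change < tol:
            break
    return overall, row, col


def median_polish_summarize(
    probe_values: ExpressionMatrix, probe_map: dict[str, str]
) -> ExpressionMatrix:
    """Summarize probe-level log2 intensities to one value per feature.

    Per feature, Tukey median polish is run on its probes-x-samples
    submatrix and the feature's per-sample value is overall + column effect
    (the probe/row effects are nuisance).  Features appear in order of
    their first probe.
    """
    if probe_values.scale != "log2":
        raise ValueError("median polish summarization expects log2-scale probes")
    unmapped = [p for p in probe_values.feature_ids if p not in probe_map]
    if unmapped:
        raise ValueError(f"unmapped probe(s): {unmapped[:5]}")
    feature_order: list[str] = []
    probes_of: dict[str, list[int]] = {}
    for i, p in enumerate(probe_values.feature_ids):
        f = probe_map[p]
        if f not in probes_of:
            probes_of[f] = []
            feature_order.append(f)
        probes_of[f].append(i)
    empty = [f for f in set(probe_map.values()) if f not in probes_of]
    if empty:
        raise ValueError(f"feature(s) with 0 probes: {sorted(empty)[:5]}")
    out = np.empty((len(feature_order), probe_values.n_samples))
    for r, f in enumerate(feature_order):
        sub = probe_values.values[probes_of[f]]
        overall, _row, colfx = _median_polish(sub)
        out[r] = overall + colfx
    return ExpressionMatrix(feature_order, list(probe_values.sample_ids), out, "log2")


def filter_low_variance(m: ExpressionMatrix, quantile_cut: float) -> ExpressionMatrix:
    """Drop features whose across-sample variance falls below the
    ``quantile_cut`` empirical quantile of all feature variances.
    Survivor order and values are untouched; ``quantile_cut=0`` is a no-op."""
    if not (0 <= quantile_cut < 1):
        raise ValueError(f"quantile_cut must be in [0, 1), got {quantile_cut}")
    if quantile_cut == 0:
        return m
    variances = np.var(m.values, axis=1, ddof=1)
    threshold = np.quantile(variances, quantile_cut)
    keep = variances >= threshold
    return ExpressionMatrix(
        [f for f, k in zip(m.feature_ids, keep) if k],
        list(m.sample_ids),
        m.values[keep],
        m.scale,
    )


def log2_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(x + offset) for linear-scale input; the offset guards zeros."""
    if m.scale == "log2":
        return m
    if offset < 0:
        raise ValueError("offset must be >= 0")
    return ExpressionMatrix(
        list(m.feature_ids), list(m.sample_ids), np.log2(m.values + offset), "log2"
    )


def background_floor(m: ExpressionMatrix, percentile: float = 2.0, floor: float = 1e-3) -> ExpressionMatrix:
    """Optional crude background step for linear intensities: subtract each
    sample's ``percentile``-th percentile and clamp at ``floor``.  Default off
    in the pipeline; not an emulation of normexp."""
    if m.scale != "linear":
        raise ValueError("background correction applies to linear-scale intensities")
    bg = np.percentile(m.values, percentile, axis=0)
    vals = np.maximum(m.values - bg[None, :], floor)
    return ExpressionMatrix(list(m.feature_ids), list(m.sample_ids), vals, "linear")
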