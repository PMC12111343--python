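"""Direction/significance concordance against externally supplied DE tables.

The external table (e.g. a published re-analysis of a comparable experiment)
is consumed as-is: this module never re-runs differential expression on the
other study's data, it only compares fold-change signs and significance
flags over the features significant in the pipeline's own table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ComparisonOutcome", "direction_concordance"]


@dataclass
class ComparisonOutcome:
    per_feature: pd.DataFrame  # log2fc_self, log2fc_other, significant_self/other, concordant
    n_common: int
    concordant_fraction: float


def direction_concordance(
    self_table: pd.DataFrame,
    other_table: pd.DataFrame,
    alpha: float = 0.05,
) -> ComparisonOutcome:
    """Compare fold-change direction with an external DE table.

    ``other_table`` must have columns feature (or an index), log2fc, p_adj.
    The comparison is restricted to features significant in ``self_table``
    (status != ns); the concordant flag records sign agreement of the two
    log2 fold changes, and the summary fraction averages it over features
    where both fold changes are nonzero.  Magnitudes never enter the result.
    """
    other = other_table.copy()
    if "feature" in other.columns:
        other = other.set_index("feature")
    for c in ("log2fc", "p_adj"):
        if c not in other.columns:
            raise ValueError(f"external table lacks required column {c!r}")
    sig_self = self_table[self_table["status"] != "ns"]
    common = sig_self.index.intersection(other.index)
    if len(common) == 0:
        unmatched = list(sig_self.index[:10])
        raise ValueError(
            "no overlap between significant features and the external table; "
            f"first unmatched ids: {unmatched}"
        )
    lfc_self = sig_self.loc[common, "log2fc"].to_numpy(dtype=float)
    lfc_other = other.loc[common, "log2fc"].to_numpy(dtype=float)
    sig_other = other.loc[common, "p_adj"].to_numpy(dtype=float) < alpha
    concordant = np.sign(lfc_self) == np.sign(lfc_other)
    per_feature = pd.DataFrame(
        {
            "log2fc_self": lfc_self,
            "log2fc_other": lfc_other,
            "significant_self": True,
            "significant_other": sig_other,
            "concordant": concordant,
        },
        index=pd.Index(common, name="feature"),
    )
    both_nonzero = (lfc_self != 0) & (lfc_other != 0)
    frac = float(concordant[both_nonzero].mean()) if both_nonzero.any() else float("nan")
    return ComparisonOutcome(per_feature, int(len(common)), frac)
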