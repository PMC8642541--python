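"""Differential-expression calling per organ.

Genes are called differentially expressed (DEG) between treated and control
samples of one organ when the raw two-sided p-value is below ``p_threshold``
(default 0.05) and the absolute log2 fold change is at least
``lfc_threshold`` (default 0.5).  Expression values are assumed to be on
log2 scale already, so the fold change is a plain difference of group means.

The per-gene test is a two-sided Welch t-test (unequal variances).  No
multiple-testing correction is applied at this stage; false-positive control
happens downstream through the permutation scheme of module discovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DEGResult", "call_degs"]


@dataclass
class DEGResult:
    """Per-gene differential-expression table for one organ.

    ``table`` has columns ``log2fc`` (treated minus control mean), ``p`` and
    ``is_deg``; the flag is exactly ``(p < p_threshold) & (|log2fc| >=
    lfc_threshold)``.
    """

    table: pd.DataFrame
    organ: str
    p_threshold: float
    lfc_threshold: float

    @property
    def deg_set(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["is_deg"]])

    @property
    def n_degs(self) -> int:
        return int(self.table["is_deg"].sum())


def call_degs(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    organ: str,
    p_threshold: float = 0.05,
    lfc_threshold: float = 0.5,
) -> DEGResult:
    """Welch-test treated vs control within one organ and flag DEGs.

    Requires at least two treated and two control samples in the organ.
    Genes with zero variance in both groups get p = 1 when the group means
    are equal and p = 0 otherwise (the test is degenerate but the direction
    of evidence is unambiguous).
    """
    organs = set(meta["organ"])
    if organ not in organs:
        raise ValueError(f"organ {organ!r} absent from metadata (has {sorted(organs)})")
    sub = meta[meta["organ"] == organ]
    treated = sub.index[sub["treatment"] == "treated"]
    control = sub.index[sub["treatment"] == "control"]
    if len(treated) < 2 or len(control) < 2:
        raise ValueError(
            f"organ {organ!r}: need >=2 samples per group, "
            f"got {len(treated)} treated / {len(control)} control"
        )

    xt = expr[list(treated)].to_numpy()
    xc = expr[list(control)].to_numpy()
    log2fc = xt.mean(axis=1) - xc.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(xt, xc, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (xt.var(axis=1) == 0) & (xc.var(axis=1) == 0)
    p[degenerate] = np.where(log2fc[degenerate] != 0, 0.0, 1.0)

    is_deg = (p < p_threshold) & (np.abs(log2fc) >= lfc_threshold)
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "is_deg": is_deg}, index=expr.index.copy()
    )
    return DEGResult(table=table, organ=organ, p_threshold=p_threshold, lfc_threshold=lfc_threshold)
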