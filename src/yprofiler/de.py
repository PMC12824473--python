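"""Two-group differential expression summary on log-scale values.

This stage is deliberately a transparent surrogate: a gene-wise Welch
two-sample t-test on log-scale expression, with Benjamini-Hochberg FDR
control across genes. It is NOT a count-model (negative-binomial) DE fit;
downstream consumers rely only on the significance filter (FDR < q_max and
|log2FC| > lfc_min, both strict) and on gene-set mean log2-fold-change
summaries, whose semantics are independent of the per-gene test.

log2FC is defined as mean(group_b) - mean(group_a) on the log2 scale, so
positive values are up in group_b.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ntp import bh_fdr

__all__ = ["gene_wise_de", "filter_significant", "pathway_mean_lfc"]


def gene_wise_de(
    logexpr: pd.DataFrame, groups: pd.Series, group_a: str | None = None, group_b: str | None = None
) -> pd.DataFrame:
    """Welch t-test per gene between two sample groups on log-scale values.

    Parameters
    ----------
    logexpr
        Genes x samples log2-scale matrix.
    groups
        Sample -> group label; exactly two levels used. ``group_a`` /
        ``group_b`` pin the contrast direction (log2fc = mean_b - mean_a);
        by default levels are taken in sorted order.

    Returns
    -------
    Per-gene frame with ``log2fc``, ``p``, ``q`` (BH), ``mean_a``,
    ``mean_b`` and a ``zero_variance`` flag for genes where both groups are
    constant (their p is reported as 1).
    """
    groups = groups.loc[[s for s in logexpr.columns if s in groups.index]]
    levels = sorted(groups.unique())
    if group_a is None or group_b is None:
        if len(levels) != 2:
            raise ValueError(f"expected exactly 2 group levels, got {levels}")
        group_a, group_b = levels
    sa = groups.index[groups == group_a]
    sb = groups.index[groups == group_b]
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each group needs at least 2 samples")
    A = logexpr[sa].to_numpy(float)
    B = logexpr[sb].to_numpy(float)
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(B, A, axis=1, equal_var=False)
    zero_var = (A.std(axis=1) == 0) & (B.std(axis=1) == 0)
    p = np.where(np.isnan(p) | zero_var, 1.0, p)
    out = pd.DataFrame(
        {
            "log2fc": mean_b - mean_a,
            "p": p,
            "q": bh_fdr(p),
            "mean_a": mean_a,
            "mean_b": mean_b,
            "zero_variance": zero_var,
        },
        index=logexpr.index,
    )
    out.attrs["contrast"] = f"{group_b} vs {group_a}"
    return out


def filter_significant(
    table: pd.DataFrame, q_max: float = 0.05, lfc_min: float = 2.0
) -> pd.DataFrame:
    """Rows with q < q_max AND |log2fc| > lfc_min (both strict).

    The fold-change cut is two-sided: strong down-regulation passes too.
    """
    if q_max <= 0 or lfc_min <= 0:
        raise ValueError("thresholds must be positive")
    mask = (table["q"] < q_max) & (table["log2fc"].abs() > lfc_min)
    return table[mask]


def pathway_mean_lfc(table: pd.DataFrame, gene_set: list[str], set_name: str = "") -> dict:
    """Mean log2FC over the gene-set members present in the DE table.

    Returns {"set", "n_set", "n_present", "mean_lfc"}; raises if no member
    of the set is present.
    """
    present = [g for g in gene_set if g in table.index]
    if not present:
        raise ValueError(f"no member of gene set {set_name or '<unnamed>'!r} present in table")
    return {
        "set": set_name,
        "n_set": len(gene_set),
        "n_present": len(present),
        "mean_lfc": float(table.loc[present, "log2fc"].mean()),
    }
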