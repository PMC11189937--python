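"""Lineage enrichment of del5q cells and cross-condition abundance tests.

Per cell type, the accumulation of del5q cells is scored with a one-sided
hypergeometric test: drawing ``n_type`` cells (the cell type) from ``N_total``
classified cells of which ``K_del_total`` are del5q, how surprising is
observing ``k_del`` or more del5q cells of that type? Ambiguous cells are in
neither genotype class and are excluded throughout. Cross-condition cell-type
abundance is compared per type with an exact two-sided rank-sum test on
per-sample proportions (groups of 3-4 samples cannot be paired; a paired
signed-rank mode exists behind ``paired=True``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .consensus import GENOTYPE_DEL, GENOTYPE_NON_DEL


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K marked, n drawn)."""
    return float(scipy.stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrichment(
    calls: pd.DataFrame,
    by_sample: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-cell-type del5q enrichment, per sample and/or pooled.

    ``calls`` needs genotype, cell_type and (if ``by_sample``) sample_id
    columns. Returns long-format rows with the hypergeometric inputs, the
    one-sided p, -log10(p) and a significance flag at ``alpha`` (raw p, no
    multiplicity adjustment, matching the usual per-patient heatmap).
    """
    classified = calls[calls["genotype"].isin([GENOTYPE_DEL, GENOTYPE_NON_DEL])]
    groups = (
        [(s, sub) for s, sub in classified.groupby("sample_id", sort=True)]
        if by_sample
        else []
    )
    groups.append(("pooled", classified))
    rows = []
    for label, sub in groups:
        N = len(sub)
        K = int((sub["genotype"] == GENOTYPE_DEL).sum())
        for ctype, tsub in sub.groupby("cell_type", sort=True):
            n = len(tsub)
            if n == 0:
                continue
            k = int((tsub["genotype"] == GENOTYPE_DEL).sum())
            p = hypergeom_pvalue(N, K, n, k)
            rows.append(
                dict(
                    scope=label,
                    cell_type=ctype,
                    n_type=n,
                    k_del=k,
                    N_total=N,
                    K_del_total=K,
                    p_hyper=p,
                    neg_log10_p=-np.log10(max(p, np.finfo(float).tiny)),
                    significant=p < alpha,
                )
            )
    return pd.DataFrame(rows)


def celltype_proportions(meta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample cell-type proportion matrix (rows sum to 1)."""
    tab = pd.crosstab(meta["sample_id"], meta["cell_type"])
    return tab.div(tab.sum(axis=1), axis=0)


def abundance_test(
    proportions: pd.DataFrame,
    groups: dict,
    paired: bool = False,
) -> pd.DataFrame:
    """Per-cell-type two-sided exact rank test of group proportion values.

    ``groups`` maps sample_id -> group label (exactly two labels). Groups with
    a single sample yield NaN p flagged ``undefined``. p-values are unadjusted.
    """
    labels = pd.Series({s: groups[s] for s in proportions.index if s in groups})
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"need exactly two group labels, got {uniq}")
    a_idx = labels.index[labels == uniq[0]]
    b_idx = labels.index[labels == uniq[1]]
    rows = []
    for ctype in proportions.columns:
        x = proportions.loc[a_idx, ctype].to_numpy()
        y = proportions.loc[b_idx, ctype].to_numpy()
        undefined = min(len(x), len(y)) < 2 or (paired and len(x) != len(y))
        if undefined:
            p = np.nan
        elif paired:
            d = x - y
            p = 1.0 if np.allclose(d, 0) else float(
                scipy.stats.wilcoxon(x, y, alternative="two-sided").pvalue
            )
        else:
            p = min(
                1.0,
                float(
                    scipy.stats.mannwhitneyu(
                        x, y, alternative="two-sided", method="exact"
                    ).pvalue
                ),
            )
        rows.append(
            dict(
                cell_type=ctype,
                group_a=uniq[0],
                group_b=uniq[1],
                n_a=len(x),
                n_b=len(y),
                mean_a=float(x.mean()) if len(x) else np.nan,
                mean_b=float(y.mean()) if len(y) else np.nan,
                p=p,
                undefined=undefined,
            )
        )
    return pd.DataFrame(rows)
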