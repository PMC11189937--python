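"""Consensus three-way genotype from the two evidence channels.

A cell is called del5q only when *both* channels independently call the target
region deleted, and non_del5q only when *neither* channel found any alteration.
Everything else — channel disagreement, an amplified arm call, or an
uninformative allele channel — is "ambiguous" and is excluded from del-vs-non-
del contrasts downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import allele as ac
from . import expression as ec
from .io import ConsistencyError

GENOTYPE_DEL = "del5q"
GENOTYPE_NON_DEL = "non_del5q"
GENOTYPE_AMBIGUOUS = "ambiguous"


def combine(expr_calls: pd.DataFrame, allele_calls: pd.DataFrame) -> pd.DataFrame:
    """Intersect per-cell channel verdicts into the consensus genotype.

    Both inputs must cover exactly the same cell set; a cell present in only
    one channel raises :class:`ConsistencyError` naming it.
    """
    e = pd.Index(expr_calls["cell_id"])
    a = pd.Index(allele_calls["cell_id"])
    only_e, only_a = e.difference(a), a.difference(e)
    if len(only_e) or len(only_a):
        example = list(only_e[:3]) + list(only_a[:3])
        raise ConsistencyError(
            f"channels cover different cell sets; e.g. {example}"
        )
    merged = expr_calls[["cell_id", "expression_call"]].merge(
        allele_calls[["cell_id", "allele_call"]], on="cell_id", validate="1:1"
    )
    both_del = (merged["expression_call"] == ec.CALL_DELETED) & (
        merged["allele_call"] == ac.CALL_DELETED
    )
    both_neutral = (merged["expression_call"] == ec.CALL_NEUTRAL) & (
        merged["allele_call"] == ac.CALL_NEUTRAL
    )
    merged["genotype"] = np.select(
        [both_del, both_neutral],
        [GENOTYPE_DEL, GENOTYPE_NON_DEL],
        default=GENOTYPE_AMBIGUOUS,
    )
    return merged


def estimate_fraction(calls: pd.DataFrame, by: str = "sample_id") -> pd.DataFrame:
    """Per-sample deletion fractions under both denominators.

    ``fraction_all`` = del5q / all cells; ``fraction_classified`` =
    del5q / (del5q + non_del5q). A sample with no classified cells gets NaN
    and ``undefined_classified_fraction=True`` rather than a number.
    """
    if by not in calls.columns:
        raise KeyError(f"calls lack a {by!r} column")
    rows = []
    for key, sub in calls.groupby(by, sort=True):
        n = len(sub)
        n_del = int((sub["genotype"] == GENOTYPE_DEL).sum())
        n_non = int((sub["genotype"] == GENOTYPE_NON_DEL).sum())
        n_amb = n - n_del - n_non
        classified = n_del + n_non
        rows.append(
            {
                by: key,
                "n_cells": n,
                "n_del5q": n_del,
                "n_non_del5q": n_non,
                "n_ambiguous": n_amb,
                "fraction_all": n_del / n if n else np.nan,
                "fraction_classified": n_del / classified if classified else np.nan,
                "ambiguous_fraction": n_amb / n if n else np.nan,
                "undefined_classified_fraction": classified == 0,
            }
        )
    return pd.DataFrame(rows)
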