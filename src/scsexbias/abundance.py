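"""Differential cell-type abundance between sexes.

Cells are pooled across replicates within each sex; each observed cell type
is compared between sexes with a pooled two-proportion test (Yates continuity
correction by default) and a pseudocounted log2 fold change of proportions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .io_qc import FEMALE, MALE, CellMetadata

FEMALE_BIASED = "female_biased"
MALE_BIASED = "male_biased"
UNBIASED = "unbiased"

DEFAULT_PSEUDOCOUNT = 1e-10
DEFAULT_ALPHA = 0.01


def abundance_log2fc(
    prop_female: float, prop_male: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """log2 of the pseudocounted female/male proportion ratio; always finite."""
    if prop_female < 0 or prop_male < 0 or prop_female > 1 or prop_male > 1:
        raise ValueError("proportions must lie in [0, 1]")
    return float(np.log2((prop_female + pseudocount) / (prop_male + pseudocount)))


def two_proportion_test(
    n1: int, total1: int, n2: int, total2: int, continuity: bool = True
) -> float:
    """Two-sided pooled two-proportion test p-value.

    Implemented as the chi-square test on the 2x2 success/failure table, with
    Yates continuity correction by default — the classical z-test squared.
    Degenerate tables (all successes or all failures) return p = 1.
    """
    for n, total in ((n1, total1), (n2, total2)):
        if total <= 0:
            raise ValueError("totals must be positive")
        if n < 0 or n > total:
            raise ValueError("counts must satisfy 0 <= n <= total")
    table = np.array([[n1, total1 - n1], [n2, total2 - n2]], dtype=float)
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return 1.0
    _, p, _, _ = stats.chi2_contingency(table, correction=continuity)
    return float(p)


def test_abundance(
    meta: CellMetadata,
    alpha: float = DEFAULT_ALPHA,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    continuity: bool = True,
) -> pd.DataFrame:
    """One differential-abundance result per observed cell type.

    Returns a DataFrame with columns cell_type, n_female, n_male,
    total_female, total_male, prop_female, prop_male, log2fc, p_value, call.
    """
    frame = meta.frame
    totals = frame["sex"].value_counts()
    for sex in (FEMALE, MALE):
        if totals.get(sex, 0) == 0:
            raise ValueError(f"no cells for sex {sex!r}")
    total_f = int(totals[FEMALE])
    total_m = int(totals[MALE])
    counts = (
        frame.groupby(["cell_type", "sex"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=[FEMALE, MALE], fill_value=0)
    )
    rows = []
    for cell_type, row in counts.iterrows():
        n_f, n_m = int(row[FEMALE]), int(row[MALE])
        p_f, p_m = n_f / total_f, n_m / total_m
        lfc = abundance_log2fc(p_f, p_m, pseudocount)
        pval = two_proportion_test(n_f, total_f, n_m, total_m, continuity=continuity)
        if pval < alpha and lfc > 0:
            call = FEMALE_BIASED
        elif pval < alpha and lfc < 0:
            call = MALE_BIASED
        else:
            call = UNBIASED
        rows.append(
            {
                "cell_type": cell_type,
                "n_female": n_f,
                "n_male": n_m,
                "total_female": total_f,
                "total_male": total_m,
                "prop_female": p_f,
                "prop_male": p_m,
                "log2fc": lfc,
                "p_value": pval,
                "call": call,
            }
        )
    return pd.DataFrame(rows)


test_abundance.__test__ = False  # not a pytest test, despite the name


def replicate_proportions(meta: CellMetadata, ci_level: float = 0.95) -> pd.DataFrame:
    """Per-sample cell-type proportions with Wilson intervals (diagnostic only)."""
    frame = meta.frame
    rows = []
    for (sample, cell_type), sub in frame.groupby(["sample_id", "cell_type"], observed=True):
        total = int((frame["sample_id"] == sample).sum())
        n = len(sub)
        lo, hi = proportion_confint(n, total, alpha=1 - ci_level, method="wilson")
        rows.append(
            {
                "sample_id": sample,
                "sex": sub["sex"].iloc[0],
                "cell_type": cell_type,
                "n_cells": n,
                "total_cells": total,
                "proportion": n / total,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)
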