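"""Combine whole-tissue and per-cell-type DE calls into causal categories.

A gene is ``bulk_only`` when sex-biased at the whole-tissue level but
unbiased in every tested cell type (abundance-driven signature);
``bulk_and_cell`` when biased at both levels; ``cell_only`` when biased in at
least one cell type but not at the whole-tissue level (dilution signature);
``unbiased`` otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pseudobulk import FEMALE_BIASED, MALE_BIASED, UNBIASED, UNTESTED

BULK_ONLY = "bulk_only"
BULK_AND_CELL = "bulk_and_cell"
CELL_ONLY = "cell_only"
CATEGORIES = (UNBIASED, BULK_ONLY, BULK_AND_CELL, CELL_ONLY)

_BIASED = {FEMALE_BIASED, MALE_BIASED}
_DIRECTION = {FEMALE_BIASED: "female", MALE_BIASED: "male"}


class ClassifyError(ValueError):
    """Gene universes of bulk and cell-type results are inconsistent."""


def classify_genes(
    bulk: pd.DataFrame, per_cell_type: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Assign each gene to a category from bulk and per-cell-type DE calls.

    ``bulk`` and each value of ``per_cell_type`` are DE result frames with
    ``gene_id`` and ``call`` columns.  Cell-type gene sets must be subsets of
    the bulk universe.  Returns a frame with gene_id, bulk_call,
    n_cell_biased, n_cell_tested, category, direction, direction_conflict.
    """
    bulk_calls = bulk.set_index("gene_id")["call"]
    universe = bulk_calls.index
    if universe.duplicated().any():
        raise ClassifyError("duplicate gene ids in bulk results")

    cell_calls = pd.DataFrame(index=universe)
    for ct, res in per_cell_type.items():
        extra = set(res["gene_id"]) - set(universe)
        if extra:
            raise ClassifyError(
                f"cell type {ct!r} has gene id(s) absent from the bulk universe, "
                f"e.g. {sorted(extra)[:3]}"
            )
        cell_calls[ct] = res.set_index("gene_id")["call"].reindex(universe)

    rows = []
    for gene in universe:
        b = bulk_calls[gene]
        calls = [] if cell_calls.empty else [
            c for c in cell_calls.loc[gene] if isinstance(c, str)
        ]
        biased_calls = [c for c in calls if c in _BIASED]
        tested_calls = [c for c in calls if c != UNTESTED]
        bulk_biased = b in _BIASED

        if bulk_biased and biased_calls:
            category = BULK_AND_CELL
        elif bulk_biased:
            category = BULK_ONLY
        elif biased_calls:
            category = CELL_ONLY
        else:
            category = UNBIASED

        conflict = False
        if category in (BULK_ONLY, BULK_AND_CELL):
            direction = _DIRECTION[b]
            conflict = any(_DIRECTION[c] != direction for c in biased_calls)
        elif category == CELL_ONLY:
            dirs = {_DIRECTION[c] for c in biased_calls}
            direction = dirs.pop() if len(dirs) == 1 else "mixed"
        else:
            direction = "n/a"

        rows.append(
            {
                "gene_id": gene,
                "bulk_call": b,
                "n_cell_biased": len(biased_calls),
                "n_cell_tested": len(tested_calls),
                "category": category,
                "direction": direction,
                "direction_conflict": conflict,
            }
        )
    return pd.DataFrame(rows)


def summarize_categories(categories: pd.DataFrame) -> dict:
    """Counts per category/direction plus the cell-level and bulk-level unions.

    The cell-level union is ``bulk_and_cell + cell_only`` (genes biased in at
    least one cell type); the bulk-level union is ``bulk_only +
    bulk_and_cell``.  Also reports the fraction of cell-level genes that are
    unbiased at bulk (``cell_only_fraction``).
    """
    counts = {
        cat: int((categories["category"] == cat).sum()) for cat in CATEGORIES
    }
    by_direction = (
        categories.groupby(["category", "direction"], observed=True)
        .size()
        .to_dict()
    )
    cell_level = counts[BULK_AND_CELL] + counts[CELL_ONLY]
    bulk_level = counts[BULK_ONLY] + counts[BULK_AND_CELL]
    return {
        "counts": counts,
        "counts_by_direction": {f"{c}|{d}": int(n) for (c, d), n in by_direction.items()},
        "cell_level_union": cell_level,
        "bulk_level_union": bulk_level,
        "cell_only_fraction": (counts[CELL_ONLY] / cell_level) if cell_level else float("nan"),
    }


def bulk_only_expression_table(
    categories: pd.DataFrame,
    celltype_means: pd.DataFrame,
    abundance: pd.DataFrame,
) -> pd.DataFrame:
    """Descriptive table: mean normalized expression of bulk_only genes in
    abundance-biased vs abundance-unbiased cell types.

    ``celltype_means`` is genes x cell types (mean normalized pseudobulk);
    ``abundance`` is the differential-abundance result frame.
    """
    biased_types = set(abundance.loc[abundance["call"] != UNBIASED, "cell_type"])
    genes = categories.loc[categories["category"] == BULK_ONLY, "gene_id"]
    sub = celltype_means.loc[celltype_means.index.intersection(genes)]
    biased_cols = [c for c in sub.columns if c in biased_types]
    unbiased_cols = [c for c in sub.columns if c not in biased_types]
    return pd.DataFrame(
        {
            "gene_id": sub.index,
            "mean_expr_abundance_biased": sub[biased_cols].mean(axis=1)
            if biased_cols
            else np.nan,
            "mean_expr_abundance_unbiased": sub[unbiased_cols].mean(axis=1)
            if unbiased_cols
            else np.nan,
        }
    ).reset_index(drop=True)
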