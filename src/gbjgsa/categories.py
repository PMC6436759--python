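"""Observed-vs-expected summary of significant pathways by category.

Under the null that every tested pathway has the same chance of reaching
significance, a category holding a fraction f of tested pathways is expected
to hold f * n_significant of the significant ones; the percent difference
between observed and expected counts highlights the biological systems
where significant pathways congregate.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["DEFAULT_CATEGORIES", "category_enrichment"]

#: top-level biological-process category vocabulary
DEFAULT_CATEGORIES = (
    "Biological Adhesion",
    "Cellular Component Organization or Biogenesis",
    "Developmental Process",
    "Growth",
    "Immune System Process",
    "Localization",
    "Locomotion",
    "Metabolic Process",
    "Reproduction",
    "Response to Stimulus",
    "Signaling",
)


def category_enrichment(results: pd.DataFrame, category_map: pd.DataFrame) -> pd.DataFrame:
    """Per-category observed and expected significant-pathway counts.

    ``results`` needs columns ``set`` and ``significant``; ``category_map``
    is two columns (pathway, category), possibly many-to-many (overlapping
    categories are each credited).  Expected count for category c is
    ``(n_tested_in_c / n_tested) * n_significant``; ``pct_diff`` is
    ``100 (O - E) / E``, reported missing (NaN) when E = 0.
    """
    if not {"set", "significant"} <= set(results.columns):
        raise ValueError("results must have 'set' and 'significant' columns")
    cm = category_map.rename(
        columns=dict(zip(category_map.columns[:2], ["set", "category"]))
    )[["set", "category"]].drop_duplicates()
    n_tested = len(results)
    n_sig = int(results["significant"].sum())
    sig_sets = set(results.loc[results["significant"], "set"])
    tested_sets = set(results["set"])
    rows = []
    for cat, sub in cm.groupby("category"):
        members = set(sub["set"]) & tested_sets
        observed = len(members & sig_sets)
        expected = (len(members) / n_tested) * n_sig if n_tested else 0.0
        pct = 100.0 * (observed - expected) / expected if expected > 0 else float("nan")
        rows.append(
            {
                "category": cat,
                "n_tested": len(members),
                "n_observed": observed,
                "n_expected": expected,
                "pct_diff": pct,
            }
        )
    return pd.DataFrame(rows).sort_values("category").reset_index(drop=True)
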