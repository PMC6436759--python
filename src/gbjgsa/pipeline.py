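"""Database-wide gene set analysis with family-wise error control."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .assembly import GeneSetDB, assemble_set, filter_db_by_size
from .containers import MappedSet
from .exceedance import two_sided_pi
from .gof import gbj_test, single_z_pvalue

__all__ = ["bonferroni_level", "run_gsa", "suggestive_density"]

logger = logging.getLogger(__name__)

#: suggestive-signal cutoff: two-sided p < 1e-5
SUGGESTIVE_P = 1e-5


def bonferroni_level(alpha: float, n_tests: int) -> float:
    """Per-test level alpha / n_tests controlling the family-wise error."""
    if n_tests < 1:
        raise ValueError("n_tests >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha in (0,1)")
    return alpha / n_tests


def suggestive_density(mapped: MappedSet, p_cut: float = SUGGESTIVE_P) -> float:
    """Fraction of a set's retained SNPs with two-sided normal p < p_cut."""
    if mapped.z is None or mapped.z.d == 0:
        raise ValueError("set has no retained SNPs")
    pvals = two_sided_pi(np.abs(mapped.z.z))
    return float(np.mean(pvals < p_cut))


def _test_mapped(mapped: MappedSet):
    if mapped.z.d == 1:
        p = single_z_pvalue(float(mapped.z.z[0]))
        return 0.0, p, False
    res = gbj_test(mapped.z, mapped.sigma)
    return res.statistic, res.p_value, res.p_floored


def run_gsa(
    db: GeneSetDB,
    sumstats: pd.DataFrame,
    annotation: pd.DataFrame,
    panel,
    alpha: float = 0.05,
    size_filter: bool = True,
    n_tests: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GBJ across a pathway database with Bonferroni control.

    Returns (results, untested): one results row per testable set with its
    statistic, analytic p-value, suggestive-signal density, and a
    significance call at ``alpha / n_tests``.  By default ``n_tests`` is the
    number of sets passing the size filter (the convention used for the
    published corrected level); pass ``n_tests`` explicitly to divide by the
    post-assembly testable count instead.
    """
    if size_filter:
        db = filter_db_by_size(db)
    rows, skipped = [], []
    for name, genes in db.sets.items():
        source, set_id = db.source_id(name)
        mapped = assemble_set(name, genes, sumstats, annotation, panel)
        if not mapped.testable:
            skipped.append(
                {"set": name, "source": source, "id": set_id, "reason": mapped.reason}
            )
            continue
        stat, p, floored = _test_mapped(mapped)
        rows.append(
            {
                "set": name,
                "source": source,
                "id": set_id,
                "n_genes": mapped.n_genes,
                "n_snps": mapped.n_snps,
                "statistic": stat,
                "p_value": p,
                "p_floored": floored,
                "suggestive_density": suggestive_density(mapped),
            }
        )
    untested = pd.DataFrame(skipped, columns=["set", "source", "id", "reason"])
    if not rows:
        logger.warning("no testable sets")
        cols = ["set", "source", "id", "n_genes", "n_snps", "statistic",
                "p_value", "p_floored", "suggestive_density", "significant"]
        return pd.DataFrame(columns=cols), untested
    results = pd.DataFrame(rows)
    denominator = n_tests if n_tests is not None else len(db.sets)
    level = bonferroni_level(alpha, max(denominator, 1))
    results["significant"] = results["p_value"] < level
    results = results.sort_values(
        ["p_value", "statistic", "set"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return results, untested
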