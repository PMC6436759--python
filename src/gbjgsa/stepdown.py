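"""Step-down inference: re-testing sets after removing their top genes.

A set that is significant only through one highly associated gene (the
classic example being FGFR2 in breast cancer pathway lists) loses its signal
once that gene's SNPs are removed; a set with dispersed signal survives.
Genes are ranked by testing each unique gene as its own set, then the SNPs
belonging to the k most associated member genes are removed, the correlation
matrix is rebuilt on the survivors, and the set is re-tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assembly import assemble_set
from .containers import MappedSet
from .gof import gbj_test, single_z_pvalue
from .refpanel import ReferencePanel

__all__ = ["StepDownResult", "gene_pvalues", "stepdown_test"]

logger = logging.getLogger(__name__)


@dataclass
class StepDownResult:
    set_name: str
    k: int
    removed_genes: list
    p_after: float
    p_original: float
    still_significant: bool
    n_snps_after: int = 0

    def __post_init__(self) -> None:
        if self.k == 0 and self.p_after != self.p_original:
            raise ValueError("k = 0 must reproduce the original p-value")


def _mapped_set_pvalue(mapped: MappedSet) -> tuple[float, float]:
    if mapped.z is None or mapped.z.d == 0:
        return 0.0, 1.0
    if mapped.z.d == 1:
        return 0.0, single_z_pvalue(float(mapped.z.z[0]))
    res = gbj_test(mapped.z, mapped.sigma)
    return res.statistic, res.p_value


def gene_pvalues(
    genes, sumstats: pd.DataFrame, annotation: pd.DataFrame, panel: ReferencePanel
) -> pd.DataFrame:
    """Single-gene association: each unique gene tested as its own set.

    Genes with one retained SNP get the two-sided normal p; genes with no
    retained SNPs get p = 1 and a flag.  Returns a DataFrame (gene, p_value,
    statistic, n_snps, no_snps).
    """
    rows = []
    for gene in dict.fromkeys(genes):
        mapped = assemble_set(gene, [gene], sumstats, annotation, panel)
        if not mapped.testable or mapped.z is None or mapped.z.d == 0:
            rows.append({"gene": gene, "p_value": 1.0, "statistic": 0.0,
                         "n_snps": 0, "no_snps": True})
            continue
        stat, p = _mapped_set_pvalue(mapped)
        rows.append({"gene": gene, "p_value": p, "statistic": stat,
                     "n_snps": mapped.z.d, "no_snps": False})
    return pd.DataFrame(rows)


def _rank_genes(member_genes, gene_p: pd.DataFrame):
    """Member genes by increasing p, ties by decreasing statistic then name."""
    gp = gene_p.set_index("gene")
    ranked = []
    for g in member_genes:
        if g in gp.index:
            ranked.append((float(gp.loc[g, "p_value"]),
                           -float(gp.loc[g, "statistic"]), g))
        else:
            ranked.append((1.0, 0.0, g))
    return [g for *_k, g in sorted(ranked)]


def stepdown_test(
    mapped: MappedSet, gene_p: pd.DataFrame, k: int, threshold: float,
    panel: ReferencePanel | None = None,
) -> StepDownResult:
    """Re-test a set after removing the SNPs of its k most associated genes.

    A SNP shared between a removed and a retained gene is removed (it belongs
    to the top gene).  The correlation matrix of the survivors is rebuilt
    from the reference panel when one is supplied, otherwise taken as the
    corresponding submatrix of the original estimate (identical for
    panel-derived correlations).
    """
    if k < 0:
        raise ValueError("k >= 0")
    member_genes = [g for g, _snps in mapped.genes]
    if k >= len(member_genes):
        raise ValueError(
            f"set exhausted: cannot remove {k} of {len(member_genes)} genes"
        )
    _stat, p_orig = _mapped_set_pvalue(mapped)
    if k == 0:
        return StepDownResult(mapped.set_name, 0, [], p_orig, p_orig,
                              p_orig < threshold, mapped.n_snps)
    removed = _rank_genes(member_genes, gene_p)[:k]
    drop_snps = {s for g, snps in mapped.genes if g in removed for s in snps}
    keep_ids = [s for s in mapped.z.snp_ids if s not in drop_snps]
    if not keep_ids:
        logger.info("set %s: no SNPs remain after removing %s", mapped.set_name, removed)
        return StepDownResult(mapped.set_name, k, removed, 1.0, p_orig, False, 0)
    idx = [mapped.z.snp_ids.index(s) for s in keep_ids]
    from .containers import CorrMatrix, ZVector
    from .refpanel import approximate_correlation

    z_red = ZVector(mapped.z.z[idx], snp_ids=keep_ids)
    if panel is not None:
        sigma_red = approximate_correlation(panel, keep_ids)
    else:
        sigma_red = CorrMatrix(mapped.sigma.sigma[np.ix_(idx, idx)],
                               source=mapped.sigma.source)
    reduced = MappedSet(
        set_name=mapped.set_name,
        genes=[(g, [s for s in snps if s in set(keep_ids)])
               for g, snps in mapped.genes if g not in removed],
        z=z_red, sigma=sigma_red,
    )
    _stat2, p_after = _mapped_set_pvalue(reduced)
    return StepDownResult(mapped.set_name, k, removed, p_after, p_orig,
                          p_after < threshold, len(keep_ids))
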